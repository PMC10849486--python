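"""Ground-truthed synthetic data for exercising the curation pipeline.

Two fidelity levels share one truth schema:

* **abstract** — no images; picking and recentering are modelled directly as
  coordinate noise, so closed-form predictions (see
  :func:`duster.core.keep_probability`) can be tested exactly;
* **rendered** — micrographs with planted template particles plus white
  Gaussian noise, for end-to-end runs through the image-based classifier.

High-S/N particles carry a structured template (a disc, or a pentamer of
Gaussian lobes on a ring — a five-lobed particle of the kind small oligomeric
complexes produce); junk particles are low-amplitude random blobs: the failure
mode being emulated is low signal-to-noise, not structured contamination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from duster.particle_io import ImageMeta


@dataclass(frozen=True)
class SimParams:
    """Generator settings.

    The default design point (recentering error 3 Å for high-S/N, 60 Å for
    junk, to be curated at D_TH = 20 Å) makes the closed-form single-round
    retentions ≈ 0.99998 and ≈ 0.0274 — cleanly separable classes.

    n_high, n_junk:
        planted particles per micrograph, by S/N class.
    n_micrographs:
        number of independent scenes sharing one parameter set.
    nx, ny, pixel_size_A:
        image geometry; 1.33 Å/px is a typical data-collection pixel size.
    template:
        "pentamer" (five Gaussian lobes on a ring) or "disc".
    snr_high, snr_low:
        per-class signal-to-noise ratio: signal variance over the template
        support divided by the (unit) noise variance.
    pick_jitter_A:
        Gaussian error σ of the simulated picker, per axis.
    fp_rate, miss_rate:
        per-set picking error rates; false positives are Poisson with mean
        fp_rate × n_true, placed uniformly.
    recenter_sigma_high_A, recenter_sigma_low_A:
        abstract recentering error σ per axis for the two classes.
    """

    n_high: int = 80
    n_junk: int = 80
    n_micrographs: int = 1
    nx: int = 1280
    ny: int = 1280
    pixel_size_A: float = 1.33
    template: str = "pentamer"
    snr_high: float = 2.0
    snr_low: float = 0.002
    pick_jitter_A: float = 5.0
    fp_rate: float = 0.05
    miss_rate: float = 0.02
    recenter_sigma_high_A: float = 3.0
    recenter_sigma_low_A: float = 60.0
    min_separation_px: float = 56.0
    edge_margin_px: float = 40.0
    placement: str = "dart"  # "dart" (rejection sampling) or "grid" (jittered lattice)

    def __post_init__(self):
        for name in ("fp_rate", "miss_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("pick_jitter_A", "recenter_sigma_high_A", "recenter_sigma_low_A"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.template not in ("pentamer", "disc"):
            raise ValueError(f"unknown template {self.template!r}")
        if self.placement not in ("dart", "grid"):
            raise ValueError(f"unknown placement {self.placement!r}")


@dataclass
class SyntheticScene:
    """Planted ground truth, optionally with rendered micrographs."""

    truth: pd.DataFrame  # particle_id, micrograph_id, true_x_px, true_y_px, snr_class, template_id
    meta: ImageMeta
    params: SimParams
    seed: int
    images: Optional[dict] = None  # micrograph_id -> noisy image
    signal_images: Optional[dict] = field(default=None, repr=False)  # noiseless renders


class PackingError(RuntimeError):
    """Could not place the requested particle count at the minimum separation."""


def pentamer_template(box: int, ring_radius: float = 7.0, lobe_sigma: float = 2.6,
                      rotation: float = 0.0) -> np.ndarray:
    """Five Gaussian lobes equally spaced on a ring (five-lobed particle)."""
    ys, xs = np.mgrid[0:box, 0:box].astype(float)
    c = (box - 1) / 2.0
    out = np.zeros((box, box))
    for k in range(5):
        ang = rotation + 2 * np.pi * k / 5
        cx = c + ring_radius * np.cos(ang)
        cy = c + ring_radius * np.sin(ang)
        out += np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * lobe_sigma**2))
    return out


def disc_template(box: int, radius: float = 8.0, edge_sigma: float = 1.5) -> np.ndarray:
    """Soft-edged disc."""
    ys, xs = np.mgrid[0:box, 0:box].astype(float)
    c = (box - 1) / 2.0
    r = np.hypot(xs - c, ys - c)
    return 1.0 / (1.0 + np.exp((r - radius) / edge_sigma))


def blob_template(box: int, sigma: float) -> np.ndarray:
    """Isotropic Gaussian blob (junk model)."""
    ys, xs = np.mgrid[0:box, 0:box].astype(float)
    c = (box - 1) / 2.0
    return np.exp(-((xs - c) ** 2 + (ys - c) ** 2) / (2 * sigma**2))


def _snr_amplitude(template: np.ndarray, snr: float) -> float:
    """Amplitude making signal variance over the template support equal snr·1."""
    support = template > 0.1 * template.max()
    var = float(template[support].var()) if support.sum() > 1 else 1.0
    return float(np.sqrt(snr / max(var, 1e-12)))


def generate_scene(params: SimParams, seed: int, render: bool = True) -> SyntheticScene:
    """Plant particles (dart-throwing at the minimum separation) and render.

    Deterministic for a given ``(params, seed)``. The rendered image is the
    sum of per-particle templates, amplitude set by the requested S/N, plus
    white Gaussian noise of unit σ.
    """
    rng = np.random.default_rng(seed)
    rows = []
    images: dict = {}
    signal_images: dict = {}
    tbox = 33  # template raster size; spans the largest template comfortably
    pid = 0
    for m in range(params.n_micrographs):
        mic_id = f"mic_{m:03d}"
        centers = _place_centers(
            rng,
            params.n_high + params.n_junk,
            params.nx,
            params.ny,
            params.min_separation_px,
            params.edge_margin_px,
            mode=params.placement,
        )
        signal = np.zeros((params.ny, params.nx)) if render else None
        for i, (x, y) in enumerate(centers):
            is_high = i < params.n_high
            # template shape parameters are always drawn so the truth table is
            # identical whether or not images are rendered
            if is_high:
                rotation = float(rng.uniform(0, 2 * np.pi))
                template_id = params.template
                snr = params.snr_high
            else:
                blob_sigma = float(rng.uniform(2.0, 5.0))
                template_id = "blob"
                snr = params.snr_low
            if render:
                if not is_high:
                    tmpl = blob_template(tbox, sigma=blob_sigma)
                elif params.template == "pentamer":
                    tmpl = pentamer_template(tbox, rotation=rotation)
                else:
                    tmpl = disc_template(tbox)
            rows.append(
                {
                    "particle_id": pid,
                    "micrograph_id": mic_id,
                    "true_x_px": x,
                    "true_y_px": y,
                    "snr_class": "high" if is_high else "low_junk",
                    "template_id": template_id,
                }
            )
            pid += 1
            if render:
                _paint(signal, tmpl, x, y, _snr_amplitude(tmpl, snr))
        if render:
            noise = rng.standard_normal(signal.shape)
            signal_images[mic_id] = signal
            images[mic_id] = signal + noise
    truth = pd.DataFrame(
        rows,
        columns=["particle_id", "micrograph_id", "true_x_px", "true_y_px", "snr_class", "template_id"],
    )
    meta = ImageMeta(pixel_size_A=params.pixel_size_A, nx=params.nx, ny=params.ny)
    return SyntheticScene(
        truth=truth,
        meta=meta,
        params=params,
        seed=seed,
        images=images if render else None,
        signal_images=signal_images if render else None,
    )


def _place_centers(rng, n, nx, ny, min_sep, margin, max_tries=20000, mode="dart"):
    if min_sep <= 0:  # unconstrained placement (abstract large-n scenes)
        xs = rng.uniform(margin, nx - margin, size=n)
        ys = rng.uniform(margin, ny - margin, size=n)
        return list(zip(xs.tolist(), ys.tolist()))
    if mode == "grid":
        # jittered square lattice: O(n), separation >= min_sep/2 guaranteed;
        # the fast path for very large coordinate-level scenes
        spacing = float(min_sep)
        cols = max(1, int((nx - 2 * margin) // spacing))
        needed_rows = -(-n // cols)
        if margin + needed_rows * spacing > ny:
            raise PackingError(f"grid of {n} at spacing {spacing} exceeds {nx}x{ny}")
        idx = np.arange(n)
        gx = margin + (idx % cols) * spacing + spacing / 2
        gy = margin + (idx // cols) * spacing + spacing / 2
        gx = gx + rng.uniform(-spacing / 4, spacing / 4, size=n)
        gy = gy + rng.uniform(-spacing / 4, spacing / 4, size=n)
        order = rng.permutation(n)  # decouple class labels from lattice order
        return list(zip(gx[order].tolist(), gy[order].tolist()))
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n:
        if tries >= max_tries:
            raise PackingError(
                f"could not place {n} centers at separation {min_sep} in {nx}x{ny}"
            )
        tries += 1
        x = float(rng.uniform(margin, nx - margin))
        y = float(rng.uniform(margin, ny - margin))
        if all((x - cx) ** 2 + (y - cy) ** 2 >= min_sep**2 for cx, cy in centers):
            centers.append((x, y))
    return centers


def _paint(image: np.ndarray, template: np.ndarray, x: float, y: float, amplitude: float) -> None:
    """Add template (integer-pixel placement) centered at (x, y) in place."""
    box = template.shape[0]
    half = box // 2
    cx, cy = int(round(x)), int(round(y))
    y0, x0 = cy - half, cx - half
    ys0, xs0 = max(0, y0), max(0, x0)
    ys1, xs1 = min(image.shape[0], y0 + box), min(image.shape[1], x0 + box)
    image[ys0:ys1, xs0:xs1] += amplitude * template[ys0 - y0 : ys1 - y0, xs0 - x0 : xs1 - x0]


def measured_snr(scene: SyntheticScene, particle_id: int, support_frac: float = 0.1) -> float:
    """Estimate a planted particle's S/N from the noiseless render.

    Signal variance over the template support divided by the (unit) noise
    variance — the same definition the generator calibrates against.
    """
    if scene.signal_images is None:
        raise ValueError("scene was generated without rendering")
    row = scene.truth.set_index("particle_id").loc[particle_id]
    img = scene.signal_images[row["micrograph_id"]]
    box = 33
    half = box // 2
    cx, cy = int(round(row["true_x_px"])), int(round(row["true_y_px"]))
    patch = img[cy - half : cy + half + 1, cx - half : cx + half + 1]
    support = np.abs(patch) > support_frac * np.abs(patch).max()
    return float(patch[support].var())


def simulate_picks(scene: SyntheticScene, params: SimParams, seed: int, set_label: str) -> pd.DataFrame:
    """One independent noisy picking of the scene.

    Each true particle is picked with probability ``1 - miss_rate`` at its
    center plus Gaussian jitter; false positives are added as a Poisson count
    with mean ``fp_rate × n_true``, uniform over the field. The returned pick
    table carries a ``source_particle_id`` provenance column (−1 for false
    positives). Two calls with different seeds model the two independent
    pickings and share no pick ids.
    """
    rng = np.random.default_rng(seed)
    jitter_px = params.pick_jitter_A / params.pixel_size_A
    truth = scene.truth
    n_true = len(truth)
    picked = rng.uniform(size=n_true) >= params.miss_rate
    jit = rng.normal(0.0, jitter_px, size=(n_true, 2))
    true_part = pd.DataFrame(
        {
            "micrograph_id": truth["micrograph_id"].to_numpy()[picked],
            "x_px": (truth["true_x_px"].to_numpy() + jit[:, 0])[picked],
            "y_px": (truth["true_y_px"].to_numpy() + jit[:, 1])[picked],
            "source_particle_id": truth["particle_id"].to_numpy(dtype=int)[picked],
        }
    )
    mic_ids = np.array(sorted(truth["micrograph_id"].unique()) or ["mic_000"])
    n_fp = int(rng.poisson(params.fp_rate * n_true))
    m = params.edge_margin_px
    fp_part = pd.DataFrame(
        {
            "micrograph_id": mic_ids[rng.integers(0, len(mic_ids), size=n_fp)],
            "x_px": rng.uniform(m, params.nx - m, size=n_fp),
            "y_px": rng.uniform(m, params.ny - m, size=n_fp),
            "source_particle_id": np.full(n_fp, -1),
        }
    )
    df = pd.concat([true_part, fp_part], ignore_index=True)
    df.insert(0, "pick_id", [f"{set_label}{seed:x}:{i:06d}" for i in range(len(df))])
    df["set_label"] = str(set_label)
    return df[["pick_id", "micrograph_id", "x_px", "y_px", "set_label", "source_particle_id"]]


def abstract_recenterer(
    scene: SyntheticScene, picks: pd.DataFrame, params: SimParams, seed: int
) -> pd.DataFrame:
    """Coordinate-level recentering model (no images).

    Picks of high-S/N particles land at truth + Gaussian(σ =
    ``recenter_sigma_high_A``); junk picks and false positives land at truth
    (or the pick itself) + Gaussian(σ = ``recenter_sigma_low_A``) — encoding
    that low-S/N particles are not reproducibly recentered. Class
    probabilities are Beta(8,2) for high-S/N and Beta(2,8) for the rest.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    truth = scene.truth.set_index("particle_id")
    px = params.pixel_size_A
    n = len(picks)
    src = pd.to_numeric(picks["source_particle_id"]).astype(int).to_numpy()
    x = picks["x_px"].to_numpy(dtype=float)
    y = picks["y_px"].to_numpy(dtype=float)
    is_high = np.zeros(n, dtype=bool)
    cx, cy = x.copy(), y.copy()
    valid = src >= 0
    if valid.any():
        t = truth.reindex(src[valid])
        cx[valid] = t["true_x_px"].to_numpy(dtype=float)
        cy[valid] = t["true_y_px"].to_numpy(dtype=float)
        is_high[valid] = (t["snr_class"] == "high").to_numpy()
    sigma_px = np.where(is_high, params.recenter_sigma_high_A, params.recenter_sigma_low_A) / px
    rx = cx + rng.normal(0.0, 1.0, n) * sigma_px
    ry = cy + rng.normal(0.0, 1.0, n) * sigma_px
    prob = np.where(is_high, rng.beta(8, 2, n), rng.beta(2, 8, n))
    return pd.DataFrame(
        {
            "pick_id": picks["pick_id"].to_numpy(),
            "shift_x_px": rx - x,
            "shift_y_px": ry - y,
            "recentered_x_px": rx,
            "recentered_y_px": ry,
            "class_id": rng.integers(0, 4, n),
            "class_prob": prob,
        }
    )


class AbstractRecenterer:
    """Recenterer-protocol wrapper around :func:`abstract_recenterer`."""

    def __init__(self, scene: SyntheticScene, params: SimParams | None = None):
        self.scene = scene
        self.params = params or scene.params

    def recenter_set(self, picks: pd.DataFrame, *, seed: int) -> pd.DataFrame:
        return abstract_recenterer(self.scene, picks, self.params, seed)
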