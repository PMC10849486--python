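"""Translational reference-free 2D classification and particle recentering.

This is the stand-in for the 2D-classification step of an SPA pipeline: it
extracts boxes at picked points, alternates between (a) aligning every box to
the best class average over integer shifts via FFT cross-correlation and (b)
re-averaging the shifted members, and reports per-particle shifts, class
assignments and a per-particle class probability. Only the contract DuSTER
relies on is claimed: high-S/N particles recenter reproducibly, pure-noise
boxes do not. Rotational alignment, CTF handling and likelihood weighting are
deliberately out of scope.

Coordinate/shift convention: ``recentered = picked + shift`` (both in px),
where ``shift`` is the estimated displacement of the particle center from the
picked point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from duster.particle_io import ImageMeta

#: assignment-change fraction below which iteration stops
CONVERGENCE_FRACTION = 0.005


@dataclass
class ClassModel:
    """K class-average images plus bookkeeping from the iteration."""

    averages: np.ndarray  # (K, box, box)
    member_counts: np.ndarray  # (K,)
    change_log: list[float] = field(default_factory=list)  # per-iteration assignment churn
    probabilities: np.ndarray | None = None  # (N, K) final per-particle class posterior


def extract_stack(
    image: np.ndarray,
    picks: pd.DataFrame,
    meta: ImageMeta,
    box_px: int | None = None,
    edge_policy: str = "skip",
) -> tuple[np.ndarray, list, list]:
    """Extract one normalized box per pick.

    Each box is mean-subtracted and variance-normalized (an all-constant box
    becomes all zeros rather than NaN). Picks whose box crosses the image edge
    are dropped under the default ``"skip"`` policy or kept via reflective
    padding under ``"pad-reflect"``.

    Returns ``(stack, pick_ids, dropped_ids)`` where ``stack[i]`` belongs to
    ``pick_ids[i]``.
    """
    if box_px is None:
        box_px = meta.box_px
    if box_px < 2:
        raise ValueError(f"box_px must be >= 2, got {box_px}")
    if edge_policy not in ("skip", "pad-reflect"):
        raise ValueError(f"unknown edge_policy {edge_policy!r}")
    half = box_px // 2
    ny, nx = image.shape
    if edge_policy == "pad-reflect":
        padded = np.pad(image, box_px, mode="reflect")
    boxes, kept_ids, dropped_ids = [], [], []
    for pick_id, x, y in zip(picks["pick_id"], picks["x_px"], picks["y_px"]):
        cx, cy = int(round(x)), int(round(y))
        x0, y0 = cx - half, cy - half
        if x0 < 0 or y0 < 0 or x0 + box_px > nx or y0 + box_px > ny:
            if edge_policy == "skip":
                dropped_ids.append(pick_id)
                continue
            box = padded[y0 + box_px : y0 + 2 * box_px, x0 + box_px : x0 + 2 * box_px]
        else:
            box = image[y0 : y0 + box_px, x0 : x0 + box_px]
        boxes.append(np.asarray(box, dtype=np.float64))
        kept_ids.append(pick_id)
    if boxes:
        stack = np.stack(boxes)
        stack -= stack.mean(axis=(1, 2), keepdims=True)
        sd = stack.std(axis=(1, 2), keepdims=True)
        np.divide(stack, sd, out=stack, where=sd > 1e-12)
        stack[np.broadcast_to(sd <= 1e-12, stack.shape)] = 0.0
    else:
        stack = np.zeros((0, box_px, box_px))
    return stack, kept_ids, dropped_ids


def classify_translational(
    stack: np.ndarray,
    K: int,
    max_shift_px: int,
    n_iter: int = 20,
    seed: int = 0,
    tau: float = 0.05,
    shift_mode: str = "argmax",
    shift_temperature: float = 1.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, ClassModel]:
    """Iterative translational K-class alignment of a box stack.

    Starting from a seeded random partition, each iteration scores every
    particle against every class average at all integer shifts with
    ``|dx|, |dy| <= max_shift_px`` (normalized cross-correlation via FFT),
    assigns the argmax class and shift, converts per-class best correlations
    into a softmax class probability (temperature ``tau`` times the
    correlation scale), and re-averages shifted members. A class that loses
    all members is reseeded from the worst-fitting particle. Stops after
    ``n_iter`` iterations or when fewer than 0.5% of assignments change.
    Deterministic for a given ``(stack, K, seed)``.

    ``shift_mode`` selects how the *reported* shift is produced once the
    iteration has converged. ``"argmax"`` returns the best correlation peak.
    ``"sample"`` draws the shift from the Boltzmann distribution over the
    assigned class's correlation field (temperature ``shift_temperature``,
    whose natural scale is 1.0 — the standard deviation of pure-noise
    correlations for variance-normalized boxes against unit-norm averages).
    Sampling emulates the stochastic shift assignment of maximum-likelihood
    classifiers: a particle with a decisive correlation peak is reported at
    that peak, while a particle whose correlation field is noise-flat gets an
    essentially random position in the search window — so replicate runs with
    different seeds recenter such particles irreproducibly even though they
    see the same underlying image. Still deterministic given the seed.

    Returns ``(shifts, class_ids, class_probs, model)`` with ``shifts`` shaped
    ``(N, 2)`` as ``(dx, dy)``.
    """
    n, box, box2 = stack.shape
    if box != box2:
        raise ValueError("boxes must be square")
    if shift_mode not in ("argmax", "sample"):
        raise ValueError(f"unknown shift_mode {shift_mode!r}")
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if K > n:
        raise ValueError(f"K={K} exceeds number of particles ({n})")
    if max_shift_px >= box // 2:
        raise ValueError(f"max_shift_px={max_shift_px} too large for box {box}")
    rng = np.random.default_rng(seed)
    assign = rng.integers(0, K, size=n)
    assign[:K] = np.arange(K)  # guarantee a non-empty start for every class
    shifts = np.zeros((n, 2), dtype=int)

    freq_y = np.fft.fftfreq(box) * box
    dy_grid = np.rint(freq_y).astype(int)  # signed shift value per FFT index
    allowed = np.abs(dy_grid) <= max_shift_px
    shift_mask = np.outer(allowed, allowed)  # (box, box) in (dy, dx) index order

    f_stack = np.fft.rfft2(stack)
    model = ClassModel(
        averages=np.zeros((K, box, box)), member_counts=np.zeros(K, dtype=int)
    )
    probs = np.full((n, K), 1.0 / K)
    for _ in range(max(1, n_iter)):
        averages = _compute_averages(stack, assign, shifts, K)
        f_avg = np.fft.rfft2(averages)
        # corr[i, k, dy, dx] = <box_i shifted by (dy,dx), average_k>
        corr = np.fft.irfft2(f_stack[:, None] * np.conj(f_avg)[None], s=(box, box))
        corr[:, :, ~shift_mask] = -np.inf
        flat = corr.reshape(n, K, -1)
        best_flat = flat.argmax(axis=2)  # (n, K)
        best_corr = np.take_along_axis(flat, best_flat[:, :, None], axis=2)[:, :, 0]
        new_assign = best_corr.argmax(axis=1)
        # reseed empty classes from the worst-fitting particle
        fit = best_corr[np.arange(n), new_assign]
        for k in range(K):
            if not (new_assign == k).any():
                worst = int(np.argmin(fit))
                new_assign[worst] = k
                fit[worst] = np.inf
        idx = best_flat[np.arange(n), new_assign]
        new_shifts = np.column_stack([dy_grid[idx % box], dy_grid[idx // box]])  # (dx, dy)
        scale = max(float(np.std(best_corr)), 1e-9)
        logits = (best_corr - best_corr.max(axis=1, keepdims=True)) / (tau * scale)
        probs = np.exp(logits)
        probs /= probs.sum(axis=1, keepdims=True)
        changed = float(np.mean(new_assign != assign)) if len(assign) else 0.0
        assign, shifts = new_assign, new_shifts
        model.change_log.append(changed)
        if changed < CONVERGENCE_FRACTION and len(model.change_log) > 1:
            break
    model.averages = _compute_averages(stack, assign, shifts, K)
    model.member_counts = np.bincount(assign, minlength=K)
    model.probabilities = probs
    class_probs = probs[np.arange(n), assign]
    if shift_mode == "sample":
        shifts = _sample_shifts(
            stack, model.averages, assign, dy_grid, shift_mask, shift_temperature, rng
        )
    return shifts, assign, class_probs, model


def _sample_shifts(stack, averages, assign, dy_grid, shift_mask, temperature, rng):
    """Draw each particle's shift from exp(corr/T) over its class's field."""
    n, box, _ = stack.shape
    f_stack = np.fft.rfft2(stack)
    f_avg = np.fft.rfft2(averages)
    shifts = np.zeros((n, 2), dtype=int)
    flat_mask = shift_mask.ravel()
    allowed_idx = np.flatnonzero(flat_mask)
    for i in range(n):
        corr = np.fft.irfft2(f_stack[i] * np.conj(f_avg[assign[i]]), s=(box, box))
        logits = corr.ravel()[allowed_idx] / max(temperature, 1e-9)
        logits -= logits.max()
        w = np.exp(logits)
        w /= w.sum()
        pick = allowed_idx[rng.choice(len(allowed_idx), p=w)]
        shifts[i] = (dy_grid[pick % box], dy_grid[pick // box])  # (dx, dy)
    return shifts


def _compute_averages(stack: np.ndarray, assign: np.ndarray, shifts: np.ndarray, K: int) -> np.ndarray:
    """Average shift-aligned members per class, then fix the translational gauge.

    Each average is rolled so that its intensity centroid sits at the box
    center: translation-only alignment is invariant to a constant offset of
    (average, all shifts), and an off-center average would bias every
    recentered point by that offset.
    """
    n, box, _ = stack.shape
    averages = np.zeros((K, box, box))
    counts = np.bincount(assign, minlength=K)
    for i in range(n):
        dx, dy = shifts[i]
        averages[assign[i]] += np.roll(stack[i], (-dy, -dx), axis=(0, 1))
    for k in range(K):
        if counts[k] == 0:
            continue
        avg = averages[k] / counts[k]
        avg -= avg.mean()
        norm = np.linalg.norm(avg)
        if norm > 1e-12:
            avg /= norm
            avg = np.roll(avg, _centroid_offset(avg), axis=(0, 1))
        averages[k] = avg
    return averages


def _centroid_offset(avg: np.ndarray) -> tuple[int, int]:
    """Integer (dy, dx) roll that moves the positive-intensity centroid to the center.

    "Center" is index ``box // 2`` — the in-box position of the pick under the
    extraction convention — so a particle sitting exactly on its pick gets
    shift (0, 0) rather than a spurious half-pixel gauge offset.
    """
    box = avg.shape[0]
    w = np.clip(avg, 0, None) ** 2
    total = w.sum()
    if total <= 0:
        return (0, 0)
    ys, xs = np.mgrid[0:box, 0:box]
    cy = float((w * ys).sum() / total)
    cx = float((w * xs).sum() / total)
    center = box // 2
    return (int(round(center - cy)), int(round(center - cx)))


def recenter(picks: pd.DataFrame, result: pd.DataFrame) -> pd.DataFrame:
    """Replace pick coordinates by their recentered coordinates.

    Every pick must have a result row (drop edge-skipped picks first);
    ``pick_id``, ``set_label`` and payload columns are preserved.
    """
    missing = set(picks["pick_id"]) - set(result["pick_id"])
    if missing:
        raise ValueError(f"no recentering result for pick_id(s): {sorted(missing)[:5]}")
    merged = picks.merge(
        result[["pick_id", "recentered_x_px", "recentered_y_px"]], on="pick_id", how="left"
    )
    out = picks.copy()
    out["x_px"] = merged["recentered_x_px"].to_numpy()
    out["y_px"] = merged["recentered_y_px"].to_numpy()
    return out


def recenter_micrographs(
    images: dict[str, np.ndarray],
    picks: pd.DataFrame,
    meta: ImageMeta,
    K: int = 6,
    max_shift_px: int = 20,
    n_iter: int = 20,
    seed: int = 0,
    tau: float = 0.05,
    box_px: int | None = None,
    edge_policy: str = "skip",
    shift_mode: str = "sample",
    shift_temperature: float = 1.5,
) -> pd.DataFrame:
    """Extract boxes from every micrograph, classify them jointly, and return
    a RecenterResult table (picks whose box crossed an edge are absent).

    All micrographs' particles enter one classification, mirroring how an SPA
    2D classification pools a whole dataset.
    """
    stacks, ids, origins = [], [], []
    for mic_id, group in picks.groupby("micrograph_id", sort=True):
        if mic_id not in images:
            raise KeyError(f"no image supplied for micrograph {mic_id!r}")
        stack, kept, _ = extract_stack(images[mic_id], group, meta, box_px, edge_policy)
        if len(kept):
            stacks.append(stack)
            ids.extend(kept)
            sub = group.set_index("pick_id")
            origins.extend(
                (float(sub.at[pid, "x_px"]), float(sub.at[pid, "y_px"])) for pid in kept
            )
    if not stacks:
        return pd.DataFrame(
            columns=[
                "pick_id", "shift_x_px", "shift_y_px",
                "recentered_x_px", "recentered_y_px", "class_id", "class_prob",
            ]
        )
    stack = np.concatenate(stacks)
    k_eff = min(K, len(stack))
    shifts, class_ids, class_probs, _ = classify_translational(
        stack, k_eff, max_shift_px, n_iter=n_iter, seed=seed, tau=tau,
        shift_mode=shift_mode, shift_temperature=shift_temperature,
    )
    origins = np.asarray(origins)
    return pd.DataFrame(
        {
            "pick_id": ids,
            "shift_x_px": shifts[:, 0].astype(float),
            "shift_y_px": shifts[:, 1].astype(float),
            "recentered_x_px": origins[:, 0] + shifts[:, 0],
            "recentered_y_px": origins[:, 1] + shifts[:, 1],
            "class_id": class_ids,
            "class_prob": class_probs,
        }
    )


class ImageRecenterer:
    """Recenterer backed by the built-in translational classifier.

    Satisfies the recenterer protocol used by the curation loop: calling
    ``recenter_set(picks, seed=...)`` runs an independent classification of
    that pick set and returns its RecenterResult table.
    """

    def __init__(
        self,
        images: dict[str, np.ndarray],
        meta: ImageMeta,
        K: int = 6,
        max_shift_px: int = 20,
        n_iter: int = 20,
        tau: float = 0.05,
        box_px: int | None = None,
        edge_policy: str = "skip",
        shift_mode: str = "sample",
        shift_temperature: float = 1.5,
    ):
        self.images = images
        self.meta = meta
        self.K = K
        self.max_shift_px = max_shift_px
        self.n_iter = n_iter
        self.tau = tau
        self.box_px = box_px
        self.edge_policy = edge_policy
        self.shift_mode = shift_mode
        self.shift_temperature = shift_temperature

    def recenter_set(self, picks: pd.DataFrame, *, seed: int) -> pd.DataFrame:
        return recenter_micrographs(
            self.images,
            picks,
            self.meta,
            K=self.K,
            max_shift_px=self.max_shift_px,
            n_iter=self.n_iter,
            seed=seed,
            tau=self.tau,
            box_px=self.box_px,
            edge_policy=self.edge_policy,
            shift_mode=self.shift_mode,
            shift_temperature=self.shift_temperature,
        )
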