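"""Scoring of curation outputs against synthetic ground truth.

Metric conventions (chosen to avoid ambiguity between picks and particles):
**precision** is computed over picks — the fraction of kept picks whose source
particle is high-S/N; **recall** over particles — the fraction of high-S/N
particles with at least one kept pick. A particle has one pick per set, so
either pick surviving counts toward recall.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from duster.core import CurationConfig, CurationReport, match_pairs
from duster.particle_io import ImageMeta
from duster.synthetic import SyntheticScene


def precision_recall(
    kept_ids,
    picks: pd.DataFrame,
    scene: SyntheticScene,
    match_radius_A: float | None = None,
) -> dict:
    """Score a kept-pick set against the scene's planted truth.

    Provenance (the ``source_particle_id`` column written by the simulator)
    is used when present; otherwise each kept pick is attributed to the
    nearest planted particle within ``match_radius_A``. An empty kept set has
    undefined precision (reported as ``None``) and recall 0.

    Returns ``{"precision", "recall", "f1", "n_kept"}``.
    """
    kept = picks[picks["pick_id"].isin(set(kept_ids))]
    truth = scene.truth
    high = truth[truth["snr_class"] == "high"]
    if len(kept) == 0:
        return {"precision": None, "recall": 0.0, "f1": None, "n_kept": 0}
    if "source_particle_id" in kept.columns:
        src = pd.to_numeric(kept["source_particle_id"]).astype(int).to_numpy()
    else:
        if match_radius_A is None:
            raise ValueError("picks lack provenance; match_radius_A is required")
        src = _radius_match(kept, truth, match_radius_A, scene.meta.pixel_size_A)
    high_ids = set(high["particle_id"].astype(int))
    is_high_pick = np.array([s in high_ids for s in src])
    precision = float(is_high_pick.mean())
    covered = {int(s) for s in src if s in high_ids}
    recall = float(len(covered) / len(high_ids)) if high_ids else 0.0
    denom = precision + recall
    f1 = float(2 * precision * recall / denom) if denom > 0 else 0.0
    return {"precision": precision, "recall": recall, "f1": f1, "n_kept": int(len(kept))}


def _radius_match(kept: pd.DataFrame, truth: pd.DataFrame, radius_A: float, px: float) -> np.ndarray:
    """Attribute each kept pick to the nearest planted particle within radius (−1 if none)."""
    out = np.full(len(kept), -1)
    for mic_id, group in kept.groupby("micrograph_id"):
        t = truth[truth["micrograph_id"] == mic_id]
        if len(t) == 0:
            continue
        tree = cKDTree(t[["true_x_px", "true_y_px"]].to_numpy(dtype=float) * px)
        d, idx = tree.query(group[["x_px", "y_px"]].to_numpy(dtype=float) * px)
        rows = [kept.index.get_loc(i) for i in group.index]
        hit = d <= radius_A
        out[np.asarray(rows)[hit]] = t["particle_id"].to_numpy(dtype=int)[idx[hit]]
    return out


def retention_curve(
    recA: pd.DataFrame,
    recB: pd.DataFrame,
    meta: ImageMeta,
    d_th_grid,
    base_cfg: CurationConfig | None = None,
    picks_for_truth: pd.DataFrame | None = None,
    scene: SyntheticScene | None = None,
) -> pd.DataFrame:
    """Retention (and optionally precision) as a function of D_TH.

    ``recA``/``recB`` are already-recentered pick tables; the same single
    recentering is reused across the whole grid so the curve reflects only
    the threshold, not re-randomization. The grid must be strictly
    increasing. Retention is exactly non-decreasing along the grid.
    """
    grid = [float(g) for g in d_th_grid]
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("d_th grid must be strictly increasing")
    base = base_cfg or CurationConfig()
    rows = []
    for d_th in grid:
        if d_th <= 0:
            # a strict "< D_TH" comparison keeps nothing at threshold zero
            rows.append({"d_th_A": d_th, "n_pairs": 0, "retention": 0.0, "precision": None})
            continue
        cfg = CurationConfig(
            d_th_A=d_th,
            rounds=1,
            prob_floor=base.prob_floor,
            match_mode=base.match_mode,
            seed=base.seed,
        )
        match = match_pairs(recA, recB, meta, cfg)
        row = {
            "d_th_A": d_th,
            "n_pairs": match.stats["n_pairs"],
            "retention": match.stats["retention_fraction"],
            "precision": None,
        }
        if scene is not None and picks_for_truth is not None:
            kept = list(match.kept_A["pick_id"]) + list(match.kept_B["pick_id"])
            row["precision"] = precision_recall(kept, picks_for_truth, scene)["precision"]
        rows.append(row)
    return pd.DataFrame(rows)


def report_to_json(report: CurationReport, path) -> None:
    """Serialize a curation report (config echo, per-round stats, kept ids)."""
    payload = {
        "config": report.config,
        "seed": report.seed,
        "stop_reason": report.stop_reason,
        "warning": report.warning,
        "rounds": report.rounds,
        "kept_ids_A": [str(i) for i in report.kept_ids_A],
        "kept_ids_B": [str(i) for i in report.kept_ids_B],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, allow_nan=False, default=_jsonify)
        fh.write("\n")


def _jsonify(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        v = float(value)
        return None if np.isnan(v) else v
    raise TypeError(f"not JSON serializable: {type(value)}")


def write_round_table(report: CurationReport, path) -> None:
    report.to_frame().to_csv(path, index=False)


def plot_retention_curve(curve: pd.DataFrame, path) -> None:
    """Static retention-vs-D_TH plot (precision overlaid when available)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curve["d_th_A"], curve["retention"], marker="o", label="retention")
    if curve["precision"].notna().any():
        ax.plot(curve["d_th_A"], curve["precision"], marker="s", label="precision")
    ax.set_xlabel(r"$D_{TH}$ (Å)")
    ax.set_ylabel("fraction")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_distance_histograms(per_round_D: dict[int, np.ndarray], d_th_A: float, path) -> None:
    """Histogram of pair distances D per curation round."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for rnd, d in sorted(per_round_D.items()):
        if len(d):
            ax.hist(d, bins=30, histtype="step", label=f"round {rnd}")
    ax.axvline(d_th_A, color="k", ls="--", lw=1, label=r"$D_{TH}$")
    ax.set_xlabel("D (Å)")
    ax.set_ylabel("pairs")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_probability_scatter(results: list[pd.DataFrame], floor: float, path) -> None:
    """Replicate-1 vs replicate-2 class-probability scatter with the floor marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    merged = results[0].merge(results[1], on="pick_id", suffixes=("_1", "_2"))
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(merged["class_prob_1"], merged["class_prob_2"], s=4, alpha=0.4)
    ax.axvline(floor, color="r", ls="--", lw=1)
    ax.axhline(floor, color="r", ls="--", lw=1)
    ax.set_xlabel("class probability (replicate 1)")
    ax.set_ylabel("class probability (replicate 2)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
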