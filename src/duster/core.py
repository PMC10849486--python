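"""The DuSTER curation algorithm.

Two independent pickings (sets A and B) of the same micrographs are recentered
independently; the distance D (in Å) between a recentered A-point and a
recentered B-point on the same micrograph measures how reproducibly that
putative particle was recentered. Picks participating in a one-to-one cross-set
pair with D strictly shorter than the threshold D_TH are kept; everything else
is rejected. Repeating the recenter→match→split cycle drives out low-S/N
particles, whose recentering is essentially random.

Matching model: within each micrograph the candidate graph contains every
cross-set pair with D < D_TH; ``match_pairs`` returns the exact optimal
one-to-one matching that first maximizes the number of pairs and then, among
those, minimizes the total distance (solved per connected component with the
Hungarian algorithm). This is deterministic, symmetric in A/B (up to exact
distance ties) and monotone in D_TH. A ``pooled_cluster`` mode reproduces the
semantics of duplicate-removal tools that pool both sets and single-linkage
cluster at the separation distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from duster.particle_io import ImageMeta


class Recenterer(Protocol):
    """A recentering engine: one independent run over one pick set."""

    def recenter_set(self, picks: pd.DataFrame, *, seed: int) -> pd.DataFrame:
        """Return a RecenterResult table covering the given picks.

        Picks may be absent from the result only if the engine dropped them
        (e.g. extraction box crossing the image edge); such picks are treated
        as rejected by the calling round.
        """
        ...


@dataclass(frozen=True)
class CurationConfig:
    """Parameters of a curation run.

    d_th_A:
        threshold distance D_TH in Å; a pair is kept iff D < d_th_A (strict).
        Published values: 20 Å for 2D-classification recentering, 15 Å for 3D.
    rounds:
        number of recenter→match cycles (7 for the published 2D runs, 6 for 3D).
    prob_floor:
        class-probability floor for :func:`probability_filter` (default 0.3).
    n_replicates:
        replicate classifications per duplicated filter (default 2).
    match_mode:
        "mutual_nn" (optimal one-to-one, default) or "pooled_cluster".
    same_set_dedup_A:
        optional same-set minimum separation in Å applied before matching.
    comprehensive_R:
        recenterings per set in :func:`comprehensive_duster` (3 → nine
        cross-set combinations).
    combine_rule:
        how comprehensive mode combines per-combination kept sets
        ("intersection" default, or "union").
    """

    d_th_A: float = 20.0
    rounds: int = 7
    prob_floor: float = 0.3
    n_replicates: int = 2
    match_mode: str = "mutual_nn"
    same_set_dedup_A: float | None = None
    comprehensive_R: int = 1
    combine_rule: str = "intersection"
    seed: int = 0

    def __post_init__(self):
        if self.d_th_A <= 0:
            raise ValueError(f"d_th_A must be > 0, got {self.d_th_A}")
        if not 0.0 <= self.prob_floor <= 1.0:
            raise ValueError(f"prob_floor must be in [0,1], got {self.prob_floor}")
        if self.rounds < 1:
            raise ValueError(f"rounds must be >= 1, got {self.rounds}")
        if self.comprehensive_R < 1:
            raise ValueError(f"comprehensive_R must be >= 1, got {self.comprehensive_R}")
        if self.match_mode not in ("mutual_nn", "pooled_cluster"):
            raise ValueError(f"unknown match_mode {self.match_mode!r}")
        if self.combine_rule not in ("intersection", "union"):
            raise ValueError(f"unknown combine_rule {self.combine_rule!r}")


@dataclass
class MatchResult:
    """Outcome of one cross-set distance matching."""

    pairs: pd.DataFrame  # columns pick_id_A, pick_id_B, D_A
    kept_A: pd.DataFrame
    kept_B: pd.DataFrame
    rejected_A: pd.DataFrame
    rejected_B: pd.DataFrame
    stats: dict


@dataclass
class CurationReport:
    """Per-round statistics and the final kept picks of a curation run."""

    rounds: list[dict] = field(default_factory=list)
    kept_ids_A: list = field(default_factory=list)
    kept_ids_B: list = field(default_factory=list)
    config: dict = field(default_factory=dict)
    seed: int = 0
    stop_reason: str = "completed"
    warning: str | None = None
    kept_A: pd.DataFrame | None = None  # final curated tables, recentered coords
    kept_B: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rounds)


def keep_probability(sigma_A: float, d_th_A: float) -> float:
    """Probability that one particle's two recentered points fall within D_TH.

    With isotropic Gaussian recentering error of std ``sigma_A`` per axis and
    per point, the A−B difference is Gaussian with variance ``2 sigma^2`` per
    axis, so D^2 is exponential and

        P(D < D_TH) = 1 − exp(−D_TH² / (4 σ²)).

    This is the single-round retention of an isolated particle picked once in
    each set.
    """
    if sigma_A <= 0:
        raise ValueError(f"sigma_A must be > 0, got {sigma_A}")
    return float(1.0 - np.exp(-(d_th_A**2) / (4.0 * sigma_A**2)))


def match_pairs(
    recA: pd.DataFrame,
    recB: pd.DataFrame,
    meta: ImageMeta,
    cfg: CurationConfig,
) -> MatchResult:
    """Match recentered picks across the two sets, micrograph by micrograph.

    ``recA``/``recB`` are pick tables whose ``x_px, y_px`` already hold the
    recentered coordinates. Distances are ``px * meta.pixel_size_A``. Only
    pairs with D < cfg.d_th_A (strict) are eligible.
    """
    recA = _maybe_dedup(recA, meta, cfg)
    recB = _maybe_dedup(recB, meta, cfg)
    pair_rows: list[tuple] = []
    kept_ids_A: set = set()
    kept_ids_B: set = set()
    for mic_id in sorted(set(recA["micrograph_id"]) | set(recB["micrograph_id"])):
        a = recA[recA["micrograph_id"] == mic_id]
        b = recB[recB["micrograph_id"] == mic_id]
        if len(a) == 0 or len(b) == 0:
            continue
        if cfg.match_mode == "pooled_cluster":
            rows, ids_a, ids_b = _match_pooled(a, b, meta.pixel_size_A, cfg.d_th_A)
            kept_ids_A |= ids_a
            kept_ids_B |= ids_b
        else:
            rows = _match_optimal(a, b, meta.pixel_size_A, cfg.d_th_A)
            kept_ids_A |= {r[0] for r in rows}
            kept_ids_B |= {r[1] for r in rows}
        pair_rows.extend(rows)
    pairs = pd.DataFrame(pair_rows, columns=["pick_id_A", "pick_id_B", "D_A"])
    pairs = pairs.sort_values(["D_A", "pick_id_A"], kind="mergesort").reset_index(drop=True)
    kept_A = recA[recA["pick_id"].isin(kept_ids_A)]
    kept_B = recB[recB["pick_id"].isin(kept_ids_B)]
    rejected_A = recA[~recA["pick_id"].isin(kept_ids_A)]
    rejected_B = recB[~recB["pick_id"].isin(kept_ids_B)]
    n_in = len(recA) + len(recB)
    stats = {
        "n_in_A": len(recA),
        "n_in_B": len(recB),
        "n_pairs": len(pairs),
        "median_D": float(pairs["D_A"].median()) if len(pairs) else float("nan"),
        "retention_fraction": ((len(kept_A) + len(kept_B)) / n_in) if n_in else 0.0,
    }
    return MatchResult(pairs, kept_A, kept_B, rejected_A, rejected_B, stats)


def _coords_A(df: pd.DataFrame, pixel_size_A: float) -> np.ndarray:
    return df[["x_px", "y_px"]].to_numpy(dtype=float) * pixel_size_A


def _candidate_edges(a_xy: np.ndarray, b_xy: np.ndarray, d_th: float):
    """All cross-set index pairs with D strictly below threshold."""
    tree = cKDTree(b_xy)
    edges = []
    for i, neighbors in enumerate(tree.query_ball_point(a_xy, r=d_th)):
        for j in neighbors:
            d = float(np.hypot(*(a_xy[i] - b_xy[j])))
            if d < d_th:
                edges.append((i, j, d))
    return edges


def _match_optimal(a: pd.DataFrame, b: pd.DataFrame, pixel_size_A: float, d_th: float):
    """Exact max-cardinality, min-total-D one-to-one matching on one micrograph.

    The candidate graph is split into connected components; each component is
    solved with the Hungarian algorithm, non-candidate pairs carrying a
    penalty large enough that cardinality dominates total distance.
    """
    a_xy = _coords_A(a, pixel_size_A)
    b_xy = _coords_A(b, pixel_size_A)
    edges = _candidate_edges(a_xy, b_xy, d_th)
    if not edges:
        return []
    a_ids = a["pick_id"].to_numpy()
    b_ids = b["pick_id"].to_numpy()
    # union-find over the bipartite candidate graph
    parent: dict = {}

    def find(u):
        while parent.setdefault(u, u) != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    for i, j, _ in edges:
        ri, rj = find(("a", i)), find(("b", j))
        if ri != rj:
            parent[ri] = rj
    components: dict = {}
    for i, j, d in edges:
        components.setdefault(find(("a", i)), []).append((i, j, d))
    out = []
    for comp_edges in components.values():
        ai = sorted({i for i, _, _ in comp_edges})
        bj = sorted({j for _, j, _ in comp_edges})
        if len(comp_edges) == 1:
            i, j, d = comp_edges[0]
            out.append((a_ids[i], b_ids[j], d))
            continue
        penalty = d_th * (len(ai) + len(bj) + 1)
        cost = np.full((len(ai), len(bj)), penalty)
        amap = {i: r for r, i in enumerate(ai)}
        bmap = {j: c for c, j in enumerate(bj)}
        for i, j, d in comp_edges:
            cost[amap[i], bmap[j]] = d
        rows, cols = linear_sum_assignment(cost)
        for r, c in zip(rows, cols):
            if cost[r, c] < d_th:
                out.append((a_ids[ai[r]], b_ids[bj[c]], float(cost[r, c])))
    return out


def _match_pooled(a: pd.DataFrame, b: pd.DataFrame, pixel_size_A: float, d_th: float):
    """Pooled single-linkage clustering at D_TH; keep clusters spanning both sets.

    Mirrors the semantics of running a duplicate-removal tool on the pooled
    sets and retaining the "duplicates": every pick in a spanning cluster is
    kept (not only one-to-one matched ones). Pair distances for reporting are
    the optimal one-to-one matching restricted to the kept clusters.

    Returns ``(pair_rows, kept_ids_a, kept_ids_b)``.
    """
    a_xy = _coords_A(a, pixel_size_A)
    b_xy = _coords_A(b, pixel_size_A)
    xy = np.vstack([a_xy, b_xy])
    n_a = len(a_xy)
    labels = np.arange(len(xy))

    def find(u):
        while labels[u] != u:
            labels[u] = labels[labels[u]]
            u = labels[u]
        return u

    tree = cKDTree(xy)
    for u, v in tree.query_pairs(r=d_th):
        if np.hypot(*(xy[u] - xy[v])) < d_th:
            labels[find(u)] = find(v)
    roots = np.array([find(u) for u in range(len(xy))])
    keep_roots = {
        r
        for r in np.unique(roots)
        if (roots[:n_a] == r).any() and (roots[n_a:] == r).any()
    }
    out = []
    kept_a: set = set()
    kept_b: set = set()
    for r in keep_roots:
        sub_a = a[roots[:n_a] == r]
        sub_b = b[roots[n_a:] == r]
        kept_a |= set(sub_a["pick_id"])
        kept_b |= set(sub_b["pick_id"])
        out.extend(_match_optimal(sub_a, sub_b, pixel_size_A, d_th))
    return out, kept_a, kept_b


def _maybe_dedup(rec: pd.DataFrame, meta: ImageMeta, cfg: CurationConfig) -> pd.DataFrame:
    """Optional same-set near-duplicate removal (keep the first by pick_id)."""
    if not cfg.same_set_dedup_A:
        return rec
    drop_ids: set = set()
    for _, group in rec.groupby("micrograph_id"):
        g = group.sort_values("pick_id", kind="mergesort")
        ids = g["pick_id"].to_numpy()
        tree = cKDTree(_coords_A(g, meta.pixel_size_A))
        removed: set = set()
        for u, v in sorted(tree.query_pairs(r=cfg.same_set_dedup_A)):
            if u not in removed:
                removed.add(v)
        drop_ids.update(ids[sorted(removed)])
    return rec[~rec["pick_id"].isin(drop_ids)]


def duster_round(
    picksA: pd.DataFrame,
    picksB: pd.DataFrame,
    recenterer: Recenterer,
    cfg: CurationConfig,
    meta: ImageMeta,
    seed_pair: tuple[int, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, MatchResult]:
    """One curation cycle: recenter each set independently, match, split.

    Each surviving set keeps its own recentered coordinates for the next
    round, mirroring the split of curated particles back into two sets for
    independent re-extraction. Picks the engine dropped (no result row) count
    as rejected.
    """
    from duster.recenter2d import recenter as _apply_shifts

    if seed_pair is None:
        sa, sb = _derive_seeds(cfg.seed, 2)
    else:
        sa, sb = seed_pair
    recenteredAB = []
    for picks, s in ((picksA, sa), (picksB, sb)):
        result = recenterer.recenter_set(picks, seed=int(s))
        covered = picks[picks["pick_id"].isin(result["pick_id"])]
        recenteredAB.append(_apply_shifts(covered, result))
    recA, recB = recenteredAB
    match = match_pairs(recA, recB, meta, cfg)
    match.stats["n_dropped_A"] = len(picksA) - len(recA)
    match.stats["n_dropped_B"] = len(picksB) - len(recB)
    return match.kept_A, match.kept_B, match


def run_duster(
    picksA: pd.DataFrame,
    picksB: pd.DataFrame,
    recenterer: Recenterer,
    cfg: CurationConfig,
    meta: ImageMeta,
) -> CurationReport:
    """Run ``cfg.rounds`` curation cycles, logging per-round statistics.

    Stops early when a round keeps 100% of its survivors (converged) or when
    everything has been eliminated (reported as a warning state, not an
    exception).
    """
    report = CurationReport(config=_config_dict(cfg), seed=cfg.seed)
    seeds = _derive_seeds(cfg.seed, 2 * cfg.rounds)
    curA, curB = picksA, picksB
    for rnd in range(cfg.rounds):
        if len(curA) == 0 or len(curB) == 0:
            report.warning = "all particles eliminated"
            report.stop_reason = "empty"
            break
        pair = (seeds[2 * rnd], seeds[2 * rnd + 1])
        curA, curB, match = duster_round(curA, curB, recenterer, cfg, meta, seed_pair=pair)
        report.rounds.append(
            {
                "round": rnd + 1,
                "n_in_A": match.stats["n_in_A"],
                "n_in_B": match.stats["n_in_B"],
                "n_pairs": match.stats["n_pairs"],
                "retention": match.stats["retention_fraction"],
                "median_D_A": match.stats["median_D"],
            }
        )
        if match.stats["retention_fraction"] >= 1.0 and rnd + 1 < cfg.rounds:
            report.stop_reason = "converged (100% retention)"
            break
    if len(curA) == 0 and len(curB) == 0 and report.warning is None and cfg.rounds > 0:
        if not report.rounds or report.rounds[-1]["n_pairs"] == 0:
            report.warning = "all particles eliminated"
    report.kept_ids_A = list(curA["pick_id"])
    report.kept_ids_B = list(curB["pick_id"])
    report.kept_A, report.kept_B = curA, curB
    return report


def probability_filter(results: Sequence[pd.DataFrame], cfg: CurationConfig) -> list:
    """Duplicated class-probability filtering.

    A pick is removed iff its class probability is below ``cfg.prob_floor`` in
    ALL replicate classifications; being above the floor in any single
    replicate rescues it (this guards against accidental loss of good
    particles to one unlucky classification).
    """
    ids = _common_ids(results)
    below_all = np.ones(len(ids), dtype=bool)
    for res in results:
        probs = res.set_index("pick_id").loc[ids, "class_prob"].to_numpy(dtype=float)
        below_all &= probs < cfg.prob_floor
    return [pid for pid, drop in zip(ids, below_all) if not drop]


def duplicated_class_selection(
    results: Sequence[pd.DataFrame], keep_classes: Sequence[Iterable[int]]
) -> list:
    """Keep a pick iff its assigned class is in the keep-set in every replicate."""
    _check_known_classes(results, keep_classes, "keep")
    ids = _common_ids(results)
    kept = np.ones(len(ids), dtype=bool)
    for res, keep in zip(results, keep_classes):
        keep = set(int(k) for k in keep)
        cls = res.set_index("pick_id").loc[ids, "class_id"].to_numpy(dtype=int)
        kept &= np.isin(cls, list(keep)) if keep else np.zeros(len(ids), bool)
    return [pid for pid, k in zip(ids, kept) if k]


def decoy_filter(
    results: Sequence[pd.DataFrame], decoy_classes: Sequence[Iterable[int]]
) -> list:
    """Remove a pick iff it is decoy-assigned in ALL replicates; else keep.

    Requiring agreement between replicate classifications prevents the
    unintentional loss of high-S/N particles to a single noisy assignment.
    """
    _check_known_classes(results, decoy_classes, "decoy")
    ids = _common_ids(results)
    decoy_all = np.ones(len(ids), dtype=bool)
    for res, decoys in zip(results, decoy_classes):
        decoys = set(int(k) for k in decoys)
        cls = res.set_index("pick_id").loc[ids, "class_id"].to_numpy(dtype=int)
        decoy_all &= np.isin(cls, list(decoys)) if decoys else np.zeros(len(ids), bool)
    return [pid for pid, drop in zip(ids, decoy_all) if not drop]


def comprehensive_duster(
    picksA: pd.DataFrame,
    picksB: pd.DataFrame,
    recenterer: Recenterer,
    cfg: CurationConfig,
    meta: ImageMeta,
) -> CurationReport:
    """Comprehensive curation: R recenterings per set, all R×R combinations.

    Each round runs ``cfg.comprehensive_R`` independent recenterings of each
    set (distinct seeds), matches every cross-set combination, and combines
    the per-combination kept sets with ``cfg.combine_rule`` (default
    intersection: a pick survives only if kept in every combination). The
    first replicate's recentered coordinates carry each set into the next
    round. With R = 1 this is exactly :func:`run_duster`.
    """
    from duster.recenter2d import recenter as _apply_shifts

    R = cfg.comprehensive_R
    report = CurationReport(config=_config_dict(cfg), seed=cfg.seed)
    seeds = _derive_seeds(cfg.seed, 2 * R * cfg.rounds)
    s = iter(int(v) for v in seeds)
    curA, curB = picksA, picksB
    for rnd in range(cfg.rounds):
        if len(curA) == 0 or len(curB) == 0:
            report.warning = "all particles eliminated"
            report.stop_reason = "empty"
            break
        recsA, recsB = [], []
        for picks, out in ((curA, recsA), (curB, recsB)):
            for _ in range(R):
                result = recenterer.recenter_set(picks, seed=next(s))
                covered = picks[picks["pick_id"].isin(result["pick_id"])]
                out.append(_apply_shifts(covered, result))
        kept_A: set | None = None
        kept_B: set | None = None
        combo_stats = []
        for ra in recsA:
            for rb in recsB:
                match = match_pairs(ra, rb, meta, cfg)
                ids_a = set(match.kept_A["pick_id"])
                ids_b = set(match.kept_B["pick_id"])
                combo_stats.append(match.stats)
                if kept_A is None:
                    kept_A, kept_B = ids_a, ids_b
                elif cfg.combine_rule == "intersection":
                    kept_A &= ids_a
                    kept_B &= ids_b
                else:
                    kept_A |= ids_a
                    kept_B |= ids_b
        curA = recsA[0][recsA[0]["pick_id"].isin(kept_A)]
        curB = recsB[0][recsB[0]["pick_id"].isin(kept_B)]
        n_in = combo_stats[0]["n_in_A"] + combo_stats[0]["n_in_B"]
        report.rounds.append(
            {
                "round": rnd + 1,
                "n_in_A": combo_stats[0]["n_in_A"],
                "n_in_B": combo_stats[0]["n_in_B"],
                "n_pairs": int(np.median([st["n_pairs"] for st in combo_stats])),
                "retention": (len(curA) + len(curB)) / n_in if n_in else 0.0,
                "median_D_A": float(np.median([st["median_D"] for st in combo_stats])),
            }
        )
    report.kept_ids_A = list(curA["pick_id"])
    report.kept_ids_B = list(curB["pick_id"])
    report.kept_A, report.kept_B = curA, curB
    return report


def _common_ids(results: Sequence[pd.DataFrame]) -> list:
    id_sets = [set(res["pick_id"]) for res in results]
    if any(s != id_sets[0] for s in id_sets[1:]):
        raise ValueError("replicate results do not cover the same pick ids")
    return sorted(id_sets[0])


def _check_known_classes(results, class_sets, what: str) -> None:
    for rep, (res, classes) in enumerate(zip(results, class_sets)):
        known = set(int(c) for c in res["class_id"].unique())
        unknown = set(int(c) for c in classes) - known
        if unknown:
            raise ValueError(
                f"replicate {rep}: unknown class id(s) in {what}-set: {sorted(unknown)}"
            )


def _derive_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def _config_dict(cfg: CurationConfig) -> dict:
    return {k: getattr(cfg, k) for k in cfg.__dataclass_fields__}


def config_for_mode(mode: str, **overrides) -> CurationConfig:
    """Named presets: "2d" → D_TH 20 Å / 7 rounds; "3d" → D_TH 15 Å / 6 rounds."""
    presets = {"2d": dict(d_th_A=20.0, rounds=7), "3d": dict(d_th_A=15.0, rounds=6)}
    if mode not in presets:
        raise ValueError(f"unknown mode {mode!r} (expected '2d' or '3d')")
    params = {**presets[mode], **{k: v for k, v in overrides.items() if v is not None}}
    return CurationConfig(**params)
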