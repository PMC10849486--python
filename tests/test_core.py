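"""Curation-core contracts: matching, rounds, filters, closed-form retention."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from duster.core import (
    CurationConfig,
    comprehensive_duster,
    config_for_mode,
    decoy_filter,
    duplicated_class_selection,
    duster_round,
    keep_probability,
    match_pairs,
    probability_filter,
    run_duster,
)
from duster.particle_io import ImageMeta
from duster.synthetic import AbstractRecenterer, SimParams, generate_scene, simulate_picks

from conftest import gaussian_recenter_results, make_picks

META1 = ImageMeta(pixel_size_A=1.0, nx=100_000, ny=100_000)


def brute_force_matching(a_xy, b_xy, d_th):
    """Exhaustive optimal one-to-one matching: max #pairs, then min total D.

    Recursive enumeration over the candidate-edge set; returns a set of
    (i, j) index pairs. Independent of the production matcher.
    """
    edges = [
        (i, j, float(np.hypot(*(np.asarray(pa) - pb))))
        for i, pa in enumerate(a_xy)
        for j, pb in enumerate(b_xy)
        if np.hypot(*(np.asarray(pa) - pb)) < d_th
    ]

    best = {"count": -1, "total": np.inf, "pairs": set()}

    def recurse(k, used_a, used_b, pairs, total):
        if k == len(edges):
            count = len(pairs)
            if count > best["count"] or (count == best["count"] and total < best["total"]):
                best.update(count=count, total=total, pairs=set(pairs))
            return
        i, j, d = edges[k]
        if i not in used_a and j not in used_b:
            recurse(k + 1, used_a | {i}, used_b | {j}, pairs | {(i, j)}, total + d)
        recurse(k + 1, used_a, used_b, pairs, total)

    recurse(0, frozenset(), frozenset(), set(), 0.0)
    return best["pairs"], best["count"], best["total"]


def _random_instance(rng, n_max=12, span=60.0):
    na, nb = rng.integers(1, n_max + 1, size=2)
    a = make_picks(rng.uniform(0, span, size=(na, 2)), prefix="a")
    b = make_picks(rng.uniform(0, span, size=(nb, 2)), set_label="B", prefix="b")
    return a, b


class TestMatchPairs:
    def test_coincident_picks_all_pair_at_distance_zero(self, default_cfg):
        a = make_picks([(10, 10), (50, 50)], prefix="a")
        b = make_picks([(10, 10), (50, 50)], set_label="B", prefix="b")
        match = match_pairs(a, b, META1, default_cfg)
        assert match.stats["n_pairs"] == 2
        assert (match.pairs["D_A"] == 0.0).all()
        assert match.stats["retention_fraction"] == 1.0

    def test_distance_exactly_at_threshold_is_rejected(self, default_cfg):
        """The rule is strictly 'shorter than D_TH'."""
        a = make_picks([(0, 0)], prefix="a")
        b = make_picks([(20.0, 0)], set_label="B", prefix="b")
        match = match_pairs(a, b, META1, default_cfg)
        assert match.stats["n_pairs"] == 0
        just_inside = make_picks([(19.999999, 0)], set_label="B", prefix="b")
        assert match_pairs(a, just_inside, META1, default_cfg).stats["n_pairs"] == 1

    def test_matches_brute_force_on_random_instances(self, default_cfg):
        rng = np.random.default_rng(2024)
        for _ in range(40):
            a, b = _random_instance(rng)
            match = match_pairs(a, b, META1, default_cfg)
            _, count, total = brute_force_matching(
                a[["x_px", "y_px"]].to_numpy(), b[["x_px", "y_px"]].to_numpy(), 20.0
            )
            assert match.stats["n_pairs"] == count
            assert match.pairs["D_A"].sum() == pytest.approx(total, abs=1e-9)

    def test_symmetry_under_set_swap(self, default_cfg):
        rng = np.random.default_rng(77)
        for _ in range(20):
            a, b = _random_instance(rng)
            ab = match_pairs(a, b, META1, default_cfg)
            ba = match_pairs(b, a, META1, default_cfg)
            fwd = set(zip(ab.pairs["pick_id_A"], ab.pairs["pick_id_B"]))
            rev = set(zip(ba.pairs["pick_id_B"], ba.pairs["pick_id_A"]))
            assert fwd == rev

    def test_pair_count_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        a, b = _random_instance(rng, n_max=10)
        counts = [
            match_pairs(a, b, META1, CurationConfig(d_th_A=d)).stats["n_pairs"]
            for d in (1, 5, 10, 20, 40, 80)
        ]
        assert counts == sorted(counts)

    def test_conservation_kept_plus_rejected_equals_input(self, default_cfg):
        rng = np.random.default_rng(13)
        a, b = _random_instance(rng)
        match = match_pairs(a, b, META1, default_cfg)
        for inp, kept, rej in (
            (a, match.kept_A, match.rejected_A),
            (b, match.kept_B, match.rejected_B),
        ):
            ids = sorted(kept["pick_id"]) + sorted(rej["pick_id"])
            assert sorted(ids) == sorted(inp["pick_id"])
            assert not (set(kept["pick_id"]) & set(rej["pick_id"]))

    def test_matching_respects_micrograph_boundaries(self, default_cfg):
        a = make_picks([(10, 10)], micrograph_id="mic_000", prefix="a")
        b = make_picks([(10, 10)], micrograph_id="mic_001", set_label="B", prefix="b")
        assert match_pairs(a, b, META1, default_cfg).stats["n_pairs"] == 0

    def test_one_to_one_even_with_crowds(self, default_cfg):
        # three A picks near one B pick: only one pair may form
        a = make_picks([(0, 0), (1, 0), (0, 1)], prefix="a")
        b = make_picks([(0.5, 0.5)], set_label="B", prefix="b")
        match = match_pairs(a, b, META1, default_cfg)
        assert match.stats["n_pairs"] == 1

    def test_pooled_cluster_keeps_cross_set_clusters(self):
        cfg = CurationConfig(d_th_A=10.0, match_mode="pooled_cluster")
        # chain a0 - b0 - a1 within threshold: all three share one cluster
        a = make_picks([(0, 0), (12, 0), (60, 60)], prefix="a")
        b = make_picks([(6, 0), (100, 100)], set_label="B", prefix="b")
        match = match_pairs(a, b, META1, cfg)
        assert set(match.kept_A["pick_id"]) == {"a0000", "a0001"}
        assert set(match.kept_B["pick_id"]) == {"b0000"}

    def test_same_set_dedup_keeps_first_pick(self):
        cfg = CurationConfig(d_th_A=20.0, same_set_dedup_A=5.0)
        a = make_picks([(0, 0), (1, 0), (50, 50)], prefix="a")
        b = make_picks([(0, 0), (50, 50)], set_label="B", prefix="b")
        match = match_pairs(a, b, META1, cfg)
        assert match.stats["n_in_A"] == 2  # a0001 removed before matching
        assert "a0001" not in set(match.pairs["pick_id_A"])


class TestKeepProbability:
    def test_closed_form_reference_values(self):
        assert keep_probability(10.0, 20.0) == pytest.approx(1 - np.exp(-1), abs=1e-12)
        assert keep_probability(3.0, 20.0) == pytest.approx(1 - np.exp(-400 / 36), rel=1e-9)
        assert keep_probability(60.0, 20.0) == pytest.approx(1 - np.exp(-400 / 14400), rel=1e-9)

    def test_monte_carlo_agreement(self):
        """Two points at truth + N(0, σ²I) each; P(|Δ| < D_TH) from 10^5 draws."""
        rng = np.random.default_rng(99)
        sigma, d_th, n = 10.0, 20.0, 100_000
        delta = rng.normal(0, sigma, (n, 2)) - rng.normal(0, sigma, (n, 2))
        frac = float((np.hypot(delta[:, 0], delta[:, 1]) < d_th).mean())
        assert frac == pytest.approx(keep_probability(sigma, d_th), abs=0.005)

    def test_vanishing_threshold_limit(self):
        assert keep_probability(10.0, 1e-9) < 1e-12


class TestDusterRound:
    def test_zero_noise_recenterer_is_fixed_point(self, flat_meta):
        class Identity:
            def recenter_set(self, picks, *, seed):
                return gaussian_recenter_results(picks, sigma_px=1e-12, seed=seed)

        a = make_picks([(10, 10), (60, 60)], prefix="a")
        b = make_picks([(10, 10), (60, 60)], set_label="B", prefix="b")
        cfg = CurationConfig(d_th_A=20.0, seed=1)
        keptA, keptB, match = duster_round(a, b, Identity(), cfg, flat_meta)
        assert sorted(keptA["pick_id"]) == sorted(a["pick_id"])
        assert sorted(keptB["pick_id"]) == sorted(b["pick_id"])

    def test_retention_matches_analytic_law(self):
        """Empirical one-round retention vs 1 − exp(−D_TH²/4σ²), ±0.01 at n=5·10⁴."""
        sigma, n = 10.0, 50_000
        side = 150 * int(np.ceil(np.sqrt(n))) + 300
        params = SimParams(
            n_high=n, n_junk=0, nx=side, ny=side, pixel_size_A=1.0,
            min_separation_px=150, placement="grid",
            recenter_sigma_high_A=sigma, fp_rate=0.0, miss_rate=0.0,
        )
        scene = generate_scene(params, seed=29, render=False)
        a = simulate_picks(scene, params, 291, "A")
        b = simulate_picks(scene, params, 292, "B")
        cfg = CurationConfig(d_th_A=20.0, rounds=1, seed=8)
        report = run_duster(a, b, AbstractRecenterer(scene), cfg, scene.meta)
        assert report.rounds[0]["retention"] == pytest.approx(
            keep_probability(sigma, 20.0), abs=0.01
        )


class TestRunDuster:
    def test_one_round_equals_duster_round(self, abstract_scene, pick_pair, flat_meta):
        a, b = pick_pair
        recenterer = AbstractRecenterer(abstract_scene)
        cfg = CurationConfig(d_th_A=20.0, rounds=1, seed=42)
        report = run_duster(a, b, recenterer, cfg, flat_meta)
        from duster.core import _derive_seeds

        seeds = _derive_seeds(42, 2)
        keptA, keptB, _ = duster_round(
            a, b, recenterer, cfg, flat_meta, seed_pair=(seeds[0], seeds[1])
        )
        assert sorted(report.kept_ids_A) == sorted(keptA["pick_id"])
        assert sorted(report.kept_ids_B) == sorted(keptB["pick_id"])

    def test_infinite_threshold_retains_everything(self, flat_meta):
        a = make_picks([(10, 10), (500, 500)], prefix="a")
        b = make_picks([(12, 10), (502, 500)], set_label="B", prefix="b")

        class Jiggle:
            def recenter_set(self, picks, *, seed):
                return gaussian_recenter_results(picks, sigma_px=2.0, seed=seed)

        cfg = CurationConfig(d_th_A=1e12, rounds=3, seed=0)
        report = run_duster(a, b, Jiggle(), cfg, flat_meta)
        assert sorted(report.kept_ids_A) == sorted(a["pick_id"])
        assert report.stop_reason.startswith("converged")

    def test_empty_result_is_warning_not_exception(self, flat_meta):
        a = make_picks([(10, 10)], prefix="a")
        b = make_picks([(5000, 5000)], set_label="B", prefix="b")

        class Identity:
            def recenter_set(self, picks, *, seed):
                return gaussian_recenter_results(picks, sigma_px=1e-12, seed=seed)

        cfg = CurationConfig(d_th_A=20.0, rounds=3, seed=0)
        report = run_duster(a, b, Identity(), cfg, flat_meta)
        assert report.warning == "all particles eliminated"
        assert report.kept_ids_A == []

    def test_junk_retention_non_increasing_over_rounds(self):
        """With mixed σ classes, the junk fraction surviving shrinks every round."""
        params = SimParams(
            n_high=1500,
            n_junk=1500,
            nx=8600,
            ny=8600,
            pixel_size_A=1.0,
            min_separation_px=150,
            placement="grid",
            fp_rate=0.0,
            miss_rate=0.0,
        )
        scene = generate_scene(params, seed=31, render=False)
        a = simulate_picks(scene, params, 311, "A")
        b = simulate_picks(scene, params, 312, "B")
        cfg = CurationConfig(d_th_A=20.0, rounds=4, seed=6)
        report = run_duster(a, b, AbstractRecenterer(scene), cfg, scene.meta)
        junk_ids = set(
            scene.truth.loc[scene.truth["snr_class"] == "low_junk", "particle_id"]
        )
        picks = pd.concat([a, b], ignore_index=True).set_index("pick_id")
        # survivor counts per round are not logged per class; check final only
        final = [
            pid
            for pid in report.kept_ids_A + report.kept_ids_B
            if int(picks.at[pid, "source_particle_id"]) in junk_ids
        ]
        assert len(final) / (2 * 1500) < keep_probability(60.0, 20.0) ** 2
        retentions = [row["retention"] for row in report.rounds]
        assert all(b2 >= a2 - 0.02 for a2, b2 in zip(retentions, retentions[1:]))


class TestFilters:
    def _results(self, probs_by_replicate, classes_by_replicate=None):
        n = len(probs_by_replicate[0])
        ids = [f"p{i:03d}" for i in range(n)]
        out = []
        for r, probs in enumerate(probs_by_replicate):
            classes = (
                classes_by_replicate[r] if classes_by_replicate else [0] * n
            )
            out.append(
                pd.DataFrame(
                    {
                        "pick_id": ids,
                        "shift_x_px": 0.0,
                        "shift_y_px": 0.0,
                        "recentered_x_px": 0.0,
                        "recentered_y_px": 0.0,
                        "class_id": classes,
                        "class_prob": probs,
                    }
                )
            )
        return ids, out

    def test_kept_when_above_floor_in_one_replicate(self):
        ids, results = self._results([[0.9], [0.1]])
        assert probability_filter(results, CurationConfig(prob_floor=0.3)) == ids

    def test_removed_only_when_below_floor_in_all_replicates(self):
        ids, results = self._results([[0.1, 0.5], [0.2, 0.1]])
        kept = probability_filter(results, CurationConfig(prob_floor=0.3))
        assert kept == [ids[1]]

    def test_zero_floor_removes_nothing(self):
        ids, results = self._results([[0.0, 0.01], [0.0, 0.99]])
        assert probability_filter(results, CurationConfig(prob_floor=0.0)) == ids

    def test_replicate_coverage_mismatch_raises(self):
        _, results = self._results([[0.5, 0.5], [0.5, 0.5]])
        results[1] = results[1].iloc[:1]
        with pytest.raises(ValueError, match="same pick ids"):
            probability_filter(results, CurationConfig())

    def test_class_selection_keep_all(self):
        ids, results = self._results(
            [[0.5] * 4, [0.5] * 4], [[0, 1, 2, 3], [3, 2, 1, 0]]
        )
        kept = duplicated_class_selection(results, [{0, 1, 2, 3}, {0, 1, 2, 3}])
        assert kept == ids

    def test_class_selection_requires_both_replicates(self):
        ids, results = self._results([[0.5] * 2, [0.5] * 2], [[0, 1], [0, 1]])
        kept = duplicated_class_selection(results, [{0}, {1}])
        assert kept == []  # p000 kept in rep 1 only, p001 in rep 2 only

    def test_class_selection_matches_set_intersection_oracle(self):
        rng = np.random.default_rng(3)
        n = 10
        c1, c2 = rng.integers(0, 4, n), rng.integers(0, 4, n)
        ids, results = self._results([[0.5] * n] * 2, [c1, c2])
        keep1, keep2 = {0, 1} & set(c1.tolist()), {1, 2} & set(c2.tolist())
        kept = duplicated_class_selection(results, [keep1, keep2])
        oracle = {
            ids[i] for i in range(n) if c1[i] in keep1
        } & {ids[i] for i in range(n) if c2[i] in keep2}
        assert set(kept) == oracle

    def test_decoy_in_one_replicate_is_kept(self):
        ids, results = self._results([[0.5, 0.5], [0.5, 0.5]], [[2, 1], [0, 1]])
        # p000 is decoy-assigned in replicate 1 only; p001 in replicate 2 only
        assert decoy_filter(results, [{2}, {1}]) == ids

    def test_decoy_in_all_replicates_is_removed(self):
        ids, results = self._results([[0.5, 0.5], [0.5, 0.5]], [[2, 0], [2, 1]])
        assert decoy_filter(results, [{2}, {2}]) == [ids[1]]

    def test_decoy_filter_equals_indicator_probability_filter(self):
        """Decoy membership as a 0/1 'probability' reduces to the 0.3-floor rule."""
        rng = np.random.default_rng(8)
        n = 50
        c1, c2 = rng.integers(0, 4, n), rng.integers(0, 4, n)
        ids, results = self._results([[0.5] * n] * 2, [c1, c2])
        decoys = [{1, 3}, {3}]
        kept = decoy_filter(results, decoys)
        indicator = [
            [0.0 if c in dec else 1.0 for c in cs]
            for cs, dec in zip((c1, c2), decoys)
        ]
        _, prob_results = self._results(indicator)
        via_prob = probability_filter(prob_results, CurationConfig(prob_floor=0.3))
        assert kept == via_prob

    def test_unknown_class_id_raises(self):
        ids, results = self._results([[0.5], [0.5]], [[0], [1]])
        with pytest.raises(ValueError, match="unknown class"):
            decoy_filter(results, [{9}, {1}])
        with pytest.raises(ValueError, match="unknown class"):
            duplicated_class_selection(results, [{0}, {7}])


class TestComprehensive:
    def test_r1_reduces_to_plain_round(self, abstract_scene, pick_pair, flat_meta):
        a, b = pick_pair
        recenterer = AbstractRecenterer(abstract_scene)
        cfg = CurationConfig(d_th_A=20.0, rounds=1, comprehensive_R=1, seed=9)
        rep_c = comprehensive_duster(a, b, recenterer, cfg, flat_meta)
        rep_p = run_duster(a, b, recenterer, cfg, flat_meta)
        assert sorted(rep_c.kept_ids_A) == sorted(rep_p.kept_ids_A)
        assert sorted(rep_c.kept_ids_B) == sorted(rep_p.kept_ids_B)

    def test_intersection_never_exceeds_single_combination(
        self, abstract_scene, pick_pair, flat_meta
    ):
        a, b = pick_pair
        sub_a, sub_b = a.iloc[:400], b.iloc[:400]
        recenterer = AbstractRecenterer(abstract_scene)
        cfg = CurationConfig(d_th_A=20.0, rounds=1, comprehensive_R=3, seed=12)
        rep = comprehensive_duster(sub_a, sub_b, recenterer, cfg, flat_meta)
        # the intersection rule is a subset of the union rule on the same seeds
        cfg_union = CurationConfig(
            d_th_A=20.0, rounds=1, comprehensive_R=3, seed=12, combine_rule="union"
        )
        rep_union = comprehensive_duster(sub_a, sub_b, recenterer, cfg_union, flat_meta)
        assert set(rep.kept_ids_A) <= set(rep_union.kept_ids_A)

    def test_nine_combination_retention_matches_simulation_oracle(self, flat_meta):
        """Dependent combinations: measured retention equals a direct simulation
        of R Gaussian recenterings per set intersected over all R×R matchings."""
        sigma, d_th, n, R = 10.0, 20.0, 4000, 3
        params = SimParams(
            n_high=n, n_junk=0, nx=9800, ny=9800, pixel_size_A=1.0,
            min_separation_px=150, placement="grid",
            recenter_sigma_high_A=sigma, fp_rate=0.0, miss_rate=0.0,
        )
        scene = generate_scene(params, seed=55, render=False)
        a = simulate_picks(scene, params, 551, "A")
        b = simulate_picks(scene, params, 552, "B")
        cfg = CurationConfig(d_th_A=d_th, rounds=1, comprehensive_R=R, seed=77)
        rep = comprehensive_duster(a, b, AbstractRecenterer(scene), cfg, flat_meta)
        measured = len(rep.kept_ids_A) / n

        # independent oracle: simulate the full dependency structure directly
        rng = np.random.default_rng(424242)
        m = 60_000
        pa = rng.normal(0, sigma, (R, m, 2))
        pb = rng.normal(0, sigma, (R, m, 2))
        kept = np.ones(m, dtype=bool)
        for i in range(R):
            for j in range(R):
                d = np.hypot(*(pa[i] - pb[j]).T)
                kept &= d < d_th
        oracle = kept.mean()
        # and the naive independence prediction must NOT match
        naive = keep_probability(sigma, d_th) ** (R * R)
        assert measured == pytest.approx(oracle, abs=0.02)
        assert abs(oracle - naive) > 0.05

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CurationConfig(d_th_A=-1)
        with pytest.raises(ValueError):
            CurationConfig(prob_floor=1.5)
        with pytest.raises(ValueError):
            CurationConfig(match_mode="nearest")


class TestModePresets:
    def test_published_presets(self):
        cfg2d = config_for_mode("2d")
        assert (cfg2d.d_th_A, cfg2d.rounds) == (20.0, 7)
        cfg3d = config_for_mode("3d")
        assert (cfg3d.d_th_A, cfg3d.rounds) == (15.0, 6)
        override = config_for_mode("3d", d_th_A=12.5)
        assert override.d_th_A == 12.5 and override.rounds == 6


@settings(max_examples=60, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_matching_is_pure_function_of_inputs(seed):
    """Same instance, same result — match_pairs has no hidden state."""
    rng = np.random.default_rng(seed)
    a, b = _random_instance(rng, n_max=6)
    cfg = CurationConfig(d_th_A=15.0)
    p1 = match_pairs(a, b, META1, cfg).pairs
    p2 = match_pairs(a, b, META1, cfg).pairs
    pd.testing.assert_frame_equal(p1, p2)
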