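"""Validation statistics against hand-computed oracles and invariances."""

import numpy as np
import pandas as pd
import pytest

from spinacarb import (
    bland_altman,
    correlation_edge_list,
    ergodicity,
    group_comparison,
    spearman_rho,
    zou_ci_difference,
)


class TestSpearman:
    def test_perfect_inverse_ranks(self):
        rho, _ = spearman_rho([1, 2, 3], [3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_perfect_monotone(self):
        rho, _ = spearman_rho([1, 2, 3], [10, 20, 30])
        assert rho == pytest.approx(1.0)

    def test_four_point_hand_value(self):
        # d^2 = 4 -> rho = 1 - 6*4/(4*15) = 0.6
        rho, _ = spearman_rho([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(0.6)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        rho_raw, _ = spearman_rho(x, y)
        rho_tr, _ = spearman_rho(np.exp(x), y**3)
        assert rho_tr == pytest.approx(rho_raw, abs=1e-12)

    def test_missing_pairs_dropped_and_minimum_enforced(self):
        rho, _ = spearman_rho([1, 2, 3, np.nan], [1, 2, 3, 4])
        assert rho == pytest.approx(1.0)
        with pytest.raises(ValueError):
            spearman_rho([1, np.nan, 3], [1, 2, 3])


class TestZouCI:
    def test_self_comparison_is_symmetric_and_contains_zero(self):
        low, high, different = zou_ci_difference(0.5, 0.5, 0.3, 100)
        assert low == pytest.approx(-high)
        assert not different

    def test_ci_widens_with_smaller_n(self):
        lo_small, hi_small, _ = zou_ci_difference(0.5, 0.5, 0.3, 25)
        lo_big, hi_big, _ = zou_ci_difference(0.5, 0.5, 0.3, 100)
        assert hi_small - lo_small > hi_big - lo_big

    def test_clear_difference_excludes_zero(self):
        # frozen from an independent transcription of the published formula
        low, high, different = zou_ci_difference(0.5, 0.1, 0.2, 500)
        assert low == pytest.approx(0.299717, rel=1e-4)
        assert high == pytest.approx(0.498491, rel=1e-4)
        assert different

    def test_degenerate_correlation_rejected(self):
        with pytest.raises(ValueError):
            zou_ci_difference(1.0, 0.5, 0.2, 100)


class TestGroupComparison:
    def test_kruskal_wallis_hand_value(self):
        report = group_comparison([1, 2, 3, 4, 5, 6], ["a", "a", "b", "b", "c", "c"])
        assert report["H"] == pytest.approx(4.571, rel=1e-3)

    def test_identical_groups_have_p_one(self):
        report = group_comparison([1, 2, 1, 2], ["a", "a", "b", "b"])
        assert report["pairwise"][0]["p"] == pytest.approx(1.0)

    def test_bh_adjustment_step_up(self):
        # groups engineered so we only check the BH mechanics directly
        from statsmodels.stats.multitest import multipletests

        _, adj, _, _ = multipletests([0.01, 0.02, 0.04], method="fdr_bh")
        assert adj == pytest.approx([0.03, 0.03, 0.04])

    def test_adjusted_p_monotone_and_bounded(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=40)
        values[:10] += 3.0
        groups = np.repeat(["a", "b", "c", "d"], 10)
        report = group_comparison(values, groups)
        recs = sorted(report["pairwise"], key=lambda r: r["p"])
        adj = [r["p_adjusted"] for r in recs]
        assert all(x <= y for x, y in zip(adj, adj[1:]))
        assert all(r["p"] <= r["p_adjusted"] <= 1.0 for r in recs)

    def test_undersized_group_named_in_error(self):
        with pytest.raises(ValueError, match="b"):
            group_comparison([1, 2, 3], ["a", "a", "b"])


class TestBlandAltman:
    def test_identical_methods(self):
        res = bland_altman([1, 2, 3], [1, 2, 3])
        assert res.bias == 0.0
        assert res.loa_low == res.loa_high == 0.0
        assert res.proportional_bias_slope == 0.0

    def test_hand_computed_example(self):
        res = bland_altman([1, 2, 3], [2, 2, 4])
        assert res.bias == pytest.approx(-0.667, rel=1e-3)
        assert res.loa_low == pytest.approx(-1.798, rel=1e-3)
        assert res.loa_high == pytest.approx(0.465, rel=1e-2)

    def test_constant_offset_has_zero_slope(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = bland_altman(a + 1.0, a)
        assert res.bias == pytest.approx(1.0)
        assert res.proportional_bias_slope == pytest.approx(0.0, abs=1e-12)

    def test_limits_bracket_bias(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=100)
        res = bland_altman(a + rng.normal(0, 0.1, 100), a)
        assert res.loa_low < res.bias < res.loa_high

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1, 2, 3], [1, 2])


class TestErgodicity:
    def test_hand_computed_decomposition(self):
        df = pd.DataFrame(
            {"subject": ["A", "A", "B", "B", "C", "C"],
             "value": [10, 12, 20, 22, 30, 28]}
        )
        res = ergodicity(df)
        assert res.var_inter == pytest.approx(81.333, rel=1e-3)
        assert res.var_intra == pytest.approx(2.0)
        assert res.e == pytest.approx(0.976, rel=1e-3)

    def test_pure_between_subject_variance_gives_e_one(self):
        df = pd.DataFrame({"subject": ["A", "A", "B", "B"], "value": [1, 1, 9, 9]})
        assert ergodicity(df).e == 1.0

    def test_pure_within_subject_variance_gives_e_zero(self):
        df = pd.DataFrame({"subject": ["A", "A", "B", "B"], "value": [1, 9, 9, 1]})
        assert ergodicity(df).e == 0.0

    def test_invariant_under_shift_and_scale(self):
        rng = np.random.default_rng(17)
        df = pd.DataFrame(
            {"subject": np.repeat([f"S{i}" for i in range(20)], 3),
             "value": rng.normal(5, 2, 60)}
        )
        base = ergodicity(df).e
        shifted = ergodicity(df.assign(value=df["value"] + 100)).e
        scaled = ergodicity(df.assign(value=df["value"] * 7.5)).e
        assert shifted == pytest.approx(base, rel=1e-12)
        assert scaled == pytest.approx(base, rel=1e-12)

    def test_single_repeat_subjects_excluded_with_warning(self):
        df = pd.DataFrame(
            {"subject": ["A", "A", "B", "B", "C"], "value": [1, 2, 3, 4, 5]}
        )
        with pytest.warns(UserWarning, match="1 subject"):
            res = ergodicity(df)
        assert res.n_subjects == 2
        assert res.n_excluded == 1

    def test_all_excluded_raises(self):
        df = pd.DataFrame({"subject": ["A", "B"], "value": [1, 2]})
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                ergodicity(df)


class TestEdgeList:
    def test_edges_cover_all_pairs_with_adjusted_p(self):
        rng = np.random.default_rng(21)
        frame = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("wxyz"))
        edges = correlation_edge_list(frame)
        assert len(edges) == 6
        assert {"marker_a", "marker_b", "rho", "p", "p_adjusted"} <= set(edges.columns)
        assert (edges["p_adjusted"] >= edges["p"] - 1e-15).all()
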