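"""Abundance scores, fold changes, rank-sum and BH oracles, final calls."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import paralogscope as ps
from paralogscope.abundance import abundance_analysis


class TestAbundanceScore:
    def test_single_constant_frame(self):
        assert ps.abundance_score([np.full((64, 64), 3.0)]) == 3.0

    def test_equal_sized_frames_average(self):
        frames = [np.full((64, 64), 2.0), np.full((64, 64), 4.0)]
        assert ps.abundance_score(frames) == 3.0

    def test_pixel_weighted_not_mean_of_means(self):
        # 2x2 frame of 8s and 4x4 frame of 2s: grand mean = (32+32)/20 = 3.2
        frames = [np.full((2, 2), 8.0), np.full((4, 4), 2.0)]
        assert ps.abundance_score(frames) == pytest.approx(3.2)
        assert ps.abundance_score(frames) != pytest.approx(5.0)  # mean of means

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ps.abundance_score([])


class TestLog2FoldChange:
    def test_equal_scores_zero(self):
        assert ps.log2_fold_change(5.0, 5.0) == 0.0

    def test_closed_form(self):
        # log2(7+1) - log2(3+1) = 3 - 2 = 1
        assert ps.log2_fold_change(3.0, 7.0) == pytest.approx(1.0)

    def test_antisymmetry(self):
        assert ps.log2_fold_change(7.0, 3.0) == pytest.approx(-1.0)
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = rng.uniform(0, 100, 2)
            assert ps.log2_fold_change(a, b) == pytest.approx(
                -ps.log2_fold_change(b, a)
            )


def _brute_force_mwu_p(x, y):
    """Exact two-sided p by enumerating all assignments of the pooled values."""
    pooled = sorted(list(x) + list(y))
    n, nx = len(pooled), len(x)
    u_obs = sum(1 for a in x for b in y if a > b)
    us = []
    for idx in combinations(range(n), nx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n) if i not in set(idx)]
        us.append(sum(1 for a in xs for b in ys if a > b))
    us = np.asarray(us)
    return min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))


class TestRankSumTest:
    def test_two_vs_two_exact_third(self):
        assert ps.rank_sum_test([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_identical_samples_give_one(self):
        assert ps.rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_large_separated_samples_tiny_p(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 300)
        y = rng.normal(5, 1, 300)
        assert ps.rank_sum_test(x, y) < 1e-6

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ps.rank_sum_test([], [1.0])

    def test_swapping_samples_preserves_p(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 40), rng.normal(0.5, 1, 35)
        assert ps.rank_sum_test(x, y) == pytest.approx(ps.rank_sum_test(y, x))

    @pytest.mark.parametrize("nx,ny", [(1, 2), (2, 2), (3, 2), (3, 3), (4, 3)])
    def test_agrees_with_exhaustive_enumeration(self, nx, ny):
        rng = np.random.default_rng(nx * 10 + ny)
        for _ in range(10):
            vals = rng.choice(10_000, size=nx + ny, replace=False).astype(float)
            x, y = vals[:nx], vals[nx:]
            assert ps.rank_sum_test(x, y) == pytest.approx(
                _brute_force_mwu_p(x, y), abs=1e-12
            )


def _bh_definition(p):
    """Naive step-up BH straight from the definition (O(m^2) oracle)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_idx, i in enumerate(order):
        candidates = [
            p[order[j]] * m / (j + 1) for j in range(rank_idx, m)
        ]
        q[i] = min(1.0, min(candidates))
    return q


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert ps.bh_adjust([0.03]).tolist() == [0.03]

    def test_step_up_worked_example(self):
        q = ps.bh_adjust([0.01, 0.02, 0.04])
        assert np.allclose(q, [0.03, 0.03, 0.04])

    def test_all_ones_stay_one(self):
        assert np.all(ps.bh_adjust([1.0, 1.0, 1.0]) == 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ps.bh_adjust([0.5, 1.2])

    def test_monotone_in_order_statistics(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=20)
        q = ps.bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= 0)
        assert np.all(q >= p) and np.all(q <= 1.0)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 40))
    def test_matches_definition_and_statsmodels(self, seed, m):
        from statsmodels.stats.multitest import multipletests

        p = np.random.default_rng(seed).uniform(size=m)
        ours = ps.bh_adjust(p)
        assert np.allclose(ours, _bh_definition(p))
        assert np.allclose(ours, multipletests(p, method="fdr_bh")[1])


class TestClassifyAbundance:
    @pytest.mark.parametrize(
        "lfc,q,expected",
        [
            (0.25, 0.01, "increased"),
            (0.25, 0.10, "none"),
            (-0.30, 0.001, "decreased"),
            (0.2, 0.049, "increased"),  # inclusive lfc boundary
            (0.19, 0.001, "none"),
            (-0.2, 0.05, "none"),  # q must be strictly below 0.05
        ],
    )
    def test_direction_rules(self, lfc, q, expected):
        assert ps.classify_abundance(lfc, q) == expected


class TestCallCompDep:
    def test_increase_without_relocalization_is_compensation(self):
        call, flags = ps.call_comp_dep("increased", None, "cytoplasm", "ER")
        assert call == "compensation" and flags == ["compensation"]

    def test_relocalization_into_paralog_compartment_is_compensation(self):
        call, _ = ps.call_comp_dep("none", "ER", "cytoplasm", "ER")
        assert call == "compensation"

    def test_relocalization_to_third_compartment_is_dependency(self):
        call, _ = ps.call_comp_dep("none", "vacuole", "cytoplasm", "ER")
        assert call == "dependency"

    def test_decrease_is_dependency(self):
        call, _ = ps.call_comp_dep("decreased", None, "cytoplasm", "ER")
        assert call == "dependency"

    def test_conflicting_evidence_reports_both_flags(self):
        call, flags = ps.call_comp_dep("increased", "vacuole", "cytoplasm", "ER")
        assert call == "conflict"
        assert set(flags) == {"compensation", "dependency"}

    def test_no_evidence_is_none(self):
        assert ps.call_comp_dep("none", None, "cytoplasm", "ER")[0] == "none"


class TestAbundanceAnalysis:
    def test_swapping_condition_labels_negates_lfc_preserves_p(self):
        rng = np.random.default_rng(2)
        wt = rng.normal(100, 10, 200)
        dl = rng.normal(120, 10, 200)
        fwd = abundance_analysis(
            {"g": {"paralog": "h", "score_wt": wt.mean(), "score_del": dl.mean(),
                   "cells_wt": wt, "cells_del": dl}}
        )[0]
        rev = abundance_analysis(
            {"g": {"paralog": "h", "score_wt": dl.mean(), "score_del": wt.mean(),
                   "cells_wt": dl, "cells_del": wt}}
        )[0]
        assert fwd.lfc == pytest.approx(-rev.lfc)
        assert fwd.p == pytest.approx(rev.p)
        assert fwd.direction == "increased" and rev.direction == "decreased"
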