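"""Exact nonparametric tests against brute-force enumeration and scipy,
Dahlberg reliability, and the cohort table builder."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mandasym.asym_stats import (
    build_tables,
    dahlberg_error,
    holm_adjust,
    mann_whitney_type_i_error,
    mann_whitney_u,
    significance_stars,
    spearman_rho,
    wilcoxon_signed_rank,
)
from mandasym.morphometry import SubjectRecord, records_to_frame
from conftest import side_means


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementation's count recursions)


def brute_force_mwu_p(x, y) -> float:
    """Two-sided exact p by enumerating all C(n+m, n) group labelings."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n, N = len(x), len(pooled)
    ranks = sps.rankdata(pooled)

    def u_of(idx):
        return ranks[list(idx)].sum() - n * (n + 1) / 2

    u_obs = u_of(range(n))
    us = np.array([u_of(c) for c in itertools.combinations(range(N), n)])
    centre = n * (N - n) / 2
    return float(np.mean(np.abs(us - centre) >= abs(u_obs - centre) - 1e-12))


def brute_force_wilcoxon_p(d) -> float:
    """Two-sided exact p by enumerating all 2^n sign patterns."""
    d = np.asarray(d, float)
    d = d[d != 0]
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    centre = n * (n + 1) / 4
    ws = []
    for signs in itertools.product((0, 1), repeat=n):
        ws.append(ranks[np.array(signs, bool)].sum())
    ws = np.array(ws)
    return float(np.mean(np.abs(ws - centre) >= abs(w_obs - centre) - 1e-12))


def brute_force_spearman_p(x, y) -> float:
    """Two-sided exact p by enumerating all n! pairings."""
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    rho_obs = np.corrcoef(rx, ry)[0, 1]
    hits = total = 0
    for perm in itertools.permutations(ry):
        rho = np.corrcoef(rx, perm)[0, 1]
        hits += abs(rho) >= abs(rho_obs) - 1e-12
        total += 1
    return hits / total


# ---------------------------------------------------------------------------


class TestMannWhitney:
    @pytest.mark.parametrize(
        "x, y, p",
        [
            ([1, 2], [3, 4], 2 / 6),
            ([1, 2, 3], [4, 5, 6], 2 / 20),
        ],
    )
    def test_complete_separation_small_samples(self, x, y, p):
        res = mann_whitney_u(x, y)
        assert res.method == "exact"
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_identical_multisets_give_p_one(self):
        assert mann_whitney_u([1, 2, 5], [1, 2, 5]).p_value == pytest.approx(1.0)
        assert mann_whitney_u([3.0] * 4, [3.0] * 4).p_value == pytest.approx(1.0)

    def test_matches_brute_force_enumeration(self, rng):
        for n, m in [(2, 3), (3, 3), (4, 4), (5, 5), (6, 6), (5, 7)]:
            x = rng.normal(size=n)
            y = rng.normal(loc=rng.normal(), size=m)
            res = mann_whitney_u(x, y)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(brute_force_mwu_p(x, y), abs=1e-12)

    def test_matches_scipy_exact(self, rng):
        for n, m in [(8, 9), (14, 14)]:
            x, y = rng.normal(size=n), rng.normal(0.7, size=m)
            res = mann_whitney_u(x, y)
            ref = sps.mannwhitneyu(x, y, method="exact")
            assert res.statistic == pytest.approx(float(ref.statistic))
            assert res.p_value == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        x, y = rng.normal(size=9), rng.normal(0.5, size=7)
        base = mann_whitney_u(x, y)
        trans = mann_whitney_u(np.exp(x), np.exp(y))
        assert trans.p_value == pytest.approx(base.p_value, abs=1e-12)
        assert trans.statistic == pytest.approx(base.statistic)

    def test_ties_fall_back_to_corrected_normal(self):
        res = mann_whitney_u([1, 1, 2, 3], [2, 3, 3, 4])
        assert res.method == "normal-approx"
        assert 0 < res.p_value <= 1

    def test_large_samples_use_normal_approx(self, rng):
        res = mann_whitney_u(rng.normal(size=25), rng.normal(size=25))
        assert res.method == "normal-approx"

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mann_whitney_u([], [1, 2])


class TestWilcoxon:
    def test_all_positive_small_sample(self):
        res = wilcoxon_signed_rank([1, 2, 3])
        assert res.statistic == 6.0
        assert res.p_value == pytest.approx(2 / 8, abs=1e-12)

    def test_antisymmetric_pair_by_enumeration(self):
        assert wilcoxon_signed_rank([1, -1]).p_value == pytest.approx(1.0)

    def test_all_zero_degenerate(self, caplog):
        with caplog.at_level("WARNING"):
            res = wilcoxon_signed_rank([0.0, 0.0, 0.0])
        assert res.p_value == 1.0
        assert any("zero" in r.message for r in caplog.records)

    def test_zeros_dropped_before_ranking(self):
        with_zeros = wilcoxon_signed_rank([0.0, 1.0, 2.0, 3.0, 0.0])
        without = wilcoxon_signed_rank([1.0, 2.0, 3.0])
        assert with_zeros.p_value == pytest.approx(without.p_value)
        assert with_zeros.n == (3,)

    def test_matches_brute_force_enumeration(self, rng):
        for n in (4, 6, 8, 10, 12):
            d = rng.normal(loc=0.4, size=n)
            res = wilcoxon_signed_rank(d)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(brute_force_wilcoxon_p(d), abs=1e-12)

    def test_matches_scipy_exact(self, rng):
        d = rng.normal(loc=0.5, size=14)
        res = wilcoxon_signed_rank(d)
        ref = sps.wilcoxon(d, method="exact")
        assert res.p_value == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_tied_magnitudes_fall_back_to_normal(self):
        res = wilcoxon_signed_rank([1.0, -1.0, 2.0, 3.0])
        assert res.method == "normal-approx"


class TestSpearman:
    def test_perfect_monotone(self):
        up = spearman_rho([1, 2, 3, 4], [10, 20, 30, 40])
        down = spearman_rho([1, 2, 3, 4], [4, 3, 2, 1])
        assert up.statistic == pytest.approx(1.0)
        assert down.statistic == pytest.approx(-1.0)

    def test_rank_difference_formula(self):
        # rho = 1 - 6*sum(d^2)/(n(n^2-1)) on tie-free data
        res = spearman_rho([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.statistic == pytest.approx(1 - 6 * 4 / (4 * 15), abs=1e-12)
        assert res.statistic == pytest.approx(0.6)

    def test_exact_p_matches_brute_force(self, rng):
        for n in (4, 5, 6, 7):
            x, y = rng.normal(size=n), rng.normal(size=n)
            res = spearman_rho(x, y)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(brute_force_spearman_p(x, y), abs=1e-12)

    def test_exact_p_with_ties_matches_brute_force(self, rng):
        x = np.array([1.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        y = rng.normal(size=6)
        res = spearman_rho(x, y)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(brute_force_spearman_p(x, y), abs=1e-12)

    def test_t_approximation_matches_scipy_for_large_n(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        res = spearman_rho(x, y)
        ref = sps.spearmanr(x, y)
        assert res.method == "t-approx"
        assert res.statistic == pytest.approx(float(ref.statistic), abs=1e-12)
        assert res.p_value == pytest.approx(float(ref.pvalue), rel=1e-9)

    def test_monotone_transform_invariance(self, rng):
        x, y = rng.normal(size=8), rng.normal(size=8)
        a = spearman_rho(x, y)
        b = spearman_rho(np.exp(x), y**3)
        assert b.statistic == pytest.approx(a.statistic, abs=1e-12)
        assert b.p_value == pytest.approx(a.p_value, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rho([1.0, 1.0, 1.0], [1, 2, 3])

    def test_length_mismatch_and_tiny_n_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            spearman_rho([1, 2], [2, 1])


class TestDahlberg:
    @pytest.mark.parametrize(
        "first, second, se",
        [
            ([5.0, 7.0, 9.0], [5.0, 7.0, 9.0], 0.0),
            ([1.0, 1.0], [0.0, 0.0], math.sqrt(2 / 4)),
            ([3.0], [0.0], math.sqrt(9 / 2)),
        ],
    )
    def test_formula(self, first, second, se):
        assert dahlberg_error(first, second) == pytest.approx(se, abs=1e-12)

    def test_linear_scaling(self, rng):
        a, b = rng.normal(size=10), rng.normal(size=10)
        base = dahlberg_error(a, b)
        for c in (0.0, 0.5, 3.0):
            assert dahlberg_error(c * a, c * b) == pytest.approx(c * base, abs=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            dahlberg_error([1, 2], [1])


def test_holm_adjustment_monotone_and_bounded():
    p = np.array([0.01, 0.04, 0.03, 0.5])
    adj = holm_adjust(p)
    assert np.all(adj >= p)
    assert np.all(adj <= 1.0)
    assert adj[0] == pytest.approx(0.04)


def test_significance_stars():
    assert significance_stars(0.001) == "**"
    assert significance_stars(0.03) == "*"
    assert significance_stars(0.2) == ""
    assert significance_stars(float("nan")) == ""


class TestTypeIError:
    def test_exact_test_holds_nominal_size(self):
        rate = mann_whitney_type_i_error(n=14, m=14, replicates=10_000, seed=99)
        assert 0.03 <= rate <= 0.07
        # discrete exact test is conservative: never above nominal by much
        assert rate <= 0.055


# ---------------------------------------------------------------------------
# table builder


def _mixed_cohort(n=6, spread=0.0, seed=5):
    """Small cohort: FA subjects at the published FA means (optionally
    jittered), NA subjects symmetric."""
    rng = np.random.default_rng(seed)
    recs = []
    fa_d, fa_n = side_means("FA", "deviated"), side_means("FA", "nondeviated")
    na = side_means("NA", "deviated")
    for i in range(n):
        recs.append(
            SubjectRecord(f"fa{i}", fa_d, fa_n, 8.9 + spread * rng.normal(), "left", "FA")
        )
        recs.append(SubjectRecord(f"na{i}", na, na, 1.6, "left", "NA"))
    return records_to_frame(recs)


class TestBuildTables:
    def test_symmetric_cohort_zero_differences_no_stars(self):
        df = _mixed_cohort()
        # overwrite FA rows to be symmetric too
        m = side_means("NA", "nondeviated")
        recs = [
            SubjectRecord(f"s{i}{g}", m, m, d, "left", g)
            for i in range(5)
            for g, d in (("FA", 9.0), ("NA", 1.0))
        ]
        tables = build_tables(records_to_frame(recs))
        assert np.allclose(tables.differences["FA_mean"], 0.0)
        assert np.allclose(tables.differences["NA_mean"], 0.0)
        assert (tables.differences["significance"] == "").all()

    def test_difference_means_equal_side_mean_differences(self):
        """Linearity of the mean ties the difference table to the side table."""
        tables = build_tables(_mixed_cohort())
        sides = tables.sides.set_index(["group", "measurement"])
        for _, row in tables.differences.iterrows():
            for g in ("FA", "NA"):
                s = sides.loc[(g, row["measurement"])]
                expected = s["nondeviated_mean"] - s["deviated_mean"]
                assert row[f"{g}_mean"] == pytest.approx(expected, abs=1e-9)

    def test_correlation_matrix_shape_and_symmetry(self):
        tables = build_tables(_mixed_cohort(n=8, spread=1.0))
        rho = tables.correlation_rho
        assert rho.shape == (7, 7)
        assert np.allclose(rho.values, rho.values.T, equal_nan=True)
        assert np.allclose(np.diag(rho.values), 1.0)

    def test_single_subject_groups_descriptive_only(self):
        df = _mixed_cohort(n=1)
        tables = build_tables(df)
        assert tables.differences["p_value"].isna().all()
        assert tables.sides["p_value"].isna().all()
        assert tables.side_comparisons["p_deviated"].isna().all()
        # descriptives still present
        assert np.isfinite(tables.differences["FA_mean"]).all()

    def test_missing_group_rejected(self):
        df = _mixed_cohort()
        with pytest.raises(ValueError, match="no NA subjects"):
            build_tables(df[df["group"] == "FA"])

    def test_pooled_side_comparison_mode_runs(self):
        df = _mixed_cohort(n=4, spread=0.5)
        matched = build_tables(df, side_comparison_mode="matched")
        pooled = build_tables(df, side_comparison_mode="pooled")
        assert not matched.side_comparisons.equals(pooled.side_comparisons)
        with pytest.raises(ValueError, match="side_comparison_mode"):
            build_tables(df, side_comparison_mode="bogus")
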