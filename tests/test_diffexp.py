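"""Weighted proportions test, fold change, BH FDR, and the comparison pipeline."""

import math

import numpy as np
import pandas as pd
import pytest

from embryoscreen import datasets
from embryoscreen.design import bj_design
from embryoscreen.diffexp import (
    ComparisonSpec,
    baggerley_group_estimate,
    baggerley_test,
    bh_fdr,
    fold_change,
    pseudo_counts,
    run_comparison,
)
from embryoscreen.errors import ValidationError
from embryoscreen.quantify import CountMatrix, ExpressionMatrix, quantile_normalize, rpkm


def brute_force_bh(p):
    """Step-up definition: q_(i) = min_{j>=i}(p_(j) * m / j), capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = min(running, 1.0)
    return q


class TestPseudoCounts:
    def test_inverse_of_rpkm(self):
        expr = ExpressionMatrix(
            values=pd.DataFrame({"S": [0.0, 5.0]}, index=["a", "b"]),
            normalised=True,
        )
        lengths = pd.Series([1000, 2000], index=["a", "b"])
        libs = pd.Series({"S": 1e6})
        out = pseudo_counts(expr, lengths, libs)
        assert out.counts["S"].tolist() == [0, 10]

    def test_round_trip_identity(self, small_counts):
        expr = rpkm(small_counts)
        back = pseudo_counts(expr, small_counts.lengths, small_counts.library_sizes)
        pd.testing.assert_frame_equal(back.counts, small_counts.counts)


class TestGroupEstimate:
    def test_equal_proportions_give_zero_sigma(self):
        est = baggerley_group_estimate([10, 20, 30], [1000, 2000, 3000])
        assert est.sigma2 == 0.0
        assert est.p_hat == pytest.approx(0.01)
        assert est.w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_library_binomial_fallback(self):
        est = baggerley_group_estimate([5], [100])
        assert est.p_hat == pytest.approx(0.05)
        assert est.sigma2 == 0.0
        assert est.V == pytest.approx(0.05 * 0.95 / 100)

    def test_large_n_limit_recovers_sample_variance(self):
        # binomial component vanishes; sigma^2 -> two-point sample variance
        n = 1e12
        p = np.array([2e-4, 6e-4])
        est = baggerley_group_estimate(p * n, [n, n])
        assert est.sigma2 == pytest.approx(np.var(p, ddof=1), rel=1e-6)

    def test_all_zero_group_degenerate(self):
        est = baggerley_group_estimate([0, 0], [100, 100])
        assert est.p_hat == 0.0 and est.V == 0.0

    def test_invalid_library_size(self):
        with pytest.raises(ValidationError):
            baggerley_group_estimate([1], [0])

    def test_duplicating_a_library_never_increases_variance(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            k = int(rng.integers(2, 5))
            n = rng.integers(10_000, 50_000, size=k).astype(float)
            x = rng.integers(0, 500, size=k).astype(float)
            base = baggerley_group_estimate(x, n)
            grown = baggerley_group_estimate(
                np.append(x, x[0]), np.append(n, n[0])
            )
            assert grown.V <= base.V + 1e-15


class TestBaggerleyTest:
    def test_identical_groups(self):
        a = baggerley_group_estimate([10, 12], [1000, 1000])
        t, df, p = baggerley_test(a, a)
        assert t == 0.0 and p == 1.0

    def test_antisymmetric(self):
        a = baggerley_group_estimate([10, 30], [1000, 1000])
        b = baggerley_group_estimate([50, 70], [1000, 1000])
        t_ab, _, p_ab = baggerley_test(a, b)
        t_ba, _, p_ba = baggerley_test(b, a)
        assert t_ab == pytest.approx(-t_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_single_libraries_match_two_proportion_z(self):
        x1, n1, x2, n2 = 40, 10_000, 90, 12_000
        a = baggerley_group_estimate([x1], [n1])
        b = baggerley_group_estimate([x2], [n2])
        t, df, p = baggerley_test(a, b)
        p1, p2 = x1 / n1, x2 / n2
        z = (p1 - p2) / math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
        assert t == pytest.approx(z)
        assert math.isinf(df)  # unreplicated: standard normal reference

    def test_both_groups_all_zero(self):
        a = baggerley_group_estimate([0, 0], [100, 100])
        t, _, p = baggerley_test(a, a)
        assert p == 1.0


class TestFoldChange:
    def test_published_male_up_example(self):
        # single male library vs two female libraries, comparison-B pattern
        fc = fold_change(185.79, np.mean([0.1, 3.29]))
        assert fc.magnitude == pytest.approx(109.6, abs=0.1)
        assert fc.value > 0

    def test_equal_means(self):
        fc = fold_change(7.0, 7.0)
        assert fc.value == 1.0 and not fc.degenerate

    def test_both_zero_degenerate(self):
        fc = fold_change(0.0, 0.0)
        assert fc.value == 1.0 and fc.degenerate

    def test_one_zero_infinite(self):
        assert math.isinf(fold_change(5.0, 0.0).value)
        assert fold_change(0.0, 5.0).value == -np.inf

    def test_sign_convention(self):
        assert fold_change(2.0, 10.0).value == pytest.approx(-5.0)
        assert fold_change(10.0, 2.0).value == pytest.approx(5.0)

    def test_negative_mean_rejected(self):
        with pytest.raises(ValidationError):
            fold_change(-1.0, 1.0)


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr([0.3]).tolist() == [0.3]

    def test_hand_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_matches_brute_force_step_up(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            m = int(rng.integers(1, 60))
            p = rng.random(m)
            np.testing.assert_allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)

    def test_q_at_least_p(self):
        rng = np.random.default_rng(22)
        p = rng.random(100)
        assert (bh_fdr(p) >= p - 1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])


@pytest.fixture(scope="module")
def cellularisation_counts():
    """The three cellularisation transcripts as pseudo-counts.

    Published normalised RPKM values are converted to counts with a
    1e9-read pseudo library so count = rpkm * length (exact inversion).
    """
    panel = datasets.marker_panel()
    rows = ["nullo", "serendipity_alpha", "slow_as_molasses"]
    values = panel.loc[rows, list(datasets.SAMPLES_ALL)].astype(float)
    lengths = panel.loc[rows, "length_bp"].astype(int)
    counts = (values.mul(lengths, axis=0)).round().astype(np.int64)
    libs = pd.Series(1e9, index=values.columns)
    return CountMatrix(counts=counts, lengths=lengths, library_sizes=libs)


class TestRunComparison:
    def test_slam_tops_late_vs_early(self, cellularisation_counts):
        spec = ComparisonSpec(
            id="early-vs-late",
            case=("BJ2", "BJ3", "BJ4"),
            baseline=("BJ6", "BJ7", "BJ8"),
            excluded=("BJ1", "BJ5"),
        )
        de = run_comparison(cellularisation_counts, bj_design(), spec)
        slam = de.table.loc["slow_as_molasses"]
        assert slam["fold_change"] > 1  # up-regulated in the older embryos
        assert slam["p"] < 0.001
        assert de.table["p"].idxmin() == "slow_as_molasses"

    def test_case_equals_baseline_rejected(self):
        with pytest.raises(ValidationError):
            ComparisonSpec(id="bad", case=("BJ1",), baseline=("BJ1",))

    def test_excluded_overlap_rejected(self):
        with pytest.raises(ValidationError):
            ComparisonSpec(
                id="bad", case=("BJ1",), baseline=("BJ2",), excluded=("BJ1",)
            )

    def test_unknown_sample_rejected(self, cellularisation_counts):
        spec = ComparisonSpec(id="x", case=("BJ9",), baseline=("BJ2",))
        with pytest.raises(ValidationError):
            run_comparison(cellularisation_counts, bj_design(), spec)

    def test_intermediates_retained(self, cellularisation_counts):
        spec = ComparisonSpec(
            id="i", case=("BJ2", "BJ3"), baseline=("BJ6", "BJ7")
        )
        de = run_comparison(cellularisation_counts, bj_design(), spec)
        assert de.expression.normalised
        assert set(de.expression.scope) == {"BJ2", "BJ3", "BJ6", "BJ7"}
        for col in ("mean_case", "mean_baseline", "fold_change", "t", "p", "q"):
            assert col in de.table.columns
        assert (de.table["q"] >= de.table["p"] - 1e-15).all()
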