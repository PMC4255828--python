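"""Weighted proportions (Baggerley-style) differential expression test.

For each transcript and group of libraries, the observed proportion of each
library's reads, p_i = x_i / n_i, is modelled as binomial sampling around a
transcript proportion that itself varies between libraries with variance
sigma^2 (overdispersion). The group estimate is the two-stage weighted
scheme of Baggerly et al. (2003):

1. start with weights w_i proportional to n_i;
2. pooled estimate p_hat = sum(w_i * p_i);
3. sigma^2 solved by moment matching
   sum((p_i - p_hat)^2 / v_i) = k - 1, with v_i = p_hat(1-p_hat)/n_i + sigma^2,
   clipped at 0 (bisection);
4. w_i proportional to 1/v_i, renormalised; repeat 2-4 to convergence.

The estimator variance is V = 1 / sum(1/v_i). Two groups are compared with
t = (p_hat_A - p_hat_B) / sqrt(V_A + V_B) on k_A + k_B - 2 degrees of
freedom, two-sided. A single-library group falls back to the binomial
variance (sigma^2 = 0); when either group is unreplicated the variance on
that side is the known binomial one rather than an estimate, and the
statistic is referenced against the standard normal (df reported as inf) —
a t reference with df = 1 has Cauchy tails and would make unreplicated
contrasts unable to reach any small significance level regardless of
effect size.

The test is applied to quantile-normalised expression via pseudo-counts:
x = round(value * L * N / 1e9), the inverse of the RPKM formula, with each
library's true size as the binomial total n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .design import StudyDesign
from .errors import ValidationError
from .quantify import CountMatrix, ExpressionMatrix, group_mean, quantile_normalize, rpkm

log = logging.getLogger(__name__)

_CONV_TOL = 1e-12
_MAX_ITER = 100
_BISECT_ITER = 60

DIRECTIONS = ("up-in-case", "up-in-baseline", "both")


# ---------------------------------------------------------------------------
# Types


@dataclass
class WeightedProportion:
    """Per-group weighted proportion estimate for one transcript."""

    p: np.ndarray  # per-library proportions
    w: np.ndarray  # weights, sum to 1
    p_hat: float
    sigma2: float  # between-library variance
    V: float  # variance of p_hat
    k: int  # number of libraries


@dataclass(frozen=True)
class ExpressionFilter:
    """Keep transcripts whose mean over ``samples`` is strictly below ``bound``."""

    samples: tuple[str, ...]
    bound: float


@dataclass
class ComparisonSpec:
    """One contrast: case vs baseline groups with exclusions and thresholds."""

    id: str
    case: tuple[str, ...]
    baseline: tuple[str, ...]
    excluded: tuple[str, ...] = ()
    fdr_alpha: float = 0.001
    direction: str = "both"
    expression_filter: Optional[ExpressionFilter] = None

    def __post_init__(self) -> None:
        self.case = tuple(self.case)
        self.baseline = tuple(self.baseline)
        self.excluded = tuple(self.excluded)
        if not self.case or not self.baseline:
            raise ValidationError(f"comparison {self.id!r}: empty case or baseline group")
        overlap = set(self.case) & set(self.baseline)
        if overlap:
            raise ValidationError(
                f"comparison {self.id!r}: case and baseline overlap: {sorted(overlap)}"
            )
        bad = set(self.excluded) & (set(self.case) | set(self.baseline))
        if bad:
            raise ValidationError(
                f"comparison {self.id!r}: excluded samples occur in a group: {sorted(bad)}"
            )
        if not 0.0 < self.fdr_alpha < 1.0:
            raise ValidationError(f"comparison {self.id!r}: fdr_alpha must be in (0, 1)")
        if self.direction not in DIRECTIONS:
            raise ValidationError(
                f"comparison {self.id!r}: direction must be one of {DIRECTIONS}"
            )

    @property
    def included(self) -> tuple[str, ...]:
        return self.case + self.baseline


@dataclass
class DETable:
    """Per-transcript results of one comparison, intermediates retained."""

    spec: ComparisonSpec
    table: pd.DataFrame  # mean_case, mean_baseline, fold_change, degenerate, t, p, q, significant
    expression: ExpressionMatrix  # the per-comparison normalised matrix
    df: float  # inf when the comparison is unreplicated (normal reference)

    @property
    def significant_ids(self) -> set[str]:
        return set(self.table.index[self.table["significant"]])


# ---------------------------------------------------------------------------
# Pseudo-counts


def pseudo_counts(
    expr: ExpressionMatrix, lengths: pd.Series, library_sizes: pd.Series
) -> CountMatrix:
    """Invert the RPKM formula: x = round(value * L * N / 1e9)."""
    if not expr.normalised:
        log.debug("pseudo_counts called on non-normalised expression")
    lengths = lengths.reindex(expr.values.index)
    library_sizes = library_sizes.reindex(expr.values.columns)
    x = (
        expr.values.mul(lengths.astype(float), axis=0)
        .mul(library_sizes.astype(float), axis=1)
        / 1e9
    )
    return CountMatrix(
        counts=x.round().astype(np.int64),
        lengths=lengths,
        library_sizes=library_sizes,
    )


# ---------------------------------------------------------------------------
# Group estimation (vectorised over transcripts; scalar API wraps it)


def _estimate_groups(x: np.ndarray, n: np.ndarray) -> tuple[np.ndarray, ...]:
    """Vectorised weighted-proportion estimate.

    x: (T, k) counts; n: (k,) library totals. Returns (p_hat, sigma2, V, P, W)
    with per-transcript arrays. Transcripts whose libraries are all at a
    degenerate proportion (all 0 or all n) get V = 0.
    """
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    if x.ndim != 2 or x.shape[1] != n.shape[0]:
        raise ValidationError("count matrix and library sizes disagree in shape")
    if (n <= 0).any():
        raise ValidationError("library sizes must be > 0")
    t_count, k = x.shape
    p = np.clip(x / n, 0.0, 1.0)
    if k == 1:
        p_hat = p[:, 0]
        sigma2 = np.zeros(t_count)
        v_est = p_hat * (1.0 - p_hat) / n[0]
        w = np.ones((t_count, 1))
        return p_hat, sigma2, v_est, p, w

    w = np.broadcast_to(n / n.sum(), (t_count, k)).copy()
    sigma2 = np.zeros(t_count)
    p_hat = (w * p).sum(axis=1)
    for _ in range(_MAX_ITER):
        binom = p_hat[:, None] * (1.0 - p_hat[:, None]) / n[None, :]
        dev2 = (p - p_hat[:, None]) ** 2
        # moment matching: sum(dev2 / (binom + s)) = k - 1, decreasing in s
        with np.errstate(divide="ignore", invalid="ignore"):
            f0 = np.where(binom > 0, dev2 / binom, np.inf * (dev2 > 0)).sum(axis=1)
        need = f0 > (k - 1)
        sigma2 = np.zeros(t_count)
        if need.any():
            hi = dev2[need].sum(axis=1) / (k - 1)  # f(hi) <= k-1 by construction
            lo = np.zeros_like(hi)
            b_need = binom[need]
            d_need = dev2[need]
            for _b in range(_BISECT_ITER):
                mid = 0.5 * (lo + hi)
                fmid = (d_need / (b_need + mid[:, None])).sum(axis=1)
                high = fmid > (k - 1)
                lo = np.where(high, mid, lo)
                hi = np.where(high, hi, mid)
            sigma2[need] = 0.5 * (lo + hi)
        v = binom + sigma2[:, None]
        with np.errstate(divide="ignore"):
            inv_v = np.where(v > 0, 1.0 / v, 0.0)
        denom = inv_v.sum(axis=1)
        w = np.where(
            denom[:, None] > 0, inv_v / np.where(denom[:, None] > 0, denom[:, None], 1.0),
            1.0 / k,
        )
        p_new = (w * p).sum(axis=1)
        delta = np.abs(p_new - p_hat)
        p_hat = p_new
        if (delta < _CONV_TOL).all():
            break
    binom = p_hat[:, None] * (1.0 - p_hat[:, None]) / n[None, :]
    v = binom + sigma2[:, None]
    with np.errstate(divide="ignore"):
        inv_v = np.where(v > 0, 1.0 / v, 0.0)
    denom = inv_v.sum(axis=1)
    v_est = np.where(denom > 0, 1.0 / np.where(denom > 0, denom, 1.0), 0.0)
    return p_hat, sigma2, v_est, p, w


def baggerley_group_estimate(x: Sequence[float], n: Sequence[float]) -> WeightedProportion:
    """Weighted proportion estimate for one transcript in one group."""
    x_arr = np.asarray(x, dtype=float)
    n_arr = np.asarray(n, dtype=float)
    if x_arr.ndim != 1 or x_arr.shape != n_arr.shape or x_arr.size < 1:
        raise ValidationError("x and n must be equal-length non-empty vectors")
    p_hat, sigma2, v_est, p, w = _estimate_groups(x_arr[None, :], n_arr)
    return WeightedProportion(
        p=p[0], w=w[0], p_hat=float(p_hat[0]), sigma2=float(sigma2[0]),
        V=float(v_est[0]), k=x_arr.size,
    )


def _degrees_of_freedom(k_a: int, k_b: int) -> float:
    """t df for replicated groups; inf (normal reference) when either k == 1."""
    if min(k_a, k_b) == 1:
        return np.inf
    return float(max(k_a + k_b - 2, 1))


def baggerley_test(
    group_a: WeightedProportion, group_b: WeightedProportion
) -> tuple[float, float, float]:
    """Two-sided weighted t (z when unreplicated) comparison of two groups."""
    df = _degrees_of_freedom(group_a.k, group_b.k)
    t, p = _t_test(
        np.array([group_a.p_hat]), np.array([group_b.p_hat]),
        np.array([group_a.V]), np.array([group_b.V]), df,
    )
    return float(t[0]), df, float(p[0])


def proportions_test(
    xa: np.ndarray, na: np.ndarray, xb: np.ndarray, nb: np.ndarray
) -> tuple[np.ndarray, float, np.ndarray]:
    """Vectorised two-group weighted proportions test over many transcripts.

    xa, xb: (T, k_A) and (T, k_B) count matrices; na, nb: library totals.
    Returns (t, df, p) with t and p per transcript.
    """
    pa, _, va, _, _ = _estimate_groups(np.atleast_2d(xa), np.asarray(na))
    pb, _, vb, _, _ = _estimate_groups(np.atleast_2d(xb), np.asarray(nb))
    df = _degrees_of_freedom(np.atleast_2d(xa).shape[1], np.atleast_2d(xb).shape[1])
    t, p = _t_test(pa, pb, va, vb, df)
    return t, df, p


def _sf(x: np.ndarray, df: float) -> np.ndarray:
    if np.isinf(df):
        return stats.norm.sf(x)
    return stats.t.sf(x, df)


def _t_test(pa, pb, va, vb, df):
    denom = np.sqrt(va + vb)
    diff = pa - pb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0),
                     np.where(diff == 0, 0.0, np.sign(diff) * np.inf))
    p = np.where(np.isinf(t), 0.0, 2.0 * _sf(np.abs(np.where(np.isinf(t), 0, t)), df))
    p = np.where((denom == 0) & (diff == 0), 1.0, p)
    return t, np.clip(p, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Fold change and FDR


@dataclass(frozen=True)
class FoldChange:
    value: float  # signed; |value| >= 1; +/-inf when one mean is 0
    degenerate: bool  # both means 0, or one mean 0 (infinite ratio)

    @property
    def magnitude(self) -> float:
        return abs(self.value)


def fold_change(case_mean: float, baseline_mean: float) -> FoldChange:
    """Signed ratio fold change; negative when case < baseline."""
    if case_mean < 0 or baseline_mean < 0:
        raise ValidationError("means must be non-negative")
    if case_mean == 0 and baseline_mean == 0:
        return FoldChange(1.0, True)
    if baseline_mean == 0:
        return FoldChange(np.inf, True)
    if case_mean == 0:
        return FoldChange(-np.inf, True)
    if case_mean >= baseline_mean:
        return FoldChange(case_mean / baseline_mean, False)
    return FoldChange(-baseline_mean / case_mean, False)


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p_arr = np.asarray(p, dtype=float)
    if p_arr.size == 0:
        return p_arr
    if np.isnan(p_arr).any() or (p_arr < 0).any() or (p_arr > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p_arr, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Full comparison pipeline


def run_comparison(
    counts: CountMatrix, design: StudyDesign, spec: ComparisonSpec
) -> DETable:
    """subset -> rpkm -> quantile normalise -> means/FC -> test -> BH."""
    for sid in spec.included:
        if sid not in design:
            raise ValidationError(f"comparison {spec.id!r}: sample {sid!r} not in design")
    if len(spec.case) == 1 or len(spec.baseline) == 1:
        log.warning(
            "comparison %s is unreplicated on one side (binomial fallback variance)",
            spec.id,
        )
    included = list(spec.included)
    sub = counts.subset_samples(included)
    expr = quantile_normalize(rpkm(sub), included)

    mean_case = group_mean(expr, list(spec.case))
    mean_base = group_mean(expr, list(spec.baseline))
    fcs = [fold_change(c, b) for c, b in zip(mean_case, mean_base)]

    pseudo = pseudo_counts(expr, sub.lengths, sub.library_sizes)
    xa = pseudo.counts[list(spec.case)].to_numpy()
    xb = pseudo.counts[list(spec.baseline)].to_numpy()
    na = pseudo.library_sizes[list(spec.case)].to_numpy()
    nb = pseudo.library_sizes[list(spec.baseline)].to_numpy()

    pa, _, va, _, _ = _estimate_groups(xa, na)
    pb, _, vb, _, _ = _estimate_groups(xb, nb)
    df = _degrees_of_freedom(len(spec.case), len(spec.baseline))
    t, p = _t_test(pa, pb, va, vb, df)
    q = bh_fdr(p)

    table = pd.DataFrame(
        {
            "mean_case": mean_case,
            "mean_baseline": mean_base,
            "fold_change": [f.value for f in fcs],
            "degenerate": [f.degenerate for f in fcs],
            "t": t,
            "p": p,
            "q": q,
            "significant": q < spec.fdr_alpha,
        },
        index=expr.values.index,
    )
    return DETable(spec=spec, table=table, expression=expr, df=df)
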