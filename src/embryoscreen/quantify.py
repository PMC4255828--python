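"""Counts -> RPKM, quantile normalisation, group means, and PCoA sample QC.

RPKM = 1e9 * C / (N * L) with C the read count, N the library size (total
mapped reads of the library, supplied, not inferred) and L the transcript
length in bp. Quantile normalisation replaces each column's values, within
a chosen sample subset, by the mean across columns of the order statistics
at the same rank (ties receive the mean of the row-means over the tied rank
range), so all normalised columns share one value distribution. The
normalisation scope is recorded because it is per comparison: only the
samples entering a contrast are normalised together.

PCoA is classical metric scaling of a sample-sample distance matrix
(double-centred squared distances, eigendecomposed); negative eigenvalues
are reported but their axes dropped. The default distance is plain
Euclidean on the expression values handed in — run it on raw (not
quantile-normalised) RPKM for sample QC, where it is the metric-scaling
equivalent of a PCA on expression values and lets high-expression dynamics
dominate, which is exactly what exposes a developmentally lagging library.
A log2(x+1) Euclidean variant is available but note that it compresses
linear expression mixtures toward the high-expression profile, which can
mask such a library.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import ValidationError


@dataclass
class CountMatrix:
    """Integer read counts per transcript per sample, with lengths and depths."""

    counts: pd.DataFrame  # transcripts x samples, int
    lengths: pd.Series  # bp per transcript
    library_sizes: pd.Series  # total mapped reads per sample

    def __post_init__(self) -> None:
        self.counts = self.counts.rename_axis(index="transcript_id", columns=None)
        if self.counts.columns.duplicated().any():
            raise ValidationError("duplicate sample ids in count matrix")
        if self.counts.index.duplicated().any():
            raise ValidationError("duplicate transcript ids in count matrix")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = list(self.lengths.index[self.lengths.isna()])[:3]
            raise ValidationError(f"missing length for transcripts {missing}")
        if (self.lengths < 1).any():
            raise ValidationError("transcript lengths must be >= 1 bp")
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)
        if self.library_sizes.isna().any():
            missing = list(self.library_sizes.index[self.library_sizes.isna()])
            raise ValidationError(f"missing library size for samples {missing}")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_samples(self, samples: Sequence[str]) -> "CountMatrix":
        unknown = [s for s in samples if s not in self.counts.columns]
        if unknown:
            raise ValidationError(f"unknown sample ids: {unknown}")
        return CountMatrix(
            self.counts[list(samples)].copy(),
            self.lengths.copy(),
            self.library_sizes[list(samples)].copy(),
        )


@dataclass
class ExpressionMatrix:
    """RPKM per transcript per sample, raw or quantile-normalised."""

    values: pd.DataFrame  # transcripts x samples, float, >= 0
    normalised: bool = False
    scope: Optional[tuple[str, ...]] = None  # samples normalised together

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("expression values must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def rpkm(counts: CountMatrix) -> ExpressionMatrix:
    """Reads Per Kilobase of transcript per Million mapped reads."""
    bad = counts.library_sizes[counts.library_sizes <= 0]
    if len(bad):
        raise ValidationError(f"library size must be > 0 for sample {bad.index[0]!r}")
    values = (
        1e9
        * counts.counts.astype(float)
        / counts.library_sizes.astype(float)
    ).div(counts.lengths.astype(float), axis=0)
    return ExpressionMatrix(values=values, normalised=False)


def _quantile_column(col: np.ndarray, mean_quantiles: np.ndarray) -> np.ndarray:
    """Map one column onto the mean order statistics, averaging over ties."""
    order = np.argsort(col, kind="stable")
    assigned = np.empty_like(mean_quantiles)
    assigned[order] = mean_quantiles
    out = pd.Series(assigned).groupby(pd.Series(col)).transform("mean")
    return out.to_numpy()


def quantile_normalize(
    expr: ExpressionMatrix, samples: Optional[Sequence[str]] = None
) -> ExpressionMatrix:
    """Quantile-normalise the given sample subset; other columns untouched."""
    samples = list(samples) if samples is not None else expr.sample_ids
    unknown = [s for s in samples if s not in expr.values.columns]
    if unknown:
        raise ValidationError(f"unknown sample ids: {unknown}")
    if len(samples) < 2:
        raise ValidationError("quantile normalisation needs >= 2 samples")
    sub = expr.values[samples].to_numpy(dtype=float)
    mean_quantiles = np.sort(sub, axis=0).mean(axis=1)
    out = expr.values.copy()
    for j, sid in enumerate(samples):
        out[sid] = _quantile_column(sub[:, j], mean_quantiles)
    return ExpressionMatrix(values=out, normalised=True, scope=tuple(samples))


def group_mean(expr: ExpressionMatrix, samples: Sequence[str]) -> pd.Series:
    """Arithmetic per-transcript mean over the subset, zeros included."""
    samples = list(samples)
    if not samples:
        raise ValidationError("group_mean needs a non-empty sample subset")
    unknown = [s for s in samples if s not in expr.values.columns]
    if unknown:
        raise ValidationError(f"unknown sample ids: {unknown}")
    return expr.values[samples].mean(axis=1)


# ---------------------------------------------------------------------------
# PCoA

SUPPORTED_METRICS = ("euclidean", "euclidean-log", "braycurtis")


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # samples x retained axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray = field(default=None)  # over positive part

    def distance_to_centroid(self, sample: str, others: Iterable[str]) -> float:
        c = self.coordinates.loc[list(others)].mean(axis=0)
        return float(np.linalg.norm(self.coordinates.loc[sample] - c))


def _distances(expr: ExpressionMatrix, metric: str) -> np.ndarray:
    x = expr.values.to_numpy(dtype=float).T  # samples x transcripts
    if metric == "euclidean-log":
        return squareform(pdist(np.log2(x + 1.0), metric="euclidean"))
    if metric == "euclidean":
        return squareform(pdist(x, metric="euclidean"))
    if metric == "braycurtis":
        return squareform(pdist(x, metric="braycurtis"))
    raise ValidationError(
        f"unknown metric {metric!r}; supported: {', '.join(SUPPORTED_METRICS)}"
    )


def pcoa(expr: ExpressionMatrix, metric: str = "euclidean") -> PCoAResult:
    """Classical metric scaling of the sample-sample distance matrix."""
    if len(expr.sample_ids) < 3:
        raise ValidationError("pcoa needs >= 3 samples")
    d = _distances(expr, metric)
    return pcoa_from_distances(d, expr.sample_ids)


def pcoa_from_distances(d: np.ndarray, sample_ids: Sequence[str]) -> PCoAResult:
    """PCoA on an explicit symmetric distance matrix."""
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T):
        raise ValidationError("distance matrix must be square and symmetric")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = 1e-9 * max(abs(eigvals[0]), 1.0)
    keep = eigvals > tol
    coords = eigvecs[:, keep] * np.sqrt(eigvals[keep])
    pos_sum = eigvals[keep].sum()
    return PCoAResult(
        coordinates=pd.DataFrame(
            coords,
            index=list(sample_ids),
            columns=[f"PCo{i + 1}" for i in range(int(keep.sum()))],
        ),
        eigenvalues=eigvals,
        proportion_explained=(eigvals[keep] / pos_sum) if pos_sum > 0 else eigvals[keep],
    )
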