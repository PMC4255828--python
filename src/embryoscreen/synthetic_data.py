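"""Synthetic sexed-embryo count matrices (and reads) with known ground truth.

The generator emulates the statistical structure of the eight-library
pre-blastoderm design: five transcript classes with distinct developmental
dynamics, negative-binomial counting noise, and one developmentally
"lagging" late library whose expected profile is pulled toward the early
profile (the BJ1 phenomenon).

Transcript classes
------------------
maternal_stable
    Deposited in the egg, constant across the window (tra-2-like).
maternal_degrading
    Maternal, degraded as development proceeds (smaug-like, default 10x down).
zygotic_shared
    Activated by the zygotic genome in both sexes (slam-like, default 75x up).
zygotic_male_only
    Activated only in male embryos; expected RPKM is exactly 0 in every
    female library (the Y-transcript candidate class).
contaminant_sporadic
    Expressed at high level in exactly one randomly chosen library and zero
    elsewhere (fungal/bacterial carry-over).

Counts are drawn per cell as NB(mean=m, var=m + dispersion*m^2) with
``m = rpkm * length_bp * library_size / 1e9``; dispersion 0 degenerates to
Poisson. All randomness flows from ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .design import StudyDesign, bj_design
from .errors import ValidationError
from .quantify import CountMatrix
from .read_qc import PhredRead

CLASSES = (
    "maternal_stable",
    "maternal_degrading",
    "zygotic_shared",
    "zygotic_male_only",
    "contaminant_sporadic",
)

#: default transcripts per class (contaminants are sporadic, hence few)
_DEFAULT_N = {
    "maternal_stable": 60,
    "maternal_degrading": 60,
    "zygotic_shared": 60,
    "zygotic_male_only": 60,
    "contaminant_sporadic": 10,
}

#: expected RPKM in each class's "on" condition (early for maternal classes,
#: late for zygotic classes, the single expressing library for contaminants)
_DEFAULT_BASELINE = {
    "maternal_stable": 50.0,
    "maternal_degrading": 30.0,
    "zygotic_shared": 300.0,
    "zygotic_male_only": 40.0,
    "contaminant_sporadic": 150.0,
}

#: multiplicative early -> late change
_DEFAULT_FOLD = {
    "maternal_stable": 1.0,
    "maternal_degrading": 0.1,
    "zygotic_shared": 75.0,
    "zygotic_male_only": 20.0,
    "contaminant_sporadic": 1.0,
}


@dataclass
class SimConfig:
    n_per_class: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_N))
    baseline_rpkm: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_BASELINE))
    fold_dynamics: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_FOLD))
    dispersion: float = 0.01
    library_size_mean: float = 2_000_000.0
    library_size_spread: float = 200_000.0
    transcript_length_range: tuple[int, int] = (200, 5000)
    lag_fraction: float = 0.8
    lag_sample: Optional[str] = None  # default: first male late replicate
    seed: int = 0

    def __post_init__(self) -> None:
        for cls in self.n_per_class:
            if cls not in CLASSES:
                raise ValidationError(f"n_per_class: unknown class {cls!r}")
        for cls, n in self.n_per_class.items():
            if n < 0:
                raise ValidationError(f"n_per_class[{cls!r}] must be >= 0, got {n}")
        for cls, b in self.baseline_rpkm.items():
            if b < 0:
                raise ValidationError(f"baseline_rpkm[{cls!r}] must be >= 0, got {b}")
        for cls, f in self.fold_dynamics.items():
            if f <= 0:
                raise ValidationError(f"fold_dynamics[{cls!r}] must be > 0, got {f}")
        if self.dispersion < 0:
            raise ValidationError(f"dispersion must be >= 0, got {self.dispersion}")
        if not 0.0 <= self.lag_fraction <= 1.0:
            raise ValidationError(f"lag_fraction must be in [0, 1], got {self.lag_fraction}")
        lo, hi = self.transcript_length_range
        if lo < 100 or hi < lo:
            raise ValidationError(
                f"transcript_length_range must satisfy 100 <= lo <= hi, got {lo, hi}"
            )
        if self.library_size_mean <= 0 or self.library_size_spread < 0:
            raise ValidationError("library_size_mean must be > 0 and spread >= 0")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass
class SimTruth:
    """Ground truth: class label per transcript, expected per-sample RPKM."""

    labels: pd.Series  # transcript_id -> class
    expected_rpkm: pd.DataFrame  # transcripts x samples

    def of_class(self, cls: str) -> list[str]:
        return list(self.labels.index[self.labels == cls])


def simulate_design() -> StudyDesign:
    """The fixed eight-sample reference design (BJ1-BJ8)."""
    return bj_design()


def _expected_rpkm(
    config: SimConfig, design: StudyDesign, labels: pd.Series, rng: np.random.Generator
) -> pd.DataFrame:
    """Expected RPKM per transcript and sample, lag applied to the lag sample."""
    n_t = len(labels)
    samples = design.sample_ids
    early = np.zeros((n_t, len(samples)))
    late = np.zeros_like(early)

    for j, sid in enumerate(samples):
        sample = design.get(sid)
        for i, cls in enumerate(labels.to_numpy()):
            base = config.baseline_rpkm.get(cls, 0.0)
            fold = config.fold_dynamics.get(cls, 1.0)
            if cls in ("maternal_stable", "maternal_degrading"):
                e, l = base, base * fold
            elif cls == "zygotic_shared":
                e, l = base / fold, base
            elif cls == "zygotic_male_only":
                if sample.sex == "female":
                    e = l = 0.0
                else:
                    e, l = base / fold, base
            else:  # contaminant_sporadic: handled separately below
                e = l = 0.0
            early[i, j], late[i, j] = e, l

    expected = np.where(
        [design.get(s).stage == "late" for s in samples], late, early
    )

    # one lagging late library: profile pulled toward the early profile
    lag_sample = config.lag_sample
    if lag_sample is None:
        male_late = design.group(sex="male", stage="late")
        lag_sample = male_late[0] if male_late else None
    if lag_sample is not None and config.lag_fraction > 0:
        if lag_sample not in design:
            raise ValidationError(f"lag_sample {lag_sample!r} not in design")
        j = samples.index(lag_sample)
        f = config.lag_fraction
        expected[:, j] = (1.0 - f) * late[:, j] + f * early[:, j]

    # contaminants: high in exactly one randomly chosen library, 0 elsewhere
    contaminants = np.flatnonzero(labels.to_numpy() == "contaminant_sporadic")
    base = config.baseline_rpkm.get("contaminant_sporadic", 0.0)
    for i in contaminants:
        expected[i, rng.integers(0, len(samples))] = base

    return pd.DataFrame(expected, index=labels.index, columns=samples)


def simulate_counts(config: SimConfig, design: StudyDesign) -> tuple[CountMatrix, SimTruth]:
    """Draw a count matrix with ground-truth labels under the class model."""
    if len(design) == 0:
        raise ValidationError("design is empty")
    rng = np.random.default_rng(config.seed)

    ids, label_list = [], []
    for cls in CLASSES:
        n = config.n_per_class.get(cls, 0)
        for k in range(n):
            ids.append(f"T{len(ids):05d}")
            label_list.append(cls)
    labels = pd.Series(label_list, index=pd.Index(ids, name="transcript_id"), dtype=object)

    lo, hi = config.transcript_length_range
    lengths = pd.Series(
        rng.integers(lo, hi + 1, size=len(ids)), index=labels.index, name="length_bp"
    )

    n_samples = len(design)
    lib_sizes = rng.normal(config.library_size_mean, config.library_size_spread, n_samples)
    lib_sizes = np.maximum(np.round(lib_sizes), 1000.0)
    library_sizes = pd.Series(lib_sizes, index=design.sample_ids, name="library_size")

    expected = _expected_rpkm(config, design, labels, rng)

    mean = (
        expected.to_numpy()
        * lengths.to_numpy()[:, None]
        * lib_sizes[None, :]
        / 1e9
    )
    if config.dispersion == 0:
        counts = rng.poisson(mean)
    else:
        r = 1.0 / config.dispersion
        with np.errstate(divide="ignore", invalid="ignore"):
            p = r / (r + mean)
        counts = np.where(mean > 0, rng.negative_binomial(r, np.where(mean > 0, p, 1.0)), 0)

    matrix = CountMatrix(
        counts=pd.DataFrame(counts.astype(np.int64), index=labels.index, columns=design.sample_ids),
        lengths=lengths,
        library_sizes=library_sizes,
    )
    truth = SimTruth(labels=labels, expected_rpkm=expected)
    return matrix, truth


# ---------------------------------------------------------------------------
# Read simulation (fixtures for the trimming stage)


@dataclass(frozen=True)
class QualityProfile:
    """Shape of simulated per-base qualities.

    ``tail_len`` bases at the 3' end are emitted at ``tail_q``; the rest at
    ``body_q``. ``n_prob`` is the per-base chance of an ambiguous call.
    """

    read_length: int = 100
    body_q: int = 40
    tail_len: int = 0
    tail_q: int = 2
    n_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.read_length < 0 or self.tail_len < 0 or self.tail_len > self.read_length:
            raise ValidationError("invalid read/tail length")
        if not 0.0 <= self.n_prob <= 1.0:
            raise ValidationError(f"n_prob must be in [0, 1], got {self.n_prob}")


#: named presets used throughout the tests
PROFILES = {
    "clean_q40": QualityProfile(),
    "bad_tail": QualityProfile(tail_len=30, tail_q=2),
    "ambiguous": QualityProfile(n_prob=0.05),
}


def simulate_reads(
    n_reads: int,
    quality_profile: QualityProfile | str = "clean_q40",
    seed: int = 0,
):
    """Yield ``n_reads`` synthetic reads under the given quality profile."""
    if n_reads < 0:
        raise ValidationError(f"n_reads must be >= 0, got {n_reads}")
    if isinstance(quality_profile, str):
        try:
            quality_profile = PROFILES[quality_profile]
        except KeyError:
            raise ValidationError(
                f"unknown quality profile {quality_profile!r}; "
                f"known: {sorted(PROFILES)}"
            ) from None
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGT"))
    p = quality_profile
    for k in range(n_reads):
        bases = rng.choice(alphabet, size=p.read_length)
        if p.n_prob > 0:
            bases[rng.random(p.read_length) < p.n_prob] = "N"
        quals = np.full(p.read_length, p.body_q, dtype=int)
        if p.tail_len:
            quals[p.read_length - p.tail_len:] = p.tail_q
        yield PhredRead(f"read{k:06d}", "".join(bases), quals.tolist())
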