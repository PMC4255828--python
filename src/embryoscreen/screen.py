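"""Candidate-mining screen over the eight-library sexed embryo design.

The screen runs fourteen case/baseline contrasts (A-N) across sex and
collection window, selects significantly up-regulated transcripts per
contrast, applies marker-calibrated expression ceilings (e.g. "mean
normalised RPKM of the early samples < 50", the ceiling calibrated 20%
above the sisA homologue's early mean), and combines contrasts by set
algebra — by default ``(I & L) - (I & L & N)``: transcripts up-regulated
over time in the replicated mixed-sex contrast (I) and in the male-only
contrast (L), minus those also up-regulated in older females (N). Every
removal is recorded with its reason so the provenance of the final
candidate set is complete.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .design import StudyDesign
from .diffexp import (
    ComparisonSpec,
    DETable,
    ExpressionFilter,
    run_comparison,
)
from .errors import ValidationError
from .quantify import CountMatrix, ExpressionMatrix, group_mean

log = logging.getLogger(__name__)

DEFAULT_MARGIN = 0.2
DEFAULT_DETECTION_FLOOR = 0.25  # normalised RPKM; lowest credible non-zero signal


# ---------------------------------------------------------------------------
# Marker calibration


@dataclass(frozen=True)
class MarkerCalibration:
    """Expression ceiling calibrated against a marker transcript."""

    marker_id: str
    baseline_samples: tuple[str, ...]
    baseline_mean: float
    margin: float
    raw_threshold: float  # baseline mean * (1 + margin)
    operational_threshold: float  # raw rounded down to nearest 10, floored at 10


def calibrate_threshold(
    expr: ExpressionMatrix,
    marker_id: str,
    baseline_samples: Sequence[str],
    margin: float = DEFAULT_MARGIN,
) -> MarkerCalibration:
    """Ceiling = marker's baseline mean x (1 + margin), rounded down to 10s.

    The rounding reconciles the stated rule ("20% more abundant than the
    marker") with a round operational value; both are reported.
    """
    if marker_id not in expr.values.index:
        raise ValidationError(f"marker {marker_id!r} absent from expression matrix")
    baseline_mean = float(group_mean(expr, list(baseline_samples)).loc[marker_id])
    raw = baseline_mean * (1.0 + margin)
    operational = max(10.0, 10.0 * math.floor(raw / 10.0))
    return MarkerCalibration(
        marker_id=marker_id,
        baseline_samples=tuple(baseline_samples),
        baseline_mean=baseline_mean,
        margin=margin,
        raw_threshold=raw,
        operational_threshold=operational,
    )


# ---------------------------------------------------------------------------
# Per-comparison selection


def select_upregulated(de: DETable, alpha: float, direction: str) -> set[str]:
    """Transcripts with q < alpha whose fold-change sign matches direction."""
    t = de.table
    sig = t["q"] < alpha
    if direction == "up-in-case":
        sig &= t["fold_change"] > 0
    elif direction == "up-in-baseline":
        sig &= t["fold_change"] < 0
    elif direction != "both":
        raise ValidationError(f"unknown direction {direction!r}")
    return set(t.index[sig])


def apply_expression_filter(
    candidates: set[str],
    expr: ExpressionMatrix,
    samples: Sequence[str],
    bound: float,
    provenance: Optional[dict[str, list[str]]] = None,
    reason: str = "expression_filter",
) -> set[str]:
    """Keep candidates whose mean over ``samples`` is strictly below bound."""
    means = group_mean(expr, list(samples))
    kept = set()
    for t in candidates:
        if t not in means.index:
            raise ValidationError(f"candidate {t!r} absent from expression matrix")
        if means.loc[t] < bound:
            kept.add(t)
        elif provenance is not None:
            provenance.setdefault(t, []).append(reason)
    return kept


def intersect_screen(
    set_i: set[str], set_l: set[str], set_n: set[str]
) -> tuple[set[str], set[str], dict[str, list[str]]]:
    """Returns (I&L, (I&L)-(I&L&N), per-transcript membership provenance)."""
    i_and_l = set_i & set_l
    final = i_and_l - (i_and_l & set_n)
    provenance: dict[str, list[str]] = {}
    for t in set_i | set_l | set_n:
        tags = []
        if t in set_i:
            tags.append("I")
        if t in set_l:
            tags.append("L")
        if t in set_n:
            tags.append("N")
        provenance[t] = tags
    return i_and_l, final, provenance


# ---------------------------------------------------------------------------
# Set-expression evaluation ("I & L - (I & L & N)")

_TOKEN = re.compile(r"\s*([A-Za-z_][A-Za-z0-9_]*|[()&|-])")


def _tokenize(text: str) -> list[str]:
    out, pos = [], 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            if text[pos:].strip():
                raise ValidationError(f"bad set expression near {text[pos:]!r}")
            break
        out.append(m.group(1))
        pos = m.end()
    return out


def eval_set_expression(text: str, sets: dict[str, set[str]]) -> set[str]:
    """Evaluate an expression over named sets with &, | and - (left-assoc)."""
    tokens = _tokenize(text)
    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos] if pos < len(tokens) else None

    def factor() -> set[str]:
        nonlocal pos
        tok = peek()
        if tok == "(":
            pos += 1
            val = expr()
            if peek() != ")":
                raise ValidationError(f"unbalanced parentheses in {text!r}")
            pos += 1
            return val
        if tok is None or tok in "()&|-":
            raise ValidationError(f"bad set expression {text!r}")
        pos += 1
        if tok not in sets:
            raise ValidationError(f"unknown set name {tok!r} in {text!r}")
        return set(sets[tok])

    def term() -> set[str]:
        nonlocal pos
        val = factor()
        while peek() == "&":
            pos += 1
            val = val & factor()
        return val

    def expr() -> set[str]:
        nonlocal pos
        val = term()
        while peek() in ("-", "|"):
            op = peek()
            pos += 1
            rhs = term()
            val = (val - rhs) if op == "-" else (val | rhs)
        return val

    result = expr()
    if pos != len(tokens):
        raise ValidationError(f"trailing tokens in set expression {text!r}")
    return result


# ---------------------------------------------------------------------------
# Screen configuration (the fourteen-row fixture)


@dataclass
class ScreenConfig:
    comparisons: dict[str, ComparisonSpec]
    intersections: dict[str, str] = field(
        default_factory=lambda: {
            "I_and_L": "I & L",
            "final": "(I & L) - (I & L & N)",
        }
    )
    final_set: str = "final"


def default_screen_config(fdr_alpha: float = 0.001) -> ScreenConfig:
    """The fourteen standard contrasts over BJ1-BJ8 plus the intersections.

    Male/female rows (A-G) select up-regulation in males (case) with a
    5-RPKM ceiling on the female mean where stated; time rows (H-N) select
    up-regulation in late embryos with a 50-RPKM ceiling on the early mean
    where stated. Exclusions mirror the lagging-sample handling (BJ1/BJ5).
    """

    def cmp(cid, case, baseline, excluded=(), filt=None, direction="up-in-case"):
        return ComparisonSpec(
            id=cid,
            case=tuple(case),
            baseline=tuple(baseline),
            excluded=tuple(excluded),
            fdr_alpha=fdr_alpha,
            direction=direction,
            expression_filter=filt,
        )

    female_lt5 = lambda samples: ExpressionFilter(tuple(samples), 5.0)
    early_lt50 = lambda samples: ExpressionFilter(tuple(samples), 50.0)

    comparisons = {
        # male vs female
        "A": cmp("A", ["BJ1", "BJ2"], ["BJ3", "BJ4"]),
        "B": cmp("B", ["BJ2"], ["BJ3", "BJ4"], ["BJ1"], female_lt5(["BJ3", "BJ4"])),
        "C": cmp("C", ["BJ5", "BJ6"], ["BJ7", "BJ8"], (), female_lt5(["BJ7", "BJ8"])),
        "D": cmp("D", ["BJ6"], ["BJ7", "BJ8"], ["BJ5"], female_lt5(["BJ7", "BJ8"])),
        "E": cmp("E", ["BJ1", "BJ2", "BJ5", "BJ6"], ["BJ3", "BJ4", "BJ7", "BJ8"]),
        "F": cmp("F", ["BJ2", "BJ6"], ["BJ3", "BJ4", "BJ7", "BJ8"], ["BJ1", "BJ5"]),
        "G": cmp("G", ["BJ2", "BJ5", "BJ6"], ["BJ3", "BJ4", "BJ7", "BJ8"], ["BJ1"]),
        # late vs early
        "H": cmp("H", ["BJ1", "BJ2", "BJ3", "BJ4"], ["BJ5", "BJ6", "BJ7", "BJ8"]),
        "I": cmp("I", ["BJ2", "BJ3", "BJ4"], ["BJ6", "BJ7", "BJ8"], ["BJ1", "BJ5"],
                 early_lt50(["BJ6", "BJ7", "BJ8"])),
        "J": cmp("J", ["BJ2", "BJ3", "BJ4"], ["BJ5", "BJ6", "BJ7", "BJ8"], ["BJ1"],
                 early_lt50(["BJ5", "BJ6", "BJ7", "BJ8"])),
        "K": cmp("K", ["BJ1", "BJ2"], ["BJ5", "BJ6"]),
        "L": cmp("L", ["BJ2"], ["BJ6"], ["BJ1", "BJ5"], early_lt50(["BJ6"])),
        "M": cmp("M", ["BJ1"], ["BJ5"], ["BJ2", "BJ6"]),
        "N": cmp("N", ["BJ3", "BJ4"], ["BJ7", "BJ8"]),
    }
    return ScreenConfig(comparisons=comparisons)


# ---------------------------------------------------------------------------
# Screen execution


@dataclass
class ComparisonOutcome:
    de: DETable
    n_significant: int
    upregulated: set[str]
    selected: set[str]  # after the expression filter (the set used downstream)
    removed: dict[str, list[str]]  # transcript -> removal reasons


@dataclass
class ScreenResult:
    comparisons: dict[str, ComparisonOutcome]
    intersections: dict[str, set[str]]
    final: set[str]
    provenance: dict[str, list[str]]  # transcript -> event trail

    def summary(self) -> pd.DataFrame:
        """One row per comparison, mirroring the standard screen table."""
        rows = []
        for cid, out in self.comparisons.items():
            rows.append(
                {
                    "comparison": cid,
                    "case": "+".join(out.de.spec.case),
                    "baseline": "+".join(out.de.spec.baseline),
                    "excluded": "+".join(out.de.spec.excluded),
                    "n_significant": out.n_significant,
                    "n_upregulated": len(out.upregulated),
                    "n_selected": len(out.selected),
                }
            )
        df = pd.DataFrame(rows).set_index("comparison")
        return df


def run_full_screen(
    counts: CountMatrix, design: StudyDesign, config: Optional[ScreenConfig] = None
) -> ScreenResult:
    """Run every configured comparison, filter, and combine by set algebra."""
    design.require_full_grid()
    if config is None:
        config = default_screen_config()
    provenance: dict[str, list[str]] = {}
    outcomes: dict[str, ComparisonOutcome] = {}
    sets: dict[str, set[str]] = {}

    for cid, spec in config.comparisons.items():
        de = run_comparison(counts, design, spec)
        significant = de.significant_ids
        upreg = select_upregulated(de, spec.fdr_alpha, spec.direction)
        removed: dict[str, list[str]] = {}
        for t in significant - upreg:
            removed.setdefault(t, []).append("direction")
            provenance.setdefault(t, []).append(f"{cid}:removed:direction")
        selected = upreg
        if spec.expression_filter is not None:
            filt = spec.expression_filter
            local_prov: dict[str, list[str]] = {}
            selected = apply_expression_filter(
                upreg, de.expression, list(filt.samples), filt.bound, local_prov
            )
            for t, reasons in local_prov.items():
                removed.setdefault(t, []).extend(reasons)
                provenance.setdefault(t, []).append(f"{cid}:removed:expression_filter")
        for t in selected:
            provenance.setdefault(t, []).append(f"{cid}:selected")
        outcomes[cid] = ComparisonOutcome(
            de=de,
            n_significant=int(len(significant)),
            upregulated=upreg,
            selected=selected,
            removed=removed,
        )
        sets[cid] = selected

    intersections = {
        name: eval_set_expression(expr_text, sets)
        for name, expr_text in config.intersections.items()
    }
    if config.final_set not in intersections:
        raise ValidationError(f"final set {config.final_set!r} not among intersections")
    final = intersections[config.final_set]
    for t in final:
        provenance.setdefault(t, []).append("final")
    # transcripts selected somewhere but not final: record why they fell out
    for cid, out in outcomes.items():
        for t in out.selected - final:
            provenance.setdefault(t, []).append(f"dropped_at_intersection:{cid}")
    return ScreenResult(
        comparisons=outcomes,
        intersections=intersections,
        final=final,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Maternal / zygotic profile classification

PROFILE_LABELS = ("maternal", "zygotic", "maternal_plus_zygotic", "undetected", "ambiguous")


@dataclass(frozen=True)
class ProfileClass:
    label: str
    early_mean: float
    late_mean: float
    significant_up_late: bool

    def __post_init__(self) -> None:
        if self.label not in PROFILE_LABELS:
            raise ValidationError(f"unknown profile label {self.label!r}")


def classify_profile(
    early_mean: float,
    late_mean: float,
    significant_up_late: bool,
    maternal_threshold: float,
    detection_floor: float = DEFAULT_DETECTION_FLOOR,
) -> ProfileClass:
    """Maternal/zygotic call from early/late means and significance.

    - undetected: both means below the detection floor;
    - zygotic: early below the maternal threshold, significantly up late;
    - maternal: early at/above the threshold, not significantly up;
    - maternal_plus_zygotic: early at/above the threshold, significantly up;
    - ambiguous: anything else (detected, low early, no significant rise).
    """
    if early_mean < detection_floor and late_mean < detection_floor:
        label = "undetected"
    elif early_mean < maternal_threshold and significant_up_late:
        label = "zygotic"
    elif early_mean >= maternal_threshold and not significant_up_late:
        label = "maternal"
    elif early_mean >= maternal_threshold and significant_up_late:
        label = "maternal_plus_zygotic"
    else:
        label = "ambiguous"
    return ProfileClass(label, early_mean, late_mean, significant_up_late)
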