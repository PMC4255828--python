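"""Packaged worked-example data.

Two small reference panels of normalised RPKM values over the eight-library
sexed embryo design ship with the package:

``marker_panel``
    20 sex-determination and 3 cellularisation gene homologues, expression
    per library from the early (BJ5-8) vs late (BJ1-4) normalisation scope.
    This panel anchors the worked examples: the slam group means, the
    marker-calibrated 50-RPKM early ceiling (from sisterless_A), and the
    textbook fold changes (nullo ~18x, extra_macrochaetae ~130x, ...).

``male_up_panel``
    The nine male-up-regulated contigs from the single-male-replicate sex
    contrasts (B: BJ2 vs BJ3+BJ4; D: BJ6 vs BJ7+BJ8), long format, with the
    originally printed fold changes for cross-checking.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .design import StudyDesign, read_design
from .quantify import ExpressionMatrix

SAMPLES_EARLY = ("BJ5", "BJ6", "BJ7", "BJ8")
SAMPLES_LATE = ("BJ1", "BJ2", "BJ3", "BJ4")
SAMPLES_ALL = SAMPLES_LATE + SAMPLES_EARLY


def _data_path(name: str):
    return resources.files("embryoscreen.data").joinpath(name)


def marker_panel() -> pd.DataFrame:
    """Marker panel with gene, category, contig, length_bp and BJ columns."""
    with resources.as_file(_data_path("marker_panel.tsv")) as path:
        return pd.read_csv(path, sep="\t").set_index("gene")


def marker_expression() -> ExpressionMatrix:
    """The marker panel as a normalised ExpressionMatrix (all 8 libraries)."""
    panel = marker_panel()
    values = panel[list(SAMPLES_ALL)].astype(float)
    return ExpressionMatrix(values=values, normalised=True, scope=SAMPLES_ALL)


def marker_lengths() -> pd.Series:
    return marker_panel()["length_bp"].astype(int)


def male_up_panel() -> pd.DataFrame:
    """Long-format male-up candidates with printed fold changes."""
    with resources.as_file(_data_path("male_up_panel.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def bj_design_fixture() -> StudyDesign:
    """The BJ1-BJ8 design read from the packaged TSV fixture."""
    with resources.as_file(_data_path("bj_design.tsv")) as path:
        return read_design(path)
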