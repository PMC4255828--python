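"""Marker calibration, selection filters, set algebra and the full screen."""

import numpy as np
import pandas as pd
import pytest

from embryoscreen import datasets
from embryoscreen.design import bj_design
from embryoscreen.diffexp import ComparisonSpec, DETable
from embryoscreen.errors import ValidationError
from embryoscreen.quantify import ExpressionMatrix, group_mean
from embryoscreen.screen import (
    ScreenConfig,
    apply_expression_filter,
    calibrate_threshold,
    classify_profile,
    default_screen_config,
    eval_set_expression,
    intersect_screen,
    run_full_screen,
    select_upregulated,
)
from embryoscreen.synthetic_data import SimConfig, simulate_counts


class TestCalibrateThreshold:
    def test_sisa_calibration_yields_the_50_rpkm_ceiling(self, marker_expr):
        cal = calibrate_threshold(
            marker_expr, "sisterless_A", list(datasets.SAMPLES_EARLY), margin=0.2
        )
        assert cal.baseline_mean == pytest.approx(44.72)
        assert cal.raw_threshold == pytest.approx(53.664)
        assert cal.operational_threshold == 50.0

    def test_zero_margin_is_the_baseline_mean(self, marker_expr):
        cal = calibrate_threshold(
            marker_expr, "transformer-2", list(datasets.SAMPLES_EARLY), margin=0.0
        )
        assert cal.raw_threshold == pytest.approx(cal.baseline_mean)

    def test_constant_marker(self):
        expr = ExpressionMatrix(
            values=pd.DataFrame({"A": [30.0], "B": [30.0]}, index=["m"]),
            normalised=True,
        )
        cal = calibrate_threshold(expr, "m", ["A", "B"])
        assert cal.raw_threshold == pytest.approx(36.0)
        assert cal.operational_threshold == 30.0

    def test_operational_floor_at_10(self):
        expr = ExpressionMatrix(
            values=pd.DataFrame({"A": [1.0], "B": [1.0]}, index=["m"]),
            normalised=True,
        )
        assert calibrate_threshold(expr, "m", ["A", "B"]).operational_threshold == 10.0

    def test_absent_marker(self, marker_expr):
        with pytest.raises(ValidationError, match="ghost"):
            calibrate_threshold(marker_expr, "ghost", ["BJ5"])


def make_de_table(rows: dict) -> DETable:
    """rows: transcript -> (fold_change, q)."""
    spec = ComparisonSpec(id="t", case=("A",), baseline=("B",))
    table = pd.DataFrame(
        {
            "fold_change": {k: v[0] for k, v in rows.items()},
            "q": {k: v[1] for k, v in rows.items()},
        }
    )
    expr = ExpressionMatrix(
        values=pd.DataFrame(
            {"A": 1.0, "B": 1.0}, index=pd.Index(list(rows), dtype=object)
        ),
        normalised=True,
    )
    return DETable(spec=spec, table=table, expression=expr, df=1)


class TestSelectUpregulated:
    def test_empty_table(self):
        de = make_de_table({})
        assert select_upregulated(de, 0.001, "both") == set()

    def test_alpha_one_both_directions_selects_everything(self):
        de = make_de_table({"a": (2.0, 0.5), "b": (-3.0, 0.9)})
        assert select_upregulated(de, 1.0, "both") == {"a", "b"}

    def test_direction_and_alpha(self):
        de = make_de_table({"a": (2.0, 1e-5), "b": (-3.0, 1e-5), "c": (4.0, 0.1)})
        assert select_upregulated(de, 0.001, "up-in-case") == {"a"}
        assert select_upregulated(de, 0.001, "up-in-baseline") == {"b"}


class TestExpressionFilter:
    def test_published_comparison_d_rows_all_pass_female_ceiling(self):
        panel = datasets.male_up_panel()
        d = panel[panel.comparison == "D"]
        wide = d.pivot_table(index="contig", columns="sample", values="rpkm")
        expr = ExpressionMatrix(values=wide, normalised=True)
        female_means = group_mean(expr, ["BJ7", "BJ8"])
        assert (female_means < 5).all()  # the printed values satisfy the rule
        kept = apply_expression_filter(
            set(wide.index), expr, ["BJ7", "BJ8"], bound=5.0
        )
        assert kept == set(wide.index)

    def test_infinite_bound_is_identity(self, marker_expr):
        ids = set(marker_expr.values.index)
        assert apply_expression_filter(ids, marker_expr, ["BJ5"], np.inf) == ids

    def test_slam_passes_the_early_50_ceiling(self, marker_expr):
        kept = apply_expression_filter(
            {"slow_as_molasses"}, marker_expr, list(datasets.SAMPLES_EARLY), 50.0
        )
        assert kept == {"slow_as_molasses"}

    def test_removal_reason_recorded(self, marker_expr):
        prov = {}
        kept = apply_expression_filter(
            {"degringolade"}, marker_expr, list(datasets.SAMPLES_EARLY), 50.0, prov
        )
        assert kept == set()
        assert prov["degringolade"] == ["expression_filter"]

    def test_independent_filters_commute(self, rng):
        universe = [f"t{i}" for i in range(40)]
        expr = ExpressionMatrix(
            values=pd.DataFrame(
                rng.random((40, 4)) * 100, index=universe, columns=list("ABCD")
            )
        )
        start = set(rng.choice(universe, size=25, replace=False))
        ab_then_cd = apply_expression_filter(
            apply_expression_filter(start, expr, ["A", "B"], 60.0), expr, ["C", "D"], 40.0
        )
        cd_then_ab = apply_expression_filter(
            apply_expression_filter(start, expr, ["C", "D"], 40.0), expr, ["A", "B"], 60.0
        )
        assert ab_then_cd == cd_then_ab


class TestIntersections:
    def test_basic_set_algebra(self):
        i_and_l, final, prov = intersect_screen({"a", "b", "c"}, {"b", "c", "d"}, {"c"})
        assert i_and_l == {"b", "c"}
        assert final == {"b"}
        assert prov["c"] == ["I", "L", "N"]

    def test_n_superset_empties_final(self):
        _, final, _ = intersect_screen({"a", "b"}, {"a", "b"}, {"a", "b", "z"})
        assert final == set()

    def test_disjoint_sets(self):
        _, final, _ = intersect_screen({"a"}, {"b"}, set())
        assert final == set()

    def test_expression_language(self):
        sets = {"I": {"a", "b", "c"}, "L": {"b", "c"}, "N": {"c"}}
        assert eval_set_expression("I & L", sets) == {"b", "c"}
        assert eval_set_expression("(I & L) - (I & L & N)", sets) == {"b"}
        assert eval_set_expression("I | N", sets) == {"a", "b", "c"}

    def test_expression_errors(self):
        with pytest.raises(ValidationError):
            eval_set_expression("I &", {"I": set()})
        with pytest.raises(ValidationError):
            eval_set_expression("I & Q", {"I": set()})
        with pytest.raises(ValidationError):
            eval_set_expression("(I", {"I": set()})


class TestRunFullScreen:
    def test_unknown_comparison_sample_rejected(self, sim_cohort):
        _, matrix, _ = sim_cohort
        config = default_screen_config()
        config.comparisons["Z"] = ComparisonSpec(
            id="Z", case=("BJ99",), baseline=("BJ2",)
        )
        with pytest.raises(ValidationError):
            run_full_screen(matrix, bj_design(), config)

    def test_unknown_final_set_rejected(self, sim_cohort):
        _, matrix, _ = sim_cohort
        config = default_screen_config()
        config.final_set = "nope"
        with pytest.raises(ValidationError):
            run_full_screen(matrix, bj_design(), config)

    def test_quiet_matrix_yields_empty_screen(self, design):
        # maternal-stable only, Poisson noise: the binomial sampling model
        # holds exactly, so no comparison finds anything and every screen
        # count is zero. (With overdispersion the unreplicated contrasts
        # are anti-conservative by construction — the binomial-fallback
        # variance ignores between-library variation — so a truly quiet
        # screen needs the noise the 1v1 model assumes.)
        config = SimConfig(
            n_per_class={"maternal_stable": 40},
            dispersion=0.0,
            lag_fraction=0.0,
            seed=3,
        )
        matrix, _ = simulate_counts(config, design)
        result = run_full_screen(matrix, design)
        assert result.final == set()
        summary = result.summary()
        assert (summary["n_selected"] == 0).all()
        # sex contrasts on sex-balanced data find nothing (E-G pattern)
        for cid in ("E", "F", "G"):
            assert result.comparisons[cid].n_significant == 0

    def test_provenance_covers_every_significant_transcript(self, sim_cohort, design):
        _, matrix, _ = sim_cohort
        result = run_full_screen(matrix, design)
        for cid, outcome in result.comparisons.items():
            for t in outcome.de.significant_ids:
                assert t in result.final or t in result.provenance, (cid, t)
                if t not in result.final:
                    trail = result.provenance.get(t, [])
                    assert any(
                        "removed" in e or "dropped_at_intersection" in e or "selected" in e
                        for e in trail
                    )

    def test_summary_mirrors_comparison_layout(self, sim_cohort, design):
        _, matrix, _ = sim_cohort
        result = run_full_screen(matrix, design)
        summary = result.summary()
        assert list(summary.index) == list("ABCDEFGHIJKLMN")
        assert summary.loc["I", "case"] == "BJ2+BJ3+BJ4"
        assert summary.loc["L", "baseline"] == "BJ6"
        assert (summary["n_selected"] <= summary["n_upregulated"]).all()


class TestClassifyProfile:
    def test_slam_like_is_zygotic(self):
        out = classify_profile(4.1, 305.3, True, maternal_threshold=10.0)
        assert out.label == "zygotic"

    def test_tra2_like_is_maternal(self):
        out = classify_profile(44.7, 40.4, False, maternal_threshold=10.0)
        assert out.label == "maternal"

    def test_all_zero_is_undetected(self):
        assert classify_profile(0.0, 0.0, False, 10.0).label == "undetected"

    def test_maternal_plus_zygotic(self):
        out = classify_profile(60.0, 400.0, True, maternal_threshold=50.0)
        assert out.label == "maternal_plus_zygotic"

    def test_low_and_flat_is_ambiguous(self):
        assert classify_profile(1.0, 2.0, False, 10.0).label == "ambiguous"
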