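"""Crossed Gage R&R ANOVA: components, classification, and recovery."""

import math

import numpy as np
import pandas as pd
import pytest

from gelquant.errors import DesignError
from gelquant.gagerr import (
    GageRR,
    classify_grr,
    gage_rr_anova,
    simulate_measurements,
    total_study_variation,
)


@pytest.fixture(scope="module")
def study_table():
    return simulate_measurements(
        n_parts=10, n_operators=3, n_replicates=3,
        sd_part=8.0, sd_operator=2.0, sd_error=1.5, sd_interaction=1.0, seed=12,
    )


class TestAnovaDecomposition:
    def test_sums_of_squares_match_statsmodels(self, study_table):
        """Independent oracle: OLS two-way ANOVA with interaction."""
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        fit = ols("value ~ C(part) * C(operator)", data=study_table).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        res = GageRR(study_table).fit()
        ours = res.anova_table
        assert ours.loc["part", "sum_sq"] == pytest.approx(table.loc["C(part)", "sum_sq"])
        assert ours.loc["operator", "sum_sq"] == pytest.approx(
            table.loc["C(operator)", "sum_sq"]
        )
        assert ours.loc["part:operator", "sum_sq"] == pytest.approx(
            table.loc["C(part):C(operator)", "sum_sq"]
        )
        assert ours.loc["residual", "sum_sq"] == pytest.approx(
            table.loc["Residual", "sum_sq"]
        )

    def test_zero_operator_effect_gives_tiny_reproducibility(self):
        """Null operator effect: estimated reproducibility is ~0.

        More than half of the seeds truncate the operator component to exactly
        zero; nearly all stay within a few percent of study variation (chance
        retention of a null interaction term keeps the rest small but nonzero).
        """
        vals = []
        for seed in range(100):
            tbl = simulate_measurements(
                n_parts=10, n_operators=2, n_replicates=10,
                sd_part=10.0, sd_operator=0.0, sd_error=1.0, seed=seed,
            )
            vals.append(GageRR(tbl).fit().pct_study_var["reproducibility"])
        vals = np.array(vals)
        assert float(np.median(vals)) == 0.0
        assert np.mean(vals < 3.0) >= 0.85
        assert vals.max() < 10.0

    def test_identical_values_flagged_degenerate(self):
        tbl = simulate_measurements(3, 2, 2, 0, 0, 0, seed=0)
        tbl["value"] = 42.0
        res = GageRR(tbl).fit()
        assert res.degenerate
        assert math.isnan(res.pct_study_var["total_gage_rr"])
        assert classify_grr(res) == "degenerate"

    def test_interaction_pooled_only_when_weak(self):
        strong = simulate_measurements(
            8, 3, 5, sd_part=5.0, sd_operator=1.0, sd_interaction=4.0, sd_error=0.5, seed=3
        )
        weak = simulate_measurements(
            8, 3, 5, sd_part=5.0, sd_operator=1.0, sd_interaction=0.0, sd_error=2.0, seed=3
        )
        assert not GageRR(strong).fit().interaction_pooled
        assert GageRR(weak).fit().interaction_pooled

    def test_negative_components_truncated_to_zero(self):
        # operator MS below pooled error -> negative EMS solution for operator
        for seed in range(20):
            tbl = simulate_measurements(
                5, 2, 3, sd_part=5.0, sd_operator=0.0, sd_error=3.0, seed=seed
            )
            res = GageRR(tbl).fit()
            assert res.var_operator >= 0 and res.var_part >= 0
            if res.truncated_components:
                return
        pytest.fail("no truncation observed across seeds")


class TestInvariants:
    def test_quadrature_identity_on_percent_scale(self, study_table):
        pct = GageRR(study_table).fit().pct_study_var
        combined = total_study_variation(pct["repeatability"], pct["reproducibility"])
        assert combined == pytest.approx(pct["total_gage_rr"], abs=0.05)

    def test_operator_label_permutation_invariance(self, study_table):
        res1 = GageRR(study_table).fit()
        swapped = study_table.copy()
        swapped["operator"] = swapped["operator"].map({"O1": "O3", "O2": "O1", "O3": "O2"})
        res2 = GageRR(swapped).fit()
        for key, val in res1.pct_study_var.items():
            assert res2.pct_study_var[key] == pytest.approx(val, abs=1e-9)

    def test_component_recovery_at_known_values(self):
        """Median % study-variation error small at the reference component mix."""
        sd_p, sd_o, sd_e = 10.0, 0.0, 1.0
        tv = math.sqrt(sd_p**2 + sd_o**2 + sd_e**2)
        expected = {
            "repeatability": 100 * sd_e / tv,
            "reproducibility": 100 * sd_o / tv,
            "part_to_part": 100 * sd_p / tv,
        }
        errs = {k: [] for k in expected}
        for seed in range(200):
            tbl = simulate_measurements(10, 2, 10, sd_p, sd_o, sd_e, seed=seed)
            pct = GageRR(tbl).fit().pct_study_var
            for k in expected:
                errs[k].append(abs(pct[k] - expected[k]))
        for k, v in errs.items():
            assert float(np.median(v)) <= 2.0, k


class TestClassification:
    @pytest.mark.parametrize(
        "total,expected",
        [
            (6.97, "acceptable"),
            (9.99, "acceptable"),
            (10.0, "conditional"),
            (28.5, "conditional"),
            (29.99, "conditional"),
            (30.0, "unacceptable"),
            (45.0, "unacceptable"),
        ],
    )
    def test_boundaries(self, total, expected):
        assert classify_grr(total) == expected

    def test_published_worked_examples_combine_in_quadrature(self):
        # single-gel scoring study: 3.99% and 5.71% -> 6.97% total
        assert round(total_study_variation(3.99, 5.71), 2) == 6.97
        # multi-gel study: 22% and 18.1% -> 28.5% total
        assert round(total_study_variation(22.0, 18.1), 1) == 28.5
        assert classify_grr(total_study_variation(3.99, 5.71)) == "acceptable"
        assert classify_grr(total_study_variation(22.0, 18.1)) == "conditional"


class TestDesignValidation:
    def test_single_operator_rejected(self):
        tbl = simulate_measurements(5, 2, 3, 1, 1, 1, seed=0)
        with pytest.raises(DesignError):
            GageRR(tbl[tbl.operator == "O1"])

    def test_unbalanced_rejected(self):
        tbl = simulate_measurements(5, 2, 3, 1, 1, 1, seed=0)
        with pytest.raises(DesignError):
            GageRR(tbl.iloc[:-1])

    def test_missing_cell_rejected(self):
        tbl = simulate_measurements(5, 2, 3, 1, 1, 1, seed=0)
        cut = tbl[~((tbl.part == "P01") & (tbl.operator == "O2"))]
        with pytest.raises(DesignError):
            GageRR(cut)

    def test_single_replicate_rejected(self):
        rows = [
            {"part": p, "operator": o, "value": 1.0 * i}
            for i, (p, o) in enumerate((p, o) for p in "AB" for o in "XY")
        ]
        with pytest.raises(DesignError):
            GageRR(pd.DataFrame(rows))


class TestResultsApi:
    def test_summary_mentions_key_quantities(self, study_table):
        text = GageRR(study_table).fit().summary()
        for token in ("repeatability", "reproducibility", "Gage R&R", "classification"):
            assert token in text

    def test_functional_wrapper_equivalent(self, study_table):
        a = gage_rr_anova(study_table).pct_study_var
        b = GageRR(study_table).fit().pct_study_var
        assert a == b

    def test_csv_constructor(self, tmp_path, study_table):
        path = tmp_path / "scores.csv"
        study_table.to_csv(path, index=False)
        res = GageRR.from_long_csv(path).fit()
        assert res.model.n_parts == 10
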