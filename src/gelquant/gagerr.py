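"""Gage repeatability & reproducibility (crossed two-factor ANOVA).

A measurement-system analysis for gel-scoring studies: repeated scores of the
same lanes (parts) by several scorers (operators) are decomposed into
repeatability (within-scorer), reproducibility (between-scorer, including any
part-by-operator interaction) and part-to-part variation via the expected
mean squares of a balanced crossed ANOVA.  Percent figures are percent of
*study variation* (standard-deviation scale), so repeatability and
reproducibility combine in quadrature to the total Gage R&R.  Totals under
10% are conventionally acceptable and totals under 30% conditionally so.

Usage follows the Model/Results convention::

    res = GageRR(table).fit()
    print(res.summary())
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError, ParameterError

__all__ = [
    "GageRR",
    "GageRRResults",
    "gage_rr_anova",
    "classify_grr",
    "total_study_variation",
    "simulate_measurements",
]

#: Conventional acceptability guidelines on total % study variation.
ACCEPTABLE_LIMIT = 10.0
CONDITIONAL_LIMIT = 30.0


def total_study_variation(repeatability_pct: float, reproducibility_pct: float) -> float:
    """Combine repeatability and reproducibility % study variation in quadrature."""
    return math.hypot(repeatability_pct, reproducibility_pct)


def classify_grr(total_grr_pct) -> str:
    """Acceptability class of a total Gage R&R % study variation.

    < 10% -> "acceptable"; 10-30% -> "conditional"; >= 30% -> "unacceptable".
    Accepts a number or a fitted :class:`GageRRResults`.
    """
    if isinstance(total_grr_pct, GageRRResults):
        if total_grr_pct.degenerate:
            return "degenerate"
        total_grr_pct = total_grr_pct.pct_study_var["total_gage_rr"]
    total = float(total_grr_pct)
    if math.isnan(total):
        return "degenerate"
    if total < ACCEPTABLE_LIMIT:
        return "acceptable"
    if total < CONDITIONAL_LIMIT:
        return "conditional"
    return "unacceptable"


class GageRR:
    """Crossed Gage R&R model for a balanced part x operator x replicate table.

    Parameters
    ----------
    data : DataFrame in long format with part, operator and value columns
        (a replicate column is optional and ignored for fitting: replicates
        are whatever repeats each part x operator cell holds).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        part_col: str = "part",
        operator_col: str = "operator",
        value_col: str = "value",
    ) -> None:
        for col in (part_col, operator_col, value_col):
            if col not in data.columns:
                raise ParameterError(f"measurement table is missing column {col!r}")
        self.data = data[[part_col, operator_col, value_col]].copy()
        self.data.columns = ["part", "operator", "value"]
        if self.data["value"].isna().any():
            raise DesignError("measurement table contains missing values")
        counts = self.data.groupby(["part", "operator"], sort=True).size()
        self.n_parts = self.data["part"].nunique()
        self.n_operators = self.data["operator"].nunique()
        if self.n_parts < 2 or self.n_operators < 2:
            raise DesignError("need at least 2 parts and 2 operators")
        if len(counts) != self.n_parts * self.n_operators:
            raise DesignError("design is not crossed: some part x operator cells are empty")
        if counts.nunique() != 1:
            raise DesignError("design is unbalanced: unequal replicates per cell")
        self.n_replicates = int(counts.iloc[0])
        if self.n_replicates < 2:
            raise DesignError("need at least 2 replicates per part x operator cell")

    @classmethod
    def from_long_csv(cls, path, **kwargs) -> "GageRR":
        return cls(pd.read_csv(path), **kwargs)

    def fit(self, pool_interaction_alpha: float = 0.25) -> "GageRRResults":
        """Solve the expected-mean-square equations for the variance components.

        The part x operator interaction is pooled into repeatability when its
        F test against error gives p > ``pool_interaction_alpha``.
        """
        d = self.data
        p, o, r = self.n_parts, self.n_operators, self.n_replicates
        grand = d["value"].mean()
        part_means = d.groupby("part")["value"].mean()
        op_means = d.groupby("operator")["value"].mean()
        cell_means = d.groupby(["part", "operator"])["value"].mean()

        ss_part = o * r * float(((part_means - grand) ** 2).sum())
        ss_op = p * r * float(((op_means - grand) ** 2).sum())
        cell_dev = (
            cell_means
            - part_means.reindex(cell_means.index.get_level_values(0)).to_numpy()
            - op_means.reindex(cell_means.index.get_level_values(1)).to_numpy()
            + grand
        )
        ss_inter = r * float((cell_dev**2).sum())
        cell_of_row = cell_means.loc[
            pd.MultiIndex.from_frame(d[["part", "operator"]])
        ].to_numpy()
        ss_err = float(((d["value"].to_numpy() - cell_of_row) ** 2).sum())

        df_part, df_op = p - 1, o - 1
        df_inter, df_err = (p - 1) * (o - 1), p * o * (r - 1)
        ms_part, ms_op = ss_part / df_part, ss_op / df_op
        ms_inter, ms_err = ss_inter / df_inter, ss_err / df_err

        if ms_err > 0:
            f_inter = ms_inter / ms_err
            p_inter = float(stats.f.sf(f_inter, df_inter, df_err))
        else:
            f_inter, p_inter = float("nan"), 1.0

        pooled = p_inter > pool_interaction_alpha
        truncated: list[str] = []

        def _nonneg(value: float, name: str) -> float:
            if value < 0:
                truncated.append(name)
                return 0.0
            return value

        if pooled:
            ms_e = (ss_inter + ss_err) / (df_inter + df_err)
            var_e = ms_e
            var_po = 0.0
            var_o = _nonneg((ms_op - ms_e) / (p * r), "operator")
            var_p = _nonneg((ms_part - ms_e) / (o * r), "part")
        else:
            var_e = ms_err
            var_po = _nonneg((ms_inter - ms_err) / r, "interaction")
            var_o = _nonneg((ms_op - ms_inter) / (p * r), "operator")
            var_p = _nonneg((ms_part - ms_inter) / (o * r), "part")

        anova = pd.DataFrame(
            {
                "sum_sq": [ss_part, ss_op, ss_inter, ss_err],
                "df": [df_part, df_op, df_inter, df_err],
                "mean_sq": [ms_part, ms_op, ms_inter, ms_err],
            },
            index=["part", "operator", "part:operator", "residual"],
        )
        anova.loc["part:operator", "F"] = f_inter
        anova.loc["part:operator", "p_value"] = p_inter

        return GageRRResults(
            model=self,
            anova_table=anova,
            var_repeatability=var_e,
            var_operator=var_o,
            var_interaction=var_po,
            var_part=var_p,
            interaction_pooled=pooled,
            truncated_components=tuple(truncated),
        )


@dataclass(frozen=True)
class GageRRResults:
    """Variance components and % study variation of a Gage R&R fit."""

    model: GageRR
    anova_table: pd.DataFrame
    var_repeatability: float  # sigma^2_e
    var_operator: float  # sigma^2_o
    var_interaction: float  # sigma^2_po (0 when pooled)
    var_part: float  # sigma^2_p
    interaction_pooled: bool
    truncated_components: tuple[str, ...] = ()

    @property
    def sd_components(self) -> dict[str, float]:
        ev = math.sqrt(self.var_repeatability)
        av = math.sqrt(self.var_operator + self.var_interaction)
        grr = math.hypot(ev, av)
        pv = math.sqrt(self.var_part)
        return {
            "repeatability": ev,
            "reproducibility": av,
            "total_gage_rr": grr,
            "part_to_part": pv,
            "total_variation": math.hypot(grr, pv),
        }

    @property
    def degenerate(self) -> bool:
        return self.sd_components["total_variation"] == 0.0

    @property
    def pct_study_var(self) -> dict[str, float]:
        """Each SD component as a percent of total study variation."""
        sd = self.sd_components
        tv = sd["total_variation"]
        if tv == 0:
            return {k: float("nan") for k in sd if k != "total_variation"}
        return {k: 100.0 * v / tv for k, v in sd.items() if k != "total_variation"}

    @property
    def classification(self) -> str:
        return classify_grr(self)

    def summary(self) -> str:
        lines = [
            "Gage Repeatability & Reproducibility (crossed ANOVA)",
            f"parts: {self.model.n_parts}  operators: {self.model.n_operators}  "
            f"replicates: {self.model.n_replicates}",
            f"interaction pooled into repeatability: {self.interaction_pooled}",
            "",
            f"{'source':<18}{'variance':>12}{'std dev':>12}{'% study var':>14}",
        ]
        sd = self.sd_components
        pct = self.pct_study_var
        rows = [
            ("repeatability", self.var_repeatability),
            ("reproducibility", self.var_operator + self.var_interaction),
            ("total Gage R&R", self.var_repeatability + self.var_operator + self.var_interaction),
            ("part-to-part", self.var_part),
        ]
        keys = ["repeatability", "reproducibility", "total_gage_rr", "part_to_part"]
        for (name, var), key in zip(rows, keys):
            pc = pct[key]
            pc_str = f"{pc:>13.2f}%" if not math.isnan(pc) else f"{'n/a':>14}"
            lines.append(f"{name:<18}{var:>12.4f}{sd[key]:>12.4f}{pc_str}")
        lines.append("")
        lines.append(f"classification: {self.classification}")
        if self.truncated_components:
            lines.append(
                "negative variance estimates truncated to 0: "
                + ", ".join(self.truncated_components)
            )
        return "\n".join(lines)


def gage_rr_anova(table: pd.DataFrame, **kwargs) -> GageRRResults:
    """Functional wrapper: fit a crossed Gage R&R ANOVA on a long-format table."""
    return GageRR(table, **kwargs).fit()


def simulate_measurements(
    n_parts: int,
    n_operators: int,
    n_replicates: int,
    sd_part: float,
    sd_operator: float,
    sd_error: float,
    sd_interaction: float = 0.0,
    mean: float = 50.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a balanced crossed measurement study with known components."""
    rng = np.random.default_rng(seed)
    part_eff = rng.normal(0.0, sd_part, n_parts)
    op_eff = rng.normal(0.0, sd_operator, n_operators)
    inter_eff = rng.normal(0.0, sd_interaction, (n_parts, n_operators))
    rows = []
    for i in range(n_parts):
        for j in range(n_operators):
            vals = mean + part_eff[i] + op_eff[j] + inter_eff[i, j] + rng.normal(
                0.0, sd_error, n_replicates
            )
            rows.extend(
                {"part": f"P{i + 1:02d}", "operator": f"O{j + 1}", "replicate": k + 1, "value": v}
                for k, v in enumerate(vals)
            )
    return pd.DataFrame(rows)
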