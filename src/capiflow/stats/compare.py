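"""Baseline comparison of the two study groups.

Continuous variables are compared with a two-sided unpaired t-test
(equal variances by default, Welch behind a flag); the sex distribution
with a chi-square test on the 2x2 contingency table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["VariableComparison", "GroupComparisonResult", "compare_groups"]

DEFAULT_VARIABLES = (
    "age",
    "axial_length_mm",
    "bcva_logmar",
    "sbp_mmHg",
    "dbp_mmHg",
    "iop_mmHg",
    "opp_mmHg",
    "pbfv_mm_s",
    "mbr_t_au",
    "rvd_a_um",
    "rvd_v_um",
)


@dataclass(frozen=True)
class VariableComparison:
    variable: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    statistic: float
    p_value: float
    test: str
    degenerate: bool = False  # variable constant in both groups


@dataclass(frozen=True)
class GroupComparisonResult:
    group_a: str
    group_b: str
    comparisons: tuple[VariableComparison, ...]

    def __getitem__(self, variable: str) -> VariableComparison:
        for c in self.comparisons:
            if c.variable == variable:
                return c
        raise KeyError(variable)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "variable": c.variable,
                    f"{self.group_a}_mean": c.mean_a,
                    f"{self.group_a}_sd": c.sd_a,
                    f"{self.group_b}_mean": c.mean_b,
                    f"{self.group_b}_sd": c.sd_b,
                    "statistic": c.statistic,
                    "p_value": c.p_value,
                    "test": c.test,
                }
                for c in self.comparisons
            ]
        )


def compare_groups(
    cohort: pd.DataFrame,
    variables: tuple[str, ...] = DEFAULT_VARIABLES,
    *,
    include_sex: bool = True,
    welch: bool = False,
    yates: bool = True,
) -> GroupComparisonResult:
    """Compare the two groups' baseline visits variable by variable.

    Uses only rows with ``visit == "baseline"``.  A variable constant
    in both groups gets a NaN p-value and a ``degenerate`` flag rather
    than an exception.

    Raises
    ------
    ValueError
        Unless both groups contribute at least 2 baseline records.
    """
    base = cohort[cohort["visit"] == "baseline"]
    groups = sorted(base["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    ga, gb = groups
    a_rows = base[base["group"] == ga]
    b_rows = base[base["group"] == gb]
    if len(a_rows) < 2 or len(b_rows) < 2:
        raise ValueError("both groups need >= 2 baseline records")

    out: list[VariableComparison] = []
    for var in variables:
        a = a_rows[var].dropna().to_numpy(dtype=float)
        b = b_rows[var].dropna().to_numpy(dtype=float)
        mean_a, sd_a = float(a.mean()), float(a.std(ddof=1))
        mean_b, sd_b = float(b.mean()), float(b.std(ddof=1))
        if np.ptp(a) == 0 and np.ptp(b) == 0 and mean_a == mean_b:
            # No variation anywhere: t = 0/0; report p = 1 if means equal.
            out.append(
                VariableComparison(var, mean_a, sd_a, mean_b, sd_b,
                                   0.0, 1.0, "unpaired_t", degenerate=True)
            )
            continue
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            out.append(
                VariableComparison(var, mean_a, sd_a, mean_b, sd_b,
                                   float("nan"), float("nan"), "unpaired_t",
                                   degenerate=True)
            )
            continue
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
        name = "welch_t" if welch else "unpaired_t"
        out.append(
            VariableComparison(var, mean_a, sd_a, mean_b, sd_b,
                               float(t), float(p), name)
        )

    if include_sex and "sex" in cohort.columns:
        table = pd.crosstab(base["group"], base["sex"])
        if table.shape == (2, 2) and table.to_numpy().min() >= 0:
            chi2, p, _, _ = stats.chi2_contingency(
                table.to_numpy(), correction=yates
            )
            stat, pval, degen = float(chi2), float(p), False
        else:  # one sex absent entirely
            stat, pval, degen = float("nan"), float("nan"), True
        n_a_male = int((a_rows["sex"] == "M").sum())
        n_b_male = int((b_rows["sex"] == "M").sum())
        out.append(
            VariableComparison(
                "sex", n_a_male, float("nan"), n_b_male, float("nan"),
                stat, pval, "chi_square", degenerate=degen,
            )
        )
    return GroupComparisonResult(group_a=ga, group_b=gb, comparisons=tuple(out))
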