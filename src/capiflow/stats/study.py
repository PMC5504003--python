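"""End-to-end study pipeline: eligibility, baseline comparison and
longitudinal analysis, emitting report tables shaped like the study's
baseline-characteristics and longitudinal-change tables."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from capiflow.stats.clinical import compute_opp
from capiflow.stats.compare import GroupComparisonResult, compare_groups
from capiflow.stats.longitudinal import LongitudinalResult, longitudinal_analysis
from capiflow.stats.vfclass import classify_vf_glaucomatous
from capiflow.vf24 import VFTest

__all__ = ["StudyConfig", "StudyReport", "run_study"]

#: Variables analysed longitudinally, in report order.
LONGITUDINAL_VARIABLES = (
    "pbfv_mm_s",
    "mbr_t_au",
    "rvd_a_um",
    "rvd_v_um",
    "iop_mmHg",
    "opp_mmHg",
    "sbp_mmHg",
    "dbp_mmHg",
)

#: Inclusion floor: best-corrected acuity of 20/40, i.e. logMAR 0.301.
BCVA_LOGMAR_MAX = 0.30103


@dataclass(frozen=True)
class StudyConfig:
    alpha: float = 0.05
    welch: bool = False
    bcva_logmar_max: float = BCVA_LOGMAR_MAX
    longitudinal_variables: tuple[str, ...] = LONGITUDINAL_VARIABLES


@dataclass(frozen=True)
class StudyReport:
    n_eligible: dict[str, int]
    excluded: tuple[tuple[str, str], ...]  # (subject_id, reason)
    baseline: GroupComparisonResult | None  # None when a group is too small
    longitudinal: dict[str, LongitudinalResult]

    def table1(self) -> pd.DataFrame:
        if self.baseline is None:
            return pd.DataFrame()
        return self.baseline.to_frame()

    def table2(self) -> pd.DataFrame:
        return pd.concat(
            [res.to_frame() for res in self.longitudinal.values()],
            ignore_index=True,
        )

    def to_dict(self) -> dict:
        return {
            "n_eligible": dict(self.n_eligible),
            "excluded": [list(e) for e in self.excluded],
            "baseline": self.table1().to_dict(orient="records"),
            "longitudinal": {
                var: {
                    "anova_f": res.anova_f,
                    "anova_p": res.anova_p,
                    "anova_refused": res.anova_refused,
                    "n_complete_cases": res.n_complete_cases,
                    "visits": res.to_frame().to_dict(orient="records"),
                }
                for var, res in self.longitudinal.items()
            },
        }


def _with_opp(cohort: pd.DataFrame) -> pd.DataFrame:
    out = cohort.copy()
    out["opp_mmHg"] = compute_opp(
        out["sbp_mmHg"].to_numpy(),
        out["dbp_mmHg"].to_numpy(),
        out["iop_mmHg"].to_numpy(),
    )
    return out


def run_study(
    cohort: pd.DataFrame,
    vf_tests: dict[str, VFTest] | None = None,
    config: StudyConfig | None = None,
) -> StudyReport:
    """Run the full statistical pipeline on one subject-visit table.

    Eligibility: every subject needs baseline best-corrected acuity of
    20/40 or better (logMAR <= 0.301); treated-group subjects
    additionally need a supplied visual-field test that classifies as
    glaucomatous (reliable indices included).  Ocular perfusion
    pressure is derived, never read, from the table.

    Raises
    ------
    ValueError
        If no eligible subject remains in either group.
    """
    config = config or StudyConfig()
    cohort = _with_opp(cohort)

    excluded: list[tuple[str, str]] = []
    keep: list[str] = []
    baseline = cohort[cohort["visit"] == "baseline"].set_index("subject_id")
    for sid, row in baseline.iterrows():
        if row["bcva_logmar"] > config.bcva_logmar_max:
            excluded.append((sid, "bcva_below_20_40"))
            continue
        if row["group"] == "POAG":
            vf = (vf_tests or {}).get(sid)
            if vf is None:
                excluded.append((sid, "no_vf_test"))
                continue
            label = classify_vf_glaucomatous(vf)
            if label != "glaucomatous":
                excluded.append((sid, f"vf_{label}"))
                continue
        keep.append(sid)

    eligible = cohort[cohort["subject_id"].isin(keep)]
    n_eligible = (
        eligible[eligible["visit"] == "baseline"]
        .groupby("group")["subject_id"]
        .nunique()
        .to_dict()
    )
    if len(n_eligible) < 2 or min(n_eligible.values()) == 0:
        raise ValueError(f"eligible set too small per group: {n_eligible}")

    base_counts = eligible[eligible["visit"] == "baseline"]["group"].value_counts()
    if base_counts.min() >= 2:
        baseline_cmp = compare_groups(eligible, welch=config.welch)
    else:  # too few subjects for a between-group test; flag, do not fail
        baseline_cmp = None
    longitudinal = {
        var: longitudinal_analysis(eligible, var, alpha=config.alpha)
        for var in config.longitudinal_variables
    }
    return StudyReport(
        n_eligible={str(k): int(v) for k, v in n_eligible.items()},
        excluded=tuple(excluded),
        baseline=baseline_cmp,
        longitudinal=longitudinal,
    )
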