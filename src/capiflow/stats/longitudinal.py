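"""Longitudinal analysis of the treated group.

One-way within-subject (repeated-measures) ANOVA across the four
visits on complete cases, followed by paired t-tests of baseline
against each follow-up visit on available pairs, with Bonferroni
correction over the three contrasts.  Percent change is computed per
subject and then averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from capiflow.stats.clinical import percent_change

__all__ = ["VisitSummary", "PostHoc", "LongitudinalResult", "rm_anova",
           "longitudinal_analysis"]

VISITS: tuple[str, ...] = ("baseline", "wk1", "wk4", "wk12")
N_CONTRASTS = 3  # baseline vs each follow-up


@dataclass(frozen=True)
class VisitSummary:
    visit: str
    n: int
    mean: float
    sd: float


@dataclass(frozen=True)
class PostHoc:
    visit: str
    n_pairs: int
    statistic: float
    p_value: float
    significant_bonferroni: bool
    mean_percent_change: float


@dataclass(frozen=True)
class LongitudinalResult:
    variable: str
    visit_summaries: tuple[VisitSummary, ...]
    anova_f: float
    anova_df: tuple[float, float]
    anova_p: float
    anova_refused: bool
    n_complete_cases: int
    post_hoc: tuple[PostHoc, ...]
    alpha: float = 0.05

    def post_hoc_for(self, visit: str) -> PostHoc:
        for ph in self.post_hoc:
            if ph.visit == visit:
                return ph
        raise KeyError(visit)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for vs in self.visit_summaries:
            row = {"variable": self.variable, "visit": vs.visit, "n": vs.n,
                   "mean": vs.mean, "sd": vs.sd}
            if vs.visit != "baseline":
                try:
                    ph = self.post_hoc_for(vs.visit)
                    row.update(
                        post_hoc_p=ph.p_value,
                        significant=ph.significant_bonferroni,
                        mean_percent_change=ph.mean_percent_change,
                    )
                except KeyError:
                    pass
            rows.append(row)
        return pd.DataFrame(rows)


def rm_anova(data: np.ndarray) -> tuple[float, tuple[float, float], float]:
    """One-way within-subject ANOVA on an (n_subjects, n_visits) array.

    Returns ``(F, (df1, df2), p)`` with df1 = m - 1 and
    df2 = (n - 1)(m - 1) (no sphericity correction).  A perfectly flat
    data set returns F = 0, p = 1.
    """
    y = np.asarray(data, dtype=float)
    if y.ndim != 2 or y.shape[0] < 2 or y.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 visits")
    if np.any(~np.isfinite(y)):
        raise ValueError("complete cases only: data contains non-finite values")
    n, m = y.shape
    grand = y.mean()
    ss_time = n * float(((y.mean(axis=0) - grand) ** 2).sum())
    ss_subj = m * float(((y.mean(axis=1) - grand) ** 2).sum())
    ss_total = float(((y - grand) ** 2).sum())
    ss_err = max(ss_total - ss_time - ss_subj, 0.0)
    df1, df2 = float(m - 1), float((n - 1) * (m - 1))
    if ss_err <= 1e-12 * max(ss_total, 1.0):
        if ss_time <= 1e-12 * max(ss_total, 1.0):
            return 0.0, (df1, df2), 1.0
        return float("inf"), (df1, df2), 0.0
    f = (ss_time / df1) / (ss_err / df2)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), (df1, df2), p


def _paired_t(base: np.ndarray, follow: np.ndarray) -> tuple[float, float]:
    diff = follow - base
    if np.ptp(diff) == 0:
        # Degenerate paired test; identical visits give t = 0, p = 1.
        return (0.0, 1.0) if diff[0] == 0 else (float("inf"), 0.0)
    t, p = stats.ttest_rel(follow, base)
    return float(t), float(p)


def longitudinal_analysis(
    cohort: pd.DataFrame,
    variable: str,
    *,
    group: str = "POAG",
    visits: tuple[str, ...] = VISITS,
    alpha: float = 0.05,
    min_complete_cases: int = 3,
) -> LongitudinalResult:
    """Analyse one variable across the visits of the treated group.

    Subjects missing any visit are excluded from the ANOVA (complete
    cases) but kept in whichever paired contrasts they have data for.
    With fewer than ``min_complete_cases`` complete cases the ANOVA is
    refused (flagged) while post hoc tests are still reported.
    """
    rows = cohort[(cohort["group"] == group) & cohort["visit"].isin(visits)]
    if rows.empty:
        raise ValueError(f"no rows for group {group!r}")
    wide = rows.pivot_table(
        index="subject_id", columns="visit", values=variable, aggfunc="mean"
    ).reindex(columns=list(visits))

    summaries = tuple(
        VisitSummary(
            visit=v,
            n=int(wide[v].notna().sum()),
            mean=float(wide[v].mean()),
            sd=float(wide[v].std(ddof=1)),
        )
        for v in visits
    )

    complete = wide.dropna()
    refused = len(complete) < min_complete_cases
    if refused:
        f_stat, dfs, p = float("nan"), (float("nan"), float("nan")), float("nan")
    else:
        f_stat, dfs, p = rm_anova(complete.to_numpy())

    post: list[PostHoc] = []
    base_col = wide[visits[0]]
    for v in visits[1:]:
        pair = wide[[visits[0], v]].dropna()
        if len(pair) < 2:
            post.append(PostHoc(v, len(pair), float("nan"), float("nan"),
                                False, float("nan")))
            continue
        t, pv = _paired_t(pair[visits[0]].to_numpy(), pair[v].to_numpy())
        pct = percent_change(pair[visits[0]].to_numpy(), pair[v].to_numpy())
        post.append(
            PostHoc(
                visit=v,
                n_pairs=len(pair),
                statistic=t,
                p_value=pv,
                significant_bonferroni=bool(pv < alpha / N_CONTRASTS),
                mean_percent_change=float(np.mean(pct)),
            )
        )

    return LongitudinalResult(
        variable=variable,
        visit_summaries=summaries,
        anova_f=f_stat,
        anova_df=dfs,
        anova_p=p,
        anova_refused=refused,
        n_complete_cases=int(len(complete)),
        post_hoc=tuple(post),
        alpha=alpha,
    )
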