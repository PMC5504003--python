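import numpy as np
import pandas as pd
import pytest

from capiflow.stats.longitudinal import (
    VISITS,
    longitudinal_analysis,
    rm_anova,
)


def _long_df(wide: np.ndarray, visits=VISITS, group="POAG"):
    rows = []
    for i, subject in enumerate(wide):
        for t, v in enumerate(visits):
            if np.isnan(subject[t]):
                continue
            rows.append(
                {
                    "subject_id": f"P{i:02d}",
                    "group": group,
                    "visit": v,
                    "pbfv_mm_s": subject[t],
                }
            )
    return pd.DataFrame(rows)


def permutation_p(wide: np.ndarray, n_perm: int = 4000, seed: int = 0) -> float:
    """Within-subject permutation oracle for the RM-ANOVA p-value."""
    rng = np.random.default_rng(seed)
    f_obs, _, _ = rm_anova(wide)
    count = 0
    for _ in range(n_perm):
        perm = np.array([rng.permutation(row) for row in wide])
        f_perm, _, _ = rm_anova(perm)
        count += f_perm >= f_obs
    return (count + 1) / (n_perm + 1)


def test_flat_data_f0_p1():
    wide = np.tile([[2.0], [3.0], [4.0]], (1, 4))
    f, _, p = rm_anova(wide)
    assert f == 0.0 and p == 1.0
    res = longitudinal_analysis(_long_df(wide), "pbfv_mm_s")
    assert res.anova_f == 0.0 and res.anova_p == 1.0
    for ph in res.post_hoc:
        assert ph.p_value == 1.0
        assert ph.mean_percent_change == 0.0
        assert not ph.significant_bonferroni


def test_matches_statsmodels_anova_rm():
    from statsmodels.stats.anova import AnovaRM

    rng = np.random.default_rng(5)
    wide = rng.normal(size=(9, 4)) + np.array([0.0, 0.4, 0.7, 0.2])
    f, (d1, d2), p = rm_anova(wide)
    long = pd.DataFrame(
        {
            "s": np.repeat(np.arange(9), 4),
            "t": np.tile(np.arange(4), 9),
            "y": wide.ravel(),
        }
    )
    tab = AnovaRM(long, "y", "s", within=["t"]).fit().anova_table
    assert f == pytest.approx(tab["F Value"].iloc[0])
    assert (d1, d2) == (tab["Num DF"].iloc[0], tab["Den DF"].iloc[0])
    assert p == pytest.approx(tab["Pr > F"].iloc[0])


def test_agrees_with_permutation_oracle():
    rng = np.random.default_rng(17)
    wide = rng.normal(size=(8, 4)) + np.array([0.0, 0.3, 0.5, 0.1])
    _, _, p_f = rm_anova(wide)
    p_perm = permutation_p(wide)
    se = np.sqrt(p_f * (1 - p_f) / 4000)
    assert p_perm == pytest.approx(p_f, abs=max(4 * se, 0.02))


def test_known_effect_detected():
    rng = np.random.default_rng(2)
    wide = rng.normal(scale=0.05, size=(10, 4)) + np.array([1.0, 1.2, 1.3, 1.15])
    res = longitudinal_analysis(_long_df(wide), "pbfv_mm_s")
    assert res.anova_p < 0.001
    for ph in res.post_hoc:
        assert ph.significant_bonferroni


def test_missing_week12_handling():
    rng = np.random.default_rng(3)
    wide = rng.normal(size=(6, 4)) + 5.0
    wide[0, 3] = np.nan  # subject P00 misses week 12
    res = longitudinal_analysis(_long_df(wide), "pbfv_mm_s")
    assert res.n_complete_cases == 5
    assert res.post_hoc_for("wk1").n_pairs == 6
    assert res.post_hoc_for("wk4").n_pairs == 6
    assert res.post_hoc_for("wk12").n_pairs == 5


def test_too_few_complete_cases_refused_but_posthoc_reported():
    rng = np.random.default_rng(4)
    wide = rng.normal(size=(4, 4)) + 5.0
    wide[0, 3] = wide[1, 3] = np.nan
    res = longitudinal_analysis(_long_df(wide), "pbfv_mm_s")
    assert res.anova_refused
    assert np.isnan(res.anova_f)
    assert res.post_hoc_for("wk1").n_pairs == 4


def test_percent_change_is_mean_of_per_subject_changes():
    wide = np.array([[1.0, 1.1, 1.0, 1.0], [2.0, 2.6, 2.0, 2.0]])
    res = longitudinal_analysis(_long_df(wide), "pbfv_mm_s",
                                min_complete_cases=2)
    # per-subject wk1 changes: +10 % and +30 % -> mean 20 %
    assert res.post_hoc_for("wk1").mean_percent_change == pytest.approx(20.0)


def test_bonferroni_monotonicity():
    rng = np.random.default_rng(8)
    wide = rng.normal(size=(10, 4)) + np.array([0.0, 0.25, 0.4, 0.1])
    res = longitudinal_analysis(_long_df(wide), "pbfv_mm_s")
    for ph in res.post_hoc:
        if ph.significant_bonferroni:
            assert ph.p_value < res.alpha  # corrected implies uncorrected
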