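import pytest

from capiflow.sim.cohort import CohortSimConfig, simulate_cohort
from capiflow.sim.vf import simulate_vf_test
from capiflow.stats.study import LONGITUDINAL_VARIABLES, run_study


GLAUC_CLUSTER = {(-9, 9): 1, (-3, 9): 1, (3, 9): 3}


def _vf_for_poag(cohort, **kwargs):
    poag_ids = cohort[cohort.group == "POAG"].subject_id.unique()
    return {sid: simulate_vf_test(GLAUC_CLUSTER, **kwargs) for sid in poag_ids}


@pytest.fixture(scope="module")
def default_cohort():
    cohort = simulate_cohort(CohortSimConfig(seed=20))
    return cohort, _vf_for_poag(cohort)


def test_report_shape(default_cohort):
    cohort, vf = default_cohort
    report = run_study(cohort, vf)
    assert set(report.longitudinal) == set(LONGITUDINAL_VARIABLES)
    for res in report.longitudinal.values():
        assert len(res.post_hoc) == 3
        assert len(res.visit_summaries) == 4
    t2 = report.table2()
    assert set(t2.variable) == set(LONGITUDINAL_VARIABLES)
    assert report.baseline is not None
    assert "opp_mmHg" in {c.variable for c in report.baseline.comparisons}


def test_opp_derived_not_read(default_cohort):
    cohort, vf = default_cohort
    assert "opp_mmHg" not in cohort.columns
    report = run_study(cohort, vf)
    assert "opp_mmHg" in report.longitudinal


def test_vf_gatekeeping():
    cohort = simulate_cohort(CohortSimConfig(seed=21))
    vf = _vf_for_poag(cohort)
    poag_ids = sorted(vf)
    vf[poag_ids[0]] = simulate_vf_test(GLAUC_CLUSTER, fixation_loss=0.3)
    vf[poag_ids[1]] = simulate_vf_test()  # normal field
    report = run_study(cohort, vf)
    assert report.n_eligible["POAG"] == len(poag_ids) - 2
    reasons = dict(report.excluded)
    assert reasons[poag_ids[0]] == "vf_unreliable"
    assert reasons[poag_ids[1]] == "vf_normal"


def test_bcva_floor_applies_to_both_groups():
    cohort = simulate_cohort(CohortSimConfig(seed=22))
    vf = _vf_for_poag(cohort)
    bad = cohort[cohort.group == "healthy"].subject_id.iloc[0]
    cohort.loc[cohort.subject_id == bad, "bcva_logmar"] = 0.5
    report = run_study(cohort, vf)
    assert report.n_eligible["healthy"] == 10
    assert ("bcva_below_20_40" in dict(report.excluded).values()) or (
        dict(report.excluded)[bad] == "bcva_below_20_40"
    )


def test_empty_eligible_set_fails():
    cohort = simulate_cohort(CohortSimConfig(seed=23))
    report_vf = {}  # no POAG subject has a VF test
    with pytest.raises(ValueError):
        run_study(cohort, report_vf)


def test_single_poag_subject_refusal_flag():
    cohort = simulate_cohort(CohortSimConfig(seed=24))
    keep = cohort[cohort.group == "POAG"].subject_id.unique()[0]
    small = cohort[(cohort.group == "healthy") | (cohort.subject_id == keep)]
    vf = {keep: simulate_vf_test(GLAUC_CLUSTER)}
    report = run_study(small, vf)
    assert report.baseline is None
    for res in report.longitudinal.values():
        assert res.anova_refused


def test_report_serialisable(default_cohort):
    import json

    cohort, vf = default_cohort
    report = run_study(cohort, vf)
    text = json.dumps(report.to_dict())
    assert "pbfv_mm_s" in text


def test_no_effect_cohort_rarely_significant():
    # Flatten the treated-group profile: no visit effect anywhere.
    cfg = CohortSimConfig(seed=30)
    cfg.poag.profile = {
        var: {v: cfg.poag.baseline[var] for v in ("baseline", "wk1", "wk4", "wk12")}
        for var in cfg.poag.profile
    }
    flags = 0
    for seed in range(10):
        cfg.seed = 100 + seed
        cohort = simulate_cohort(cfg)
        report = run_study(cohort, _vf_for_poag(cohort))
        flags += any(
            ph.significant_bonferroni
            for res in report.longitudinal.values()
            for ph in res.post_hoc
        )
    assert flags <= 3  # 8 variables x 3 contrasts at corrected alpha
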