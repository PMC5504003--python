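"""Synthetic clinical cohorts with the study's group structure.

Two groups are generated: healthy controls measured at baseline only,
and glaucoma (POAG) patients measured at baseline and 1, 4 and 12 weeks
after starting topical treatment.  Each variable is drawn from a
compound-symmetric Gaussian model,

    X[i, t] = mu[t] + sd[t] * (sqrt(rho) * z[i] + sqrt(1 - rho) * e[i, t]),

so its per-visit mean and SD equal the configured values and any two
visits of the same subject correlate at ``rho``.

Ocular perfusion pressure is never stored; it is always derived
downstream from blood pressure and intraocular pressure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VISITS",
    "LONGITUDINAL_VARS",
    "BASELINE_VARS",
    "COHORT_COLUMNS",
    "GroupParams",
    "CohortSimConfig",
    "simulate_cohort",
]

VISITS: tuple[str, ...] = ("baseline", "wk1", "wk4", "wk12")

#: Variables re-measured at every visit.
LONGITUDINAL_VARS: tuple[str, ...] = (
    "sbp_mmHg",
    "dbp_mmHg",
    "iop_mmHg",
    "pbfv_mm_s",
    "mbr_t_au",
    "rvd_a_um",
    "rvd_v_um",
)

#: Variables measured once per subject.
BASELINE_VARS: tuple[str, ...] = ("age", "axial_length_mm", "bcva_logmar", "vf_md_db")

COHORT_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "group",
    "visit",
    "sex",
    *BASELINE_VARS,
    *LONGITUDINAL_VARS,
)

# Published group summaries (mean, SD) used as simulator defaults.
_HEALTHY_DEFAULTS: dict[str, tuple[float, float]] = {
    "age": (50.3, 11.8),
    "axial_length_mm": (23.98, 0.72),
    "bcva_logmar": (-0.18, 0.07),
    "vf_md_db": (float("nan"), 0.0),
    "sbp_mmHg": (121.3, 10.6),
    "dbp_mmHg": (72.3, 6.8),
    "iop_mmHg": (13.3, 1.2),
    "pbfv_mm_s": (1.35, 0.33),
    "mbr_t_au": (14.5, 3.2),
    "rvd_a_um": (109.3, 7.4),
    "rvd_v_um": (149.9, 12.6),
}

_POAG_BASELINE_DEFAULTS: dict[str, tuple[float, float]] = {
    "age": (54.9, 8.4),
    "axial_length_mm": (25.33, 1.48),
    "bcva_logmar": (-0.16, 0.04),
    "vf_md_db": (-5.23, 4.41),
}

# Per-visit (mean, SD) of the treated group, baseline / wk1 / wk4 / wk12.
_POAG_PROFILE_DEFAULTS: dict[str, dict[str, tuple[float, float]]] = {
    "pbfv_mm_s": {
        "baseline": (1.05, 0.16), "wk1": (1.21, 0.26),
        "wk4": (1.28, 0.24), "wk12": (1.19, 0.21),
    },
    "mbr_t_au": {
        "baseline": (11.8, 2.7), "wk1": (12.2, 3.1),
        "wk4": (12.3, 3.3), "wk12": (11.9, 3.2),
    },
    "rvd_a_um": {
        "baseline": (98.0, 12.4), "wk1": (98.5, 13.1),
        "wk4": (98.6, 13.5), "wk12": (93.7, 11.6),
    },
    "rvd_v_um": {
        "baseline": (131.9, 11.7), "wk1": (133.6, 13.7),
        "wk4": (135.7, 15.3), "wk12": (134.8, 16.7),
    },
    "iop_mmHg": {
        "baseline": (17.1, 2.3), "wk1": (13.7, 1.5),
        "wk4": (14.0, 2.0), "wk12": (14.4, 2.0),
    },
    "sbp_mmHg": {
        "baseline": (116.0, 18.0), "wk1": (111.0, 19.5),
        "wk4": (118.4, 20.2), "wk12": (120.9, 18.9),
    },
    "dbp_mmHg": {
        "baseline": (69.2, 11.0), "wk1": (67.2, 12.1),
        "wk4": (68.8, 15.9), "wk12": (71.1, 13.0),
    },
}


@dataclass
class GroupParams:
    """Per-group simulation parameters.

    ``baseline`` maps every variable name to its (mean, SD);
    ``profile`` optionally overrides longitudinal variables with a
    per-visit map ``{visit: (mean, SD)}``.  Variables without a profile
    keep their baseline distribution at every visit.
    """

    n: int = 11
    p_male: float = 0.5
    baseline: dict[str, tuple[float, float]] = field(default_factory=dict)
    profile: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)

    def moments(self, var: str, visit: str) -> tuple[float, float]:
        if var in self.profile:
            return self.profile[var][visit]
        return self.baseline[var]

    def validate(self) -> None:
        if self.n < 2:
            raise ValueError("each group needs at least 2 subjects")
        if not (0.0 <= self.p_male <= 1.0):
            raise ValueError("p_male must lie in [0, 1]")
        for var, (_, sd) in self.baseline.items():
            if sd < 0:
                raise ValueError(f"negative SD for {var}")
        for var, visits in self.profile.items():
            for visit, (_, sd) in visits.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {var} at {visit}")


def _default_healthy() -> GroupParams:
    return GroupParams(n=11, p_male=6 / 11, baseline=dict(_HEALTHY_DEFAULTS))


def _default_poag() -> GroupParams:
    baseline = dict(_POAG_BASELINE_DEFAULTS)
    baseline.update({v: p["baseline"] for v, p in _POAG_PROFILE_DEFAULTS.items()})
    return GroupParams(
        n=11,
        p_male=7 / 11,
        baseline=baseline,
        profile={v: dict(p) for v, p in _POAG_PROFILE_DEFAULTS.items()},
    )


@dataclass
class CohortSimConfig:
    """Cohort-level simulation parameters.

    ``rho`` is the within-subject correlation between any two visits of
    the same variable.  ``n_missing_week12`` subjects from the treated
    group lose their week-12 row entirely, mirroring study dropout.
    """

    healthy: GroupParams = field(default_factory=_default_healthy)
    poag: GroupParams = field(default_factory=_default_poag)
    rho: float = 0.5
    n_missing_week12: int = 1
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")
        if not (0 <= self.n_missing_week12 <= self.poag.n):
            raise ValueError("n_missing_week12 outside [0, n_poag]")
        self.healthy.validate()
        self.poag.validate()


#: Cross-correlation between the systolic and diastolic latent draws;
#: keeps marginal moments exact while making sBP < dBP vanishingly rare.
BP_COUPLING = 0.7


def _draw_longitudinal(
    params: GroupParams, visits: tuple[str, ...], rho: float,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Draw an (n_subjects, n_visits) array per longitudinal variable."""
    out = {}
    a, b = np.sqrt(rho), np.sqrt(1.0 - rho)
    latents = {}
    draw_order = ("dbp_mmHg",) + tuple(
        v for v in LONGITUDINAL_VARS if v != "dbp_mmHg"
    )
    for var in draw_order:
        z = rng.standard_normal((params.n, 1))
        e = rng.standard_normal((params.n, len(visits)))
        latent = a * z + b * e
        if var == "sbp_mmHg":
            # Couple systolic to diastolic so the pulse pressure stays
            # positive almost surely; marginal variance is preserved.
            r = BP_COUPLING
            latent = r * latents["dbp_mmHg"] + np.sqrt(1 - r * r) * latent
        latents[var] = latent
        mu = np.array([params.moments(var, v)[0] for v in visits])
        sd = np.array([params.moments(var, v)[1] for v in visits])
        out[var] = mu + sd * latent
    if "sbp_mmHg" in out and "dbp_mmHg" in out:
        # Reflect the (rare) residual crossings; bias is negligible.
        pulse = out["sbp_mmHg"] - out["dbp_mmHg"]
        out["sbp_mmHg"] = out["dbp_mmHg"] + np.abs(pulse)
    return out


def simulate_cohort(cfg: CohortSimConfig | None = None) -> pd.DataFrame:
    """Simulate one subject-visit table.

    Returns a data frame with one row per subject per visit (healthy:
    baseline only; treated: all four visits minus configured dropout)
    and the fixed column set :data:`COHORT_COLUMNS`.  Reproducible from
    ``cfg.seed``.
    """
    cfg = cfg or CohortSimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    rows: list[dict] = []
    for group, params, visits in (
        ("healthy", cfg.healthy, ("baseline",)),
        ("POAG", cfg.poag, VISITS),
    ):
        prefix = "H" if group == "healthy" else "P"
        sex = np.where(rng.random(params.n) < params.p_male, "M", "F")
        base_vals = {}
        for var in BASELINE_VARS:
            mean, sd = params.baseline.get(var, (float("nan"), 0.0))
            if np.isnan(mean):
                base_vals[var] = np.full(params.n, np.nan)
            else:
                base_vals[var] = mean + sd * rng.standard_normal(params.n)
        longi = _draw_longitudinal(params, visits, cfg.rho, rng)
        dropped: set[int] = set()
        if group == "POAG" and cfg.n_missing_week12 > 0:
            dropped = set(
                rng.choice(params.n, size=cfg.n_missing_week12, replace=False)
            )
        for i in range(params.n):
            for t, visit in enumerate(visits):
                if visit == "wk12" and i in dropped:
                    continue
                row = {
                    "subject_id": f"{prefix}{i + 1:02d}",
                    "group": group,
                    "visit": visit,
                    "sex": sex[i],
                }
                row.update({var: base_vals[var][i] for var in BASELINE_VARS})
                row.update({var: longi[var][i, t] for var in LONGITUDINAL_VARS})
                rows.append(row)

    return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
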