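"""A-priori power and sample size for the within-subject RM-ANOVA design.

The power of the within-factor F-test follows the conventional
noncentral-F computation: with n subjects, m occasions, effect size f
(Cohen), among-repetition correlation rho and nonsphericity epsilon,

    lambda = n * m * f^2 / (1 - rho) * epsilon
    df1    = (m - 1) * epsilon
    df2    = (n - 1) * (m - 1) * epsilon

and power = P[F'(df1, df2, lambda) > F_crit(alpha)].
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

__all__ = ["PowerSpec", "rm_anova_power", "required_sample_size"]

MIN_N = 2
MAX_N = 100_000


@dataclass(frozen=True)
class PowerSpec:
    """Design parameters of the within-subject F-test."""

    effect_size_f: float = 0.4
    alpha: float = 0.05
    power: float = 0.8
    n_timepoints: int = 4
    corr_among_reps: float = 0.5
    nonsphericity_eps: float = 1.0

    def validate(self) -> None:
        if not (0.0 < self.alpha < 1.0) or not (0.0 < self.power < 1.0):
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.effect_size_f < 0:
            raise ValueError("effect size must be non-negative")
        if self.n_timepoints < 2:
            raise ValueError("need at least 2 timepoints")
        if not (0.0 <= self.corr_among_reps < 1.0):
            raise ValueError("correlation must lie in [0, 1)")
        if not (0.0 < self.nonsphericity_eps <= 1.0):
            raise ValueError("nonsphericity epsilon must lie in (0, 1]")


def rm_anova_power(spec: PowerSpec, n: int) -> float:
    """Power of the within-subject F-test at sample size ``n``."""
    spec.validate()
    if n < MIN_N:
        raise ValueError(f"n must be >= {MIN_N}")
    m, eps = spec.n_timepoints, spec.nonsphericity_eps
    lam = n * m * spec.effect_size_f**2 / (1.0 - spec.corr_among_reps) * eps
    df1 = (m - 1) * eps
    df2 = (n - 1) * (m - 1) * eps
    f_crit = stats.f.ppf(1.0 - spec.alpha, df1, df2)
    return float(stats.ncf.sf(f_crit, df1, df2, lam))


def required_sample_size(spec: PowerSpec) -> int:
    """Smallest n whose within-subject F-test power reaches ``spec.power``.

    Raises
    ------
    ValueError
        If the effect size is zero (power never exceeds alpha, so no
        finite n exists).
    """
    spec.validate()
    if spec.effect_size_f == 0:
        raise ValueError("effect size 0: required sample size is unbounded")
    for n in range(MIN_N, MAX_N + 1):
        if rm_anova_power(spec, n) >= spec.power:
            return n
    raise RuntimeError(f"no n <= {MAX_N} reaches the requested power")
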