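"""Elementary clinical conversions: ocular perfusion pressure, logMAR
acuity and percent change.  All accept scalars or numpy arrays."""

from __future__ import annotations

import numpy as np

__all__ = ["compute_opp", "decimal_to_logmar", "percent_change"]


def compute_opp(sbp_mmHg, dbp_mmHg, iop_mmHg):
    """Ocular perfusion pressure, mmHg.

    OPP = 2/3 * [dBP + 1/3 * (sBP - dBP)] - IOP, i.e. two thirds of the
    estimated mean arterial pressure minus intraocular pressure.
    Linear in all three arguments.

    Raises
    ------
    ValueError
        If any systolic value is below its diastolic value, a blood
        pressure is non-positive, or an IOP is negative.
    """
    sbp = np.asarray(sbp_mmHg, dtype=float)
    dbp = np.asarray(dbp_mmHg, dtype=float)
    iop = np.asarray(iop_mmHg, dtype=float)
    if np.any(sbp < dbp):
        raise ValueError("systolic pressure below diastolic pressure")
    if np.any(dbp <= 0):
        raise ValueError("blood pressures must be positive")
    if np.any(iop < 0):
        raise ValueError("IOP must be non-negative")
    opp = 2.0 / 3.0 * (dbp + (sbp - dbp) / 3.0) - iop
    return opp if opp.ndim else float(opp)


def decimal_to_logmar(decimal_acuity):
    """Convert decimal visual acuity to logMAR: -log10(acuity)."""
    acuity = np.asarray(decimal_acuity, dtype=float)
    if np.any(acuity <= 0):
        raise ValueError("decimal acuity must be positive")
    out = -np.log10(acuity)
    return out if out.ndim else float(out)


def percent_change(baseline_value, follow_up_value):
    """Percent change from baseline: 100 * (follow-up - baseline) / baseline."""
    base = np.asarray(baseline_value, dtype=float)
    follow = np.asarray(follow_up_value, dtype=float)
    if np.any(base == 0):
        raise ValueError("baseline value must be non-zero")
    out = 100.0 * (follow - base) / base
    return out if out.ndim else float(out)
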