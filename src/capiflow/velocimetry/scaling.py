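"""Angular-to-metric conversion on the retina.

Field angles are converted to retinal distance with a Bennett-style
schematic-eye scaling in which one degree of visual angle corresponds to

    q = 0.01306 * (axial_length_mm - 1.82)   [mm/deg]

The 1.82 mm offset is the distance from the corneal apex to the eye's
second nodal point in the reduced schematic eye.
"""

from __future__ import annotations

import numpy as np

__all__ = ["deg_to_mm", "mm_per_deg"]

#: Bennett scaling constant, mm of retina per degree per mm of (AL - offset).
BENNETT_COEF = 0.01306
#: Distance from corneal apex to the second nodal point, mm.
NODAL_OFFSET_MM = 1.82

#: Plausible adult axial-length range, mm; values outside are rejected.
AXIAL_LENGTH_RANGE_MM = (20.0, 30.0)


def mm_per_deg(axial_length_mm: float) -> float:
    """Retinal millimetres subtended by one degree of visual angle.

    Parameters
    ----------
    axial_length_mm
        Axial length of the eye in millimetres; must lie in [20, 30].
    """
    lo, hi = AXIAL_LENGTH_RANGE_MM
    if not (lo <= axial_length_mm <= hi):
        raise ValueError(
            f"axial length {axial_length_mm!r} mm outside plausible "
            f"range [{lo}, {hi}] mm"
        )
    return BENNETT_COEF * (axial_length_mm - NODAL_OFFSET_MM)


def deg_to_mm(angle_deg, axial_length_mm: float):
    """Convert a visual angle to retinal distance.

    Linear in ``angle_deg`` and strictly increasing in
    ``axial_length_mm``.  Accepts scalars or arrays of angles.

    Returns
    -------
    Distance on the retina in millimetres, same shape as ``angle_deg``.
    """
    q = mm_per_deg(axial_length_mm)
    return np.multiply(angle_deg, q)
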