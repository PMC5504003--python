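"""Visual-field eligibility classification (Anderson-Patella style).

A test is *unreliable* when any reliability index exceeds 15 %.
Otherwise it is *glaucomatous* when the glaucoma hemifield test is
outside normal limits, the pattern-standard-deviation probability is
below 5 %, or the pattern-deviation plot contains a cluster of three or
more adjacent non-edge points within one hemifield, all depressed at
p < 5 % with at least one at p < 1 %.  Adjacency is 8-neighbour on the
24-2 lattice; edge and blind-spot points never count (constants in
:mod:`capiflow.vf24`).
"""

from __future__ import annotations

import numpy as np

from capiflow.vf24 import (
    BLIND_SPOT_POINTS,
    EDGE_POINTS,
    GRID_24_2,
    NEIGHBOURS,
    PD_CODE_P1,
    PD_CODE_P5,
    VFTest,
)

__all__ = ["classify_vf_glaucomatous", "has_qualifying_cluster"]

RELIABILITY_CUTOFF = 0.15
MIN_CLUSTER_SIZE = 3

#: Indices eligible for cluster membership (non-edge, non-blind-spot).
_CLUSTER_ELIGIBLE = np.array(
    [
        p not in EDGE_POINTS and p not in BLIND_SPOT_POINTS
        for p in GRID_24_2
    ]
)
_HEMIFIELD = np.array([1 if y > 0 else -1 for _, y in GRID_24_2])


def has_qualifying_cluster(pd_prob: np.ndarray) -> bool:
    """True if a qualifying depressed cluster exists in either hemifield.

    Connected components (8-neighbour) of eligible points depressed at
    p < 5 % are grown within one hemifield; a component qualifies when
    it has >= 3 points and contains a point depressed at p < 1 %.
    """
    pd = np.asarray(pd_prob)
    for hemi in (1, -1):
        candidate = _CLUSTER_ELIGIBLE & (_HEMIFIELD == hemi) & (pd >= PD_CODE_P5)
        seen = np.zeros(len(pd), dtype=bool)
        for start in np.flatnonzero(candidate):
            if seen[start]:
                continue
            comp, queue = [], [start]
            seen[start] = True
            while queue:
                i = queue.pop()
                comp.append(i)
                for j in NEIGHBOURS[i]:
                    if candidate[j] and not seen[j]:
                        seen[j] = True
                        queue.append(j)
            if len(comp) >= MIN_CLUSTER_SIZE and np.any(pd[comp] >= PD_CODE_P1):
                return True
    return False


def classify_vf_glaucomatous(vf: VFTest) -> str:
    """Classify one 24-2 test as 'glaucomatous', 'normal' or 'unreliable'."""
    if (
        vf.fixation_loss > RELIABILITY_CUTOFF
        or vf.false_pos > RELIABILITY_CUTOFF
        or vf.false_neg > RELIABILITY_CUTOFF
    ):
        return "unreliable"
    if vf.ght_outside_normal or vf.psd_prob_lt_5pct:
        return "glaucomatous"
    if has_qualifying_cluster(vf.pd_prob):
        return "glaucomatous"
    return "normal"
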