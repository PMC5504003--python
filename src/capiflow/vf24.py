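"""The Humphrey 24-2 test-point grid and the visual-field test record.

All grid geometry lives here so the simulator, the classifier and any
test oracle agree on a single set of constants.

Point order
-----------
The canonical order of the 54 points is row-major from the superior
field: y descends from +21 to -21 degrees and, within a row, x ascends.
Coordinates are in degrees of visual angle for a right eye (positive x
temporal-to-nasal on the chart).

Pattern-deviation categories
----------------------------
Probability-of-normality categories are integer codes::

    0  p >= 5 %   (within normal limits)
    1  p < 5 %
    2  p < 2 %
    3  p < 1 %
    4  p < 0.5 %

A point is "depressed at p < 5 %" when its code is >= 1 and
"depressed at p < 1 %" when its code is >= 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GRID_24_2",
    "POINT_INDEX",
    "EDGE_POINTS",
    "BLIND_SPOT_POINTS",
    "NEIGHBOURS",
    "N_POINTS",
    "PD_CODE_NORMAL",
    "PD_CODE_P5",
    "PD_CODE_P2",
    "PD_CODE_P1",
    "PD_CODE_P05",
    "VFTest",
]

# Number of points per row, superior to inferior (y = +21 ... -21).
_ROW_X = {
    21: (-9, 9),
    15: (-15, 15),
    9: (-21, 21),
    3: (-27, 21),
    -3: (-27, 21),
    -9: (-21, 21),
    -15: (-15, 15),
    -21: (-9, 9),
}


def _build_grid() -> tuple[tuple[int, int], ...]:
    pts = []
    for y in (21, 15, 9, 3, -3, -9, -15, -21):
        lo, hi = _ROW_X[y]
        for x in range(lo, hi + 1, 6):
            pts.append((x, y))
    return tuple(pts)


#: The 54 (x_deg, y_deg) test locations in canonical order.
GRID_24_2: tuple[tuple[int, int], ...] = _build_grid()
N_POINTS = len(GRID_24_2)
assert N_POINTS == 54

#: Coordinate -> canonical index.
POINT_INDEX: dict[tuple[int, int], int] = {p: i for i, p in enumerate(GRID_24_2)}

#: Physiologic blind-spot locations; never counted in clusters.
BLIND_SPOT_POINTS: frozenset[tuple[int, int]] = frozenset({(15, 3), (15, -3)})


def _build_edge() -> frozenset[tuple[int, int]]:
    edge: set[tuple[int, int]] = set()
    for y, (lo, hi) in _ROW_X.items():
        if abs(y) == 21:  # whole outermost rows
            edge.update((x, y) for x in range(lo, hi + 1, 6))
        else:  # row endpoints
            edge.update({(lo, y), (hi, y)})
    return frozenset(edge)


#: Outermost-ring points, excluded from cluster membership.
EDGE_POINTS: frozenset[tuple[int, int]] = _build_edge()


def _build_neighbours() -> tuple[tuple[int, ...], ...]:
    out = []
    for (x, y) in GRID_24_2:
        nbrs = []
        for dx in (-6, 0, 6):
            for dy in (-6, 0, 6):
                if dx == 0 and dy == 0:
                    continue
                j = POINT_INDEX.get((x + dx, y + dy))
                if j is not None:
                    nbrs.append(j)
        out.append(tuple(nbrs))
    return tuple(out)


#: 8-neighbour adjacency (6-degree king moves) as index tuples.
NEIGHBOURS: tuple[tuple[int, ...], ...] = _build_neighbours()

PD_CODE_NORMAL = 0
PD_CODE_P5 = 1
PD_CODE_P2 = 2
PD_CODE_P1 = 3
PD_CODE_P05 = 4


@dataclass(frozen=True)
class VFTest:
    """One 24-2 standard-automated-perimetry result.

    Attributes
    ----------
    pd_prob
        54 integer pattern-deviation category codes in canonical point
        order (see module docstring).
    ght_outside_normal
        Glaucoma hemifield test flag, consumed as an input (the
        normative database is not modelled).
    psd_prob_lt_5pct
        Pattern-standard-deviation probability < 5 % flag.
    fixation_loss, false_pos, false_neg
        Reliability indices as rates in [0, 1].
    """

    pd_prob: np.ndarray
    ght_outside_normal: bool = False
    psd_prob_lt_5pct: bool = False
    fixation_loss: float = 0.0
    false_pos: float = 0.0
    false_neg: float = 0.0

    def __post_init__(self) -> None:
        pd = np.asarray(self.pd_prob, dtype=int)
        if pd.shape != (N_POINTS,):
            raise ValueError(f"pd_prob must have exactly {N_POINTS} points")
        if pd.min() < PD_CODE_NORMAL or pd.max() > PD_CODE_P05:
            raise ValueError("pd_prob codes must lie in 0..4")
        for name in ("fixation_loss", "false_pos", "false_neg"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        object.__setattr__(self, "pd_prob", pd)

    def to_dict(self) -> dict:
        return {
            "point_order": [list(p) for p in GRID_24_2],
            "pd_prob": self.pd_prob.tolist(),
            "ght_outside_normal": bool(self.ght_outside_normal),
            "psd_prob_lt_5pct": bool(self.psd_prob_lt_5pct),
            "fixation_loss": float(self.fixation_loss),
            "false_pos": float(self.false_pos),
            "false_neg": float(self.false_neg),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VFTest":
        return cls(
            pd_prob=np.asarray(d["pd_prob"], dtype=int),
            ght_outside_normal=bool(d.get("ght_outside_normal", False)),
            psd_prob_lt_5pct=bool(d.get("psd_prob_lt_5pct", False)),
            fixation_loss=float(d.get("fixation_loss", 0.0)),
            false_pos=float(d.get("false_pos", 0.0)),
            false_neg=float(d.get("false_neg", 0.0)),
        )
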