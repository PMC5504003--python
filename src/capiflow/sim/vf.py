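"""Synthetic 24-2 visual-field tests with a prescribed depression pattern."""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np

from capiflow.vf24 import (
    N_POINTS,
    PD_CODE_NORMAL,
    PD_CODE_P05,
    PD_CODE_P5,
    POINT_INDEX,
    VFTest,
)

__all__ = ["simulate_vf_test", "random_vf_test"]


def simulate_vf_test(
    depressed: Mapping[tuple[int, int], int] | Sequence[tuple[int, int]] | None = None,
    *,
    ght_outside_normal: bool = False,
    psd_prob_lt_5pct: bool = False,
    fixation_loss: float = 0.0,
    false_pos: float = 0.0,
    false_neg: float = 0.0,
    seed: int | None = None,
) -> VFTest:
    """Build a 24-2 test with exactly the requested depressed points.

    Parameters
    ----------
    depressed
        Either a mapping of grid coordinates ``(x_deg, y_deg)`` to a
        pattern-deviation category code (1..4), or a sequence of
        coordinates which are all depressed at p < 5 % (code 1).
        ``None`` or empty yields a fully normal map.
    seed
        Accepted for interface symmetry with the other generators; the
        map itself is fully determined by the arguments.

    Raises
    ------
    ValueError
        If a requested point is not on the 24-2 grid or a code is
        outside 1..4.
    """
    del seed  # deterministic by construction
    pd = np.full(N_POINTS, PD_CODE_NORMAL, dtype=int)
    if depressed:
        if not isinstance(depressed, Mapping):
            depressed = {tuple(p): PD_CODE_P5 for p in depressed}
        for point, code in depressed.items():
            idx = POINT_INDEX.get(tuple(point))
            if idx is None:
                raise ValueError(f"point {point!r} is not on the 24-2 grid")
            if not (PD_CODE_P5 <= int(code) <= PD_CODE_P05):
                raise ValueError(f"depression code {code!r} outside 1..4")
            pd[idx] = int(code)
    return VFTest(
        pd_prob=pd,
        ght_outside_normal=ght_outside_normal,
        psd_prob_lt_5pct=psd_prob_lt_5pct,
        fixation_loss=fixation_loss,
        false_pos=false_pos,
        false_neg=false_neg,
    )


def random_vf_test(
    rng: np.random.Generator,
    p_depressed: float = 0.25,
    p_unreliable: float = 0.15,
    p_flag: float = 0.15,
) -> VFTest:
    """A random map for stress-testing the classifier.

    Each point is independently depressed with probability
    ``p_depressed`` (category then uniform over 1..4); reliability
    indices occasionally exceed the 15 % cut-off.
    """
    pd = np.where(
        rng.random(N_POINTS) < p_depressed,
        rng.integers(1, 5, N_POINTS),
        PD_CODE_NORMAL,
    )
    def rate() -> float:
        return float(rng.uniform(0.16, 0.6) if rng.random() < p_unreliable
                     else rng.uniform(0.0, 0.15))
    return VFTest(
        pd_prob=pd,
        ght_outside_normal=bool(rng.random() < p_flag),
        psd_prob_lt_5pct=bool(rng.random() < p_flag),
        fixation_loss=rate(),
        false_pos=rate(),
        false_neg=rate(),
    )
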