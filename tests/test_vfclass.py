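"""Classifier tests, including an exhaustive triple-enumeration oracle
that is independent of the component-growing implementation."""

from itertools import combinations

import numpy as np

from capiflow.sim.vf import random_vf_test, simulate_vf_test
from capiflow.stats.vfclass import classify_vf_glaucomatous
from capiflow.vf24 import (
    BLIND_SPOT_POINTS,
    EDGE_POINTS,
    GRID_24_2,
    VFTest,
)


def oracle_classify(vf: VFTest) -> str:
    """Brute force over all point triples (no component growing)."""
    if max(vf.fixation_loss, vf.false_pos, vf.false_neg) > 0.15:
        return "unreliable"
    if vf.ght_outside_normal or vf.psd_prob_lt_5pct:
        return "glaucomatous"
    # Any connected same-hemifield triple of eligible depressed points
    # with one point at p < 1 % certifies a qualifying cluster of >= 3.
    for hemi in (1, -1):
        eligible = [
            i
            for i, (x, y) in enumerate(GRID_24_2)
            if (y > 0) == (hemi > 0)
            and (x, y) not in EDGE_POINTS
            and (x, y) not in BLIND_SPOT_POINTS
            and vf.pd_prob[i] >= 1
        ]
        for triple in combinations(eligible, 3):
            if not any(vf.pd_prob[i] >= 3 for i in triple):
                continue
            edges = sum(
                1
                for a, b in combinations(triple, 2)
                if abs(GRID_24_2[a][0] - GRID_24_2[b][0]) <= 6
                and abs(GRID_24_2[a][1] - GRID_24_2[b][1]) <= 6
            )
            if edges >= 2:  # 3-node graph connected
                return "glaucomatous"
    return "normal"


def test_direct_criterion_cluster():
    vf = simulate_vf_test({(-9, 9): 1, (-3, 9): 1, (3, 9): 3})
    assert classify_vf_glaucomatous(vf) == "glaucomatous"


def test_cluster_needs_a_p1_point():
    vf = simulate_vf_test({(-9, 9): 1, (-3, 9): 1, (3, 9): 2})
    assert classify_vf_glaucomatous(vf) == "normal"


def test_cluster_crossing_meridian_does_not_count():
    # Two superior + one inferior adjacent points: neither hemifield
    # holds three, so the map is normal.
    vf = simulate_vf_test({(-9, 3): 1, (-3, 3): 1, (-9, -3): 3})
    assert classify_vf_glaucomatous(vf) == "normal"


def test_edge_points_do_not_count():
    vf = simulate_vf_test({(-9, 21): 3, (-3, 21): 1, (3, 21): 1})
    assert classify_vf_glaucomatous(vf) == "normal"


def test_fixation_loss_20pct_unreliable():
    vf = simulate_vf_test(
        {(-9, 9): 1, (-3, 9): 1, (3, 9): 3}, fixation_loss=0.20
    )
    assert classify_vf_glaucomatous(vf) == "unreliable"


def test_reliability_cutoff_is_inclusive():
    vf = simulate_vf_test(fixation_loss=0.15, false_pos=0.15, false_neg=0.15)
    assert classify_vf_glaucomatous(vf) == "normal"


def test_ght_or_psd_flag_sufficient():
    assert classify_vf_glaucomatous(simulate_vf_test(ght_outside_normal=True)) \
        == "glaucomatous"
    assert classify_vf_glaucomatous(simulate_vf_test(psd_prob_lt_5pct=True)) \
        == "glaucomatous"


def test_diagonal_adjacency_counts():
    # A diagonal chain in the superior hemifield: (-9,9),(-3,15),(3,9).
    vf = simulate_vf_test({(-9, 9): 1, (-3, 15): 3, (3, 9): 1})
    assert classify_vf_glaucomatous(vf) == oracle_classify(vf) == "glaucomatous"


def test_agrees_with_bruteforce_oracle_on_random_maps():
    rng = np.random.default_rng(2024)
    n_glauc = n_normal = 0
    for i in range(200):
        dense = rng.random() < 0.5
        vf = random_vf_test(rng, p_depressed=0.30 if dense else 0.08)
        got = classify_vf_glaucomatous(vf)
        assert got == oracle_classify(vf)
        n_glauc += got == "glaucomatous"
        n_normal += got == "normal"
    assert n_glauc > 20 and n_normal > 20  # both labels exercised
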