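import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from watchwalk.bouts import (
    assemble_bouts,
    gap_bridgeable,
    longest_walk,
    walk_exposure_proportions,
)
from watchwalk.config import PipelineConfig


def _rule_oracle(prev, gap, nxt, cfg):
    """Direct, independent evaluation of the three bridging criteria."""
    c1 = gap <= 60.0
    c2 = gap <= prev and gap <= nxt
    c3 = gap <= prev / 5.0 or gap <= nxt / 5.0
    return c1 and c2 and c3


# twelve hand-constructed (prev, gap, next) cases spanning every criterion
TRUTH_TABLE = [
    (120.0, 20.0, 160.0, True),   # all three pass (20<=60, 20<=120, 20<=32)
    (120.0, 70.0, 120.0, False),  # criterion 1: gap exceeds 60 s
    (8.0, 12.0, 100.0, False),    # criterion 2: gap exceeds preceding run
    (100.0, 12.0, 8.0, False),    # criterion 2: gap exceeds following run
    (40.0, 20.0, 40.0, False),    # criterion 3: 20 > 40/5 on both sides
    (40.0, 8.0, 40.0, True),      # exactly one-fifth of either neighbour
    (300.0, 60.0, 300.0, True),   # exactly at the 60 s cap
    (300.0, 60.000001, 300.0, False),
    (4.0, 4.0, 4.0, False),       # tiny runs: gap equals runs but > runs/5
    (20.0, 4.0, 400.0, True),     # one-fifth of either neighbour (max rule)
    (400.0, 4.0, 20.0, True),
    (60.0, 0.0, 60.0, True),      # zero gap always bridges
]


@pytest.mark.parametrize("prev, gap, nxt, expected", TRUTH_TABLE)
def test_bridging_truth_table_matches_rule_oracle(cfg, prev, gap, nxt, expected):
    assert _rule_oracle(prev, gap, nxt, cfg) == expected
    assert gap_bridgeable(prev, gap, nxt, cfg) == expected


def _labels_for(pattern, cfg):
    """pattern: list of (seconds, is_walking) -> per-window labels + times."""
    labels, times = [], []
    t = 0.0
    w = cfg.window_s
    for seconds, walking in pattern:
        n = int(round(seconds / w))
        for _ in range(n):
            labels.append("walk_arm_swing" if walking else "stationary")
            times.append(t)
            t += w
    return np.asarray(labels, dtype=object), np.asarray(times)


def test_assemble_bridges_qualifying_gap(cfg):
    labels, times = _labels_for([(120, True), (20, False), (160, True)], cfg)
    bouts = assemble_bouts(labels, times, cfg)
    assert len(bouts) == 1
    assert bouts[0].duration_s == pytest.approx(300.0)
    assert len(bouts[0].bridged_gaps) == 1
    assert bouts[0].bridged_gaps[0][1] == pytest.approx(20.0)


@pytest.mark.parametrize(
    "pattern",
    [
        [(120, True), (72, False), (120, True)],  # criterion 1 fails
        [(8, True), (12, False), (100, True)],    # criterion 2 fails
    ],
)
def test_assemble_keeps_runs_apart_when_a_criterion_fails(cfg, pattern):
    labels, times = _labels_for(pattern, cfg)
    bouts = assemble_bouts(labels, times, cfg)
    assert len(bouts) == 2


def test_iterative_bridging_cascades_left_to_right(cfg):
    # the 44 s gap does not bridge against the raw 40 s run (criterion 2),
    # but does after the first merge lengthens its left neighbour to 248 s
    labels, times = _labels_for(
        [(200, True), (8, False), (40, True), (44, False), (200, True)], cfg
    )
    bouts = assemble_bouts(labels, times, cfg)
    assert len(bouts) == 1
    assert bouts[0].duration_s == pytest.approx(492.0)
    assert gap_bridgeable(40.0, 44.0, 200.0, cfg) is False
    assert gap_bridgeable(248.0, 44.0, 200.0, cfg) is True


def test_longest_walk(cfg):
    labels, times = _labels_for(
        [(40, True), (100, False), (332, True), (100, False), (12, True)], cfg
    )
    bouts = assemble_bouts(labels, times, cfg)
    assert longest_walk(bouts) == pytest.approx(332.0)
    assert longest_walk([]) == 0.0


def test_exposure_proportions_hand_computed(cfg):
    labels, times = _labels_for(
        [(4, True), (100, False), (8, True), (100, False), (120, True)], cfg
    )
    bouts = assemble_bouts(labels, times, cfg)
    p8, p60 = walk_exposure_proportions(bouts, cfg)
    assert p8 == pytest.approx(100 * 128 / 132)
    assert p60 == pytest.approx(100 * 120 / 132)
    assert walk_exposure_proportions([], cfg) == (None, None)


def test_single_bout_and_all_short(cfg):
    labels, times = _labels_for([(120, True)], cfg)
    bouts = assemble_bouts(labels, times, cfg)
    assert walk_exposure_proportions(bouts, cfg) == (100.0, 100.0)
    labels, times = _labels_for([(4, True), (100, False), (4, True)], cfg)
    p8, _ = walk_exposure_proportions(assemble_bouts(labels, times, cfg), cfg)
    assert p8 == 0.0


def test_unordered_times_rejected(cfg):
    labels = np.asarray(["walk_arm_swing", "walk_arm_swing"], dtype=object)
    with pytest.raises(ValueError):
        assemble_bouts(labels, np.array([4.0, 0.0]), cfg)


@settings(max_examples=50, deadline=None)
@given(st.lists(st.booleans(), min_size=1, max_size=60))
def test_bridging_never_shortens_longest_walk(walk_flags):
    cfg = PipelineConfig()
    labels = np.asarray(
        ["walk_arm_swing" if w else "stationary" for w in walk_flags], dtype=object
    )
    times = np.arange(len(walk_flags)) * cfg.window_s
    bridged = assemble_bouts(labels, times, cfg)
    raw = assemble_bouts(labels, times, PipelineConfig(bridge_max_gap_s=1e-9))
    assert longest_walk(bridged) >= longest_walk(raw)
    # raw runs contain no bridged gaps and exactly cover walking windows
    assert sum(len(b.window_indices) for b in raw) == int(sum(walk_flags))
    assert all(not b.bridged_gaps for b in raw)
    total_walk_time = sum(walk_flags) * cfg.window_s
    assert sum(b.duration_s for b in bridged) >= total_walk_time - 1e-9
    assert sum(b.duration_s for b in bridged) <= len(walk_flags) * cfg.window_s + 1e-9
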