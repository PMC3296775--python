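import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import cnadiff as cd
from cnadiff.segmentation import GAIN, LOSS, NEUTRAL


def _flat_panel(n, spacing=1_000):
    model = cd.GenomeModel(chromosomes=(("chr1", n * spacing),), probe_spacing=float(spacing),
                           spacing_jitter=0.0)
    return cd.build_probe_panel(model, seed=0)


def test_flat_profile_yields_single_neutral_segment(uniform_panel):
    prof = cd.segment_profile(np.zeros(uniform_panel.n_probes), uniform_panel)
    assert len(prof.segments) == len(uniform_panel.chrom_order)
    assert all(s.state == NEUTRAL for s in prof.segments)
    assert prof.segments[0].n_markers == 1000
    assert prof.segments[1].n_markers == 2000


def test_noisy_step_profile_breakpoints_close_to_truth():
    panel = _flat_panel(1300)
    rng = np.random.default_rng(77)
    x = np.concatenate([np.zeros(500), np.full(300, 0.8), np.zeros(500)])
    x = x + rng.normal(0, 0.1, 1300)
    prof = cd.segment_profile(x, panel)
    assert len(prof.segments) == 3
    starts = [s.n_markers for s in prof.segments]
    # cumulative marker counts give the breakpoint probe indices
    b1 = starts[0]
    b2 = starts[0] + starts[1]
    assert abs(b1 - 500) <= 5
    assert abs(b2 - 800) <= 5
    assert [s.state for s in prof.segments] == [NEUTRAL, GAIN, NEUTRAL]


def test_noise_free_breakpoints_recovered_exactly():
    panel = _flat_panel(1300)
    x = np.concatenate([np.zeros(500), np.full(300, 0.8), np.zeros(500)])
    prof = cd.segment_profile(x, panel)
    assert [s.n_markers for s in prof.segments] == [500, 300, 500]
    assert [s.state for s in prof.segments] == [NEUTRAL, GAIN, NEUTRAL]


def test_short_aberrant_run_below_min_markers_usually_absorbed():
    """A single-copy run shorter than min_markers is suppressed in the
    typical noise realization, while a run above the floor is found."""
    panel = _flat_panel(1000)
    absorbed_short = detected_long = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        noise = rng.normal(0, 0.1, 1000)
        short = noise.copy()
        short[400:430] += 0.58  # 30 probes < min_markers=50
        if all(s.state != GAIN for s in cd.segment_profile(short, panel).segments):
            absorbed_short += 1
        long = noise.copy()
        long[400:480] += 0.58  # 80 probes > min_markers
        if any(s.state == GAIN for s in cd.segment_profile(long, panel).segments):
            detected_long += 1
    assert absorbed_short >= 7
    assert detected_long >= 9


def test_min_marker_floor_respected_on_noisy_input():
    panel = _flat_panel(2000)
    rng = np.random.default_rng(5)
    x = rng.normal(0, 0.15, 2000)
    x[700:1100] += -1.0
    prof = cd.segment_profile(x, panel)
    assert all(s.n_markers >= 50 for s in prof.segments)


def test_tiny_chromosome_kept_as_single_segment(caplog):
    model = cd.GenomeModel(chromosomes=(("chrS", 60_000),), probe_spacing=1_000.0,
                           spacing_jitter=0.0)
    panel = cd.build_probe_panel(model, seed=0)  # 60 probes < 2*min_markers
    with caplog.at_level("WARNING"):
        prof = cd.segment_profile(np.zeros(60), panel)
    assert len(prof.segments) == 1


def test_profile_tiles_panel_without_overlap():
    panel = _flat_panel(1500)
    rng = np.random.default_rng(8)
    x = rng.normal(0, 0.1, 1500)
    x[200:600] += 0.58
    x[900:1300] += -1.0
    prof = cd.segment_profile(x, panel)
    assert sum(s.n_markers for s in prof.segments) == 1500
    for a, b in zip(prof.segments, prof.segments[1:]):
        assert a.end_bp <= b.start_bp


@pytest.mark.parametrize(
    "mean,sd,n,expected",
    [
        (0.0, 0.3, 100, NEUTRAL),
        (0.8, 0.1, 200, GAIN),
        (-0.02, 0.5, 60, NEUTRAL),
        (-0.7, 0.1, 200, LOSS),
        (0.4, 0.0, 50, GAIN),   # zero variance: state by sign
        (-0.4, 0.0, 50, LOSS),
    ],
)
def test_classify_state(mean, sd, n, expected):
    assert cd.classify_state(mean, sd, n, cd.SegParams()) == expected


def _seg(chrom, start, end, n, mean, state):
    return cd.Segment(chrom=chrom, start_bp=start, end_bp=end, n_markers=n,
                      mean_logratio=mean, state=state)


def test_merge_fuses_same_state_within_window():
    prof = cd.SegmentProfile("s", [
        _seg("chr1", 1_000_000, 2_000_000, 100, 0.5, GAIN),
        _seg("chr1", 2_500_000, 3_500_000, 100, 0.7, GAIN),
    ])
    merged = cd.merge_segments(prof, 1_000_000)
    assert len(merged.segments) == 1
    s = merged.segments[0]
    assert (s.start_bp, s.end_bp) == (1_000_000, 3_500_000)
    assert s.n_markers == 200
    assert s.mean_logratio == pytest.approx(0.6)


def test_merge_respects_window_and_state():
    far = cd.SegmentProfile("s", [
        _seg("chr1", 1_000_000, 2_000_000, 100, 0.5, GAIN),
        _seg("chr1", 3_500_000, 4_000_000, 60, 0.5, GAIN),  # gap 1.5 Mbp
    ])
    assert len(cd.merge_segments(far, 1_000_000).segments) == 2
    mixed = cd.SegmentProfile("s", [
        _seg("chr1", 1_000_000, 2_000_000, 100, 0.5, GAIN),
        _seg("chr1", 2_000_000, 3_000_000, 100, -0.8, LOSS),  # gap 0
    ])
    assert len(cd.merge_segments(mixed, 1_000_000).segments) == 2


def test_merge_drops_neutral_and_is_idempotent():
    prof = cd.SegmentProfile("s", [
        _seg("chr1", 0, 1_000_000, 100, 0.0, NEUTRAL),
        _seg("chr1", 1_000_000, 2_000_000, 100, 0.5, GAIN),
        _seg("chr1", 2_100_000, 2_600_000, 50, 0.5, GAIN),
        _seg("chr2", 0, 500_000, 50, -0.9, LOSS),
    ])
    once = cd.merge_segments(prof, 1_000_000)
    twice = cd.merge_segments(once, 1_000_000)
    assert once.segments == twice.segments
    assert all(s.state != NEUTRAL for s in once.segments)


@given(
    gap=st.integers(min_value=0, max_value=3_000_000),
    window=st.integers(min_value=0, max_value=2_000_000),
)
def test_merge_decision_matches_gap_window_rule(gap, window):
    prof = cd.SegmentProfile("s", [
        _seg("chr1", 0, 1_000_000, 100, 0.5, GAIN),
        _seg("chr1", 1_000_000 + gap, 2_000_000 + gap, 100, 0.5, GAIN),
    ])
    merged = cd.merge_segments(prof, window)
    assert len(merged.segments) == (1 if gap < window else 2)
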