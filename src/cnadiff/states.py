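"""Typed copy-number states, region collapsing, and frequency landscapes.

Segment calls are expanded to per-probe states (+1 gain, 0 neutral, -1
loss), stacked across samples, and collapsed into a breakpoint-delimited
region grid on which every sample is constant. Frequency tracks are moving
averages of per-probe alteration frequencies, and the functional resolution
is the typical genomic span of a minimum-marker probe window — the smallest
aberration the segmentation can report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import ProbePanel
from .segmentation import GAIN, LOSS, SegmentProfile

__all__ = [
    "StateVector",
    "RegionGrid",
    "StateMatrix",
    "FrequencyTrack",
    "to_state_vector",
    "collapse_regions",
    "frequency_track",
    "functional_resolution",
]

log = logging.getLogger(__name__)


@dataclass
class StateVector:
    sample_id: str
    states: np.ndarray  # int8, one entry per panel probe


@dataclass
class RegionGrid:
    """Breakpoint-delimited intervals tiling the panel."""

    chrom: np.ndarray  # per region
    start: np.ndarray  # bp, position of first probe
    end: np.ndarray  # bp, position of last probe + 1
    probe_lo: np.ndarray  # panel index range [lo, hi)
    probe_hi: np.ndarray

    def __len__(self) -> int:
        return len(self.chrom)

    @property
    def n_probes(self) -> np.ndarray:
        return self.probe_hi - self.probe_lo


@dataclass
class StateMatrix:
    """Region x sample matrix of typed states with group labels."""

    grid: RegionGrid
    states: np.ndarray  # (n_regions, n_samples) int8
    samples: list
    groups: np.ndarray  # per-sample group label

    @property
    def n_regions(self) -> int:
        return len(self.grid)

    def expand(self) -> np.ndarray:
        """Re-expand to the (n_probes, n_samples) probe-level state matrix."""
        total = int(self.grid.probe_hi[-1])
        out = np.zeros((total, self.states.shape[1]), dtype=np.int8)
        for i in range(len(self.grid)):
            out[self.grid.probe_lo[i]:self.grid.probe_hi[i], :] = self.states[i]
        return out


@dataclass
class FrequencyTrack:
    """Per-probe moving-average alteration frequencies."""

    window_probes: int
    gain: np.ndarray
    loss: np.ndarray
    any_alteration: np.ndarray


def to_state_vector(profile: SegmentProfile, panel: ProbePanel) -> StateVector:
    """Score every probe +1/0/-1 from the profile's aberrant segments.

    Segment intervals are half-open, so a probe sitting exactly at a
    segment's ``end_bp`` stays neutral. Overlapping opposite-state segments
    violate profile integrity and raise.
    """
    states = np.zeros(panel.n_probes, dtype=np.int8)
    for seg in profile.cna_segments():
        lo, hi = panel.probe_range(seg.chrom, seg.start_bp, seg.end_bp)
        val = 1 if seg.state == GAIN else -1
        existing = states[lo:hi]
        if np.any(existing == -val):
            raise ValueError(
                f"overlapping opposite-state segments in {profile.sample_id} on {seg.chrom}"
            )
        states[lo:hi] = val
    return StateVector(sample_id=profile.sample_id, states=states)


def collapse_regions(
    vectors: list[StateVector], panel: ProbePanel, groups=None
) -> StateMatrix:
    """Collapse probe-level states into cross-sample constant regions.

    Region boundaries are the union over samples of state change-points
    (plus chromosome starts); within any region every sample's state is
    constant by construction. Adjacent regions with identical state columns
    are fused.
    """
    if not vectors:
        raise ValueError("need at least one state vector")
    S = np.column_stack([v.states for v in vectors])
    if S.shape[0] != panel.n_probes:
        raise ValueError("state vectors must match panel size")
    samples = [v.sample_id for v in vectors]
    if groups is None:
        groups = np.array([""] * len(samples), dtype=object)
    groups = np.asarray(groups, dtype=object)

    is_boundary = np.zeros(panel.n_probes, dtype=bool)
    for name in panel.chrom_order:
        lo, hi = panel.chrom_ranges[name]
        is_boundary[lo] = True
        if hi - lo > 1:
            change = np.any(S[lo + 1:hi] != S[lo:hi - 1], axis=1)
            is_boundary[lo + 1:hi] = change
    starts = np.flatnonzero(is_boundary)
    ends = np.append(starts[1:], panel.n_probes)

    # fuse adjacent identical columns within a chromosome (no-op for
    # boundaries induced by actual change-points, but cheap to guarantee)
    keep_s, keep_e = [], []
    for s, e in zip(starts, ends):
        if (
            keep_s
            and panel.chrom[s] == panel.chrom[keep_s[-1]]
            and np.array_equal(S[s], S[keep_s[-1]])
        ):
            keep_e[-1] = e
        else:
            keep_s.append(int(s))
            keep_e.append(int(e))
    lo = np.array(keep_s)
    hi = np.array(keep_e)

    grid = RegionGrid(
        chrom=panel.chrom[lo].copy(),
        start=panel.pos[lo].copy(),
        end=panel.pos[hi - 1] + 1,
        probe_lo=lo,
        probe_hi=hi,
    )
    return StateMatrix(grid=grid, states=S[lo].copy(), samples=samples, groups=groups)


def frequency_track(
    vectors: list[StateVector], panel: ProbePanel, window: int = 500
) -> FrequencyTrack:
    """Moving-average gain/loss/any alteration frequencies per probe.

    The window is centered on each probe and truncated at chromosome ends;
    ``window=1`` returns the raw per-probe frequencies. Windows larger than
    a chromosome degrade to the whole-chromosome mean (logged).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    S = np.column_stack([v.states for v in vectors])
    raw = {
        "gain": (S == 1).mean(axis=1),
        "loss": (S == -1).mean(axis=1),
        "any": (S != 0).mean(axis=1),
    }
    out = {k: np.empty(panel.n_probes) for k in raw}
    for name in panel.chrom_order:
        clo, chi = panel.chrom_ranges[name]
        if window > chi - clo:
            log.warning(
                "window %d exceeds %s probe count %d; whole-chromosome mean used",
                window, name, chi - clo,
            )
        for k, v in raw.items():
            out[k][clo:chi] = (
                pd.Series(v[clo:chi])
                .rolling(window, center=True, min_periods=1)
                .mean()
                .to_numpy()
            )
    return FrequencyTrack(
        window_probes=window, gain=out["gain"], loss=out["loss"], any_alteration=out["any"]
    )


def functional_resolution(panel: ProbePanel, min_markers: int = 50) -> float:
    """Median genomic span of every ``min_markers``-probe window.

    Serves as the smallest reportable differential-region size: an
    aberration narrower than this typically cannot gather enough markers to
    form a segment.
    """
    spans = []
    for name in panel.chrom_order:
        p = panel.positions(name)
        if len(p) < min_markers:
            raise ValueError(f"chromosome {name!r} has fewer than {min_markers} probes")
        spans.append(p[min_markers - 1:] - p[: len(p) - min_markers + 1])
    return float(np.median(np.concatenate(spans)))
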