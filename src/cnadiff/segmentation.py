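"""Recursive binary segmentation of paired log2-ratio profiles.

Each chromosome's probe-level tumor/normal log-ratio vector is split
recursively: a candidate breakpoint is accepted only when a Welch two-sample
test between the flanking stretches is significant at ``p_break``, the
signal-to-noise ratio (|mean difference| / pooled within-segment SD) exceeds
``snr_threshold``, and both children keep at least ``min_markers`` probes.
Terminal segments are typed gain/neutral/loss by a one-sample test of the
segment mean against zero at ``p_dev``. Adjacent same-state aberrant
segments closer than ``merge_window_bp`` are then fused.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .panel import ProbePanel

__all__ = [
    "SegParams",
    "Segment",
    "SegmentProfile",
    "segment_profile",
    "classify_state",
    "merge_segments",
]

log = logging.getLogger(__name__)

GAIN, NEUTRAL, LOSS = "gain", "neutral", "loss"


@dataclass(frozen=True)
class SegParams:
    """Segmentation thresholds.

    Defaults are the stringent settings used for high-density SNP arrays:
    at least 50 markers per segment, signal-to-noise above 0.3, and 1e-7
    significance both for adjacent-segment differences and for deviation of
    a segment from the neutral baseline; same-state aberrant segments within
    1 Mbp are merged. ``min_markers`` may be lowered for sparser panels
    (e.g. 20 for older 250K-style arrays).
    """

    min_markers: int = 50
    snr_threshold: float = 0.3
    p_break: float = 1e-7
    p_dev: float = 1e-7
    merge_window_bp: int = 1_000_000

    def __post_init__(self):
        if self.min_markers < 2:
            raise ValueError("min_markers must be >= 2")
        for name in ("p_break", "p_dev"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1)")
        if self.snr_threshold < 0:
            raise ValueError("snr_threshold must be >= 0")
        if self.merge_window_bp < 0:
            raise ValueError("merge_window_bp must be >= 0")


@dataclass(frozen=True)
class Segment:
    """A contiguous constant-copy-number stretch, half-open in bp.

    ``start_bp`` is the position of the first probe and ``end_bp`` the
    position of the last probe + 1, so ``end_bp - start_bp`` is the segment
    size used in all reported tables.
    """

    chrom: str
    start_bp: int
    end_bp: int
    n_markers: int
    mean_logratio: float
    state: str = NEUTRAL

    def __post_init__(self):
        if self.end_bp <= self.start_bp:
            raise ValueError("segment end must exceed start")
        if self.state not in (GAIN, NEUTRAL, LOSS):
            raise ValueError(f"unknown state {self.state!r}")
        if self.state == GAIN and not self.mean_logratio > 0:
            raise ValueError("gain segment requires positive mean log-ratio")
        if self.state == LOSS and not self.mean_logratio < 0:
            raise ValueError("loss segment requires negative mean log-ratio")

    @property
    def size(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class SegmentProfile:
    """Ordered per-sample segment list.

    Straight out of :func:`segment_profile` the segments tile the probe
    panel; after :func:`merge_segments` only the aberrant (gain/loss)
    segments are kept, which is the CNA call set.
    """

    sample_id: str
    segments: list = field(default_factory=list)

    def cna_segments(self) -> list:
        return [s for s in self.segments if s.state != NEUTRAL]


def _welch_scan(x: np.ndarray, min_markers: int):
    """Best breakpoint of ``x`` with Welch-test evidence at that split.

    The candidate is chosen by the change-point likelihood criterion:
    the split ``x[:k] | x[k:]`` minimising the total within-segment sum of
    squares (leftmost on ties), which recovers noise-free step boundaries
    exactly. Returns ``(k, log_p, snr)`` where ``log_p`` is the two-sided
    Welch log p-value at that split and ``snr`` the |mean difference| over
    the pooled within-segment SD; None when no split leaves ``min_markers``
    probes on both sides. Zero-variance flanks with unequal means give
    log_p = -inf (the deterministic limit).
    """
    n = x.size
    if n < 2 * min_markers:
        return None
    cs = np.cumsum(x)
    cs2 = np.cumsum(x * x)
    k = np.arange(min_markers, n - min_markers + 1)
    n1 = k.astype(float)
    n2 = n - n1
    s1 = cs[k - 1]
    ss1 = cs2[k - 1]
    m1 = s1 / n1
    m2 = (cs[-1] - s1) / n2
    rss1 = np.maximum(ss1 - n1 * m1 * m1, 0.0)
    rss2 = np.maximum((cs2[-1] - ss1) - n2 * m2 * m2, 0.0)
    i = int(np.argmin(rss1 + rss2))  # argmin returns the leftmost minimum

    n1, n2, m1, m2 = n1[i], n2[i], m1[i], m2[i]
    v1 = rss1[i] / (n1 - 1)
    v2 = rss2[i] / (n2 - 1)
    d = m1 - m2
    # guard against float-roundoff "differences" within a constant stretch,
    # which would otherwise look infinitely significant (tiny d, zero var)
    if abs(d) <= 1e-12 + 1e-9 * max(abs(m1), abs(m2)):
        return int(k[i]), 0.0, 0.0
    se2 = v1 / n1 + v2 / n2
    pooled_var = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    if se2 == 0:
        logp = -np.inf if d != 0 else 0.0
    else:
        t = abs(d) / np.sqrt(se2)
        df = se2 * se2 / (v1 * v1 / (n1 * n1 * (n1 - 1)) + v2 * v2 / (n2 * n2 * (n2 - 1)))
        logp = float(np.log(2.0) + stats.t.logsf(t, df))
    if pooled_var == 0:
        snr = np.inf if abs(d) > 0 else 0.0
    else:
        snr = abs(d) / np.sqrt(pooled_var)
    return int(k[i]), logp, float(snr)


def _split_recursive(x: np.ndarray, lo: int, hi: int, params: SegParams, out: list):
    best = _welch_scan(x[lo:hi], params.min_markers)
    if best is not None:
        k, logp, snr = best
        if logp < np.log(params.p_break) and snr > params.snr_threshold:
            _split_recursive(x, lo, lo + k, params, out)
            _split_recursive(x, lo + k, hi, params, out)
            return
    out.append((lo, hi))


def classify_state(seg_mean: float, seg_sd: float, n_markers: int, params: SegParams) -> str:
    """Type a segment by a one-sample two-sided test of its mean against 0.

    Gain if p < ``p_dev`` and the mean is positive, loss if negative,
    neutral otherwise. A zero-variance segment with nonzero mean is typed
    by sign (the deterministic limit of the test).
    """
    if n_markers < 2:
        raise ValueError("classify_state requires n_markers >= 2")
    if seg_mean == 0:
        return NEUTRAL
    if seg_sd == 0:
        return GAIN if seg_mean > 0 else LOSS
    t = abs(seg_mean) / (seg_sd / np.sqrt(n_markers))
    logp = np.log(2.0) + stats.t.logsf(t, n_markers - 1)
    if logp < np.log(params.p_dev):
        return GAIN if seg_mean > 0 else LOSS
    return NEUTRAL


def segment_profile(
    logratios: Sequence[float],
    panel: ProbePanel,
    params: SegParams | None = None,
    sample_id: str = "sample",
) -> SegmentProfile:
    """Segment one per-probe log-ratio profile into typed segments.

    The result tiles the panel: one ordered, non-overlapping segment list
    per chromosome covering every probe. Chromosomes with fewer than
    ``2 * min_markers`` probes cannot be split and come back as a single
    segment (logged).
    """
    params = params or SegParams()
    x = np.asarray(logratios, dtype=float)
    if x.shape != (panel.n_probes,):
        raise ValueError("profile length must equal panel size")
    if not np.all(np.isfinite(x)):
        raise ValueError("profile contains non-finite values")

    segments: list[Segment] = []
    for name in panel.chrom_order:
        clo, chi = panel.chrom_ranges[name]
        if chi - clo < 2 * params.min_markers:
            log.warning(
                "chromosome %s has %d probes (< 2*min_markers=%d); kept as one segment",
                name, chi - clo, 2 * params.min_markers,
            )
            bounds = [(clo, chi)]
        else:
            bounds = []
            _split_recursive(x, clo, chi, params, bounds)
        for lo, hi in bounds:
            vals = x[lo:hi]
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1)) if hi - lo > 1 else 0.0
            state = classify_state(mean, sd, hi - lo, params) if hi - lo > 1 else NEUTRAL
            if state == GAIN and mean <= 0:  # pragma: no cover - classify guards sign
                state = NEUTRAL
            segments.append(
                Segment(
                    chrom=name,
                    start_bp=int(panel.pos[lo]),
                    end_bp=int(panel.pos[hi - 1]) + 1,
                    n_markers=hi - lo,
                    mean_logratio=mean,
                    state=state,
                )
            )
    return SegmentProfile(sample_id=sample_id, segments=segments)


def merge_segments(profile: SegmentProfile, window_bp: int = 1_000_000) -> SegmentProfile:
    """Fuse nearby same-state aberrant segments; drop neutral segments.

    Consecutive gain (or loss) segments on one chromosome whose gap is
    smaller than ``window_bp`` become a single segment spanning both, with
    marker counts summed and the mean re-weighted by markers. The returned
    profile contains only the aberrant segments (the CNA calls). The
    operation is idempotent.
    """
    cnas = profile.cna_segments()  # precondition: already in genome order
    merged: list[Segment] = []
    for seg in cnas:
        if merged:
            prev = merged[-1]
            gap = seg.start_bp - prev.end_bp
            if seg.chrom == prev.chrom and seg.state == prev.state and gap < window_bp:
                n = prev.n_markers + seg.n_markers
                mean = (
                    prev.mean_logratio * prev.n_markers + seg.mean_logratio * seg.n_markers
                ) / n
                merged[-1] = replace(
                    prev,
                    end_bp=max(prev.end_bp, seg.end_bp),
                    n_markers=n,
                    mean_logratio=mean,
                )
                continue
        merged.append(seg)
    return SegmentProfile(sample_id=profile.sample_id, segments=merged)
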