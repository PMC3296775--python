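"""Differentially altered regions and minimal common regions (MCRs).

Every collapsed region is tested with an exact 3x2 (gain/neutral/loss by
group) contingency test. Significant regions of the same copy-number status
within the merge window are fused, then frequency-gap and size filters are
applied. Differential regions from independent cohorts are intersected into
minimal common regions, and MCR co-occurrence within a cohort is measured
by Pearson correlation of per-sample carrier indicators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exact import fisher_exact_2x2, fisher_exact_3x2
from .panel import ProbePanel
from .segmentation import GAIN, LOSS
from .states import StateMatrix, StateVector

__all__ = [
    "DiffParams",
    "DifferentialRegion",
    "MCR",
    "call_differential_regions",
    "intersect_mcrs",
    "mcr_cooccurrence",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiffParams:
    """Filters for reporting a region as differentially altered.

    A region must test below ``alpha`` (raw, uncorrected), show at least
    ``min_freq_diff`` frequency gap between groups for its status type,
    reach ``min_freq_any`` in at least one group, and span at least
    ``min_size_bp`` (defaulting to a typical high-density array functional
    resolution; pass the panel's own resolution when available).
    """

    alpha: float = 0.05
    min_freq_diff: float = 0.15
    min_freq_any: float = 0.15
    merge_window_bp: int = 1_000_000
    min_size_bp: int = 139_000

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        for name in ("min_freq_diff", "min_freq_any"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.merge_window_bp < 0 or self.min_size_bp < 0:
            raise ValueError("window/size thresholds must be >= 0")


@dataclass
class DifferentialRegion:
    """A region whose alteration frequency differs between groups."""

    chrom: str
    start: int
    end: int
    etype: str  # gain | loss
    group: str  # enriched group
    freq_a: float  # status-type frequency in group A
    freq_b: float  # ... and in group B
    p: float
    dataset: str | None = None
    sources: list = field(default_factory=list)  # contributing (start, end, p)

    @property
    def size(self) -> int:
        return self.end - self.start

    @property
    def status(self) -> str:
        return f"{self.etype}_{self.group}"


@dataclass
class MCR:
    """Intersection of same-status differential regions across datasets."""

    chrom: str
    start: int
    end: int
    etype: str
    group: str
    sources: dict = field(default_factory=dict)  # dataset -> list of regions

    @property
    def size(self) -> int:
        return self.end - self.start

    @property
    def status(self) -> str:
        return f"{self.etype}_{self.group}"


def _region_counts(col: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> tuple:
    a, b = col[idx_a], col[idx_b]
    return (
        (int((a == 1).sum()), int((b == 1).sum())),
        (int((a == 0).sum()), int((b == 0).sum())),
        (int((a == -1).sum()), int((b == -1).sum())),
    )


def call_differential_regions(
    matrix: StateMatrix,
    params: DiffParams | None = None,
    group_order: Sequence[str] | None = None,
    dataset: str | None = None,
) -> list[DifferentialRegion]:
    """Test every region, merge significant same-status neighbours, filter.

    Per region a 3x2 gain/neutral/loss by group table is tested exactly;
    regions with p < alpha get a status (the alteration type with the
    larger between-group frequency gap, enriched in the group with the
    higher frequency). Significant same-status regions on one chromosome
    separated by less than the merge window are fused: the merged p is the
    minimum of the contributors and the reported frequencies are the
    minima observed among contributors. Frequency-gap, minimum-frequency
    and size filters are applied after merging.
    """
    params = params or DiffParams()
    labels = np.asarray(matrix.groups, dtype=object)
    uniq = sorted(set(labels))
    if group_order is not None:
        uniq = list(group_order)
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {uniq}")
    ga, gb = uniq
    idx_a = np.flatnonzero(labels == ga)
    idx_b = np.flatnonzero(labels == gb)
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("need >= 2 samples per group")
    na, nb = len(idx_a), len(idx_b)

    significant: list[DifferentialRegion] = []
    for i in range(matrix.n_regions):
        counts = _region_counts(matrix.states[i], idx_a, idx_b)
        tab = np.array(counts, dtype=np.int64)
        if np.all(tab[0] == 0) and np.all(tab[2] == 0):
            continue  # fully neutral region
        p = fisher_exact_3x2(tab)
        if p >= params.alpha:
            continue
        fga, fgb = tab[0, 0] / na, tab[0, 1] / nb
        fla, flb = tab[2, 0] / na, tab[2, 1] / nb
        d_gain, d_loss = abs(fga - fgb), abs(fla - flb)
        if d_gain == 0 and d_loss == 0:
            continue
        if d_gain > d_loss:
            etype = GAIN
        elif d_loss > d_gain:
            etype = LOSS
        else:
            # tie: prefer the alteration type with the smaller 2x2 p
            p_gain = fisher_exact_2x2([[tab[0, 0], tab[0, 1]], [na - tab[0, 0], nb - tab[0, 1]]])
            p_loss = fisher_exact_2x2([[tab[2, 0], tab[2, 1]], [na - tab[2, 0], nb - tab[2, 1]]])
            etype = GAIN if p_gain <= p_loss else LOSS
            log.info(
                "gain/loss frequency-gap tie at %s:%d-%d resolved to %s",
                matrix.grid.chrom[i], matrix.grid.start[i], matrix.grid.end[i], etype,
            )
        fa, fb = (fga, fgb) if etype == GAIN else (fla, flb)
        group = ga if fa > fb else gb
        significant.append(
            DifferentialRegion(
                chrom=matrix.grid.chrom[i],
                start=int(matrix.grid.start[i]),
                end=int(matrix.grid.end[i]),
                etype=etype,
                group=group,
                freq_a=fa,
                freq_b=fb,
                p=p,
                dataset=dataset,
                sources=[(int(matrix.grid.start[i]), int(matrix.grid.end[i]), p)],
            )
        )

    # merge same-status neighbours (input is in genome order already)
    merged: list[DifferentialRegion] = []
    for reg in significant:
        if merged:
            prev = merged[-1]
            if (
                reg.chrom == prev.chrom
                and reg.status == prev.status
                and reg.start - prev.end < params.merge_window_bp
            ):
                prev.end = max(prev.end, reg.end)
                prev.freq_a = min(prev.freq_a, reg.freq_a)
                prev.freq_b = min(prev.freq_b, reg.freq_b)
                prev.p = min(prev.p, reg.p)
                prev.sources.extend(reg.sources)
                continue
        merged.append(reg)

    out = [
        r for r in merged
        if abs(r.freq_a - r.freq_b) >= params.min_freq_diff
        and max(r.freq_a, r.freq_b) >= params.min_freq_any
        and r.size >= params.min_size_bp
    ]
    log.info(
        "differential regions: %d tested, %d significant, %d after merge, %d reported",
        matrix.n_regions, len(significant), len(merged), len(out),
    )
    return out


def intersect_mcrs(
    datasets: Mapping[str, Sequence[DifferentialRegion]],
    require_all: bool = True,
    min_datasets: int = 2,
) -> list[MCR]:
    """Intersect same-status differential regions across datasets.

    With ``require_all=True`` an MCR is emitted only where every dataset
    contributes an overlapping region of the same status; otherwise any
    stretch covered by at least ``min_datasets`` datasets qualifies. The
    MCR interval is the intersection of its contributors over that stretch,
    so it is never larger than any contributing region.
    """
    names = list(datasets.keys())
    if len(names) < 2:
        raise ValueError("need at least two datasets")
    need = len(names) if require_all else min_datasets

    by_status: dict[tuple, dict[str, list]] = {}
    for ds in names:
        for r in datasets[ds]:
            key = (r.chrom, r.etype, r.group)
            by_status.setdefault(key, {}).setdefault(ds, []).append(r)

    mcrs: list[MCR] = []
    for (chrom, etype, group), per_ds in sorted(
        by_status.items(), key=lambda kv: (str(kv[0][0]), kv[0][1], kv[0][2])
    ):
        edges = sorted(
            {r.start for rs in per_ds.values() for r in rs}
            | {r.end for rs in per_ds.values() for r in rs}
        )
        # runs are keyed on the exact set of covering regions, so every run
        # lies inside each of its contributors (MCR <= every source region)
        runs: list[tuple[int, int, frozenset]] = []
        for s, e in zip(edges, edges[1:]):
            covering = frozenset(
                (ds, i)
                for ds, rs in per_ds.items()
                for i, r in enumerate(rs)
                if r.start <= s and e <= r.end
            )
            if len({ds for ds, _ in covering}) >= need:
                if runs and runs[-1][1] == s and runs[-1][2] == covering:
                    runs[-1] = (runs[-1][0], e, covering)
                else:
                    runs.append((s, e, covering))
        for s, e, covering in runs:
            sources: dict[str, list] = {}
            for ds, i in sorted(covering):
                sources.setdefault(ds, []).append(per_ds[ds][i])
            mcrs.append(MCR(chrom=chrom, start=s, end=e, etype=etype, group=group, sources=sources))
    mcrs.sort(key=lambda m: (str(m.chrom), m.start))
    return mcrs


def mcr_cooccurrence(
    mcrs: Sequence[MCR],
    vectors: Sequence[StateVector],
    panel: ProbePanel,
    rule: str = "strict",
) -> pd.DataFrame:
    """Pearson correlation matrix of per-sample MCR carrier indicators.

    A sample carries an MCR when all (``rule='strict'``, default — MCRs are
    short) or most (``rule='majority'``) probes inside the MCR show the
    MCR's alteration state. Zero-variance carrier vectors yield undefined
    correlations, reported as NaN.
    """
    if len(mcrs) < 2:
        raise ValueError("need at least two MCRs")
    if rule not in ("strict", "majority"):
        raise ValueError("rule must be 'strict' or 'majority'")
    S = np.column_stack([v.states for v in vectors])
    labels = [f"{m.chrom}:{m.start}-{m.end}:{m.status}" for m in mcrs]
    carriers = np.zeros((len(mcrs), S.shape[1]), dtype=float)
    for i, m in enumerate(mcrs):
        lo, hi = panel.probe_range(m.chrom, m.start, m.end)
        if hi <= lo:
            raise ValueError(f"MCR {labels[i]} contains no probes")
        want = 1 if m.etype == GAIN else -1
        hits = (S[lo:hi] == want)
        carriers[i] = hits.all(axis=0) if rule == "strict" else hits.mean(axis=0) > 0.5
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(carriers)
    for i in range(len(mcrs)):
        if carriers[i].std() == 0:
            log.warning("MCR %s has a constant carrier vector; correlations undefined", labels[i])
    corr = np.asarray(corr, dtype=float)
    np.fill_diagonal(corr, np.where(np.std(carriers, axis=1) > 0, 1.0, np.nan))
    return pd.DataFrame(corr, index=labels, columns=labels)


def region_overlaps(region: DifferentialRegion, chrom: str, start: int, end: int) -> bool:
    """True when the region overlaps the half-open query interval."""
    return region.chrom == chrom and region.start < end and start < region.end
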