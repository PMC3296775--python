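"""Genome model and probe panels.

A :class:`ProbePanel` is the ordered genomic coordinate lattice shared by
every per-sample profile: a sorted list of (chromosome, position) probes,
emulating a high-density SNP array map. All downstream containers (state
vectors, region grids, frequency tracks) are indexed against one panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["GenomeModel", "ProbePanel", "build_probe_panel", "DEFAULT_GENOME"]


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome sizes plus probe-density parameters.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    probe_spacing
        Mean inter-probe distance in bp.
    spacing_jitter
        Fraction of the spacing used as uniform positional jitter
        (half-width ``spacing_jitter * probe_spacing / 2``); must be < 1 so
        probe positions stay strictly increasing.
    """

    chromosomes: tuple
    probe_spacing: float = 10_000.0
    spacing_jitter: float = 0.2

    def __post_init__(self):
        if not self.chromosomes:
            raise ValueError("genome model needs at least one chromosome")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        if self.probe_spacing <= 0:
            raise ValueError("probe_spacing must be > 0")
        if not (0.0 <= self.spacing_jitter < 1.0):
            raise ValueError("spacing_jitter must be in [0, 1)")

    @property
    def total_bp(self) -> int:
        return int(sum(length for _, length in self.chromosomes))


#: Scaled-down multi-chromosome genome used as the default simulation lattice.
DEFAULT_GENOME = GenomeModel(
    chromosomes=(
        ("chr1", 30_000_000),
        ("chr2", 30_000_000),
        ("chr3", 30_000_000),
        ("chr4", 30_000_000),
    ),
    probe_spacing=10_000.0,
    spacing_jitter=0.2,
)


class ProbePanel:
    """Ordered genomic probe map.

    Probes are sorted by (chromosome order, position) and positions are
    strictly increasing within each chromosome.
    """

    def __init__(self, chrom: Sequence[str], pos: Sequence[int], probe_id: Sequence[str] | None = None):
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        if self.chrom.shape != self.pos.shape:
            raise ValueError("chrom and pos must have equal length")
        if probe_id is None:
            probe_id = np.array([f"p{i}" for i in range(len(self.pos))], dtype=object)
        self.probe_id = np.asarray(probe_id, dtype=object)

        # per-chromosome contiguous index ranges, in order of first appearance
        order: list[str] = []
        ranges: dict[str, tuple[int, int]] = {}
        i = 0
        n = len(self.chrom)
        while i < n:
            name = self.chrom[i]
            j = i
            while j < n and self.chrom[j] == name:
                j += 1
            if name in ranges:
                raise ValueError(f"chromosome {name!r} appears in non-contiguous blocks")
            order.append(name)
            ranges[name] = (i, j)
            p = self.pos[i:j]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions on {name!r} not strictly increasing")
            i = j
        self.chrom_order: list[str] = order
        self.chrom_ranges: dict[str, tuple[int, int]] = ranges

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def n_probes(self) -> int:
        return len(self.pos)

    def chrom_slice(self, name: str) -> slice:
        lo, hi = self.chrom_ranges[name]
        return slice(lo, hi)

    def positions(self, name: str) -> np.ndarray:
        return self.pos[self.chrom_slice(name)]

    @property
    def covered_bp(self) -> int:
        """Sum over chromosomes of (last probe pos - first probe pos + 1).

        This is the span the array actually observes and the default
        denominator of proportion-of-genome-altered.
        """
        total = 0
        for name in self.chrom_order:
            p = self.positions(name)
            total += int(p[-1] - p[0] + 1)
        return total

    def probe_range(self, chrom: str, start_bp: int, end_bp: int) -> tuple[int, int]:
        """Panel index range [lo, hi) of probes with start_bp <= pos < end_bp."""
        clo, chi = self.chrom_ranges[chrom]
        p = self.pos[clo:chi]
        lo = int(np.searchsorted(p, start_bp, side="left"))
        hi = int(np.searchsorted(p, end_bp, side="left"))
        return clo + lo, clo + hi

    def __eq__(self, other) -> bool:
        if not isinstance(other, ProbePanel):
            return NotImplemented
        return (
            np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.probe_id, other.probe_id)
        )


def build_probe_panel(model: GenomeModel, seed: int = 0) -> ProbePanel:
    """Lay probes along the genome at the model's spacing with uniform jitter.

    Deterministic for a fixed seed. With zero jitter and spacing ``s`` a
    chromosome of length ``L`` gets probes at ``s, 2s, ..., floor(L/s)*s``.
    """
    rng = np.random.default_rng(seed)
    chroms: list[str] = []
    positions: list[np.ndarray] = []
    s = model.probe_spacing
    for name, length in model.chromosomes:
        k = int(np.floor(length / s))
        if k < 1:
            raise ValueError(f"chromosome {name!r} shorter than probe spacing")
        base = s * np.arange(1, k + 1, dtype=float)
        if model.spacing_jitter > 0:
            half = model.spacing_jitter * s / 2.0
            base = base + rng.uniform(-half, half, size=k)
        pos = np.clip(np.round(base), 1, length).astype(np.int64)
        # jitter half-width < s/2 guarantees strict increase before rounding;
        # rounding with s >= 2 keeps it strict as well
        if np.any(np.diff(pos) <= 0):  # pragma: no cover - guarded by model invariants
            raise AssertionError("generated probe positions not strictly increasing")
        chroms.append(np.full(k, name, dtype=object))
        positions.append(pos)
    return ProbePanel(np.concatenate(chroms), np.concatenate(positions))
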