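"""Model/results front end for the two-group copy-number comparison.

:class:`CNAComparison` is constructed from probe-level log-ratio profiles
(or pre-computed segment profiles), a probe panel, and a per-sample
annotation table carrying the grouping variable. ``fit()`` runs the whole
comparison — segmentation, merging, typed states, proportion of genome
altered, Welch group tests, sequential ANOVA, and differential-region
calling — and returns a :class:`CNAComparisonResults` with a ``summary()``
table, exports, and plotting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import ProbePanel
from .pga import ANOVA_FACTOR_ORDER, GroupComparison, compare_pga, compute_pga, multifactor_anova
from .regions import DiffParams, call_differential_regions
from .segmentation import SegParams, SegmentProfile, merge_segments, segment_profile
from .states import (
    StateMatrix,
    collapse_regions,
    frequency_track,
    functional_resolution,
    to_state_vector,
)

__all__ = ["CNAComparison", "CNAComparisonResults"]

log = logging.getLogger(__name__)


class CNAComparison:
    """Two-group comparative CNA model.

    Parameters
    ----------
    profiles
        Probe x sample log-ratio matrix (columns are sample ids), or None
        when ``segments`` are supplied directly.
    panel
        The probe panel the profiles live on.
    annotations
        Per-sample table with a ``sample_id`` column and the grouping
        variable (plus any covariates for the ANOVA).
    group
        Annotation column that defines the two cohorts.
    """

    def __init__(
        self,
        profiles: pd.DataFrame | None,
        panel: ProbePanel,
        annotations: pd.DataFrame,
        group: str = "group",
        seg_params: SegParams | None = None,
        diff_params: DiffParams | None = None,
        segments: list[SegmentProfile] | None = None,
    ):
        if profiles is None and segments is None:
            raise ValueError("provide probe profiles or segment profiles")
        self.profiles = profiles
        self.panel = panel
        self.annotations = annotations.set_index("sample_id", drop=False)
        self.group = group
        if group not in annotations.columns:
            raise ValueError(f"grouping column {group!r} missing from annotations")
        self.seg_params = seg_params or SegParams()
        self.diff_params = diff_params
        self._segments = segments
        sample_ids = list(profiles.columns) if profiles is not None else [s.sample_id for s in segments]
        missing = [s for s in sample_ids if s not in self.annotations.index]
        if missing:
            raise ValueError(f"annotations missing samples: {missing[:5]}")
        self.sample_ids = sample_ids

    @classmethod
    def from_cohort(cls, cohort, **kwargs) -> "CNAComparison":
        """Build directly from a :class:`~cnadiff.simulate.SimulatedCohort`."""
        return cls(cohort.profiles, cohort.panel, cohort.annotations, **kwargs)

    def fit(self, trim="group", anova_factors=None) -> "CNAComparisonResults":
        """Run the full comparison and return the results object."""
        if self.diff_params is None:
            min_size = functional_resolution(self.panel, self.seg_params.min_markers)
            diff_params = DiffParams(min_size_bp=int(min_size))
        else:
            diff_params = self.diff_params

        if self._segments is not None:
            raw = self._segments
        else:
            raw = [
                segment_profile(self.profiles[sid].to_numpy(), self.panel, self.seg_params, sid)
                for sid in self.sample_ids
            ]
        merged = [merge_segments(p, self.seg_params.merge_window_bp) for p in raw]

        pga_rows = [compute_pga(p, self.panel) for p in merged]
        pga = pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in pga_rows],
                "pga_gain": [r.pga_gain for r in pga_rows],
                "pga_loss": [r.pga_loss for r in pga_rows],
                "pga_all": [r.pga_all for r in pga_rows],
            }
        ).set_index("sample_id")

        groups = self.annotations.loc[self.sample_ids, self.group].to_numpy(object)
        levels = sorted(set(groups))
        if len(levels) != 2:
            raise ValueError(f"grouping column must have exactly two levels, got {levels}")
        ga, gb = levels
        mask_a = groups == ga
        comparisons = {}
        for kind in ("pga_gain", "pga_loss", "pga_all"):
            comparisons[kind] = compare_pga(pga.loc[mask_a, kind], pga.loc[~mask_a, kind], trim=trim)

        vectors = [to_state_vector(p, self.panel) for p in merged]
        matrix = collapse_regions(vectors, self.panel, groups)
        regions = call_differential_regions(matrix, diff_params, group_order=levels)

        tracks = {
            ga: frequency_track([v for v, m in zip(vectors, mask_a) if m], self.panel),
            gb: frequency_track([v for v, m in zip(vectors, mask_a) if not m], self.panel),
        }

        anova = None
        factors = list(anova_factors) if anova_factors is not None else None
        if factors is None:
            factors = []
            for c in ANOVA_FACTOR_ORDER:
                name = self.group if c == "group" else c
                if (
                    name in self.annotations.columns
                    and name not in factors
                    and (name == self.group or self.annotations[name].nunique() > 1)
                ):
                    factors.append(name)
        if factors:
            try:
                anova = multifactor_anova(
                    pga["pga_all"].to_numpy(),
                    self.annotations.loc[self.sample_ids, factors],
                    order=factors,
                )
            except ValueError as exc:
                log.warning("ANOVA skipped: %s", exc)

        return CNAComparisonResults(
            model=self,
            group_levels=(ga, gb),
            segments=merged,
            vectors=vectors,
            pga=pga,
            comparisons=comparisons,
            state_matrix=matrix,
            differential_regions=regions,
            frequency_tracks=tracks,
            anova=anova,
            diff_params=diff_params,
        )


@dataclass
class CNAComparisonResults:
    """Fitted comparison: per-sample estimates, tests, and regions."""

    model: CNAComparison
    group_levels: tuple
    segments: list
    vectors: list
    pga: pd.DataFrame
    comparisons: dict
    state_matrix: StateMatrix
    differential_regions: list
    frequency_tracks: dict
    anova: pd.DataFrame | None
    diff_params: DiffParams

    def pga_table(self) -> pd.DataFrame:
        """Average/median/range of each PGA type per group."""
        ga, gb = self.group_levels
        rows = []
        for kind, comp in self.comparisons.items():
            rows.append(
                dict(pga_type=kind,
                     **{f"mean_{ga}": comp.mean_a, f"mean_{gb}": comp.mean_b,
                        f"median_{ga}": comp.median_a, f"median_{gb}": comp.median_b,
                        f"range_{ga}": comp.range_a, f"range_{gb}": comp.range_b,
                        "t": comp.t, "df": comp.df, "p": comp.p})
            )
        return pd.DataFrame(rows).set_index("pga_type")

    def summary(self) -> str:
        ga, gb = self.group_levels
        lines = [
            "Two-group copy-number comparison",
            "=" * 48,
            f"groups: {ga} (n={int((self.state_matrix.groups == ga).sum())}) vs "
            f"{gb} (n={int((self.state_matrix.groups == gb).sum())})",
            f"panel: {self.model.panel.n_probes} probes, "
            f"{self.model.panel.covered_bp / 1e6:.1f} Mbp covered",
            "",
            "Proportion of genome altered (Welch t-test, trimmed):",
        ]
        for kind, comp in self.comparisons.items():
            lines.append(
                f"  {kind:<9} {ga} {comp.mean_a:.3f}  {gb} {comp.mean_b:.3f}  "
                f"t={comp.t:+.2f} df={comp.df:.1f} p={comp.p:.3g}"
            )
        lines += [
            "",
            f"collapsed regions tested: {self.state_matrix.n_regions}",
            f"differential regions reported: {len(self.differential_regions)} "
            f"(alpha={self.diff_params.alpha}, freq gap >= {self.diff_params.min_freq_diff}, "
            f"size >= {self.diff_params.min_size_bp / 1e3:.0f} kbp)",
        ]
        for r in self.differential_regions[:10]:
            lines.append(
                f"  {r.chrom}:{r.start}-{r.end} {r.status} "
                f"freq {r.freq_a:.2f}/{r.freq_b:.2f} p={r.p:.2g}"
            )
        if self.anova is not None:
            lines += ["", "Sequential ANOVA of PGA (type I):", self.anova.to_string()]
        return "\n".join(lines)

    def plot_frequency(self, ax=None):
        """Plot per-group gain/loss frequency landscapes along the panel."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        x = np.arange(self.model.panel.n_probes)
        colors = {self.group_levels[0]: "tab:red", self.group_levels[1]: "tab:blue"}
        for g, track in self.frequency_tracks.items():
            ax.plot(x, track.gain, color=colors.get(g), lw=0.8, label=f"{g} gain")
            ax.plot(x, -track.loss, color=colors.get(g), lw=0.8, ls="--", label=f"{g} loss")
        for name in self.model.panel.chrom_order[1:]:
            ax.axvline(self.model.panel.chrom_ranges[name][0], color="grey", lw=0.5)
        ax.set_xlabel("probe index")
        ax.set_ylabel("frequency (gain up / loss down)")
        ax.legend(fontsize=7, ncol=2)
        return ax
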