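"""Configurable multi-stage pipeline with a reproducibility manifest.

Stages: ``simulate`` (synthetic cohorts), ``segment``, ``states``, ``pga``,
``diff``, ``mcr``, ``stats``. Each stage reads its inputs from the config
or from the previous stage's outputs in the run directory, writes
tab-delimited outputs, and records record counts in the manifest so the
effect of every filter is auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as cio
from .associations import association_matrix, association_screen
from .model import CNAComparison
from .panel import DEFAULT_GENOME, GenomeModel, build_probe_panel
from .regions import DiffParams, intersect_mcrs, mcr_cooccurrence
from .segmentation import SegParams
from .simulate import InjectedEvent, default_cohort_spec, simulate_cohort
from .states import functional_resolution

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "ALL_STAGES"]

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "segment", "states", "pga", "diff", "mcr", "stats")
VERSION = "0.1.0"


class DependencyError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Paths, parameters and seed for one pipeline run."""

    outdir: str = "cnadiff_run"
    seed: int = 0
    n_datasets: int = 2  # simulated cohorts (>= 2 lets the mcr stage run)
    profiles: str | None = None  # external probe-level matrix (TSV)
    seg: str | None = None  # external pre-segmented calls (SEG)
    annotations: str | None = None
    mcr_inputs: tuple = ()  # extra region BEDs to intersect
    group: str = "group"
    trim_pga: bool = True
    min_markers: int = 50
    snr_threshold: float = 0.3
    p_break: float = 1e-7
    p_dev: float = 1e-7
    merge_window_bp: int = 1_000_000
    alpha: float = 0.05
    min_freq_diff: float = 0.15
    min_freq_any: float = 0.15
    min_size_bp: int | None = None  # None -> panel functional resolution
    injected_events: tuple = ()  # dicts accepted from YAML
    association_pairs: tuple = (
        ("egfr", "group"), ("kras", "group"), ("race", "group"),
        ("egfr", "race"), ("kras", "race"), ("egfr", "kras"),
    )

    def seg_params(self) -> SegParams:
        return SegParams(
            min_markers=self.min_markers, snr_threshold=self.snr_threshold,
            p_break=self.p_break, p_dev=self.p_dev, merge_window_bp=self.merge_window_bp,
        )

    def diff_params(self, min_size_bp: int) -> DiffParams:
        return DiffParams(
            alpha=self.alpha, min_freq_diff=self.min_freq_diff,
            min_freq_any=self.min_freq_any, merge_window_bp=self.merge_window_bp,
            min_size_bp=self.min_size_bp if self.min_size_bp is not None else min_size_bp,
        )

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def canonical(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=str)


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    input_checksums: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    timestamp: str = ""

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _events_from_config(cfg: PipelineConfig):
    events = []
    for ev in cfg.injected_events:
        if isinstance(ev, InjectedEvent):
            events.append(ev)
        else:
            events.append(InjectedEvent(**ev))
    return events


def run_pipeline(config: PipelineConfig, stages=None) -> RunManifest:
    """Execute the requested stages in dependency order.

    Outputs land under ``config.outdir`` (per-dataset subdirectories
    ``ds0``, ``ds1``, ...). A missing upstream output raises a
    :class:`DependencyError` naming the stage that needs it.
    """
    stages = list(stages) if stages else list(ALL_STAGES)
    order = [s for s in ALL_STAGES if s in stages]
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest = RunManifest(
        version=VERSION,
        config_hash=hashlib.sha256(config.canonical().encode()).hexdigest(),
        seed=config.seed,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    for p in filter(None, [config.profiles, config.seg, config.annotations]):
        manifest.input_checksums[str(p)] = _sha256(p)

    seg_params = config.seg_params()
    datasets: dict[str, dict] = {}

    def _dataset_dirs():
        if config.profiles or config.seg:
            return [outdir / "ds0"]
        return [outdir / f"ds{d}" for d in range(config.n_datasets)]

    # ---- simulate -------------------------------------------------------
    if "simulate" in order:
        events = _events_from_config(config)
        panel = build_probe_panel(DEFAULT_GENOME, seed=config.seed)
        count = 0
        for d in range(config.n_datasets):
            ds_dir = outdir / f"ds{d}"
            ds_dir.mkdir(exist_ok=True)
            spec = default_cohort_spec(events=events, seed=config.seed + d)
            cohort = simulate_cohort(spec, panel)
            cio.write_profiles(panel, cohort.profiles, ds_dir / "profiles.tsv")
            cio.write_seg(cohort.truth_profiles(), ds_dir / "truth.seg")
            cio.write_annotations(cohort.annotations, ds_dir / "annotations.tsv")
            datasets[f"ds{d}"] = dict(panel=panel, profiles=cohort.profiles,
                                      annotations=cohort.annotations)
            count += len(cohort.sample_ids)
        manifest.stage_counts["simulate"] = count

    def _load_dataset(ds_dir: Path, stage: str) -> dict:
        name = ds_dir.name
        if name in datasets:
            return datasets[name]
        entry: dict = {}
        if config.profiles and name == "ds0":
            entry["panel"], entry["profiles"] = cio.read_profiles(config.profiles)
        elif (ds_dir / "profiles.tsv").exists():
            entry["panel"], entry["profiles"] = cio.read_profiles(ds_dir / "profiles.tsv")
        elif config.seg and name == "ds0":
            entry["segments"] = cio.read_seg(config.seg)
        else:
            raise DependencyError(f"stage {stage!r}: no profiles for {name}; run 'simulate' first")
        if config.annotations and name == "ds0":
            entry["annotations"] = cio.read_annotations(config.annotations)
        elif (ds_dir / "annotations.tsv").exists():
            entry["annotations"] = cio.read_annotations(ds_dir / "annotations.tsv")
        else:
            raise DependencyError(f"stage {stage!r}: no annotations for {name}")
        datasets[name] = entry
        return entry

    def _fit(ds_dir: Path, stage: str):
        entry = _load_dataset(ds_dir, stage)
        if "fit" not in entry:
            model = CNAComparison(
                entry.get("profiles"),
                entry.get("panel") or _panel_from_segments(entry),
                entry["annotations"],
                group=config.group,
                seg_params=seg_params,
                diff_params=(
                    config.diff_params(config.min_size_bp)
                    if config.min_size_bp is not None else None
                ),
                segments=entry.get("segments"),
            )
            entry["fit"] = model.fit(trim=config.trim_pga)
        return entry["fit"]

    def _panel_from_segments(entry):
        raise DependencyError("SEG-only input requires a probe panel via 'profiles'")

    # ---- per-dataset stages --------------------------------------------
    for stage in ("segment", "states", "pga", "diff"):
        if stage not in order:
            continue
        count = 0
        for ds_dir in _dataset_dirs():
            ds_dir.mkdir(parents=True, exist_ok=True)
            res = _fit(ds_dir, stage)
            if stage == "segment":
                cio.write_seg(res.segments, ds_dir / "segments.seg")
                count += sum(len(p.segments) for p in res.segments)
            elif stage == "states":
                cio.write_state_matrix(res.state_matrix, ds_dir / "state_matrix.tsv")
                for g, track in res.frequency_tracks.items():
                    cio.write_frequency_track(track, res.model.panel, ds_dir / f"freq_{g}.tsv")
                count += res.state_matrix.n_regions
            elif stage == "pga":
                res.pga.to_csv(ds_dir / "pga.tsv", sep="\t")
                res.pga_table().to_csv(ds_dir / "pga_comparison.tsv", sep="\t")
                if res.anova is not None:
                    res.anova.to_csv(ds_dir / "anova.tsv", sep="\t")
                count += len(res.pga)
            elif stage == "diff":
                cio.write_bed(res.differential_regions, ds_dir / "diff_regions.bed")
                cio.write_regions_table(res.differential_regions, ds_dir / "diff_regions.tsv")
                count += len(res.differential_regions)
        manifest.stage_counts[stage] = count

    # ---- mcr ------------------------------------------------------------
    if "mcr" in order:
        region_sets: dict[str, list] = {}
        for ds_dir in _dataset_dirs():
            name = ds_dir.name
            if name in datasets and "fit" in datasets[name]:
                region_sets[name] = datasets[name]["fit"].differential_regions
            elif (ds_dir / "diff_regions.bed").exists():
                region_sets[name] = cio.read_bed(ds_dir / "diff_regions.bed")
            else:
                raise DependencyError(f"stage 'mcr': missing differential regions for {name}; run 'diff'")
        for i, path in enumerate(config.mcr_inputs):
            region_sets[f"external{i}"] = cio.read_bed(path)
            manifest.input_checksums[str(path)] = _sha256(path)
        if len(region_sets) < 2:
            raise DependencyError("stage 'mcr': need >= 2 region sets (datasets or mcr_inputs)")
        mcrs = intersect_mcrs(region_sets, require_all=True)
        cio.write_bed(mcrs, outdir / "mcrs.bed")
        cio.write_regions_table(mcrs, outdir / "mcrs.tsv")
        first = _dataset_dirs()[0].name
        if len(mcrs) >= 2 and first in datasets and "fit" in datasets[first]:
            fit = datasets[first]["fit"]
            try:
                corr = mcr_cooccurrence(mcrs, fit.vectors, fit.model.panel)
                corr.to_csv(outdir / "mcr_cooccurrence.tsv", sep="\t")
            except (ValueError, KeyError) as exc:
                log.warning("MCR co-occurrence skipped: %s", exc)
                manifest.warnings.append(f"mcr co-occurrence skipped: {exc}")
        manifest.stage_counts["mcr"] = len(mcrs)

    # ---- stats ----------------------------------------------------------
    if "stats" in order:
        ds_dir = _dataset_dirs()[0]
        entry = _load_dataset(ds_dir, "stats")
        pairs = [tuple(p) for p in config.association_pairs]
        results = association_screen(entry["annotations"], pairs,
                                     positive_levels={config.group: {"smoker", "current"}})
        rows = pd.DataFrame(
            [dict(var_x=r.var_x, var_y=r.var_y, n=r.n, p=r.p, phi=r.phi) for r in results]
        )
        rows.to_csv(outdir / "associations.tsv", sep="\t", index=False)
        association_matrix(results).to_csv(outdir / "association_matrix.tsv", sep="\t")
        manifest.stage_counts["stats"] = len(results)

    manifest.write(outdir / "manifest.json")
    return manifest
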