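"""Synthetic paired tumor/normal log-ratio cohorts with known CNA truth.

Two patient groups (by default 30 never smokers and 39 current smokers,
matching a realistic two-arm adenocarcinoma cohort) are simulated on a
shared probe panel. Each sample carries:

* *injected events* — segmental gains/losses with group-specific carrier
  frequencies, used to plant differentially altered regions with a known
  frequency gap;
* *background events* — a Poisson number of random gains/losses per genome,
  uniformly placed with log-uniform lengths, identical in distribution for
  both groups (these set the baseline genome-altered fraction);
* per-probe Gaussian noise on the log-ratio; and
* clinical covariates (gender, age, stage, race, EGFR/KRAS mutation,
  pack-years) drawn from group-specific marginals, with EGFR and KRAS
  mutations mutually exclusive within a sample.

Everything is reproducible from the spec's integer seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import ProbePanel
from .segmentation import GAIN, LOSS, NEUTRAL, Segment, SegmentProfile

__all__ = [
    "InjectedEvent",
    "GroupCovariates",
    "CohortSpec",
    "SimulatedCohort",
    "simulate_cohort",
    "default_cohort_spec",
    "DEFAULT_GAIN_LOGRATIO",
    "DEFAULT_LOSS_LOGRATIO",
]

log = logging.getLogger(__name__)

# single-copy gain / single-copy loss on a diploid background:
# log2(3/2) ~ +0.58 and log2(1/2) = -1.0
DEFAULT_GAIN_LOGRATIO = 0.58
DEFAULT_LOSS_LOGRATIO = -1.0


@dataclass(frozen=True)
class InjectedEvent:
    """A planted segmental CNA with group-specific carrier frequencies."""

    chrom: str
    start: int
    end: int
    etype: str  # "gain" | "loss"
    freq_group_a: float
    freq_group_b: float
    mean_logratio: float | None = None

    def __post_init__(self):
        if self.etype not in (GAIN, LOSS):
            raise ValueError("etype must be 'gain' or 'loss'")
        for f in (self.freq_group_a, self.freq_group_b):
            if not (0.0 <= f <= 1.0):
                raise ValueError("frequencies must lie in [0, 1]")
        if self.end <= self.start:
            raise ValueError("event end must exceed start")
        mean = self.mean()
        if self.etype == GAIN and mean <= 0:
            raise ValueError("gain event requires positive mean log-ratio")
        if self.etype == LOSS and mean >= 0:
            raise ValueError("loss event requires negative mean log-ratio")

    def mean(self) -> float:
        if self.mean_logratio is not None:
            return self.mean_logratio
        return DEFAULT_GAIN_LOGRATIO if self.etype == GAIN else DEFAULT_LOSS_LOGRATIO


@dataclass(frozen=True)
class GroupCovariates:
    """Per-group marginal rates for the clinical covariates."""

    p_egfr: float
    p_kras: float
    p_asian: float
    p_female: float
    age_mean: float
    age_sd: float
    age_range: tuple = (35, 90)
    stage_levels: tuple = ("IA", "IB", "IIA", "IIB", "IIIA", "IIIB", "IV")
    stage_probs: tuple = ()
    pack_years_mean: float = 0.0
    pack_years_range: tuple = (0, 0)

    def __post_init__(self):
        for name in ("p_egfr", "p_kras", "p_asian", "p_female"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.p_egfr + self.p_kras > 1.0:
            raise ValueError("p_egfr + p_kras must not exceed 1 (mutations are exclusive)")
        if self.stage_probs and abs(sum(self.stage_probs) - 1.0) > 1e-9:
            raise ValueError("stage_probs must sum to 1")


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for one simulated two-group cohort."""

    n_group_a: int = 30
    n_group_b: int = 39
    group_names: tuple = ("never", "smoker")
    background_event_rate: float = 12.0
    background_length_range: tuple = (500_000, 8_000_000)
    events: tuple = ()
    noise_sd: float = 0.1
    covariates: Mapping[str, GroupCovariates] | None = None
    purity: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_group_a <= 0 or self.n_group_b <= 0:
            raise ValueError("group sizes must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.background_event_rate < 0:
            raise ValueError("background_event_rate must be >= 0")
        lo, hi = self.background_length_range
        if not (0 < lo <= hi):
            raise ValueError("background_length_range must satisfy 0 < min <= max")
        if not (0.0 < self.purity <= 1.0):
            raise ValueError("purity must be in (0, 1]")
        # injected events must not overlap one another (keeps truth disjoint)
        evs = sorted(self.events, key=lambda e: (e.chrom, e.start))
        for a, b in zip(evs, evs[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise ValueError("injected events must be pairwise non-overlapping")


def default_covariates() -> dict:
    """Group covariate marginals for a realistic smoker/never-smoker cohort.

    Never smokers: EGFR-mutation-rich, mostly Asian and female, pack-years 0.
    Smokers: KRAS-mutation-rich, mostly Caucasian, positive pack-years.
    """
    return {
        "never": GroupCovariates(
            p_egfr=17 / 30, p_kras=3 / 30, p_asian=21 / 30, p_female=23 / 30,
            age_mean=70, age_sd=10, age_range=(39, 86),
            stage_probs=(8 / 30, 9 / 30, 1 / 30, 7 / 30, 4 / 30, 1 / 30, 0.0),
            pack_years_mean=0.0, pack_years_range=(0, 0),
        ),
        "smoker": GroupCovariates(
            p_egfr=1 / 39, p_kras=24 / 39, p_asian=2 / 39, p_female=28 / 39,
            age_mean=64, age_sd=8, age_range=(45, 78),
            stage_probs=(12 / 39, 12 / 39, 2 / 39, 7 / 39, 5 / 39, 0.0, 1 / 39),
            pack_years_mean=50.0, pack_years_range=(2, 120),
        ),
    }


def default_cohort_spec(events: Sequence[InjectedEvent] = (), seed: int = 0, **overrides) -> CohortSpec:
    """A :class:`CohortSpec` with the package's study-emulating defaults."""
    kw = dict(events=tuple(events), covariates=default_covariates(), seed=seed)
    kw.update(overrides)
    return CohortSpec(**kw)


@dataclass
class SimulatedCohort:
    """Generated cohort: probe profiles, per-sample truth, annotations."""

    panel: ProbePanel
    profiles: pd.DataFrame  # probes x samples
    truth_segments: dict  # sample_id -> list[Segment]
    annotations: pd.DataFrame

    @property
    def sample_ids(self) -> list:
        return list(self.profiles.columns)

    def truth_profiles(self) -> list:
        return [
            SegmentProfile(sample_id=sid, segments=list(segs))
            for sid, segs in self.truth_segments.items()
        ]


def _chrom_bounds(panel: ProbePanel) -> dict:
    return {name: int(panel.positions(name)[-1]) + 1 for name in panel.chrom_order}


def _place_background(rng: np.random.Generator, panel: ProbePanel, spec: CohortSpec):
    """Draw one sample's background events: (chrom, start, end, etype)."""
    bounds = _chrom_bounds(panel)
    names = panel.chrom_order
    lengths = np.array([bounds[c] for c in names], dtype=float)
    weights = lengths / lengths.sum()
    k = rng.poisson(spec.background_event_rate)
    lo, hi = spec.background_length_range
    out = []
    for _ in range(k):
        ci = rng.choice(len(names), p=weights)
        chrom = names[ci]
        length = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        length = min(length, int(lengths[ci]) - 1)
        start = int(rng.integers(0, int(lengths[ci]) - length))
        etype = GAIN if rng.random() < 0.5 else LOSS
        out.append((chrom, start, start + length, etype))
    return out


def _add_event(accepted: list, chrom: str, start: int, end: int, etype: str, mean: float):
    """Insert an interval into the per-sample truth, unioning same-type
    overlaps and discarding the new draw on opposite-type collision."""
    overlaps = [
        i for i, (c, s, e, t, _m) in enumerate(accepted)
        if c == chrom and start < e and s < end
    ]
    if any(accepted[i][3] != etype for i in overlaps):
        return  # opposite-type collision: later draw discarded
    for i in sorted(overlaps, reverse=True):
        _c, s, e, _t, m = accepted.pop(i)
        w_old, w_new = (e - s), (end - start)
        mean = (m * w_old + mean * w_new) / (w_old + w_new)
        start, end = min(start, s), max(end, e)
    accepted.append((chrom, start, end, etype, mean))


def simulate_cohort(spec: CohortSpec, panel: ProbePanel) -> SimulatedCohort:
    """Generate a two-group cohort on ``panel`` per ``spec``.

    Injected events are applied first (taking precedence over background
    draws), then background events; within a sample the resulting truth is a
    disjoint interval set. Probes inside an event have mean
    ``purity * event mean`` and mean 0 elsewhere, plus Gaussian ``noise_sd``.
    """
    bounds = _chrom_bounds(panel)
    for ev in spec.events:
        if ev.chrom not in bounds or ev.start < 0 or ev.end > bounds[ev.chrom]:
            raise ValueError(f"injected event outside panel genome: {ev}")

    rng = np.random.default_rng(spec.seed)
    covs = dict(spec.covariates) if spec.covariates is not None else default_covariates()
    name_a, name_b = spec.group_names
    for g in (name_a, name_b):
        if g not in covs:
            raise ValueError(f"covariate model missing group {g!r}")

    groups = [name_a] * spec.n_group_a + [name_b] * spec.n_group_b
    n = len(groups)
    width = len(str(n))
    sample_ids = [f"S{str(i + 1).zfill(width)}" for i in range(n)]

    profiles = np.empty((panel.n_probes, n), dtype=float)
    truth: dict[str, list] = {}
    rows = []

    for j, (sid, group) in enumerate(zip(sample_ids, groups)):
        accepted: list = []
        for ev in spec.events:
            freq = ev.freq_group_a if group == name_a else ev.freq_group_b
            if rng.random() < freq:
                _add_event(accepted, ev.chrom, ev.start, ev.end, ev.etype, ev.mean())
        for chrom, start, end, etype in _place_background(rng, panel, spec):
            mean = DEFAULT_GAIN_LOGRATIO if etype == GAIN else DEFAULT_LOSS_LOGRATIO
            _add_event(accepted, chrom, start, end, etype, mean)

        signal = np.zeros(panel.n_probes)
        segs = []
        order = {c: i for i, c in enumerate(panel.chrom_order)}
        for chrom, start, end, etype, mean in sorted(
            accepted, key=lambda r: (order[r[0]], r[1])
        ):
            lo, hi = panel.probe_range(chrom, start, end)
            signal[lo:hi] = mean * spec.purity
            segs.append(
                Segment(
                    chrom=chrom, start_bp=start, end_bp=end,
                    n_markers=hi - lo, mean_logratio=mean * spec.purity, state=etype,
                )
            )
        truth[sid] = segs
        noise = rng.normal(0.0, spec.noise_sd, panel.n_probes) if spec.noise_sd > 0 else 0.0
        profiles[:, j] = signal + noise

        cv = covs[group]
        gender = "female" if rng.random() < cv.p_female else "male"
        age = int(np.clip(round(rng.normal(cv.age_mean, cv.age_sd)), *cv.age_range))
        probs = cv.stage_probs or tuple([1.0 / len(cv.stage_levels)] * len(cv.stage_levels))
        stage = cv.stage_levels[rng.choice(len(cv.stage_levels), p=np.asarray(probs))]
        race = "asian" if rng.random() < cv.p_asian else "caucasian"
        u = rng.random()  # one draw => EGFR and KRAS can never co-occur
        if u < cv.p_egfr:
            egfr, kras = "mutant", "wild-type"
        elif u < cv.p_egfr + cv.p_kras:
            egfr, kras = "wild-type", "mutant"
        else:
            egfr, kras = "wild-type", "wild-type"
        if cv.pack_years_mean > 0:
            py_lo, py_hi = cv.pack_years_range
            pack_years = int(np.clip(round(rng.normal(cv.pack_years_mean, cv.pack_years_mean / 2)), py_lo, py_hi))
        else:
            pack_years = 0
        rows.append(
            dict(sample_id=sid, group=group, gender=gender, age=age, stage=stage,
                 race=race, egfr=egfr, kras=kras, pack_years=pack_years)
        )

    return SimulatedCohort(
        panel=panel,
        profiles=pd.DataFrame(profiles, columns=sample_ids),
        truth_segments=truth,
        annotations=pd.DataFrame(rows),
    )
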