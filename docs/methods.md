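# Methods

## Scope and data model

`cnadiff` compares somatic copy-number landscapes between two patient
groups measured on paired tumor/normal arrays. All coordinates are 0-based
half-open internally, so every size is `end − start`; SEG input/output uses
the community 1-based inclusive convention and BED output is 0-based
half-open, with lossless conversions between the three. A `ProbePanel`
(sorted chromosome/position lattice) anchors every per-sample container.

## Segmentation

Each sample's per-probe log2 tumor/normal ratio vector is segmented per
chromosome by recursive binary splitting. The candidate breakpoint within a
segment is the split minimising the total within-segment sum of squares
(the change-point maximum-likelihood criterion; leftmost on ties), which
recovers noise-free step boundaries exactly. The candidate is *accepted*
only if

* Welch's two-sample test between the two flanks has p < `p_break`
  (default 10⁻⁷),
* the signal-to-noise ratio — |mean difference| divided by the pooled
  within-segment SD — exceeds `snr_threshold` (default 0.3), and
* both children keep at least `min_markers` probes (default 50;
  lower-density panels can use e.g. 20).

Welch p-values are evaluated on the log scale (`t.logsf`) so very strong
breaks never underflow into artificial ties, and mean differences below
1e-9 relative are treated as zero so float roundoff inside a constant
stretch cannot fabricate an infinitely significant split. Terminal segments
are typed by a one-sample two-sided test of the segment mean against zero
at `p_dev` (default 10⁻⁷): gain if significantly positive, loss if
significantly negative, neutral otherwise; a zero-variance segment with a
nonzero mean is typed by sign (the test's deterministic limit). The
deviation test uses segment-level means — the upstream array normalisation
is assumed to have removed probe-level pairing structure.

Same-state aberrant segments on one chromosome separated by less than
`merge_window_bp` (default 1 Mbp) are merged: the interval spans both,
marker counts add, and the mean is re-weighted by markers. Merging is
idempotent and drops neutral segments, leaving the CNA call set.

**Known limitation.** An aberrant run shorter than `min_markers` is
*usually* absorbed (the diluted flank test fails the stringent `p_break`),
but it is not impossible for such a run to be isolated inside a padded
minimum-width segment — in the degenerate zero-noise case the flank test is
scale-free and always fires. With realistic probe noise (SD ≈ 0.1 against a
single-copy gain of +0.58) suppression holds in ~90 % of noise
realizations; the test suite checks exactly this contrast.

## Typed states and region grid

Aberrant segments are expanded to per-probe states (+1/0/−1, half-open
intervals, so a probe at a segment's `end_bp` stays neutral). State vectors
are stacked and collapsed on the union of all samples' change-points;
within any resulting region every sample is constant, and re-expansion
reproduces each input vector exactly. Frequency landscapes are centered
moving averages (default 500 probes) of the per-probe gain/loss/any
frequencies, truncated at chromosome ends (windows larger than a chromosome
degrade to the chromosome mean, with a warning).

**Functional resolution** — the smallest reportable aberration — is
computed as the genome-wide median span of every `min_markers`-probe
window. On the default synthetic panel (10 kbp spacing, 50 markers) this is
≈ 490 kbp; for a real high-density panel it is in the 100–150 kbp range.
It is the default minimum size for reported differential regions.

## Proportion of genome altered

PGA = Σ bp in (merged) CNA segments / denominator, split into gain, loss
and all. The denominator defaults to the probe-covered span (sum over
chromosomes of last-minus-first probe position + 1) because the array
cannot observe anything outside it; a fixed genome length can be supplied
instead. Because merged calls are disjoint, `pga_all = pga_gain +
pga_loss` exactly.

Group comparison uses Welch's unequal-variance two-sided t-test. Before
testing, samples with PGA strictly outside the [5th, 95th] percentile band
(linear-interpolation percentiles) are excluded. The band is computed
**within each group** by default: per-group trimming removes each group's
own outliers symmetrically, whereas a pooled band preferentially trims the
high tail of the high-PGA group and the low tail of the low-PGA group,
systematically shrinking a real between-group difference (in simulation at
a realistic effect — means 0.41 vs 0.32, SD 0.15, n 30/39 — pooled
trimming cuts power from ≈ 0.77 to ≈ 0.45). Pooled trimming remains
available as `trim="pooled"`.

The multifactor ANOVA is sequential (type I): factors enter an OLS fit one
at a time in a fixed order (default: stage, gender, age, race, group,
EGFR, KRAS — clinical before genetic), each factor's SS is the drop in
residual SS when it enters, and F is the factor mean square over the full
model's residual mean square. The decomposition identity (factor SS +
residual SS = total SS) is asserted at runtime. Sequential SS is computed
directly by incremental least squares rather than through a formula
interface because formula machinery reorders categorical and numeric terms,
which silently changes type I sums. Aliased columns contribute zero df
(logged); a constant response reports all SS and F as 0.

## Exact differential-region testing

Per region the 3×2 table (gain/neutral/loss × group) is tested with the
exact conditional test: with both margins fixed, the probability of a
table is multivariate hypergeometric, and the two-sided p is the sum of
probabilities of all tables no more probable than the observed one (ties
admitted within 10⁻⁷ relative, so float noise cannot drop a tied table).
Enumeration is over column-1 count vectors; margins whose enumeration
would exceed 10⁷ tables raise with a pointer to the Monte-Carlo estimator
(`fisher_exact_mc`, flagged approximate). The 2×2 clinical associations go
through the same engine.

Calling proceeds region by region at raw α = 0.05 — deliberately **no
multiple-testing correction**, matching the frequency-gap-filter design
where the 15 % rules, not the p-value, carry most of the specificity
burden. A significant region's status is the alteration type (gain or
loss) with the larger between-group frequency gap, enriched in the group
with the higher frequency; exact ties are resolved toward the type with
the smaller 2×2 p (logged). Significant same-status regions within the
merge window are fused; the merged region keeps the *minimum* of its
contributors' p-values and reports the *minimum* frequencies observed
among contributors (a conservative summary of a heterogeneous merged
interval). After merging, regions must show ≥ `min_freq_diff` (0.15)
frequency gap, ≥ `min_freq_any` (0.15) frequency in one group, and size ≥
the functional resolution. Note the frequency-gap filter subsumes the
minimum-frequency filter arithmetically; both are kept as independent
knobs.

## Minimal common regions and co-occurrence

Differential regions from ≥ 2 cohorts are intersected per (chromosome,
alteration type, enriched group): a boundary sweep finds maximal stretches
covered by the same set of source regions with every required dataset
contributing, so an MCR always lies inside each of its contributors.
`require_all=False` relaxes the requirement to `min_datasets`.
Co-occurrence between MCRs is the Pearson correlation of per-sample binary
carrier vectors; a sample carries an MCR when **all** probes inside it
show the MCR's state (strict rule, default, appropriate because MCRs are
short; a majority rule is available). Constant carrier vectors yield
undefined correlations, reported as missing.

## Synthetic cohorts

The generator emulates a two-arm adenocarcinoma study at desk scale:

* **Genome/panel.** Default 4 chromosomes × 30 Mbp, 10 kbp mean probe
  spacing with 20 % uniform jitter (12 000 probes). This is a deliberate
  ~25× scale-down of a genome-wide high-density panel that keeps per-probe
  density, segment marker counts, and region statistics realistic while a
  100-cohort experiment runs in minutes.
* **Groups.** 30 "never" vs 39 "smoker" samples.
* **Background events.** Poisson(12) per genome per sample, uniform
  placement weighted by chromosome length, log-uniform lengths 0.5–8 Mbp,
  gain/loss equiprobable — identical in distribution for both groups.
  This yields a background genome-altered fraction of ≈ 0.25, in the range
  reported for adenocarcinoma cohorts.
* **Injected differential events** carry group-specific frequencies; the
  benchmark event is a 3 Mbp gain at 40 % (never) vs 5 % (smoker) carrier
  frequency. Injected events take precedence over background draws:
  same-type overlaps are unioned, opposite-type background collisions are
  discarded, keeping each sample's truth a disjoint interval set.
* **Signal.** Probes in an event have mean log-ratio +0.58 (single-copy
  gain, log₂ 3/2) or −1.0 (single-copy loss, log₂ 1/2), scaled by an
  optional tumor-purity multiplier (default 1.0); everything gets i.i.d.
  Gaussian probe noise (default SD 0.1).
* **Covariates.** Group-specific marginals for gender, age, stage,
  ethnicity, pack-years, and EGFR/KRAS mutation (never smokers
  EGFR-mutation- and Asian-enriched; smokers KRAS-enriched), with EGFR and
  KRAS mutually exclusive by construction (one uniform draw is partitioned
  into EGFR / KRAS / wild-type bins). Chromosome X is not modelled
  separately — all chromosomes behave as autosomes.

What the generator does **not** emulate: wave/GC artefacts, probe-specific
variances, allele-specific signal, subclonality, correlated noise between
neighbouring probes, and recurrent cancer-gene architecture. Passing tests
therefore demonstrate the statistical machinery under idealised noise, not
robustness to array artefacts.

## Operating characteristics (recomputed by `scripts/acceptance.py`)

* **Sensitivity.** Across 100 seeded cohorts, the planted 40 %/5 % gain is
  reported as a never-enriched differential region in ≥ 80 % of cohorts
  (≈ 0.84 measured; misses are cohorts where binomial sampling plus
  background gains shrink the observed frequency gap below the 15 % filter
  or the exact test's significance).
* **Specificity.** On cohorts with no planted difference the per-region
  false-call rate (false regions / regions tested) is ≈ 0.003, far below
  the nominal α = 0.05 — the frequency and size filters do most of the
  work. Because a genome contains on the order of a thousand correlated
  regions and no multiplicity correction is applied, the *count* of false
  regions per null genome is about 3; both numbers are reported.
* **PGA power.** With group means 0.41 vs 0.32, SD 0.15, n = 30/39, the
  trimmed Welch comparison rejects at 0.05 in ≈ 78 % of 200 replicates.

## Numerical and degenerate-input conventions

* Exact-test tie tolerance: 10⁻⁷ relative on table probabilities.
* Welch test with zero variance in both groups: p = 1 if means equal,
  otherwise the deterministic limit p = 0.
* Percentile trimming uses numpy linear interpolation; exclusion is strict
  (values equal to the 5th/95th percentile are kept).
* Region grids fuse adjacent regions with identical state columns; region
  intervals run from their first probe's position to their last probe's
  position + 1.
* Chromosomes with fewer than `2 × min_markers` probes are kept as a
  single segment with a warning.
* Random streams: every public entry point takes an integer seed;
  experiment replicates derive child seeds via `numpy` `SeedSequence`
  so they are independent and reproducible.
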