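import numpy as np
import pytest

import cnadiff as cd
from cnadiff.exact import fisher_exact_3x2
from cnadiff.regions import DifferentialRegion
from cnadiff.states import RegionGrid, StateMatrix


def _matrix(region_states, groups, spacing=100_000):
    """Build a StateMatrix from a list of per-region state columns on chr1."""
    S = np.array(region_states, dtype=np.int8)
    n = S.shape[0]
    lo = np.arange(n)
    grid = RegionGrid(
        chrom=np.array(["chr1"] * n, dtype=object),
        start=lo * spacing,
        end=(lo + 1) * spacing,
        probe_lo=lo,
        probe_hi=lo + 1,
    )
    return StateMatrix(grid=grid, states=S, samples=[f"s{i}" for i in range(S.shape[1])],
                       groups=np.asarray(groups, dtype=object))


def _column(n_gain_a, n_a, n_gain_b, n_b, loss_a=0, loss_b=0):
    col = [1] * n_gain_a + [-1] * loss_a + [0] * (n_a - n_gain_a - loss_a)
    col += [1] * n_gain_b + [-1] * loss_b + [0] * (n_b - n_gain_b - loss_b)
    return col


GROUPS = ["never"] * 30 + ["smoker"] * 39


def test_enriched_gain_region_called_with_oracle_p():
    # gain/neutral/loss = (12,16,2) vs (2,35,2): frequencies 0.40 vs 0.051
    col = _column(12, 30, 2, 39, loss_a=2, loss_b=2)
    m = _matrix([col], GROUPS, spacing=500_000)
    regions = cd.call_differential_regions(m, cd.DiffParams(min_size_bp=100_000))
    assert len(regions) == 1
    r = regions[0]
    assert (r.etype, r.group) == ("gain", "never")
    assert r.freq_a == pytest.approx(12 / 30)
    assert r.freq_b == pytest.approx(2 / 39)
    assert r.p == pytest.approx(fisher_exact_3x2([[12, 2], [16, 35], [2, 2]]), rel=1e-9)


def test_small_frequency_gap_excluded_despite_significance():
    # loss in 14/30 vs 9/39 -> gap 0.24; gain gap small: craft p<0.05 but gap 0.10
    col = _column(12, 30, 12, 39)  # 0.40 vs 0.31 -> gap 0.09
    m = _matrix([col], GROUPS, spacing=500_000)
    p = fisher_exact_3x2([[12, 12], [18, 27], [0, 0]])
    regions = cd.call_differential_regions(m, cd.DiffParams(min_size_bp=100_000))
    assert regions == []  # either insignificant or filtered by the 15% gap rule


def test_small_region_without_neighbor_excluded_by_size():
    col = _column(15, 30, 1, 39)
    m = _matrix([col], GROUPS, spacing=50_000)  # region size 50 kbp < 139 kbp
    regions = cd.call_differential_regions(m, cd.DiffParams(min_size_bp=139_000))
    assert regions == []


def test_nearby_same_status_regions_merge_with_min_frequencies():
    strong = _column(15, 30, 1, 39)
    weaker = _column(12, 30, 2, 39)
    neutral = _column(0, 30, 0, 39)
    m = _matrix([strong, weaker, neutral], GROUPS, spacing=400_000)
    regions = cd.call_differential_regions(
        m, cd.DiffParams(min_size_bp=100_000, merge_window_bp=1_000_000))
    assert len(regions) == 1
    r = regions[0]
    assert (r.start, r.end) == (0, 800_000)
    assert r.freq_a == pytest.approx(12 / 30)  # minimum across contributors
    assert r.freq_b == pytest.approx(1 / 39)
    assert len(r.sources) == 2


def test_output_invariant_to_sample_ordering():
    rng = np.random.default_rng(0)
    cols = []
    for _ in range(6):
        cols.append(_column(rng.integers(0, 16), 30, rng.integers(0, 6), 39,
                            loss_a=rng.integers(0, 8), loss_b=rng.integers(0, 8)))
    m = _matrix(cols, GROUPS, spacing=500_000)
    base = cd.call_differential_regions(m, cd.DiffParams(min_size_bp=100_000))

    perm = rng.permutation(69)
    m2 = StateMatrix(grid=m.grid, states=m.states[:, perm],
                     samples=[m.samples[i] for i in perm],
                     groups=m.groups[perm])
    shuffled = cd.call_differential_regions(m2, cd.DiffParams(min_size_bp=100_000))
    assert [(r.start, r.end, r.status, r.p) for r in base] == \
        [(r.start, r.end, r.status, r.p) for r in shuffled]


def _dr(chrom, start, end, etype="gain", group="never", ds=None, p=0.01):
    return DifferentialRegion(chrom=chrom, start=start, end=end, etype=etype,
                              group=group, freq_a=0.4, freq_b=0.05, p=p, dataset=ds)


class TestMCR:
    def test_pairwise_intersection(self):
        mcrs = cd.intersect_mcrs({
            "A": [_dr("chr5", 100_000, 300_000)],
            "B": [_dr("chr5", 200_000, 400_000)],
        })
        assert len(mcrs) == 1
        m = mcrs[0]
        assert (m.start, m.end, m.size) == (200_000, 300_000, 100_000)
        assert set(m.sources) == {"A", "B"}

    def test_status_mismatch_gives_no_mcr(self):
        mcrs = cd.intersect_mcrs({
            "A": [_dr("chr5", 100_000, 300_000, etype="gain")],
            "B": [_dr("chr5", 100_000, 300_000, etype="loss")],
        })
        assert mcrs == []
        mcrs = cd.intersect_mcrs({
            "A": [_dr("chr5", 100_000, 300_000, group="never")],
            "B": [_dr("chr5", 100_000, 300_000, group="smoker")],
        })
        assert mcrs == []

    def test_three_dataset_core_matches_pairwise_associativity(self):
        a = [_dr("chr7", 100_000, 900_000)]
        b = [_dr("chr7", 300_000, 1_200_000)]
        c = [_dr("chr7", 500_000, 800_000)]
        abc = cd.intersect_mcrs({"A": a, "B": b, "C": c})
        ab = cd.intersect_mcrs({"A": a, "B": b})
        ab_regions = [_dr("chr7", m.start, m.end) for m in ab]
        ab_c = cd.intersect_mcrs({"AB": ab_regions, "C": c})
        assert [(m.start, m.end) for m in abc] == [(m.start, m.end) for m in ab_c]
        assert [(m.start, m.end) for m in abc] == [(500_000, 800_000)]

    def test_mcr_never_larger_than_contributors(self):
        rng = np.random.default_rng(5)
        sets = {}
        for ds in "ABC":
            regions = []
            for _ in range(5):
                s = int(rng.integers(0, 5_000_000))
                e = s + int(rng.integers(100_000, 2_000_000))
                regions.append(_dr("chr1", s, e))
            sets[ds] = regions
        for m in cd.intersect_mcrs(sets):
            for regs in m.sources.values():
                for r in regs:
                    assert m.size <= r.size
                    assert r.start <= m.start and m.end <= r.end or \
                        (r.start < m.end and m.start < r.end)

    def test_require_all_versus_min_datasets(self):
        sets = {
            "A": [_dr("chr5", 0, 1_000_000)],
            "B": [_dr("chr5", 500_000, 1_500_000)],
            "C": [_dr("chr5", 2_000_000, 3_000_000)],
        }
        assert cd.intersect_mcrs(sets, require_all=True) == []
        partial = cd.intersect_mcrs(sets, require_all=False, min_datasets=2)
        assert [(m.start, m.end) for m in partial] == [(500_000, 1_000_000)]


class TestCooccurrence:
    def _setup(self, carriers_a, carriers_b, n=20):
        model = cd.GenomeModel(chromosomes=(("chr7", 2_000_000),), probe_spacing=10_000.0,
                               spacing_jitter=0.0)
        panel = cd.build_probe_panel(model, seed=0)
        mcrs = [
            cd.MCR(chrom="chr7", start=100_000, end=400_000, etype="gain", group="never"),
            cd.MCR(chrom="chr7", start=1_000_000, end=1_400_000, etype="gain", group="never"),
        ]
        vectors = []
        for i in range(n):
            states = np.zeros(panel.n_probes, dtype=np.int8)
            if i in carriers_a:
                lo, hi = panel.probe_range("chr7", 100_000, 400_000)
                states[lo:hi] = 1
            if i in carriers_b:
                lo, hi = panel.probe_range("chr7", 1_000_000, 1_400_000)
                states[lo:hi] = 1
            vectors.append(cd.StateVector(sample_id=f"s{i}", states=states))
        return mcrs, vectors, panel

    def test_identical_carriers_r_one(self):
        carriers = set(range(8))
        mcrs, vectors, panel = self._setup(carriers, carriers)
        corr = cd.mcr_cooccurrence(mcrs, vectors, panel)
        assert corr.iloc[0, 1] == pytest.approx(1.0)

    def test_complementary_carriers_r_minus_one(self):
        mcrs, vectors, panel = self._setup(set(range(10)), set(range(10, 20)))
        corr = cd.mcr_cooccurrence(mcrs, vectors, panel)
        assert corr.iloc[0, 1] == pytest.approx(-1.0)

    def test_linked_gains_strongly_correlated(self):
        rng = np.random.default_rng(9)
        carriers_a, carriers_b = set(), set()
        for i in range(40):
            if rng.random() < 0.5:
                carriers_a.add(i)
                if rng.random() < 0.8:  # co-occurrence 0.8
                    carriers_b.add(i)
        mcrs, vectors, panel = self._setup(carriers_a, carriers_b, n=40)
        corr = cd.mcr_cooccurrence(mcrs, vectors, panel)
        assert corr.iloc[0, 1] > 0.5

    def test_constant_carrier_vector_reported_missing(self):
        mcrs, vectors, panel = self._setup(set(), set(range(5)))
        corr = cd.mcr_cooccurrence(mcrs, vectors, panel)
        assert np.isnan(corr.iloc[0, 1])
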