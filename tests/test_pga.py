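import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cnadiff as cd
from cnadiff.segmentation import GAIN, LOSS


def _seg(chrom, start, end, mean, state, n=100):
    return cd.Segment(chrom=chrom, start_bp=start, end_bp=end, n_markers=n,
                      mean_logratio=mean, state=state)


def _span_panel(length=10_000_000):
    model = cd.GenomeModel(chromosomes=(("chr1", length),), probe_spacing=length / 1000,
                           spacing_jitter=0.0)
    return cd.build_probe_panel(model, seed=0)


class TestComputePGA:
    def test_no_cna_segments_gives_zero(self, uniform_panel):
        r = cd.compute_pga(cd.SegmentProfile("s", []), uniform_panel)
        assert r.pga_all == r.pga_gain == r.pga_loss == 0.0

    def test_full_span_gain_gives_one(self):
        panel = _span_panel()
        span = (int(panel.pos[0]), int(panel.pos[-1]) + 1)
        prof = cd.SegmentProfile("s", [_seg("chr1", *span, 0.5, GAIN)])
        r = cd.compute_pga(prof, panel)
        assert r.pga_gain == r.pga_all == 1.0
        assert r.pga_loss == 0.0

    def test_interval_arithmetic(self):
        panel = _span_panel()
        denom = panel.covered_bp
        prof = cd.SegmentProfile("s", [
            _seg("chr1", 1_000_000, 3_000_000, 0.5, GAIN),
            _seg("chr1", 5_000_000, 6_000_000, -0.8, LOSS),
        ])
        r = cd.compute_pga(prof, panel)
        assert r.pga_gain == pytest.approx(2_000_000 / denom)
        assert r.pga_loss == pytest.approx(1_000_000 / denom)
        assert r.pga_all == pytest.approx(3_000_000 / denom)

    def test_invariant_to_splitting_segments(self):
        panel = _span_panel()
        whole = cd.SegmentProfile("s", [_seg("chr1", 1_000_000, 3_000_000, 0.5, GAIN)])
        halves = cd.SegmentProfile("s", [
            _seg("chr1", 1_000_000, 2_000_000, 0.5, GAIN, n=50),
            _seg("chr1", 2_000_000, 3_000_000, 0.5, GAIN, n=50),
        ])
        assert cd.compute_pga(whole, panel) == cd.compute_pga(halves, panel)

    def test_fixed_denominator_option(self):
        panel = _span_panel()
        prof = cd.SegmentProfile("s", [_seg("chr1", 0, 1_000_000, 0.5, GAIN)])
        r = cd.compute_pga(prof, panel, covered_bp=2_000_000)
        assert r.pga_gain == 0.5


class TestComparePGA:
    def test_identical_groups_give_t_zero_p_one(self):
        vals = [0.2, 0.3, 0.4, 0.5]
        comp = cd.compare_pga(vals, vals, trim=False)
        assert comp.t == pytest.approx(0.0)
        assert comp.p == pytest.approx(1.0)

    def test_matches_textbook_welch_formula(self):
        a = np.array([0.1, 0.2, 0.3])
        b = np.array([0.4, 0.5, 0.6])
        comp = cd.compare_pga(a, b, trim=False)
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se2 = va / 3 + vb / 3
        t = (a.mean() - b.mean()) / np.sqrt(se2)
        df = se2**2 / (va**2 / (9 * 2) + vb**2 / (9 * 2))
        p = 2 * stats.t.sf(abs(t), df)
        assert comp.t == pytest.approx(t)
        assert comp.df == pytest.approx(df)
        assert comp.p == pytest.approx(p)

    def test_trim_removes_at_most_ceiling_five_percent_per_tail(self):
        rng = np.random.default_rng(0)
        a = pd.Series(rng.normal(0.4, 0.1, 41))
        b = pd.Series(rng.normal(0.3, 0.1, 37))
        comp = cd.compare_pga(a, b, trim="group")
        assert len(comp.excluded_a) <= 2 * int(np.ceil(0.05 * len(a)))
        assert len(comp.excluded_b) <= 2 * int(np.ceil(0.05 * len(b)))
        assert set(comp.excluded_a) <= set(a.index)

    def test_welch_p_agrees_with_permutation_test(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0.40, 0.1, 12)
        b = rng.normal(0.30, 0.1, 15)
        comp = cd.compare_pga(a, b, trim=False)

        def welch_t(x, y):
            va, vb = x.var(ddof=1, axis=-1), y.var(ddof=1, axis=-1)
            return (x.mean(axis=-1) - y.mean(axis=-1)) / np.sqrt(va / x.shape[-1] + vb / y.shape[-1])

        pooled = np.concatenate([a, b])
        n_resamples = 20_000
        perm_rng = np.random.default_rng(1)
        idx = np.argsort(perm_rng.random((n_resamples, len(pooled))), axis=1)
        shuffled = pooled[idx]
        t_null = welch_t(shuffled[:, : len(a)], shuffled[:, len(a):])
        p_perm = (np.abs(t_null) >= abs(comp.t)).mean()
        mc_se = np.sqrt(max(comp.p * (1 - comp.p), 1e-6) / n_resamples)
        assert abs(p_perm - comp.p) < max(5 * mc_se, 0.02)

    def test_degenerate_zero_variance_equal_means(self):
        comp = cd.compare_pga([0.3] * 5, [0.3] * 5, trim=False)
        assert comp.p == 1.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            cd.compare_pga([0.1, 0.2], [0.3, 0.4, 0.5], trim=False)


class TestMultifactorAnova:
    def test_constant_response_gives_zero_ss_and_f(self):
        factors = pd.DataFrame({"g": ["a", "b"] * 10, "x": np.arange(20.0)})
        tab = cd.multifactor_anova(np.full(20, 0.5), factors)
        assert tab.loc["g", "sum_sq"] == 0.0
        assert tab.loc["g", "F"] == 0.0
        assert tab.loc["x", "F"] == 0.0

    def test_single_binary_factor_f_equals_t_squared(self):
        rng = np.random.default_rng(3)
        y = np.concatenate([rng.normal(0.4, 0.1, 14), rng.normal(0.3, 0.1, 16)])
        g = ["a"] * 14 + ["b"] * 16
        tab = cd.multifactor_anova(y, pd.DataFrame({"g": g}))
        t = stats.ttest_ind(y[:14], y[14:], equal_var=True).statistic
        assert tab.loc["g", "F"] == pytest.approx(t**2)

    def test_orthogonal_factors_order_invariant(self):
        # balanced 2x2 layout -> factors orthogonal -> type I SS order-free
        g1 = np.repeat(["a", "b"], 20)
        g2 = np.tile(["u", "v"], 20)
        rng = np.random.default_rng(4)
        y = rng.normal(0, 1, 40) + (g1 == "a") * 0.5 + (g2 == "u") * 0.3
        f = pd.DataFrame({"g1": g1, "g2": g2})
        t1 = cd.multifactor_anova(y, f, order=["g1", "g2"])
        t2 = cd.multifactor_anova(y, f, order=["g2", "g1"])
        assert t1.loc["g1", "sum_sq"] == pytest.approx(t2.loc["g1", "sum_sq"])
        assert t1.loc["g2", "sum_sq"] == pytest.approx(t2.loc["g2", "sum_sq"])

    def test_matches_statsmodels_sequential_table(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(5)
        df = pd.DataFrame({
            "stage": rng.choice(["I", "II", "III"], 60),
            "gender": rng.choice(["m", "f"], 60),
            "race": rng.choice(["a", "c"], 60),
        })
        y = rng.normal(0.35, 0.15, 60)
        ours = cd.multifactor_anova(y, df)
        d2 = df.copy()
        d2["y"] = y
        ref = sm.stats.anova_lm(
            ols("y ~ C(stage) + C(gender) + C(race)", data=d2).fit(), typ=1
        )
        for ours_key, ref_key in [("stage", "C(stage)"), ("gender", "C(gender)"),
                                  ("race", "C(race)")]:
            assert ours.loc[ours_key, "sum_sq"] == pytest.approx(ref.loc[ref_key, "sum_sq"])
            assert ours.loc[ours_key, "F"] == pytest.approx(ref.loc[ref_key, "F"])
            assert ours.loc[ours_key, "PR(>F)"] == pytest.approx(ref.loc[ref_key, "PR(>F)"])

    def test_ss_decomposition_and_aliased_factor(self):
        rng = np.random.default_rng(6)
        g = rng.choice(["a", "b"], 30)
        f = pd.DataFrame({"g": g, "g_copy": g})  # perfectly aliased
        y = rng.normal(0, 1, 30)
        tab = cd.multifactor_anova(y, f)
        assert tab.loc["g_copy", "df"] == 0.0
        assert tab.loc["g_copy", "sum_sq"] == pytest.approx(0.0, abs=1e-10)
        total = ((y - y.mean()) ** 2).sum()
        assert tab["sum_sq"].sum() == pytest.approx(total)
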