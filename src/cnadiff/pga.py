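"""Proportion of genome altered (PGA) and group-level comparisons.

PGA is the fraction of the assayed genome covered by CNA segments in one
tumor, computed separately for gains, losses, and all alterations. Group
comparisons use Welch's unequal-variance t-test after optional trimming of
samples outside the pooled 5th-95th percentile band, and a sequential
(type I) multifactor ANOVA apportions PGA variance across clinical and
genetic covariates in a fixed factor order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import ProbePanel
from .segmentation import GAIN, LOSS, SegmentProfile

__all__ = [
    "PGAResult",
    "GroupComparison",
    "compute_pga",
    "compare_pga",
    "multifactor_anova",
    "ANOVA_FACTOR_ORDER",
]

log = logging.getLogger(__name__)

#: Default sequential-ANOVA factor order: clinical first, then genetic.
ANOVA_FACTOR_ORDER = ("stage", "gender", "age", "race", "group", "egfr", "kras")


@dataclass(frozen=True)
class PGAResult:
    sample_id: str
    pga_gain: float
    pga_loss: float
    pga_all: float
    covered_bp: int


@dataclass
class GroupComparison:
    """Welch comparison of per-sample PGA between two groups."""

    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    median_a: float
    median_b: float
    range_a: tuple
    range_b: tuple
    t: float
    df: float
    p: float
    excluded_a: list
    excluded_b: list


def compute_pga(profile: SegmentProfile, panel: ProbePanel, covered_bp: int | None = None) -> PGAResult:
    """Sum CNA base pairs and divide by the panel's covered span.

    The profile is expected to be merged (disjoint CNA segments), so gains
    and losses never overlap and ``pga_all = pga_gain + pga_loss``. The
    denominator defaults to the probe-covered span; pass ``covered_bp`` to
    use a fixed genome length instead.
    """
    denom = panel.covered_bp if covered_bp is None else int(covered_bp)
    gain_bp = sum(s.size for s in profile.segments if s.state == GAIN)
    loss_bp = sum(s.size for s in profile.segments if s.state == LOSS)
    return PGAResult(
        sample_id=profile.sample_id,
        pga_gain=min(gain_bp / denom, 1.0),
        pga_loss=min(loss_bp / denom, 1.0),
        pga_all=min((gain_bp + loss_bp) / denom, 1.0),
        covered_bp=denom,
    )


def compare_pga(values_a, values_b, trim="group") -> GroupComparison:
    """Welch two-sided t-test on per-sample PGA values.

    ``trim`` controls the outlier exclusion applied before testing: samples
    strictly below the 5th or strictly above the 95th percentile (linear
    interpolation) are dropped, with the percentiles computed within each
    group (``"group"``, the default — keeps the exclusion symmetric per
    group so it cannot shrink a real between-group difference) or on the
    pooled cohort (``"pooled"``); ``False``/``None`` disables trimming.
    Each group must keep at least 3 samples.
    """
    a = pd.Series(values_a, dtype=float)
    b = pd.Series(values_b, dtype=float)
    excluded_a: list = []
    excluded_b: list = []
    if trim:
        mode = "group" if trim is True else trim
        if mode == "pooled":
            p5, p95 = np.percentile(np.concatenate([a.to_numpy(), b.to_numpy()]), [5, 95])
            bounds_a = bounds_b = (p5, p95)
        elif mode == "group":
            bounds_a = tuple(np.percentile(a.to_numpy(), [5, 95]))
            bounds_b = tuple(np.percentile(b.to_numpy(), [5, 95]))
        else:
            raise ValueError("trim must be 'group', 'pooled', or falsy")
        keep_a = (a >= bounds_a[0]) & (a <= bounds_a[1])
        keep_b = (b >= bounds_b[0]) & (b <= bounds_b[1])
        excluded_a = list(a.index[~keep_a])
        excluded_b = list(b.index[~keep_b])
        a, b = a[keep_a], b[keep_b]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs >= 3 samples after trimming")
    xa, xb = a.to_numpy(), b.to_numpy()
    if xa.std(ddof=1) == 0 and xb.std(ddof=1) == 0:
        # degenerate: no variance anywhere
        equal = xa.mean() == xb.mean()
        t, df, p = (0.0, float(len(xa) + len(xb) - 2), 1.0) if equal else (np.inf, 1.0, 0.0)
    else:
        res = stats.ttest_ind(xa, xb, equal_var=False)
        t, df, p = float(res.statistic), float(res.df), float(res.pvalue)
    return GroupComparison(
        n_a=len(xa), n_b=len(xb),
        mean_a=float(xa.mean()), mean_b=float(xb.mean()),
        median_a=float(np.median(xa)), median_b=float(np.median(xb)),
        range_a=(float(xa.min()), float(xa.max())),
        range_b=(float(xb.min()), float(xb.max())),
        t=t, df=df, p=p,
        excluded_a=excluded_a, excluded_b=excluded_b,
    )


def multifactor_anova(response, factors: pd.DataFrame, order=None) -> pd.DataFrame:
    """Sequential (type I) ANOVA of ``response`` on the given covariates.

    Factors enter an ordinary-least-squares fit one at a time, strictly in
    ``order`` (default: the table's column order); each factor's sum of
    squares is the drop in residual sum of squares when it enters, so the
    factor SS plus the residual SS always add up to the total SS.
    Object/category/bool columns are dummy-coded; numeric columns enter as
    single regressors. F is the factor mean square over the residual mean
    square of the full model. Aliased (rank-deficient) columns contribute
    no degrees of freedom and are logged.
    """
    if factors.isna().any().any():
        raise ValueError("factor table contains missing values")
    cols = list(order) if order is not None else list(factors.columns)
    for c in cols:
        if c not in factors.columns:
            raise ValueError(f"factor {c!r} not in table")
    y = np.asarray(response, dtype=float)
    n = len(y)
    if n != len(factors):
        raise ValueError("response and factor table lengths differ")

    blocks = []
    for c in cols:
        s = factors[c]
        if s.dtype == object or str(s.dtype) == "category" or s.dtype == bool:
            block = pd.get_dummies(s.astype(str), drop_first=True).to_numpy(float)
        else:
            block = s.to_numpy(float)[:, None]
        blocks.append(block)

    def _fit(X):
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return float(resid @ resid), int(rank)

    X = np.ones((n, 1))
    rss_prev, rank_prev = _fit(X)
    total_ss = rss_prev
    rows = []
    for c, block in zip(cols, blocks):
        X = np.hstack([X, block])
        rss, rank = _fit(X)
        df_c = rank - rank_prev
        if df_c < block.shape[1]:
            log.warning("factor %r is aliased with earlier terms; %d column(s) dropped",
                        c, block.shape[1] - df_c)
        rows.append([c, float(df_c), max(rss_prev - rss, 0.0)])
        rss_prev, rank_prev = rss, rank

    df_resid = n - rank_prev
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    ms_resid = rss_prev / df_resid
    table = pd.DataFrame(rows, columns=["factor", "df", "sum_sq"]).set_index("factor")
    table.index.name = None
    with np.errstate(divide="ignore", invalid="ignore"):
        msq = table["sum_sq"] / table["df"]
        F = msq / ms_resid
    # 0/0 cases (constant response or zero-df factor) are reported as F = 0
    F = F.where(np.isfinite(F), 0.0)
    table["F"] = np.where(table["sum_sq"] == 0, 0.0, F)
    table["PR(>F)"] = np.where(
        (table["df"] > 0) & (table["F"] > 0),
        stats.f.sf(table["F"], table["df"], df_resid),
        1.0,
    )
    table.loc["Residual"] = [float(df_resid), rss_prev, np.nan, np.nan]
    # invariant check: sequential SS decomposes the total SS
    assert abs(table["sum_sq"].sum() - total_ss) <= 1e-8 * max(total_ss, 1.0)
    return table
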