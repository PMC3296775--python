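"""Exact conditional tests for r x 2 contingency tables by enumeration.

The two-sided p-value is the conventional exact r x c definition: condition
on both margins, enumerate every table with those margins, and sum the
(multivariate hypergeometric) probabilities of all tables no more probable
than the observed one. Ties are admitted with a small relative tolerance so
floating-point noise cannot drop a genuinely tied table.

For region-level comparisons the table is 3 x 2: rows gain/neutral/loss,
columns the two patient groups. The 2 x 2 case used for clinical
associations goes through the same enumeration.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import gammaln

__all__ = [
    "fisher_exact_rx2",
    "fisher_exact_3x2",
    "fisher_exact_2x2",
    "fisher_exact_mc",
]

TIE_REL_TOL = 1e-7


def _validate(table) -> np.ndarray:
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[1] != 2:
        raise ValueError("table must be r x 2")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    c = t.sum(axis=0)
    if c[0] == 0 or c[1] == 0:
        raise ValueError("both column sums must be positive")
    return t


def _logp_terms(x: np.ndarray, rows: np.ndarray) -> np.ndarray:
    # log of prod_i [ C(rows_i, x_i) ] for column-1 count vectors x
    return np.sum(
        gammaln(rows + 1) - gammaln(x + 1) - gammaln(rows - x + 1), axis=-1
    )


def _column_vectors(rows: tuple, c1: int):
    """All column-1 count vectors x with 0 <= x_i <= rows_i and sum(x) == c1."""
    if len(rows) == 1:
        if 0 <= c1 <= rows[0]:
            yield (c1,)
        return
    rest_max = sum(rows[1:])
    for x in range(max(0, c1 - rest_max), min(rows[0], c1) + 1):
        for rest in _column_vectors(rows[1:], c1 - x):
            yield (x,) + rest


def _enumerate_logp(rows: np.ndarray, c1: int) -> np.ndarray:
    """Log-probabilities of every column-1 vector with the given margins."""
    X = np.array(list(_column_vectors(tuple(int(v) for v in rows), c1)), dtype=np.int64)
    N = int(rows.sum())
    log_denom = gammaln(N + 1) - gammaln(c1 + 1) - gammaln(N - c1 + 1)
    return _logp_terms(X, rows) - log_denom


def _count_tables(rows: np.ndarray, c1: int) -> float:
    # cheap upper bound on the enumeration size
    return float(np.prod(np.minimum(rows, c1) + 1.0))


@lru_cache(maxsize=100_000)
def _exact_rx2_cached(rows: tuple, col1: tuple) -> float:
    rows_arr = np.asarray(rows, dtype=np.int64)
    x_obs = np.asarray(col1, dtype=np.int64)
    c1 = int(x_obs.sum())
    N = int(rows_arr.sum())
    log_denom = gammaln(N + 1) - gammaln(c1 + 1) - gammaln(N - c1 + 1)
    logp_obs = float(_logp_terms(x_obs, rows_arr) - log_denom)
    logp_all = _enumerate_logp(rows_arr, c1)
    mask = logp_all <= logp_obs + np.log1p(TIE_REL_TOL)
    return float(np.exp(logp_all[mask]).sum())


def fisher_exact_rx2(table, max_tables: int = 10_000_000) -> float:
    """Two-sided exact p for an r x 2 table with both column sums positive.

    Raises when the enumeration would exceed ``max_tables`` tables; use
    :func:`fisher_exact_mc` (flagged approximate) for such margins.
    """
    t = _validate(table)
    rows = t.sum(axis=1)
    if _count_tables(rows, int(t[:, 0].sum())) > max_tables:
        raise ValueError(
            "margins exceed the enumeration budget; use fisher_exact_mc "
            "for a Monte-Carlo (approximate) p-value"
        )
    p = _exact_rx2_cached(tuple(int(v) for v in rows), tuple(int(v) for v in t[:, 0]))
    return min(p, 1.0)


def fisher_exact_3x2(table, **kw) -> float:
    """Exact p for a gain/neutral/loss x two-group table."""
    t = np.asarray(table)
    if t.shape != (3, 2):
        raise ValueError("expected a 3 x 2 table")
    return fisher_exact_rx2(t, **kw)


def fisher_exact_2x2(table, **kw) -> float:
    """Two-sided exact p for a 2 x 2 table (same enumeration engine)."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2 x 2 table")
    return fisher_exact_rx2(t, **kw)


def fisher_exact_mc(table, n_draws: int = 100_000, seed: int = 0) -> float:
    """Monte-Carlo estimate of the exact p (for over-budget margins).

    Draws column-1 count vectors from the conditional multivariate
    hypergeometric distribution and reports the fraction of draws no more
    probable than the observed table. Approximate by construction.
    """
    t = _validate(table)
    rows = t.sum(axis=1)
    c1 = int(t[:, 0].sum())
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(rows, c1, size=n_draws)
    logp_obs = float(_logp_terms(t[:, 0], rows))
    logp_draws = _logp_terms(draws, rows)
    return float(np.mean(logp_draws <= logp_obs + np.log1p(TIE_REL_TOL)))
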