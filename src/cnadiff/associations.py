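"""Clinical/molecular association screen on binary covariates.

Every requested variable pair is dichotomized, cross-tabulated into a 2x2
table, and summarised by a two-sided exact test p-value and the phi
coefficient (the Pearson correlation of the 0/1 indicators, with closed
form ``(n11*n00 - n10*n01) / sqrt(r1*r0*c1*c0)``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exact import fisher_exact_2x2

__all__ = [
    "AssociationResult",
    "phi_correlation",
    "binarize",
    "association_screen",
    "DEFAULT_POSITIVE_LEVELS",
]

log = logging.getLogger(__name__)

#: Conventional positive levels for the standard annotation columns.
#: Age and stage carry no default — a dichotomization rule must be supplied.
DEFAULT_POSITIVE_LEVELS: dict = {
    "group": {"smoker", "current"},
    "smoking": {"smoker", "current"},
    "gender": {"female"},
    "race": {"asian"},
    "egfr": {"mutant"},
    "kras": {"mutant"},
}


@dataclass(frozen=True)
class AssociationResult:
    var_x: str
    var_y: str
    n: int
    counts: tuple  # ((n11, n10), (n01, n00))
    p: float
    phi: float


def phi_correlation(x, y) -> float:
    """Pearson correlation of two binary 0/1 vectors.

    Undefined (NaN, logged) when either vector is constant.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1 or len(xa) < 2:
        raise ValueError("x and y must be equal-length vectors of length >= 2")
    if not (set(np.unique(xa)) <= {0.0, 1.0} and set(np.unique(ya)) <= {0.0, 1.0}):
        raise ValueError("inputs must be binary 0/1 vectors")
    if xa.std() == 0 or ya.std() == 0:
        log.warning("constant indicator vector; phi undefined")
        return float("nan")
    return float(np.corrcoef(xa, ya)[0, 1])


def binarize(series: pd.Series, rule) -> pd.Series:
    """Map a covariate column to a 0/1 indicator.

    ``rule`` is either a collection of positive levels or a callable
    applied elementwise. Missing values stay missing.
    """
    if callable(rule):
        out = series.map(lambda v: (np.nan if pd.isna(v) else int(bool(rule(v)))))
    else:
        levels = set(rule)
        out = series.map(lambda v: (np.nan if pd.isna(v) else int(v in levels)))
    return out


def association_screen(
    annotations: pd.DataFrame,
    pairs: Sequence[tuple],
    positive_levels: Mapping[str, object] | None = None,
) -> list[AssociationResult]:
    """Exact p and phi for every variable pair, dropping missing pairwise.

    ``positive_levels`` maps a variable to its positive-level set or a
    callable; it extends/overrides the built-in defaults. Variables without
    a rule (e.g. age, stage) raise a configuration error.
    """
    rules = dict(DEFAULT_POSITIVE_LEVELS)
    if positive_levels:
        rules.update(positive_levels)
    results = []
    for vx, vy in pairs:
        for v in (vx, vy):
            if v not in annotations.columns:
                raise KeyError(f"variable {v!r} not present in annotations")
            if v not in rules:
                raise KeyError(f"no dichotomization rule for variable {v!r}")
        bx = binarize(annotations[vx], rules[vx])
        by = binarize(annotations[vy], rules[vy])
        keep = bx.notna() & by.notna()
        xv = bx[keep].astype(int).to_numpy()
        yv = by[keep].astype(int).to_numpy()
        n11 = int(((xv == 1) & (yv == 1)).sum())
        n10 = int(((xv == 1) & (yv == 0)).sum())
        n01 = int(((xv == 0) & (yv == 1)).sum())
        n00 = int(((xv == 0) & (yv == 0)).sum())
        table = ((n11, n10), (n01, n00))
        if min(n11 + n10, n01 + n00, n11 + n01, n10 + n00) == 0:
            log.warning("degenerate 2x2 margin for (%s, %s); p/phi undefined", vx, vy)
            p, phi = float("nan"), float("nan")
        else:
            p = fisher_exact_2x2(table)
            phi = phi_correlation(xv, yv)
        results.append(
            AssociationResult(var_x=vx, var_y=vy, n=len(xv), counts=table, p=p, phi=phi)
        )
    return results


def association_matrix(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Symmetric phi matrix over all variables seen in the results."""
    variables = []
    for r in results:
        for v in (r.var_x, r.var_y):
            if v not in variables:
                variables.append(v)
    m = pd.DataFrame(np.nan, index=variables, columns=variables, dtype=float)
    np.fill_diagonal(m.values, 1.0)
    for r in results:
        m.loc[r.var_x, r.var_y] = r.phi
        m.loc[r.var_y, r.var_x] = r.phi
    return m
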