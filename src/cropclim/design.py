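"""The 13-term polynomial/interaction expansion of climate anomalies.

The model vocabulary for yield anomalies is a fixed set of thirteen terms in
current-year temperature and drought (SPEI) anomalies, their squares, their
cross-products up to degree two in each variable, and previous-year
("intensification") terms:

====  ==============  =========================
col   name            exponents (dT, dS, dTl, dSl)
====  ==============  =========================
1     intercept       (0, 0, 0, 0)
2     dT              (1, 0, 0, 0)
3     dT2             (2, 0, 0, 0)
4     dS              (0, 1, 0, 0)
5     dS2             (0, 2, 0, 0)
6     dT:dS           (1, 1, 0, 0)
7     dT2:dS          (2, 1, 0, 0)
8     dT:dS2          (1, 2, 0, 0)
9     dT2:dS2         (2, 2, 0, 0)
10    dT_lag          (0, 0, 1, 0)
11    dS_lag          (0, 0, 0, 1)
12    dT_lag:dT       (1, 0, 1, 0)
13    dS_lag:dS       (0, 1, 0, 1)
====  ==============  =========================

Marginality (a lower-order term may not be dropped while a higher-order term
containing it is retained) and the ranking used to find the "highest-order"
terms of a model are both derived from the exponent table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TERM_NAMES",
    "TERM_EXPONENTS",
    "N_TERMS",
    "INTERACTION_TERMS",
    "LINEAR_TERMS",
    "DesignMatrix",
    "build_design",
    "design_row",
    "contains",
    "removable_terms",
    "term_order_rank",
    "highest_order_terms",
]

#: term names, index 0 = column 1
TERM_NAMES: tuple[str, ...] = (
    "intercept",
    "dT",
    "dT2",
    "dS",
    "dS2",
    "dT:dS",
    "dT2:dS",
    "dT:dS2",
    "dT2:dS2",
    "dT_lag",
    "dS_lag",
    "dT_lag:dT",
    "dS_lag:dS",
)

#: exponents of (dT, dS, dT_lag, dS_lag) for each term
TERM_EXPONENTS: np.ndarray = np.array(
    [
        (0, 0, 0, 0),
        (1, 0, 0, 0),
        (2, 0, 0, 0),
        (0, 1, 0, 0),
        (0, 2, 0, 0),
        (1, 1, 0, 0),
        (2, 1, 0, 0),
        (1, 2, 0, 0),
        (2, 2, 0, 0),
        (0, 0, 1, 0),
        (0, 0, 0, 1),
        (1, 0, 1, 0),
        (0, 1, 0, 1),
    ],
    dtype=int,
)

N_TERMS = 13

#: 1-based columns of interaction terms (products of two distinct variables)
INTERACTION_TERMS: tuple[int, ...] = (6, 7, 8, 9, 12, 13)
#: 1-based columns of the purely linear terms (plus intercept)
LINEAR_TERMS: tuple[int, ...] = (1, 2, 4, 10, 11)

_ANOM_COLS = ("d_temp", "d_spei", "d_temp_lag", "d_spei_lag")


def design_row(d_temp: float, d_spei: float, d_temp_lag: float = 0.0,
               d_spei_lag: float = 0.0) -> np.ndarray:
    """Evaluate all 13 terms at a single anomaly point."""
    vals = np.array([d_temp, d_spei, d_temp_lag, d_spei_lag], dtype=float)
    return np.prod(vals[None, :] ** TERM_EXPONENTS, axis=1)


@dataclass
class DesignMatrix:
    """Model matrix for the 13-term expansion, keyed by (region, year).

    Rows whose lagged anomalies are undefined (the first year of each
    series) are dropped before construction, so ``X`` is always complete.
    """

    X: np.ndarray                 # (n, 13)
    y: np.ndarray                 # (n,) response (detrended log yield)
    regions: np.ndarray           # (n,) region label per row
    index: pd.DataFrame           # columns: region, year (and crop if present)
    names: tuple[str, ...] = TERM_NAMES
    mask: tuple[int, ...] = field(default_factory=lambda: tuple(range(1, 14)))

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    def active_X(self, mask: tuple[int, ...] | None = None) -> np.ndarray:
        mask = self.mask if mask is None else mask
        cols = [m - 1 for m in mask]
        return self.X[:, cols]


def build_design(panel: pd.DataFrame, response: str = "d_yield") -> DesignMatrix:
    """Expand an anomaly panel into the 13-column design matrix.

    Parameters
    ----------
    panel
        One row per (region, year) with columns ``d_temp``, ``d_spei``,
        ``d_temp_lag``, ``d_spei_lag`` and the response.  Rows with
        missing lags (first year of each series) are dropped.
    """
    needed = set(_ANOM_COLS) | {response, "region"}
    missing = needed - set(panel.columns)
    if missing:
        raise ValueError(f"panel lacks columns: {sorted(missing)}")
    ok = panel[list(_ANOM_COLS) + [response]].notna().all(axis=1)
    sub = panel.loc[ok].reset_index(drop=True)
    if len(sub) == 0:
        raise ValueError("no usable rows: all rows lack lagged anomalies or response")
    A = sub[list(_ANOM_COLS)].to_numpy(float)          # (n, 4)
    # X[i, j] = prod_k A[i, k] ** E[j, k]
    X = np.prod(A[:, None, :] ** TERM_EXPONENTS[None, :, :], axis=2)
    idx_cols = [c for c in ("region", "crop", "year") if c in sub.columns]
    return DesignMatrix(
        X=X,
        y=sub[response].to_numpy(float),
        regions=sub["region"].to_numpy(),
        index=sub[idx_cols].copy(),
    )


def contains(outer: int, inner: int) -> bool:
    """True if 1-based term ``outer`` contains ``inner`` in the marginality sense."""
    eo, ei = TERM_EXPONENTS[outer - 1], TERM_EXPONENTS[inner - 1]
    return outer != inner and bool(np.all(eo >= ei))


def removable_terms(mask: tuple[int, ...]) -> list[int]:
    """Terms that marginality allows to be dropped from ``mask``.

    The intercept is never removable; a term is blocked while any retained
    higher-order term contains it.
    """
    out = []
    for t in mask:
        if t == 1:
            continue
        if any(contains(other, t) for other in mask if other != t):
            continue
        out.append(t)
    return out


def term_order_rank(term: int) -> tuple[int, int]:
    """Ranking key for polynomial order: interaction beats quadratic beats linear.

    The key is (involves >= 2 distinct variables, total degree); terms are
    compared lexicographically.
    """
    e = TERM_EXPONENTS[term - 1]
    return (int(np.count_nonzero(e) >= 2), int(e.sum()))


def highest_order_terms(mask: tuple[int, ...]) -> list[int]:
    """All retained terms of maximal polynomial order, as a joint-test group."""
    cand = [t for t in mask if t != 1]
    if not cand:
        raise ValueError("mask contains only the intercept; no testable terms")
    top = max(term_order_rank(t) for t in cand)
    return [t for t in cand if term_order_rank(t) == top]
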