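"""Single-region regressions with the 13-term design and BIC selection.

For each top-producing region the same anomaly expansion is fit by ordinary
least squares -- one time series, no random effects -- and terms are removed
greedily (largest p-value first, marginality respected) as long as BIC
decreases.  This is the per-region counterpart to the pooled hierarchical
model and feeds the per-region effect curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .design import (
    DesignMatrix,
    N_TERMS,
    TERM_NAMES,
    removable_terms,
    term_order_rank,
)

__all__ = ["CountryFit", "fit_country", "bic_select"]


@dataclass
class CountryFit:
    """An OLS fit of one region's series on the active terms."""

    region: str
    crop: str
    mask: tuple[int, ...]
    beta: np.ndarray
    cov_beta: np.ndarray          # classical OLS covariance
    sigma2: float                 # ML residual variance (rss / n)
    loglik: float
    bic: float
    n_obs: int
    trace: list[dict] = field(default_factory=list)

    @property
    def term_names(self) -> list[str]:
        return [TERM_NAMES[m - 1] for m in self.mask]

    @property
    def fixef(self) -> pd.Series:
        return pd.Series(self.beta, index=self.term_names)

    @property
    def fixef_cov(self) -> pd.DataFrame:
        return pd.DataFrame(self.cov_beta, index=self.term_names,
                            columns=self.term_names)

    def pvalues(self) -> pd.Series:
        """Classical two-sided t-based p-values."""
        df = self.n_obs - len(self.mask)
        se = np.sqrt(np.diag(self.cov_beta))
        tv = np.divide(self.beta, se, out=np.full_like(self.beta, np.nan),
                       where=se > 0)
        return pd.Series(2 * t_dist.sf(np.abs(tv), df), index=self.term_names)

    def to_dict(self) -> dict:
        return {"region": self.region, "crop": self.crop, "mask": list(self.mask),
                "beta": dict(zip(self.term_names, map(float, self.beta))),
                "bic": float(self.bic), "loglik": float(self.loglik),
                "n_obs": self.n_obs}


def _bic(loglik: float, k: int, n: int) -> float:
    # parameters: k coefficients + the residual variance
    return -2.0 * loglik + (k + 1) * np.log(n)


def fit_country(
    design: DesignMatrix,
    mask: tuple[int, ...] | None = None,
    region: str | None = None,
    crop: str = "",
    min_extra_obs: int = 5,
) -> CountryFit:
    """OLS on the active columns of one region's design rows.

    Requires ``n >= len(mask) + min_extra_obs`` observations; rank
    deficiency is reported with the names of the offending columns.
    """
    if region is not None:
        sel = design.regions == region
        X_all, y = design.X[sel], design.y[sel]
    else:
        regions = pd.unique(design.regions)
        if len(regions) != 1:
            raise ValueError("design holds several regions; pass region=...")
        region = str(regions[0])
        X_all, y = design.X, design.y
    mask = tuple(mask) if mask is not None else tuple(range(1, N_TERMS + 1))
    X = X_all[:, [m - 1 for m in mask]]
    n, k = X.shape
    if n < k + min_extra_obs:
        raise ValueError(
            f"{region}: n={n} below required {k}+{min_extra_obs} for {k} terms")
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    if np.any(diag < 1e-10 * diag.max()):
        bad = [TERM_NAMES[mask[j] - 1] for j in np.where(diag < 1e-10 * diag.max())[0]]
        raise np.linalg.LinAlgError(f"{region}: rank-deficient design, columns {bad}")
    beta = np.linalg.solve(r, q.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2_ml = rss / n
    s2_unbiased = rss / (n - k) if n > k else np.nan
    XtX_inv = np.linalg.inv(r.T @ r)
    cov = s2_unbiased * XtX_inv
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2_ml) + 1) if rss > 0 else np.inf
    if rss == 0:  # exact fit: degenerate likelihood, flag via -inf BIC path
        loglik = np.inf
    return CountryFit(
        region=str(region), crop=crop, mask=mask, beta=beta, cov_beta=cov,
        sigma2=sigma2_ml, loglik=loglik,
        bic=-np.inf if rss == 0 else _bic(loglik, k, n), n_obs=n,
    )


def bic_select(
    design: DesignMatrix,
    start_mask: tuple[int, ...] | None = None,
    region: str | None = None,
    crop: str = "",
    order: str = "pvalue",
    allowed: tuple[int, ...] | None = None,
) -> CountryFit:
    """Backward selection: drop non-significant terms while BIC decreases.

    At each step the candidate is the removable term with the largest
    p-value (``order="pvalue"``, default; ties broken by higher polynomial
    order, then higher column index), or the removal that lowers BIC most
    (``order="bic"``).  Selection stops at the first BIC increase.  The
    full trace is recorded and the reported BIC is its minimum.
    """
    mask = tuple(start_mask) if start_mask is not None else tuple(range(1, N_TERMS + 1))
    if allowed is not None:
        mask = tuple(t for t in mask if t == 1 or t in allowed)
    fit = fit_country(design, mask, region=region, crop=crop)
    trace = [{"mask": list(mask), "bic": fit.bic, "removed": None}]
    while True:
        cand = removable_terms(fit.mask)
        if not cand:
            break
        if order == "pvalue":
            pv = fit.pvalues()
            worst = max(cand, key=lambda t: (pv[TERM_NAMES[t - 1]],
                                             term_order_rank(t), t))
            trial_masks = [tuple(t for t in fit.mask if t != worst)]
        elif order == "bic":
            trial_masks = [tuple(t for t in fit.mask if t != c) for c in cand]
        else:
            raise ValueError(f"unknown order {order!r}")
        trials = [fit_country(design, m, region=region, crop=crop)
                  for m in trial_masks]
        best = min(trials, key=lambda f: f.bic)
        if best.bic >= fit.bic:
            break
        removed = set(fit.mask) - set(best.mask)
        trace.append({"mask": list(best.mask), "bic": best.bic,
                      "removed": TERM_NAMES[removed.pop() - 1]})
        fit = best
    fit.trace = trace
    return fit
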