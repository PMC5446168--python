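"""Hierarchical model of yield anomalies with region-varying sensitivities.

The panel model couples all regions for one crop:

    d_yield[c, t] = x[c, t] @ (beta + b_c) + eps[c, t]

where ``x`` is the 13-term anomaly expansion (see :mod:`cropclim.design`),
``beta`` are the global fixed effects, ``b_c ~ N(0, D)`` are per-region
deviations with *diagonal* covariance ``D = diag(d_1, ..., d_13)``, and
``eps[c, t] ~ N(0, sigma2 * phi_c)`` with region variance ratios ``phi_c``
(``phi_1 = 1`` for the first region in sort order).  Random effects share the
active-term mask with the fixed effects: eliminating a term removes both its
global slope and its per-region deviations.

Estimation is maximum likelihood.  The fixed effects and the residual scale
are profiled out in closed form (GLS at each variance evaluation), and the
remaining variance parameters -- log relative random-effect variances and log
variance ratios -- are optimized quasi-Newton with an analytic gradient.
ML (not REML) is the default so that likelihoods, BIC and the elimination
path are comparable across fixed-effect structures; REML is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.stats import chi2, norm

from .design import DesignMatrix, N_TERMS, TERM_NAMES, removable_terms

__all__ = [
    "VarianceParams",
    "MixedFit",
    "marginal_loglik",
    "fit_mixed",
    "wald_tests",
    "joint_wald_test",
    "backward_eliminate",
    "blups",
    "information_criteria",
]

_LOG_CLAMP = 30.0   # variance parameters live in exp([-30, 30]) x scale


@dataclass
class VarianceParams:
    """Variance components: diagonal D, residual variance, region ratios."""

    D_diag: np.ndarray            # (13,) random-effect variances (0 = inactive)
    sigma2: float
    phi: pd.Series                # per-region ratio, first region == 1.0

    def __post_init__(self):
        self.D_diag = np.asarray(self.D_diag, float)
        if self.D_diag.shape != (N_TERMS,):
            raise ValueError("D_diag must have length 13")
        if np.any(self.D_diag < 0):
            raise ValueError("D_diag must be non-negative")
        if not self.sigma2 > 0:
            raise ValueError("sigma2 must be positive")
        if np.any(self.phi.to_numpy() <= 0):
            raise ValueError("phi must be positive")

    @property
    def boundary_flags(self) -> np.ndarray:
        """Active variances clamped at the lower boundary."""
        return (self.D_diag > 0) & (self.D_diag < self.sigma2 * np.exp(-_LOG_CLAMP + 1))


@dataclass
class MixedFit:
    """A fitted hierarchical model."""

    mask: tuple[int, ...]
    beta: np.ndarray              # active fixed effects, in mask order
    cov_beta: np.ndarray
    variance: VarianceParams
    blup: pd.DataFrame            # regions x 13 (inactive terms are 0)
    loglik: float
    n_obs: int
    n_regions: int
    converged: bool
    n_iter: int
    message: str = ""
    method: str = "ML"
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

    def to_dict(self) -> dict:
        return {
            "mask": list(self.mask),
            "beta": dict(zip(self.term_names, map(float, self.beta))),
            "cov_beta": self.cov_beta.tolist(),
            "D_diag": self.variance.D_diag.tolist(),
            "sigma2": float(self.variance.sigma2),
            "phi": {str(k): float(v) for k, v in self.variance.phi.items()},
            "blup": {str(r): row.tolist() for r, row in self.blup.iterrows()},
            "loglik": float(self.loglik),
            "n_obs": self.n_obs,
            "n_regions": self.n_regions,
            "converged": self.converged,
            "method": self.method,
        }


# ---------------------------------------------------------------------------
# block data


class _Blocks:
    """Per-region views of the active design."""

    def __init__(self, design: DesignMatrix, mask: tuple[int, ...]):
        self.mask = tuple(mask)
        cols = [m - 1 for m in self.mask]
        X = design.X[:, cols]
        y = design.y
        self.regions = np.array(sorted(pd.unique(design.regions)))
        self.X, self.y = [], []
        for r in self.regions:
            sel = design.regions == r
            self.X.append(np.ascontiguousarray(X[sel]))
            self.y.append(np.ascontiguousarray(y[sel]))
        self.n_obs = len(y)
        self.p = X.shape[1]
        self.C = len(self.regions)


def marginal_loglik(
    design: DesignMatrix,
    beta: np.ndarray,
    variance: VarianceParams,
    mask: tuple[int, ...] | None = None,
) -> float:
    """Exact Gaussian log-likelihood, summed over region blocks.

    ``V_c = Z_c D Z_c' + sigma2 * phi_c * I`` with ``Z_c`` equal to the
    active design columns.  Direct per-block Cholesky evaluation; used for
    inference checks and as the quantity the optimizer maximizes.
    """
    mask = tuple(mask) if mask is not None else tuple(design.mask)
    blocks = _Blocks(design, mask)
    d = variance.D_diag[[m - 1 for m in mask]]
    ll = 0.0
    for ci, r in enumerate(blocks.regions):
        Xc, yc = blocks.X[ci], blocks.y[ci]
        nc = len(yc)
        Vc = (Xc * d) @ Xc.T + variance.sigma2 * float(variance.phi[r]) * np.eye(nc)
        try:
            L = np.linalg.cholesky(Vc)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"block covariance for region {r} is not PD "
                f"(cond ~ {np.linalg.cond(Vc):.2e})"
            ) from err
        rc = yc - Xc @ np.asarray(beta, float)
        u = solve_triangular(L, rc, lower=True)
        ll += -0.5 * (nc * np.log(2 * np.pi) + 2 * np.sum(np.log(np.diag(L)))
                      + u @ u)
    return float(ll)


# ---------------------------------------------------------------------------
# profiled ML machinery


def _profile_nll_grad(theta, blocks: _Blocks, rand_idx, reml: bool):
    """Negative profiled log-likelihood and gradient.

    theta = [log g_j for active random terms, log phi_c for c >= 2] with
    g = D / sigma2.  beta and sigma2 are profiled in closed form.
    """
    q = len(rand_idx)
    g = np.exp(theta[:q])
    phi = np.concatenate([[1.0], np.exp(theta[q:])])

    XtWiX = np.zeros((blocks.p, blocks.p))
    XtWiy = np.zeros(blocks.p)
    logdet = 0.0
    chols, LiX, Liy = [], [], []
    for ci in range(blocks.C):
        Xc, yc = blocks.X[ci], blocks.y[ci]
        nc = len(yc)
        Zc = Xc[:, rand_idx]
        W = (Zc * g) @ Zc.T + phi[ci] * np.eye(nc)
        L = np.linalg.cholesky(W)
        lx = solve_triangular(L, Xc, lower=True)
        ly = solve_triangular(L, yc, lower=True)
        XtWiX += lx.T @ lx
        XtWiy += lx.T @ ly
        logdet += 2 * np.sum(np.log(np.diag(L)))
        chols.append(L)
        LiX.append(lx)
        Liy.append(ly)

    cf = cho_factor(XtWiX)
    beta = cho_solve(cf, XtWiy)
    N = blocks.n_obs
    quad = 0.0
    Lir = []
    for ci in range(blocks.C):
        lr = Liy[ci] - LiX[ci] @ beta
        quad += lr @ lr
        Lir.append(lr)
    dof = N - blocks.p if reml else N
    sigma2 = quad / dof
    nll = 0.5 * (N * np.log(2 * np.pi) + dof * np.log(sigma2) + logdet + dof)
    if reml:
        nll += 0.5 * (2 * np.sum(np.log(np.diag(cf[0]))) - blocks.p * np.log(2 * np.pi))

    grad = np.zeros_like(theta)
    for ci in range(blocks.C):
        L, lx, lr = chols[ci], LiX[ci], Lir[ci]
        lz = lx[:, rand_idx]                      # L^-1 Z_c
        # d/d log g_j : dW = g_j z_j z_j'
        tr_j = np.einsum("ij,ij->j", lz, lz)      # z_j' W^-1 z_j
        qd_j = (lz.T @ lr) ** 2                   # (z_j' W^-1 r)^2
        grad[:q] += 0.5 * g * (tr_j - qd_j / sigma2)
        # d/d log phi_c : dW = phi_c I  (c >= 2)
        if ci >= 1:
            Li = solve_triangular(L, np.eye(L.shape[0]), lower=True)
            trW = float(np.sum(Li * Li))
            wir = solve_triangular(L, lr, lower=True, trans="T")
            grad[q + ci - 1] = 0.5 * phi[ci] * (trW - (wir @ wir) / sigma2)
    return nll, grad, beta, sigma2, phi


def fit_mixed(
    design: DesignMatrix,
    mask: tuple[int, ...] | None = None,
    random_terms: tuple[int, ...] | None = None,
    reml: bool = False,
    start: np.ndarray | None = None,
    multi_start: bool = False,
    warm: "MixedFit | None" = None,
    gtol: float = 1e-6,
) -> MixedFit:
    """Maximum-likelihood fit of the hierarchical model.

    Parameters
    ----------
    design
        The 13-column design (see :func:`cropclim.design.build_design`).
    mask
        Active 1-based term columns; defaults to all 13.
    random_terms
        Terms carrying per-region random deviations; defaults to ``mask``
        (fixed and random parts move together).
    warm
        A previous fit on like-structured data; its variance parameters
        seed the optimizer (used by the noise simulation for speed).
    """
    mask = tuple(mask) if mask is not None else tuple(design.mask)
    if 1 not in mask:
        raise ValueError("the intercept (term 1) must stay in the model")
    blocks = _Blocks(design, mask)
    if blocks.C < 2:
        raise ValueError("need at least 2 regions; use the single-region OLS path")
    _check_rank(blocks, mask)
    random_terms = tuple(random_terms) if random_terms is not None else mask
    rand_idx = [mask.index(t) for t in random_terms]
    q = len(rand_idx)
    n_theta = q + blocks.C - 1

    starts: list[np.ndarray] = []
    if start is not None:
        starts.append(np.asarray(start, float))
    elif warm is not None and tuple(warm.mask) == mask and warm.n_regions == blocks.C:
        g0 = warm.variance.D_diag[[m - 1 for m in random_terms]] / warm.variance.sigma2
        th = np.concatenate([np.log(np.maximum(g0, 1e-10)),
                             np.log(warm.variance.phi.to_numpy()[1:])])
        starts.append(th)
    else:
        starts.append(np.concatenate([np.full(q, np.log(0.1)), np.zeros(blocks.C - 1)]))
        if multi_start:
            starts.append(np.concatenate([np.full(q, np.log(1e-3)),
                                          np.zeros(blocks.C - 1)]))
            starts.append(np.concatenate([np.full(q, 0.0), np.zeros(blocks.C - 1)]))

    bounds = [(-_LOG_CLAMP, _LOG_CLAMP)] * n_theta

    # the analytic gradient omits the REML log|X'W^-1X| derivative, so REML
    # falls back to finite differences
    if reml:
        def obj(theta):
            return _profile_nll_grad(theta, blocks, rand_idx, True)[0]
        jac = None
    else:
        def obj(theta):
            nll, grad, *_ = _profile_nll_grad(theta, blocks, rand_idx, False)
            return nll, grad
        jac = True

    best = None
    for th0 in starts:
        res = optimize.minimize(
            obj, th0, jac=jac, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": gtol},
        )
        if best is None or res.fun < best.fun:
            best = res
    res = best

    nll, grad, beta, sigma2, phi = _profile_nll_grad(res.x, blocks, rand_idx, reml)
    g = np.exp(res.x[:q])
    D_diag = np.zeros(N_TERMS)
    for j, t in enumerate(random_terms):
        D_diag[t - 1] = sigma2 * g[j]
    variance = VarianceParams(
        D_diag=D_diag, sigma2=float(sigma2),
        phi=pd.Series(phi, index=blocks.regions),
    )

    # covariance of beta at the ML variance estimates
    XtWiX = np.zeros((blocks.p, blocks.p))
    for ci in range(blocks.C):
        Xc = blocks.X[ci]
        Zc = Xc[:, rand_idx]
        W = (Zc * g) @ Zc.T + phi[ci] * np.eye(Xc.shape[0])
        L = np.linalg.cholesky(W)
        lx = solve_triangular(L, Xc, lower=True)
        XtWiX += lx.T @ lx
    cov_beta = sigma2 * np.linalg.inv(XtWiX)
    cov_beta = 0.5 * (cov_beta + cov_beta.T)

    fit = MixedFit(
        mask=mask, beta=beta, cov_beta=cov_beta, variance=variance,
        blup=pd.DataFrame(np.zeros((blocks.C, N_TERMS)), index=blocks.regions,
                          columns=TERM_NAMES),
        loglik=-nll, n_obs=blocks.n_obs, n_regions=blocks.C,
        converged=bool(res.success and np.linalg.norm(grad, np.inf) < 1e-3),
        n_iter=int(res.nit), message=str(res.message),
        method="REML" if reml else "ML",
    )
    fit.blup = blups(fit, design)
    return fit


def _check_rank(blocks: _Blocks, mask) -> None:
    Xall = np.vstack(blocks.X)
    s = np.linalg.svd(Xall, compute_uv=False)
    if s[-1] < 1e-10 * s[0]:
        # diagnose which columns are involved
        _, R = np.linalg.qr(Xall)
        bad = [TERM_NAMES[mask[j] - 1] for j in range(len(mask))
               if abs(R[j, j]) < 1e-8 * abs(R[0, 0])]
        raise np.linalg.LinAlgError(f"singular design; suspect columns: {bad}")


def gls_at(
    design: DesignMatrix,
    variance: VarianceParams,
    mask: tuple[int, ...] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Generalized least squares at *fixed* variance parameters.

    Returns (beta, cov_beta).  At ``D = 0`` and ``phi == 1`` this is exactly
    ordinary least squares -- the degenerate limit of the hierarchical model.
    """
    mask = tuple(mask) if mask is not None else tuple(design.mask)
    blocks = _Blocks(design, mask)
    d = variance.D_diag[[m - 1 for m in mask]]
    XtViX = np.zeros((blocks.p, blocks.p))
    XtViy = np.zeros(blocks.p)
    for ci, r in enumerate(blocks.regions):
        Xc, yc = blocks.X[ci], blocks.y[ci]
        Vc = (Xc * d) @ Xc.T + variance.sigma2 * float(variance.phi[r]) * np.eye(len(yc))
        L = np.linalg.cholesky(Vc)
        lx = solve_triangular(L, Xc, lower=True)
        ly = solve_triangular(L, yc, lower=True)
        XtViX += lx.T @ lx
        XtViy += lx.T @ ly
    cov = np.linalg.inv(XtViX)
    return cov @ XtViy, 0.5 * (cov + cov.T)


def blups(fit: MixedFit, design: DesignMatrix) -> pd.DataFrame:
    """Empirical BLUPs ``b_c = D Z_c' V_c^-1 (y_c - X_c beta)`` per region."""
    mask = fit.mask
    blocks = _Blocks(design, mask)
    d = fit.variance.D_diag[[m - 1 for m in mask]]
    out = pd.DataFrame(np.zeros((blocks.C, N_TERMS)), index=blocks.regions,
                       columns=TERM_NAMES)
    for ci, r in enumerate(blocks.regions):
        Xc, yc = blocks.X[ci], blocks.y[ci]
        nc = len(yc)
        Vc = (Xc * d) @ Xc.T + fit.variance.sigma2 * float(fit.variance.phi[r]) * np.eye(nc)
        rc = yc - Xc @ fit.beta
        b_active = d * (Xc.T @ np.linalg.solve(Vc, rc))
        for j, t in enumerate(mask):
            out.loc[r, TERM_NAMES[t - 1]] = b_active[j]
    return out


# ---------------------------------------------------------------------------
# inference


def wald_tests(fit: MixedFit) -> pd.DataFrame:
    """Per-coefficient Wald z tests with two-sided normal p-values."""
    se = np.sqrt(np.diag(fit.cov_beta))
    rows = []
    for j, name in enumerate(fit.term_names):
        if se[j] == 0:
            rows.append({"term": name, "estimate": fit.beta[j], "se": 0.0,
                         "z": np.nan, "p": np.nan, "flag": "zero se"})
            continue
        z = fit.beta[j] / se[j]
        rows.append({"term": name, "estimate": fit.beta[j], "se": se[j],
                     "z": z, "p": 2 * norm.sf(abs(z)), "flag": ""})
    return pd.DataFrame(rows).set_index("term")


def joint_wald_test(fit: MixedFit, terms: tuple[int, ...]) -> dict:
    """Joint chi-square test that a group of terms is zero."""
    idx = [fit.mask.index(t) for t in terms]
    b = fit.beta[idx]
    V = fit.cov_beta[np.ix_(idx, idx)]
    stat = float(b @ np.linalg.solve(V, b))
    df = len(idx)
    return {"stat": stat, "df": df, "p": float(chi2.sf(stat, df))}


def information_criteria(fit: MixedFit) -> dict:
    """BIC/AIC at the ML fit, counting fixed + variance parameters."""
    # parameters: active fixed effects + active D entries + sigma2 + (C-1) phis
    n_var = int(np.count_nonzero(fit.variance.D_diag))
    p = len(fit.mask) + n_var + 1 + (fit.n_regions - 1)
    n = fit.n_obs
    return {"BIC": -2 * fit.loglik + p * np.log(n),
            "AIC": -2 * fit.loglik + 2 * p,
            "n_params": p}


def backward_eliminate(
    design: DesignMatrix,
    alpha: float = 0.05,
    allowed: tuple[int, ...] | None = None,
    start_mask: tuple[int, ...] | None = None,
    **fit_kw,
) -> MixedFit:
    """Marginality-respecting backward elimination of non-significant terms.

    Starting from the full (or given) mask, the least-significant removable
    term with p > ``alpha`` is dropped -- fixed and random parts together --
    and the model refit, until every removable term is significant.  The
    elimination trace is stored on the returned fit.
    """
    mask = tuple(start_mask) if start_mask is not None else tuple(range(1, N_TERMS + 1))
    if allowed is not None:
        mask = tuple(t for t in mask if t == 1 or t in allowed)
    trace = []
    while True:
        fit = fit_mixed(design, mask=mask, **fit_kw)
        tests = wald_tests(fit)
        cand = removable_terms(mask)
        if not cand:
            break
        pvals = {t: tests.loc[TERM_NAMES[t - 1], "p"] for t in cand}
        worst = max(pvals, key=lambda t: (pvals[t], TERM_NAMES[t - 1]))
        if pvals[worst] <= alpha or np.isnan(pvals[worst]):
            break
        trace.append({"removed": TERM_NAMES[worst - 1], "p": float(pvals[worst]),
                      "loglik": fit.loglik, "mask": list(mask)})
        mask = tuple(t for t in mask if t != worst)
    fit.trace = trace
    return fit
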