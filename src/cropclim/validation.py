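"""Leave-one-out cross-validation and nested model comparison.

Every observation is predicted from a model estimated without it; prediction
errors on the log scale are summarized as RMSE (root mean square error) and
MAE (median absolute error).  The model structure (active-term mask) is
fixed *before* cross-validation -- no re-selection inside folds.  For the
hierarchical model, variance parameters are frozen at their full-data ML
values by default and only the fixed effects and the held-out region's BLUP
are re-estimated per fold; a full per-fold refit is available but costs a
model fit per observation.

Three nested variants mirror the standard robustness table: the selected
model (Full), the model re-selected without interaction terms (NoInter),
and a linear-terms-only model (OnlyLin).  When a simpler variant coincides
with the richer one, its cells are left empty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from .country import bic_select, fit_country
from .design import DesignMatrix, INTERACTION_TERMS, LINEAR_TERMS
from .mixed import MixedFit, backward_eliminate, fit_mixed

__all__ = ["CVResult", "loocv", "compare_models"]


@dataclass
class CVResult:
    """LOOCV prediction-error summary for one model variant."""

    model_id: str
    scope: str
    rmse: float
    mae: float                    # median absolute error
    n_pred: int
    mask: tuple[int, ...] = ()
    skipped: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"model": self.model_id, "scope": self.scope,
                "rmse": self.rmse, "mae": self.mae, "n": self.n_pred,
                "mask": list(self.mask)}


def _loocv_mixed(design: DesignMatrix, fit: MixedFit,
                 refit_variance: bool, model_id: str) -> CVResult:
    mask = fit.mask
    cols = [m - 1 for m in mask]
    g = fit.variance.D_diag[cols] / fit.variance.sigma2
    regions = sorted(pd.unique(design.regions))
    Xa = design.X[:, cols]
    y = design.y

    # per-region frozen-variance GLS pieces
    blocks = {}
    p = len(cols)
    A_tot = np.zeros((p, p))
    v_tot = np.zeros(p)
    for r in regions:
        sel = np.where(design.regions == r)[0]
        Xc, yc = Xa[sel], y[sel]
        phi = float(fit.variance.phi[r])
        W = (Xc * g) @ Xc.T + phi * np.eye(len(sel))
        L = np.linalg.cholesky(W)
        lx = solve_triangular(L, Xc, lower=True)
        ly = solve_triangular(L, yc, lower=True)
        A_c, v_c = lx.T @ lx, lx.T @ ly
        A_tot += A_c
        v_tot += v_c
        blocks[r] = (sel, Xc, yc, phi, A_c, v_c)

    errors, skipped = [], []
    for r in regions:
        sel, Xc, yc, phi, A_c, v_c = blocks[r]
        nc = len(sel)
        if nc - 1 < 3:
            skipped.append({"region": r, "reason": f"region reduced to {nc - 1} rows"})
            continue
        for i in range(nc):
            keep = np.arange(nc) != i
            Xci, yci = Xc[keep], yc[keep]
            if refit_variance:
                sub = _subset_design(design, np.concatenate(
                    [np.where(design.regions != r)[0], sel[keep]]))
                f_i = fit_mixed(sub, mask=mask, warm=fit)
                beta = f_i.beta
                b = f_i.blup.loc[r].to_numpy()[cols]
            else:
                W = (Xci * g) @ Xci.T + phi * np.eye(nc - 1)
                L = np.linalg.cholesky(W)
                lx = solve_triangular(L, Xci, lower=True)
                ly = solve_triangular(L, yci, lower=True)
                A_ci, v_ci = lx.T @ lx, lx.T @ ly
                beta = np.linalg.solve(A_tot - A_c + A_ci, v_tot - v_c + v_ci)
                lr = ly - lx @ beta
                wir = solve_triangular(L, lr, lower=True, trans="T")
                b = g * (Xci.T @ wir)
            pred = Xc[i] @ beta + Xc[i] @ b
            errors.append(yc[i] - pred)
    errors = np.asarray(errors)
    return CVResult(model_id=model_id, scope="global",
                    rmse=float(np.sqrt(np.mean(errors**2))),
                    mae=float(np.median(np.abs(errors))),
                    n_pred=len(errors), mask=mask, skipped=skipped)


def _subset_design(design: DesignMatrix, rows: np.ndarray) -> DesignMatrix:
    rows = np.sort(rows)
    return DesignMatrix(X=design.X[rows], y=design.y[rows],
                        regions=design.regions[rows],
                        index=design.index.iloc[rows].reset_index(drop=True))


def _loocv_ols(design: DesignMatrix, mask, region, crop, model_id) -> CVResult:
    sel = np.where(design.regions == region)[0] if region is not None \
        else np.arange(design.n_obs)
    errors = []
    for i in range(len(sel)):
        keep = sel[np.arange(len(sel)) != i]
        sub = _subset_design(design, keep)
        f = fit_country(sub, mask, crop=crop, min_extra_obs=1)
        c = design.X[sel[i], [m - 1 for m in mask]]
        errors.append(design.y[sel[i]] - c @ f.beta)
    errors = np.asarray(errors)
    return CVResult(model_id=model_id, scope=str(region) if region else "series",
                    rmse=float(np.sqrt(np.mean(errors**2))),
                    mae=float(np.median(np.abs(errors))),
                    n_pred=len(errors), mask=tuple(mask))


def loocv(
    design: DesignMatrix,
    fit: MixedFit | None = None,
    mask: tuple[int, ...] | None = None,
    kind: str = "mixed",
    region: str | None = None,
    crop: str = "",
    refit_variance: bool = False,
    model_id: str = "model",
) -> CVResult:
    """Leave-one-out cross-validation for a fixed model structure.

    ``kind="mixed"`` requires ``fit`` (its mask and variance estimates are
    used); ``kind="ols"`` requires ``mask`` and, for multi-region designs,
    ``region``.  LOOCV involves no randomness: results are reproducible
    bit-for-bit and invariant to observation order.
    """
    if kind == "mixed":
        if fit is None:
            raise ValueError("mixed LOOCV needs a fitted model")
        return _loocv_mixed(design, fit, refit_variance, model_id)
    if kind == "ols":
        if mask is None:
            raise ValueError("OLS LOOCV needs a mask")
        return _loocv_ols(design, mask, region, crop, model_id)
    raise ValueError(f"unknown kind {kind!r}")


def _nointer_mask(full_mask: tuple[int, ...]) -> tuple[int, ...]:
    return tuple(t for t in full_mask if t not in INTERACTION_TERMS)


def compare_models(
    design: DesignMatrix,
    level: str = "global",
    region: str | None = None,
    crop: str = "",
    alpha: float = 0.05,
    full_fit: MixedFit | None = None,
    refit_variance: bool = False,
) -> pd.DataFrame:
    """Full / NoInter / OnlyLin LOOCV comparison (the robustness table rows).

    Full is the backward-eliminated model (or ``full_fit`` if provided);
    NoInter starts from Full without interaction columns and is
    re-eliminated with interactions excluded; OnlyLin uses the linear
    columns (1, 2, 4, 10, 11) as-is.  Variants whose formula equals the
    richer one produce empty (NaN) cells.
    """
    allowed_nointer = tuple(t for t in range(1, 14) if t not in INTERACTION_TERMS)
    if level == "global":
        full = full_fit if full_fit is not None else backward_eliminate(design, alpha)
        nointer = backward_eliminate(design, alpha, allowed=allowed_nointer,
                                     start_mask=_nointer_mask(full.mask))
        masks = {"Full": full.mask, "NoInter": nointer.mask,
                 "OnlyLin": tuple(LINEAR_TERMS)}
        fits = {"Full": full, "NoInter": nointer,
                "OnlyLin": fit_mixed(design, mask=tuple(LINEAR_TERMS))}
        run = {v: (lambda f=fits[v], v=v: loocv(design, fit=f, kind="mixed",
                                                refit_variance=refit_variance,
                                                model_id=v))
               for v in masks}
    elif level == "region":
        full_c = bic_select(design, region=region, crop=crop)
        nointer_c = bic_select(design, start_mask=_nointer_mask(full_c.mask),
                               region=region, crop=crop, allowed=allowed_nointer)
        masks = {"Full": full_c.mask, "NoInter": nointer_c.mask,
                 "OnlyLin": tuple(LINEAR_TERMS)}
        run = {v: (lambda m=masks[v], v=v: loocv(design, mask=m, kind="ols",
                                                 region=region, crop=crop,
                                                 model_id=v))
               for v in masks}
    else:
        raise ValueError(f"unknown level {level!r}")

    rows = []
    shown: dict[str, tuple] = {}
    order = ["Full", "NoInter", "OnlyLin"]
    for i, variant in enumerate(order):
        same_as_richer = any(set(masks[variant]) == set(masks[r])
                             for r in order[:i])
        if same_as_richer:
            rows.append({"model": variant, "rmse": np.nan, "mae": np.nan,
                         "n": np.nan, "mask": list(masks[variant]),
                         "note": "same formula as richer model"})
            continue
        res = run[variant]()
        shown[variant] = masks[variant]
        d = res.to_dict()
        d["note"] = ""
        rows.append(d)
    out = pd.DataFrame(rows)
    out["crop"] = crop
    out["level"] = level if level == "global" else str(region)
    return out
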