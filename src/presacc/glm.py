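"""Per-sensor condition-template GLM.

For each participant and combined-gradiometer site, the Saccade+stimulus
evoked gradient Y(t) over the [-0.6, 0] s window is modelled as

    Y = beta_saccade * X_saccade + beta_stimulus * X_stimulus + eps

where the regressors are the Saccade-only and Stimulus-only evoked
gradients of the same site. All traces are baseline-corrected, so no
intercept is included by default (an ``intercept`` flag exists for
sensitivity analyses). Ordinary least squares over time samples, all
samples equally weighted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .layout import SensorLayout

__all__ = [
    "GlmResult",
    "fit_condition_glm",
    "fit_condition_glm_batch",
    "variance_explained",
    "hemispheric_median",
]


@dataclass
class GlmResult:
    beta_saccade: float
    beta_stimulus: float
    intercept: float
    y_hat: np.ndarray
    residual: np.ndarray      # eps = Y - Y_hat, full length
    r2: float                 # 1 - SS_res / SS_tot, SS_tot about the mean of Y
    participant: int = -1
    site: str = ""


def _r2(y: np.ndarray, resid: np.ndarray) -> float:
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot <= 0:
        warnings.warn("zero-variance response; R^2 undefined")
        return float("nan")
    return 1.0 - float((resid**2).sum()) / ss_tot


def fit_condition_glm(y, x_saccade, x_stimulus, intercept: bool = False,
                      participant: int = -1, site: str = "") -> GlmResult:
    """OLS fit of one site's evoked trace on the two condition templates.

    Collinear regressors are handled by the minimum-norm least-squares
    solution (with a warning).
    """
    y = np.asarray(y, dtype=float)
    xs = np.asarray(x_saccade, dtype=float)
    xt = np.asarray(x_stimulus, dtype=float)
    if not (len(y) == len(xs) == len(xt)):
        raise ValueError("response and regressors must have equal length")
    if not (np.any(xs) or np.any(xt)):
        raise ValueError("both regressors are identically zero")
    cols = [xs, xt]
    if intercept:
        cols.append(np.ones_like(y))
    X = np.column_stack(cols)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        warnings.warn("collinear regressors; minimum-norm solution returned")
    y_hat = X @ beta
    resid = y - y_hat
    return GlmResult(beta_saccade=float(beta[0]), beta_stimulus=float(beta[1]),
                     intercept=float(beta[2]) if intercept else 0.0,
                     y_hat=y_hat, residual=resid, r2=_r2(y, resid),
                     participant=participant, site=site)


def fit_condition_glm_batch(Y: np.ndarray, Xs: np.ndarray, Xt: np.ndarray):
    """Vectorized per-site OLS (no intercept) via 2x2 normal equations.

    Y, Xs, Xt: (n_sites, n_samples). Returns (betas (n_sites, 2),
    residuals (n_sites, n_samples), r2 (n_sites,)). Rank-deficient sites
    fall back to the minimum-norm solution.
    """
    a = np.einsum("st,st->s", Xs, Xs)
    b = np.einsum("st,st->s", Xs, Xt)
    c = np.einsum("st,st->s", Xt, Xt)
    p = np.einsum("st,st->s", Xs, Y)
    q = np.einsum("st,st->s", Xt, Y)
    det = a * c - b * b
    scale = np.maximum(a, c)
    betas = np.empty((Y.shape[0], 2))
    good = det > 1e-12 * np.maximum(scale**2, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        betas[:, 0] = (c * p - b * q) / det
        betas[:, 1] = (a * q - b * p) / det
    for s in np.flatnonzero(~good):
        X = np.column_stack([Xs[s], Xt[s]])
        betas[s], *_ = np.linalg.lstsq(X, Y[s], rcond=None)
    resid = Y - betas[:, :1] * Xs - betas[:, 1:] * Xt
    ss_tot = ((Y - Y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - (resid**2).sum(axis=1) / ss_tot
    r2[ss_tot <= 0] = np.nan
    return betas, resid, r2


def variance_explained(result: GlmResult) -> float:
    """Proportion of variance explained by the fit (about the mean of Y)."""
    return result.r2


def hemispheric_median(values_per_site, layout: SensorLayout, side: str) -> float:
    """Median of a per-site quantity over one hemisphere (midline excluded)."""
    idx = layout.hemisphere_sites(side)
    if idx.size == 0:
        raise ValueError(f"hemisphere {side!r} has no sites")
    return float(np.median(np.asarray(values_per_site)[idx]))
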