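"""Expression-dependent empirical-Bayes shrinkage of variance estimates.

Each variance class (residual or random-effect) is modelled hierarchically: the
observed estimate s² given the true σ² is scaled-χ²_d, and 1/σ² has a scaled-χ²
prior with df d₀ and location s₀², both allowed to vary smoothly with the gene's
average log expression α.  The hyperparameters are recovered by the log-moment
method: with e = log s² − ψ(d/2) + log(d/2),

    E[e]   = log s₀² − ψ(d₀/2) + log(d₀/2)
    Var[e] = ψ′(d/2) + ψ′(d₀/2)

so smoothing the mean and the squared residuals of e against α and inverting the
trigamma function yields per-gene (d₀, s₀²).  The posterior-mean (moderated)
variance is then the df-weighted average (d₀s₀² + d·s²)/(d₀ + d).

The residual-class and random-class fits share no state: each call of
``estimate_hyperparameters`` is self-contained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import polygamma, psi
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)

__all__ = [
    "HyperParams",
    "log_variance_stats",
    "fit_trend",
    "trigamma_inverse",
    "estimate_hyperparameters",
    "posterior_variance",
]

# trigamma_inverse caps: below this target the solution is effectively infinite
_TINY_TRIGAMMA = 1e-7
_HUGE_TRIGAMMA = 1e7
_D0_CAP = 2.0 * _HUGE_TRIGAMMA  # d0 = 2x with x capped at 1e7
_VAR_TREND_FLOOR = 1e-8


@dataclass
class HyperParams:
    """Per-gene prior df and location for one variance class, plus the trends they came from."""

    d0: np.ndarray
    s0_sq: np.ndarray
    mean_trend: np.ndarray
    var_trend: np.ndarray
    included: np.ndarray  # genes whose s² entered the trend fits


def _trigamma(x):
    return polygamma(1, x)


def log_variance_stats(s_sq, d):
    """Bias-adjusted log variance e = log s² − ψ(d/2) + log(d/2).

    Genes with s² ≤ 0 return NaN (flagged, excluded from trend fitting) rather
    than raising.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    d = np.broadcast_to(np.asarray(d, dtype=float), s_sq.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.log(s_sq) - psi(d / 2.0) + np.log(d / 2.0)
    e = np.where(s_sq > 0, e, np.nan)
    if e.ndim == 0:
        return float(e)
    return e


def fit_trend(x, y, span: float = 0.4) -> np.ndarray:
    """Tricube-weighted local linear regression of y on x, evaluated at every x.

    Thin wrapper around a lowess smoother (no robustness iterations); falls back
    to a global linear fit, with a logged warning, when there are too few points
    for the local window.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    n = len(x)
    window = max(int(np.ceil(span * n)), 2)
    if n < 5 or window < 4:
        logger.warning("fit_trend: %d points too few for span %.3g; using global linear fit", n, span)
        coef = np.polyfit(x, y, 1)
        return np.polyval(coef, x)
    xr = x.max() - x.min()
    if xr == 0:
        return np.full(n, y.mean())
    fitted = lowess(
        y, x, frac=span, it=0, delta=0.01 * xr, return_sorted=True, is_sorted=False
    )
    return np.interp(x, fitted[:, 0], fitted[:, 1])


def trigamma_inverse(y):
    """Solve ψ′(x) = y for x > 0 by safeguarded Newton iteration.

    Targets below 1e−7 return the cap 1e7 (an effectively infinite solution —
    the caller should treat the corresponding d0 as "effectively infinite");
    targets above 1e7 return the near-zero asymptotic root 1/√y.  Non-positive
    targets raise, since ψ′ is positive everywhere.
    """
    y_arr = np.atleast_1d(np.asarray(y, dtype=float))
    if np.any(y_arr <= 0):
        raise ValueError("trigamma has no finite inverse at a non-positive value; cap d0 instead")
    x = np.where(y_arr > _HUGE_TRIGAMMA, 1.0 / np.sqrt(y_arr), 0.5 + 1.0 / y_arr)
    active = (y_arr >= _TINY_TRIGAMMA) & (y_arr <= _HUGE_TRIGAMMA)
    for _ in range(60):
        if not np.any(active):
            break
        f = _trigamma(x[active]) - y_arr[active]
        # ψ″ < 0, so Newton steps stay monotone; damp to keep x positive
        step = f / polygamma(2, x[active])
        new = x[active] - step
        new = np.where(new <= 0, x[active] / 2.0, new)
        conv = np.abs(f) < 1e-10 * y_arr[active]
        x[active] = new
        rem = np.where(active)[0][conv]
        active = active.copy()
        active[rem] = False
    x = np.where(y_arr < _TINY_TRIGAMMA, _HUGE_TRIGAMMA, x)
    if np.isscalar(y) or np.asarray(y).ndim == 0:
        return float(x[0])
    return x


def estimate_hyperparameters(s_sq, d, alpha, span: float = 0.4) -> HyperParams:
    """Estimate expression-dependent prior df d₀(α) and location s₀²(α).

    Genes with non-positive variance estimates are excluded from the trend fits
    but still receive priors interpolated at their α (the posterior formula is
    well defined for them).  The variance trend is clamped below at 1e−8, and
    the trigamma inversion caps d₀ at 2×10⁷ when the observed dispersion shows
    no excess over the sampling noise ψ′(d/2).
    """
    s_sq = np.asarray(s_sq, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    d = np.broadcast_to(np.asarray(d, dtype=float), s_sq.shape).astype(float)
    included = np.isfinite(s_sq) & (s_sq > 0)
    if not np.any(included):
        raise ValueError("variance class degenerate: no positive variance estimates")

    e = log_variance_stats(s_sq, d)
    ai, ei = alpha[included], e[included]
    mean_in = fit_trend(ai, ei, span=span)
    var_in = fit_trend(ai, (ei - mean_in) ** 2, span=span)

    # interpolate both trends to every gene's alpha (excluded genes included)
    order = np.argsort(ai)
    mean_trend = np.interp(alpha, ai[order], mean_in[order])
    var_trend = np.interp(alpha, ai[order], var_in[order])
    var_trend = np.maximum(var_trend, _VAR_TREND_FLOOR)

    excess = np.maximum(var_trend - _trigamma(d / 2.0), _VAR_TREND_FLOOR)
    d0 = 2.0 * trigamma_inverse(excess)
    d0 = np.minimum(d0, _D0_CAP)
    s0_sq = np.exp(mean_trend + psi(d0 / 2.0) - np.log(d0 / 2.0))
    return HyperParams(d0=d0, s0_sq=s0_sq, mean_trend=mean_trend,
                       var_trend=var_trend, included=included)


def posterior_variance(s_sq, d, s0_sq, d0):
    """Posterior-mean (moderated) variance s̃² = (d₀s₀² + d·s²)/(d₀ + d)."""
    s_sq = np.asarray(s_sq, dtype=float)
    d = np.asarray(d, dtype=float)
    s0_sq = np.asarray(s0_sq, dtype=float)
    d0 = np.asarray(d0, dtype=float)
    total = d0 + d
    if np.any(total <= 0):
        raise ValueError("d0 + d must be positive")
    out = (d0 * s0_sq + d * s_sq) / total
    # exact limits (also keeps the unmoderated path bit-identical to raw s²)
    out = np.where(np.broadcast_to(d0, out.shape) == 0, np.broadcast_to(s_sq, out.shape), out)
    out = np.where(np.broadcast_to(d, out.shape) == 0, np.broadcast_to(s0_sq, out.shape), out)
    if out.ndim == 0:
        return float(out)
    return out


def diagnostics_table(fits, hyper_e: HyperParams, hyper_r: HyperParams,
                      s_tilde_e, s_tilde_r) -> pd.DataFrame:
    """Per-gene shrinkage diagnostics for both variance classes (TSV-exportable)."""
    return pd.DataFrame(
        {
            "gene_id": fits.gene_ids,
            "alpha": fits.alpha_hat,
            "s2_e": fits.s2_e,
            "e_stat_e": log_variance_stats(fits.s2_e, fits.d_e),
            "mean_trend_e": hyper_e.mean_trend,
            "var_trend_e": hyper_e.var_trend,
            "d0_e": hyper_e.d0,
            "s0_sq_e": hyper_e.s0_sq,
            "s_tilde_sq_e": s_tilde_e,
            "s2_r": fits.s2_r,
            "e_stat_r": log_variance_stats(fits.s2_r, fits.d_r),
            "mean_trend_r": hyper_r.mean_trend,
            "var_trend_r": hyper_r.var_trend,
            "d0_r": hyper_r.d0,
            "s0_sq_r": hyper_r.s0_sq,
            "s_tilde_sq_r": s_tilde_r,
        }
    )
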