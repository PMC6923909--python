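"""Moderated t-statistics, effective degrees of freedom, p-values and PFER control.

The contrast variance is assembled from the two (possibly moderated) variance
classes as Ṽ_L = a_r·s̃_r² + a_e·s̃_e².  Two df conventions are provided:

* variance-components (VC) — when subjects are nested in the tested fixed
  effect, the between-subject stratum governs, so ν = d_r + d0_r;
* Welch–Satterthwaite (Sat) — ν = (Σu_i)²/Σ(u_i²/ν_i) over the positive
  variance terms u_i with their (moderated) df.

Multiplicity is controlled on the per-family error rate (PFER): with m genes
and an allowance of k expected false positives, reject at p ≤ k/m (the extended
Bonferroni rule).  m stays the full panel size even when some genes have NA
p-values, which keeps the expected-false-positive interpretation conservative.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .ebayes import estimate_hyperparameters, posterior_variance
from .model_fit import GeneFits

logger = logging.getLogger(__name__)

__all__ = [
    "moderated_contrast_variance",
    "df_vc",
    "df_satterthwaite",
    "t_test_pvalue",
    "pfer_adjust",
    "moderated_t_test",
]

_NORMAL_DF = 1e6  # above this, the t tail is evaluated as normal

METHOD_TAGS = ("FMT-VC", "FMT-Sat", "OT-VC", "OT-Sat")


def moderated_contrast_variance(a_r, a_e, s_tilde_r_sq, s_tilde_e_sq):
    """Ṽ_L = a_r·s̃_r² + a_e·s̃_e² (the L C̃ L′ of the nested two-group design)."""
    a_r = np.asarray(a_r, dtype=float)
    a_e = np.asarray(a_e, dtype=float)
    if np.any(a_r < 0) or np.any(a_e < 0):
        raise ValueError("variance coefficients must be nonnegative")
    v = a_r * np.asarray(s_tilde_r_sq, dtype=float) + a_e * np.asarray(s_tilde_e_sq, dtype=float)
    if v.ndim == 0:
        return float(v)
    return v


def df_vc(d_r, d0_r=0.0):
    """Variance-components effective df: the between-subject stratum df plus its prior df."""
    d_r = np.asarray(d_r, dtype=float)
    if np.any(d_r < 1):
        raise ValueError("between-subject df must be at least 1")
    out = d_r + np.asarray(d0_r, dtype=float)
    if out.ndim == 0:
        return float(out)
    return out


def df_satterthwaite(terms):
    """Welch–Satterthwaite effective df for a sum of independent variance terms.

    ``terms`` is a sequence of (u_i, ν_i) pairs, u_i = a_i·s̃_i² ≥ 0 and ν_i > 0;
    u_i may be vectors.  Terms with u_i = 0 contribute nothing.  Genes where all
    u_i vanish get NaN df (flagged downstream); an all-zero scalar call raises.
    """
    us = [np.asarray(u, dtype=float) for u, _ in terms]
    vs = [np.asarray(v, dtype=float) for _, v in terms]
    for u, v in zip(us, vs):
        if np.any(u < 0):
            raise ValueError("variance terms must be nonnegative")
        if np.any(v <= 0):
            raise ValueError("term df must be positive")
    total = sum(us)
    denom = sum(u**2 / v for u, v in zip(us, vs))
    scalar = np.asarray(total).ndim == 0
    if scalar:
        if total <= 0:
            raise ValueError("all variance terms are zero; effective df undefined")
        return float(total**2 / denom)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(total > 0, total**2 / np.where(denom > 0, denom, np.nan), np.nan)
    return out


def t_test_pvalue(beta_hat, v_l, df):
    """t = β̂/√V_L and the two-sided Student-t p-value (normal tail above 1e6 df).

    Non-positive or NaN contrast variance propagates NA (NaN) into t and p.
    """
    beta_hat = np.asarray(beta_hat, dtype=float)
    v_l = np.asarray(v_l, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(v_l) & (v_l > 0) & np.isfinite(df) & (df > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(ok, beta_hat / np.sqrt(v_l), np.nan)
    p = np.full(np.broadcast(t, df).shape, np.nan)
    t_b, df_b, ok_b = np.broadcast_arrays(t, df, ok)
    use_norm = ok_b & (df_b > _NORMAL_DF)
    use_t = ok_b & ~use_norm
    p[use_t] = 2.0 * stats.t.sf(np.abs(t_b[use_t]), df_b[use_t])
    p[use_norm] = 2.0 * stats.norm.sf(np.abs(t_b[use_norm]))
    if np.asarray(beta_hat).ndim == 0 and p.ndim == 0:
        return float(t), float(p)
    if p.ndim == 0:
        return float(t), float(p)
    return t, p


def pfer_adjust(p, k: float):
    """Extended-Bonferroni rejection flags controlling E[#false positives] ≤ k.

    Rejects p ≤ k/m over the full panel of m tests; NA p-values are never
    rejected but still count in m.
    """
    p = np.asarray(p, dtype=float)
    if k <= 0:
        raise ValueError("k must be positive")
    m = p.size
    if m < 1:
        raise ValueError("empty p-value vector")
    thresh = k / m
    with np.errstate(invalid="ignore"):
        return np.where(np.isfinite(p), p <= thresh, False)


def moderated_t_test(
    fits: GeneFits,
    method: str = "FMT-VC",
    k: float = 5.0,
    span: float = 0.4,
    hyper_e=None,
    hyper_r=None,
    with_fdr: bool = False,
) -> pd.DataFrame:
    """Run the full testing pipeline on fitted variance components.

    method is one of 'FMT-VC', 'FMT-Sat' (both variance classes moderated) or
    'OT-VC', 'OT-Sat' (no moderation: both prior df forced to zero).  Explicit
    ``hyper_e`` / ``hyper_r`` (HyperParams or (d0, s0_sq) tuples) override the
    estimated priors — useful for oracle calibration studies.

    Returns the per-gene results table (sorted by p ascending): gene_id,
    alpha, beta_hat, t, df_eff, p, rejected, method_tag.
    """
    tag = method.replace("fmt", "FMT").replace("ot", "OT").replace("vc", "VC").replace("sat", "Sat")
    if tag not in METHOD_TAGS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHOD_TAGS}")
    moderate = tag.startswith("FMT")
    use_sat = tag.endswith("Sat")

    def _resolve(hyper, s_sq, d):
        if hyper is None:
            return estimate_hyperparameters(s_sq, d, fits.alpha_hat, span=span)
        if isinstance(hyper, tuple):
            d0, s0 = hyper
            return _ManualPrior(np.broadcast_to(np.asarray(d0, float), s_sq.shape).copy(),
                                np.broadcast_to(np.asarray(s0, float), s_sq.shape).copy())
        return hyper

    if moderate:
        he = _resolve(hyper_e, fits.s2_e, fits.d_e)
        hr = _resolve(hyper_r, fits.s2_r, fits.d_r)
        d0_e, s0_e = he.d0, he.s0_sq
        d0_r, s0_r = hr.d0, hr.s0_sq
        s_tilde_e = posterior_variance(fits.s2_e, fits.d_e, s0_e, d0_e)
        s_tilde_r = posterior_variance(fits.s2_r, fits.d_r, s0_r, d0_r)
    else:
        d0_e = np.zeros(len(fits))
        d0_r = np.zeros(len(fits))
        s_tilde_e = fits.s2_e
        s_tilde_r = fits.s2_r

    v_l = moderated_contrast_variance(fits.a_r, fits.a_e, s_tilde_r, s_tilde_e)
    if use_sat:
        df_eff = df_satterthwaite(
            [(fits.a_r * s_tilde_r, fits.d_r + d0_r), (fits.a_e * s_tilde_e, fits.d_e + d0_e)]
        )
    else:
        df_eff = df_vc(fits.d_r, d0_r)

    t, p = t_test_pvalue(fits.beta_hat, v_l, df_eff)
    n_na = int(np.sum(~np.isfinite(p)))
    if n_na:
        logger.info("%d of %d genes have NA p (zero contrast variance); m stays %d",
                    n_na, len(fits), len(fits))
    rejected = pfer_adjust(p, k)

    out = pd.DataFrame(
        {
            "gene_id": fits.gene_ids,
            "alpha": fits.alpha_hat,
            "beta_hat": fits.beta_hat,
            "t": t,
            "df_eff": df_eff,
            "p": p,
            "rejected": rejected,
            "method_tag": tag,
        }
    )
    if with_fdr:
        out["fdr"] = _bh_fdr(p)
    return out.sort_values("p", kind="stable").reset_index(drop=True)


class _ManualPrior:
    """Minimal stand-in for HyperParams when priors are supplied directly."""

    def __init__(self, d0, s0_sq):
        self.d0 = d0
        self.s0_sq = s0_sq
        self.mean_trend = None
        self.var_trend = None
        self.included = None


def _bh_fdr(p):
    from statsmodels.stats.multitest import multipletests

    q = np.full_like(np.asarray(p, dtype=float), np.nan)
    ok = np.isfinite(p)
    if np.any(ok):
        q[ok] = multipletests(np.asarray(p)[ok], method="fdr_bh")[1]
    return q
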