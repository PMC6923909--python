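"""Per-gene linear mixed-model fitting: Y = Xβ + Zγ + ε with a random subject intercept.

Two fitting paths share one result container:

* ``fit_balanced_anova`` — closed-form nested-ANOVA estimators, vectorized over
  all genes at once; requires a balanced design.
* ``fit_reml_profile`` — per-gene REML via the profiled restricted likelihood in
  λ = σ_r²/σ_e²; handles unbalanced designs.

Both return variance components on their natural χ² strata: the within-subject
mean square s_e² with d_e degrees of freedom, and the (truncated) between-subject
moment estimator s_r² with d_r degrees of freedom, plus coefficients (a_r, a_e)
such that Var(Lβ̂) = a_r·σ_r² + a_e·σ_e².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .design import ExperimentDesign

__all__ = ["GeneFits", "average_log_expression", "fit_balanced_anova", "fit_reml_profile", "fit_lmm"]

# bounds for log λ, λ = σ_r²/σ_e², in the REML profile search
_LOG_LAMBDA_LO = -12.0
_LOG_LAMBDA_HI = 12.0


@dataclass
class GeneFits:
    """Variance-component fits for one or more genes (arrays aligned by gene).

    Attributes
    ----------
    gene_ids : identifiers.
    alpha_hat : average log2 expression per gene.
    beta_hat : contrast estimate Lβ̂ (log2 fold change for the default contrast).
    s2_e, d_e : residual (within-subject) variance estimate and its df.
    s2_r, d_r : random-effect (between-subject) variance estimate, truncated at
        zero, and its df.  ``s2_r_raw`` keeps the untruncated value for
        diagnostics.
    a_r, a_e : Var(Lβ̂) = a_r σ_r² + a_e σ_e².
    """

    gene_ids: np.ndarray
    alpha_hat: np.ndarray
    beta_hat: np.ndarray
    s2_e: np.ndarray
    d_e: np.ndarray
    s2_r: np.ndarray
    d_r: np.ndarray
    a_r: np.ndarray
    a_e: np.ndarray
    s2_r_raw: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.s2_r_raw is None:
            self.s2_r_raw = self.s2_r.copy()

    def __len__(self) -> int:
        return len(self.gene_ids)

    @staticmethod
    def concatenate(fits: list["GeneFits"]) -> "GeneFits":
        return GeneFits(
            *[np.concatenate([getattr(f, name) for f in fits]) for name in (
                "gene_ids", "alpha_hat", "beta_hat", "s2_e", "d_e", "s2_r", "d_r",
                "a_r", "a_e", "s2_r_raw")]
        )


def average_log_expression(Y: np.ndarray) -> np.ndarray:
    """Row means of the expression matrix: the per-gene average log2 expression α̂_g."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[1] < 1 or Y.shape[0] < 1:
        raise ValueError("expression matrix must be 2-d with at least one gene and one sample")
    if not np.all(np.isfinite(Y)):
        raise ValueError("expression matrix contains non-finite values")
    return Y.mean(axis=1)


def fit_balanced_anova(Y: np.ndarray, design: ExperimentDesign, gene_ids=None) -> GeneFits:
    """Closed-form nested-ANOVA fit for all genes of a balanced two-group design.

    Per gene: β̂ = mean(group1) − mean(group2); s_e² is the within-subject mean
    square on d_e = 2·n_s·(n_r−1) df; s_r² = max(0, (MS_B − MS_W)/n_r) where MS_B
    is the between-subject (within-group) mean square on d_r = 2·(n_s−1) df.
    a_r = 2/n_s and a_e = 2/(n_s·n_r).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[None, :]
    if not design.balanced:
        raise ValueError("fit_balanced_anova requires a balanced design")
    n_s, n_r = design.n_s, design.n_r
    if n_r < 2:
        raise ValueError("residual df zero; random effect not separable (n_r must be >= 2)")
    if n_s < 2:
        raise ValueError("at least two subjects per group required")
    if Y.shape[1] != design.n_samples:
        raise ValueError("matrix columns do not match design samples")
    if not np.all(np.isfinite(Y)):
        raise ValueError("expression matrix contains missing or non-finite values")

    order = design.sorted_order()
    G = Y.shape[0]
    # genes × group × subject × replicate
    cube = Y[:, order].reshape(G, 2, n_s, n_r)

    subj_means = cube.mean(axis=3)            # G × 2 × n_s
    grp_means = subj_means.mean(axis=2)       # G × 2
    sign = design.contrast  # over design.groups order
    beta_hat = grp_means @ sign

    d_e = 2 * n_s * (n_r - 1)
    d_r = 2 * (n_s - 1)
    ss_within = ((cube - subj_means[..., None]) ** 2).sum(axis=(1, 2, 3))
    s2_e = ss_within / d_e
    ms_b = n_r * ((subj_means - grp_means[..., None]) ** 2).sum(axis=(1, 2)) / d_r
    s2_r_raw = (ms_b - s2_e) / n_r
    s2_r = np.maximum(s2_r_raw, 0.0)

    if gene_ids is None:
        gene_ids = np.array([f"gene_{i}" for i in range(G)])
    full = np.full(G, 0.0)
    return GeneFits(
        gene_ids=np.asarray(gene_ids),
        alpha_hat=Y.mean(axis=1),
        beta_hat=beta_hat,
        s2_e=s2_e,
        d_e=full + d_e,
        s2_r=s2_r,
        d_r=full + d_r,
        a_r=full + 2.0 / n_s,
        a_e=full + 2.0 / (n_s * n_r),
        s2_r_raw=s2_r_raw,
    )


def _reml_neg_loglik(log_lam: float, y, X, ZZt, n, p):
    """Negative profiled restricted log-likelihood (constants dropped)."""
    lam = np.exp(log_lam)
    Vc = np.eye(n) + lam * ZZt
    Lc = np.linalg.cholesky(Vc)
    Wy = np.linalg.solve(Vc, y)
    WX = np.linalg.solve(Vc, X)
    A = X.T @ WX
    beta = np.linalg.solve(A, WX.T @ y)
    r = y - X @ beta
    Wr = np.linalg.solve(Vc, r)
    rss = float(r @ Wr)
    logdet_V = 2.0 * np.sum(np.log(np.diag(Lc)))
    _, logdet_A = np.linalg.slogdet(A)
    return 0.5 * (logdet_V + logdet_A + (n - p) * np.log(max(rss, 1e-300)))


def fit_reml_profile(y: np.ndarray, design: ExperimentDesign, gene_id="gene_0") -> GeneFits:
    """REML fit of the single-random-intercept model for one gene.

    Maximizes the restricted likelihood profiled over λ = σ_r²/σ_e² on
    log λ ∈ [−12, 12] (boundary ties resolve to the boundary, with σ̂_r²
    truncated to 0 there).  β̂ is the GLS estimate at the REML variances and
    (a_r, a_e) decompose Var(Lβ̂) = LĈL′ into its σ_r² and σ_e² parts via the
    exact Euler decomposition of the degree-1-homogeneous form LĈL′.

    Degrees of freedom follow the containment convention:
    d_r = n_subjects − n_groups and d_e = N − n_subjects.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = design.n_samples
    if y.shape[0] != n:
        raise ValueError("sample vector length does not match design")
    if not np.all(np.isfinite(y)):
        raise ValueError("sample vector contains missing or non-finite values")
    for g, cnt in design.subjects_per_group.items():
        if cnt < 2:
            raise ValueError(f"group {g!r} has fewer than two subjects")
    if design.n_subjects >= n:
        raise ValueError("one sample per subject everywhere: σ_r and σ_e are confounded")

    X = design.fixed_effects_matrix()
    Z = design.random_effects_matrix()
    ZZt = Z @ Z.T
    p = X.shape[1]

    res = minimize_scalar(
        _reml_neg_loglik,
        bounds=(_LOG_LAMBDA_LO, _LOG_LAMBDA_HI),
        args=(y, X, ZZt, n, p),
        method="bounded",
        options={"xatol": 1e-10},
    )
    log_lam = float(res.x)
    # local polish: the bounded search can stop short of its nominal tolerance
    if _LOG_LAMBDA_LO + 1e-6 < log_lam < _LOG_LAMBDA_HI - 1e-6:
        try:
            polished = minimize_scalar(
                _reml_neg_loglik,
                bracket=(log_lam - 1e-4, log_lam, log_lam + 1e-4),
                args=(y, X, ZZt, n, p),
                method="brent",
                options={"xtol": 1e-12},
            )
            if polished.fun <= res.fun and _LOG_LAMBDA_LO <= polished.x <= _LOG_LAMBDA_HI:
                log_lam = float(polished.x)
                res = polished
        except (ValueError, RuntimeError):
            pass
    # on balanced designs the moment estimator is the analytic REML optimum;
    # prefer it whenever it matches the search result to within the profile's
    # numerical flatness
    if design.balanced and design.n_r >= 2:
        bal = fit_balanced_anova(y[None, :], design)
        if bal.s2_r_raw[0] > 0 and bal.s2_e[0] > 0:
            cand = float(np.log(bal.s2_r_raw[0] / bal.s2_e[0]))
            if (_LOG_LAMBDA_LO <= cand <= _LOG_LAMBDA_HI
                    and _reml_neg_loglik(cand, y, X, ZZt, n, p) <= res.fun + 1e-9):
                log_lam = cand
    # prefer the boundary when it does at least as well (optimizer may stop a hair inside)
    for bound in (_LOG_LAMBDA_LO, _LOG_LAMBDA_HI):
        if _reml_neg_loglik(bound, y, X, ZZt, n, p) <= res.fun + 1e-12:
            log_lam = bound
            break
    lam = np.exp(log_lam)
    at_zero = log_lam <= _LOG_LAMBDA_LO + 1e-9

    if at_zero:
        lam = 0.0
    Vc = np.eye(n) + lam * ZZt
    WX = np.linalg.solve(Vc, X)
    A = X.T @ WX
    beta = np.linalg.solve(A, WX.T @ y)
    r = y - X @ beta
    rss = float(r @ np.linalg.solve(Vc, r))
    s2_e_hat = rss / (n - p)
    s2_r_hat = lam * s2_e_hat

    # Euler decomposition of LCL' into a_r σ_r² + a_e σ_e²
    L = design.contrast
    C = np.linalg.inv(A) * s2_e_hat  # (X' V⁻¹ X)⁻¹ with V = s2_e·Vc
    M = C @ WX.T / s2_e_hat  # C X' V⁻¹  (rows: coefficients)
    m = L @ M
    a_r = float(m @ ZZt @ m)
    a_e = float(m @ m)

    d_r = design.n_subjects - design.n_groups
    d_e = n - design.n_subjects

    arr = lambda v: np.array([v], dtype=float)
    return GeneFits(
        gene_ids=np.array([gene_id]),
        alpha_hat=arr(y.mean()),
        beta_hat=arr(float(L @ beta)),
        s2_e=arr(s2_e_hat),
        d_e=arr(d_e),
        s2_r=arr(max(s2_r_hat, 0.0)),
        d_r=arr(d_r),
        a_r=arr(a_r),
        a_e=arr(a_e),
        s2_r_raw=arr(s2_r_hat),
    )


def fit_lmm(Y: np.ndarray, design: ExperimentDesign, gene_ids=None) -> GeneFits:
    """Fit every gene: vectorized closed form on balanced designs, REML otherwise."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[None, :]
    if design.balanced and design.n_r >= 2:
        return fit_balanced_anova(Y, design, gene_ids=gene_ids)
    if gene_ids is None:
        gene_ids = [f"gene_{i}" for i in range(Y.shape[0])]
    return GeneFits.concatenate(
        [fit_reml_profile(Y[i], design, gene_id=gene_ids[i]) for i in range(Y.shape[0])]
    )
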