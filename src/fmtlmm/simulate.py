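"""Synthetic expression generator for the two-group nested design.

The generator emulates log2-scale microarray-like data whose variance structure
depends on expression level:

1. average log expression α_g from a shifted (three-parameter) log-normal,
   ln(α_g − 3.75) ~ N(1.35, 0.35) (variance parameterisation);
2. smooth hyperparameter surfaces s₀e²(α), d₀e(α), s₀r²(α), d₀r(α) giving each
   gene a prior for its residual and random-effect variance;
3. per-gene true variances drawn from the corresponding scaled inverse-χ²;
4. subject random effects S_i ~ N(0, σ_r,g²), fresh per gene and subject;
5. a seeded random subset of n_de genes made differentially expressed with
   log-difference μ_g ~ N(0, 2): group-1 means α_g + μ_g/2 + S_i, group-2 means
   α_g − μ_g/2 + S_i; null genes use μ_g = 0;
6. residual noise N(0, σ_e,g²) per sample, optionally with block-exchangeable
   gene–gene correlation (blocks of 10, ρ = 0.5) applied to both the subject
   effect and residual streams.

Each logical draw uses its own child stream of the seed, so changing one knob
(say n_de) leaves unrelated draws untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .design import ExperimentDesign

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_alpha",
    "hyperparameter_surfaces",
    "draw_gene_variances",
    "simulate_dataset",
    "apply_block_correlation",
]

# α_g = ALPHA_SHIFT + exp(Z), Z ~ N(ALPHA_MEANLOG, ALPHA_VARLOG)
ALPHA_SHIFT = 3.75
ALPHA_MEANLOG = 1.35
ALPHA_VARLOG = 0.35
DE_MEAN_VARIANCE = 2.0  # μ_g ~ N(0, 2)


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset (defaults follow the benchmark design)."""

    n_genes: int = 12000
    n_de: int = 500
    n_s: int = 3
    n_r: int = 2
    seed: int = 0
    de_mean_sd: float = np.sqrt(DE_MEAN_VARIANCE)
    block_size: Optional[int] = None  # None → independent genes
    rho: float = 0.5
    correlate_subject_effects: bool = True

    def __post_init__(self) -> None:
        if self.n_de > self.n_genes:
            raise ValueError("n_de cannot exceed n_genes")
        if self.n_s < 2:
            raise ValueError("need at least two subjects per group")
        if self.n_r < 1:
            raise ValueError("need at least one technical replicate")
        if not (0 <= self.rho < 1):
            raise ValueError("rho must be in [0, 1)")
        if self.block_size is not None and self.block_size > self.n_genes:
            raise ValueError("block_size cannot exceed n_genes")


@dataclass
class SimulatedDataset:
    """Expression matrix plus the ground truth it was generated from."""

    Y: np.ndarray                  # n_genes × (2·n_s·n_r)
    design: ExperimentDesign
    alpha: np.ndarray              # true average log expression α_g
    mu: np.ndarray                 # true log-difference (0 for null genes)
    sigma2_e: np.ndarray           # true residual variance
    sigma2_r: np.ndarray           # true random-effect variance
    is_de: np.ndarray              # boolean DE flags (exactly n_de True)
    subject_effects: np.ndarray    # n_genes × n_subjects draws S_i
    gene_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    config: SimulationConfig = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.gene_ids is None:
            self.gene_ids = np.array([f"gene_{i}" for i in range(self.Y.shape[0])])
        if self.Y.shape[1] != self.design.n_samples:
            raise ValueError("matrix width inconsistent with design")

    def expression_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.Y, index=pd.Index(self.gene_ids, name="gene_id"),
                            columns=self.design.sample_ids)

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "alpha": self.alpha,
                "mu": self.mu,
                "sigma2_e": self.sigma2_e,
                "sigma2_r": self.sigma2_r,
                "is_de": self.is_de,
            }
        )


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_alpha(n: int, seed=0) -> np.ndarray:
    """Draw average log expression from the shifted log-normal (always > 3.75)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = _rng(seed)
    z = rng.normal(ALPHA_MEANLOG, np.sqrt(ALPHA_VARLOG), size=n)
    return ALPHA_SHIFT + np.exp(z)


def hyperparameter_surfaces(alpha):
    """Evaluate the four smooth prior surfaces at α.

    Returns (s0e_sq, d0e, s0r_sq, d0r):

        s0e² = 0.2·exp(−1.2(α−4.6)) + 0.05
        d0e  = 1.5·√(−1.1·exp(0.1(α−6)) + 0.6(α−7)² + 20) + exp(0.25(α−14)) + 2
        s0r² = 0.5·exp(−0.8(α−5.25)) + 0.1
        d0r  = 1.2·√(same radicand) + exp(0.25(α−14)) + 2
    """
    alpha = np.asarray(alpha, dtype=float)
    if not np.all(np.isfinite(alpha)):
        raise ValueError("alpha must be finite")
    radicand = -1.1 * np.exp(0.1 * (alpha - 6.0)) + 0.6 * (alpha - 7.0) ** 2 + 20.0
    if np.any(radicand <= 0):
        raise ValueError("df surface radicand non-positive; alpha outside supported range")
    tail = np.exp(0.25 * (alpha - 14.0))
    s0e_sq = 0.2 * np.exp(-1.2 * (alpha - 4.6)) + 0.05
    d0e = 1.5 * np.sqrt(radicand) + tail + 2.0
    s0r_sq = 0.5 * np.exp(-0.8 * (alpha - 5.25)) + 0.1
    d0r = 1.2 * np.sqrt(radicand) + tail + 2.0
    return s0e_sq, d0e, s0r_sq, d0r


def draw_gene_variances(s0_sq, d0, seed=0) -> np.ndarray:
    """Draw true variances from the scaled inverse-χ² prior: σ² = d₀·s₀²/χ²_{d₀}.

    Equivalently 1/σ² ~ χ²_{d₀}/(d₀·s₀²), so E[1/σ²] = 1/s₀².
    """
    s0_sq = np.asarray(s0_sq, dtype=float)
    d0 = np.asarray(d0, dtype=float)
    if np.any(s0_sq <= 0) or np.any(d0 <= 0):
        raise ValueError("prior location and df must be positive")
    rng = _rng(seed)
    chi2 = rng.chisquare(np.broadcast_to(d0, s0_sq.shape))
    return d0 * s0_sq / chi2


def _exchangeable_normals(rng: np.random.Generator, blocks: np.ndarray, rho: float,
                          shape: tuple) -> np.ndarray:
    """Standard normals of shape (n_genes, *shape) with correlation rho within gene blocks.

    x_g = √rho · w_block + √(1−rho) · u_g keeps unit marginal variance while
    giving every within-block pair correlation rho; blocks are independent.
    """
    n_genes = len(blocks)
    u = rng.standard_normal((n_genes, *shape))
    if rho == 0:
        return u
    n_blocks = int(blocks.max()) + 1
    w = rng.standard_normal((n_blocks, *shape))
    return np.sqrt(rho) * w[blocks] + np.sqrt(1.0 - rho) * u


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate one dataset per the six-step recipe (see module docstring)."""
    ss = np.random.SeedSequence(config.seed)
    (ss_alpha, ss_var, ss_de, ss_mu, ss_subj, ss_resid, ss_block) = ss.spawn(7)

    G = config.n_genes
    alpha = simulate_alpha(G, np.random.default_rng(ss_alpha))
    s0e_sq, d0e, s0r_sq, d0r = hyperparameter_surfaces(alpha)
    rng_var = np.random.default_rng(ss_var)
    sigma2_e = draw_gene_variances(s0e_sq, d0e, rng_var)
    sigma2_r = draw_gene_variances(s0r_sq, d0r, rng_var)

    # DE labels: a seeded random subset of genes
    rng_de = np.random.default_rng(ss_de)
    de_idx = rng_de.permutation(G)[: config.n_de]
    is_de = np.zeros(G, dtype=bool)
    is_de[de_idx] = True
    mu = np.zeros(G)
    mu[de_idx] = np.random.default_rng(ss_mu).normal(0.0, config.de_mean_sd, size=config.n_de)

    design = ExperimentDesign.balanced_two_group(config.n_s, config.n_r)
    n_subjects = design.n_subjects
    N = design.n_samples

    blocks = None
    rho = 0.0
    if config.block_size is not None and config.rho > 0:
        rng_block = np.random.default_rng(ss_block)
        blocks = rng_block.permutation(G) // config.block_size
        rho = config.rho

    rng_subj = np.random.default_rng(ss_subj)
    if blocks is not None and config.correlate_subject_effects:
        z_subj = _exchangeable_normals(rng_subj, blocks, rho, (n_subjects,))
    else:
        z_subj = rng_subj.standard_normal((G, n_subjects))
    subject_effects = z_subj * np.sqrt(sigma2_r)[:, None]

    rng_resid = np.random.default_rng(ss_resid)
    if blocks is not None:
        z_resid = _exchangeable_normals(rng_resid, blocks, rho, (N,))
    else:
        z_resid = rng_resid.standard_normal((G, N))
    resid = z_resid * np.sqrt(sigma2_e)[:, None]

    # group means: α ± μ/2 (columns ordered g1 then g2 in balanced_two_group)
    group_sign = np.where(design.group == design.groups[0], 0.5, -0.5)  # length N
    subj_col = np.array([list(design.subjects).index(s) for s in design.subject])
    mean_matrix = alpha[:, None] + mu[:, None] * group_sign[None, :]
    Y = mean_matrix + subject_effects[:, subj_col] + resid

    return SimulatedDataset(
        Y=Y,
        design=design,
        alpha=alpha,
        mu=mu,
        sigma2_e=sigma2_e,
        sigma2_r=sigma2_r,
        is_de=is_de,
        subject_effects=subject_effects,
        config=config,
    )


def apply_block_correlation(dataset: SimulatedDataset, block_size: int = 10,
                            rho: float = 0.5, seed: Optional[int] = None) -> SimulatedDataset:
    """Re-generate a dataset's noise with block-exchangeable gene correlation.

    Keeps the ground truth (α, μ, σ², DE flags) fixed and redraws the subject
    effect and residual streams from block-correlated normals, so per-gene
    marginal variances are unchanged while genes inside a block correlate at
    rho.  Returns a new dataset.
    """
    cfg = dataset.config
    new_cfg = SimulationConfig(
        n_genes=cfg.n_genes, n_de=cfg.n_de, n_s=cfg.n_s, n_r=cfg.n_r,
        seed=cfg.seed if seed is None else seed,
        de_mean_sd=cfg.de_mean_sd, block_size=block_size, rho=rho,
        correlate_subject_effects=cfg.correlate_subject_effects,
    )
    ss = np.random.SeedSequence(new_cfg.seed)
    (_, _, _, _, ss_subj, ss_resid, ss_block) = ss.spawn(7)

    G = cfg.n_genes
    design = dataset.design
    blocks = np.random.default_rng(ss_block).permutation(G) // block_size

    rng_subj = np.random.default_rng(ss_subj)
    if new_cfg.correlate_subject_effects:
        z_subj = _exchangeable_normals(rng_subj, blocks, rho, (design.n_subjects,))
    else:
        z_subj = rng_subj.standard_normal((G, design.n_subjects))
    subject_effects = z_subj * np.sqrt(dataset.sigma2_r)[:, None]

    z_resid = _exchangeable_normals(np.random.default_rng(ss_resid), blocks, rho,
                                    (design.n_samples,))
    resid = z_resid * np.sqrt(dataset.sigma2_e)[:, None]

    group_sign = np.where(design.group == design.groups[0], 0.5, -0.5)
    subj_col = np.array([list(design.subjects).index(s) for s in design.subject])
    mean_matrix = dataset.alpha[:, None] + dataset.mu[:, None] * group_sign[None, :]
    Y = mean_matrix + subject_effects[:, subj_col] + resid

    return SimulatedDataset(
        Y=Y, design=design, alpha=dataset.alpha, mu=dataset.mu,
        sigma2_e=dataset.sigma2_e, sigma2_r=dataset.sigma2_r, is_de=dataset.is_de,
        subject_effects=subject_effects, gene_ids=dataset.gene_ids, config=new_cfg,
    )
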