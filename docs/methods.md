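# Methods

This note records the model, the estimation procedures, the synthetic-data
generator, the numerical conventions, and the design choices made where the
design was genuinely open. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Per-gene mixed model and strata

Each gene is modelled as `Y = Xβ + Zγ + ε` with a cell-means fixed-effect
matrix `X` (one column per group), a subject-indicator `Z`, independent
`γ ~ N(0, σ²_r I)` and `ε ~ N(0, σ²_e I)`. The tested contrast is the group
difference `L = (1, −1)` over the sorted group labels; sorting makes the sign
convention independent of sample order.

**Balanced path.** For `n_s` subjects per group and `n_r` technical replicates
per subject, the nested-ANOVA decomposition gives closed forms, vectorized
over all genes at once:

* `β̂ = ȳ_1 − ȳ_2`;
* residual (within-subject) mean square `s²_e` on `d_e = 2 n_s (n_r − 1)` df;
* between-subject (within-group) mean square `MS_B` on `d_r = 2(n_s − 1)` df,
  and the moment estimator `s²_r = max(0, (MS_B − s²_e)/n_r)` (the untruncated
  value is kept for diagnostics);
* `Var(Lβ̂) = a_r σ²_r + a_e σ²_e` with `a_r = 2/n_s`, `a_e = 2/(n_s n_r)`.

**Unbalanced path.** Per-gene REML on the profiled restricted likelihood in
`λ = σ²_r/σ²_e`, maximized over `log λ ∈ [−12, 12]` by bounded scalar search
with a Brent polish; boundary ties resolve to the boundary and `σ̂²_r` is
floored at 0. On balanced inputs the moment estimator is the analytic interior
optimum and is preferred whenever it matches the search result within the
profile's numerical flatness, which makes the two paths agree to ≤1e−8 there.
At the `λ = 0` boundary REML pools the two strata (`σ̂²_e = RSS/(N−2)`), which
differs from the balanced-path convention `s²_e = MS_W`; the equivalence is
therefore an interior-optimum statement only. `(a_r, a_e)` come from the Euler
decomposition `a_k = L C X'V⁻¹ (∂V/∂θ_k) V⁻¹X C L'`: because `LCL'` is
homogeneous of degree 1 in `(σ²_r, σ²_e)`, this reproduces `LĈL'` exactly and
reduces to the balanced constants.

**Degrees of freedom** follow the containment convention:
`d_r = n_subjects − n_groups`, `d_e = N − n_subjects`, matching the balanced
χ² strata the hierarchical model assumes. The shrunken `s²_r` is the truncated
moment estimator treated as approximately scaled-χ² with `d_r` df; the χ²
assumption is exact only for the untruncated stratum mean square. This is a
documented approximation — the oracle-prior calibration test
(`tests/test_inference.py`, 10⁶ null genes) measures its practical effect and
finds per-gene type-I error within 3 binomial SEs of nominal.

## Empirical-Bayes shrinkage

Each variance class is shrunk independently (the two pipelines share no
state). With `e_g = log s²_g − ψ(d_g/2) + log(d_g/2)`, the marginal model
implies `E[e] = log s₀² − ψ(d₀/2) + log(d₀/2)` and
`Var[e] = ψ′(d/2) + ψ′(d₀/2)`. The procedure:

1. compute `e_g` for genes with `s²_g > 0` (zero variances — common for the
   truncated `s²_r` — are excluded from trend fitting but receive priors
   interpolated at their `α̂_g` and are shrunk normally);
2. `mean_trend = loess(α, e)`; the smoother is tricube-weighted local linear
   regression (statsmodels lowess, no robustness iterations, interpolation
   delta 1% of the x-range), span 0.4 by default;
3. `var_trend = loess(α, (e − mean_trend)²)`, clamped below at 1e−8; squared
   residuals rather than a robust scale estimator, robustness iterations 0;
4. `d₀ = 2 ψ′⁻¹( max(var_trend − ψ′(d/2), 1e−8) )`, capped at 2×10⁷ when the
   observed dispersion shows no excess over the sampling floor (the posterior
   then collapses onto `s₀²`);
5. `s₀² = exp( mean_trend + ψ(d₀/2) − log(d₀/2) )`.

`ψ′⁻¹` is a safeguarded Newton iteration on the trigamma function (relative
tolerance 1e−10 on the target); targets below 1e−7 return the 1e7 cap,
targets above 1e7 the asymptotic root `1/√y`. Span, clamps and caps are
configurable. Posterior variances use the exact weighted average with exact
`d₀ = 0` / `d = 0` limits, so the unmoderated tests are bit-identical to raw
variance estimates.

Recovery behavior is tested two ways: constant-truth simulation (d₀ = 6,
s₀² = 0.5, d = 10) recovers the prior with median `d₀ ∈ [4.5, 8]` and
`s₀² ∈ [0.45, 0.55]`; simulation from the expression-dependent surfaces below
recovers `log s₀²(α)` with RMSE well under 0.15 over `α ∈ [5, 12]`.

## Inference and error control

The moderated contrast variance is `Ṽ_L = a_r s̃²_r + a_e s̃²_e`. Two df
rules are exposed:

* **VC**: `ν = d_r + d₀r`. The between-subject stratum carries the contrast
  when subjects are nested in groups, and moderation earns it the random
  class's prior df — mirroring the classical moderated-t result `df = d + d₀`
  applied to the governing stratum. (The stratum-assignment principle is
  standard; the `+ d₀r` arithmetic is this package's choice.)
* **Satterthwaite**: `ν = (Σu_i)²/Σ(u_i²/ν_i)` over the positive terms, with
  moderated per-component df `(d_e + d₀e)` and `(d_r + d₀r)` for FMT and raw
  df for OT.

Two-sided Student-t p-values (normal tail above 1e6 df). Genes with zero
total contrast variance get NA p and are never rejected, but the panel size
`m` in the PFER rule `p ≤ k/m` stays the full gene count — the conservative
reading of the expected-false-positive guarantee; both counts are logged.
Rejection uses the closed threshold (`≤`). Benjamini–Hochberg FDR is available
as an optional extra column only.

## Synthetic-data generator

The generator emulates a two-group microarray-like study on the log2 scale;
its defaults are the benchmark study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 12,000 | panel size |
| `n_de` | 500 | differentially expressed genes |
| `n_s`, `n_r` | 3, 2 | subjects per group, technical replicates per subject |
| `de_mean_sd` | √2 | SD of the log2 difference `μ_g ~ N(0, 2)` |
| `block_size`, `rho` | off, 0.5 | optional block-exchangeable gene correlation |

Steps: (1) `α_g = 3.75 + exp(Z)`, `Z ~ N(1.35, 0.35)` (mean/variance
notation, so SD = √0.35; the same reading applies to `μ_g ~ N(0, 2)` — both
configurable in case the SD reading was intended); (2) smooth prior surfaces

```
s₀e² = 0.2·exp(−1.2(α−4.6)) + 0.05
d₀e  = 1.5·√(−1.1·exp(0.1(α−6)) + 0.6(α−7)² + 20) + exp(0.25(α−14)) + 2
s₀r² = 0.5·exp(−0.8(α−5.25)) + 0.1
d₀r  = 1.2·√(same radicand) + exp(0.25(α−14)) + 2
```

(3) true variances `σ² = d₀ s₀²/χ²_{d₀}` per gene and class; (4) subject
effects `S_i ~ N(0, σ²_r,g)` fresh per gene and subject (gene-specific, so
independent across genes in the uncorrelated mode, matching per-gene LMM
analysis); (5) a seeded random *subset* of `n_de` genes — not the first
indices — gets `μ_g ~ N(0, 2)`, group means `α ± μ/2 + S_i`; (6) null genes
use `μ = 0`; residual noise `N(0, σ²_e,g)` per sample.

Each logical draw (α, variances, DE labels, μ, subject effects, residuals,
block assignment) has its own child stream of the seed, so changing one knob
leaves unrelated draws untouched; everything is reproducible under
`(seed, config)`.

The df surfaces have a bounded domain: the radicand turns negative for
α ≳ 84. The shifted log-normal reaches that region with probability ≈ 2×10⁻⁷
per gene, so about 0.3% of 12,000-gene datasets abort with an error; the
benchmark harness logs and excludes such runs and reports the number of runs
actually aggregated.

**Gene correlation.** Block mode assigns genes to blocks at random under the
run seed and replaces both the subject-effect and residual streams with
exchangeable normals `√ρ·w_block + √(1−ρ)·u_g` (both-streams correlation is a
switch), preserving per-gene marginal variances exactly while giving
within-block correlation ρ.

**What the generator does not emulate:** count noise (RNA-Seq), probe-level
artifacts, normalization residue, batch structure, unequal group sizes, or
heavier-than-Gaussian tails. Passing tests demonstrate correctness of the
machinery and calibration *under the assumed Gaussian mixed model*, not
robustness to real-data violations of it.

## Comparator constructions

These are behavioral reimplementations of the published *descriptions* of the
comparison methods, not ports of their codebases.

* **OT (VC/Sat)** — the identical pipeline with both prior df forced to 0;
  p-values are bit-identical to FMT in that limit (tested).
* **Limma-like** — per-gene within-subject correlation
  `ρ_g = s²_r/(s²_r+s²_e)` from the ANOVA components; consensus
  `ρ̂ = tanh(trimmed mean of atanh ρ_g)` (15% per tail, ρ clipped to
  [0, 0.999]); per-gene GLS at the shared `ρ̂` with one residual variance on
  `N−2` df; constant-prior (non-trended) moderation of that variance via the
  same log-moment equations with global means; `df = (N−2) + d₀`.
* **Dream-like** — the per-gene ratio `r_g = s²_r/s²_e` is frozen; only the
  residual variance receives trended moderation; the random part is
  reconstructed as `r_g·s̃²_e` (so the ratio is identical before and after
  shrinkage — asserted in tests); contrast variance
  `a_r r_g s̃²_e + a_e s̃²_e`; Satterthwaite df over `(a_r r_g s̃²_e, d_r)`
  and `(a_e s̃²_e, d_e + d₀e)`. Genes with `s²_e = 0` are flagged NA. The raw
  `d_r` is kept for the random term since only residual variances are shrunk.

The exact df bookkeeping of the real residual-only-shrinkage pipeline is not
published, so `ComparatorConfig.dream_df_mode` exposes two stronger-shrinkage
variants as sensitivity analyses: `"total"` treats the frozen ratio as known
(the whole contrast variance carries `d_e + d₀e` df) and `"trend"` is the
full-shrinkage limit (per-gene residual variance replaced by its trend value,
normal reference) that precision-weighted pipelines approach. Under the null
the frozen-ratio statistic equals `t_{d_r}·√(s²_e/s̃²_e)` with the two factors
independent, which bounds how far any of these variants can inflate false
positives; the default construction shows roughly an order of magnitude
inflation at `n_s = 3, n_r = 2` in the benchmark, the `"trend"` limit several
times more. This is the one place where a comparator's *magnitude* of failure
depends on interpretation; the direction (largest false-positive count of all
methods, shrinking with `n_s`) does not.

## Benchmark harness

Per grid cell `(n_s, n_r)` and run: a counter-derived child seed
(`SeedSequence([master, n_s, n_r, run])`, reduced below 2³¹) generates a
dataset; the balanced closed-form fit and the FMT hyperparameter fits are
computed once and shared across methods; each method is scored as
`power = rejected DE / n_de` and `fp = rejected nulls`. Aggregates are means
with Monte-Carlo standard errors; failed runs are logged and excluded, never
silently. Determinism under the master seed is tested.

Problem sizes used by the shipped studies: the acceptance script runs the full
12,000-gene panel, 100 runs per condition; the test suite's calibration
fixtures use 30 runs (Monte-Carlo SE on mean false positives ≈ 0.2–0.6 at that
size), and its property studies use panels of 10³–10⁶ genes chosen so each
check's Monte-Carlo error is well inside its asserted tolerance.

## Known limitations

* Single random intercept, two groups, one contrast; no crossed or multi-level
  random effects, no Kenward–Roger df.
* The χ²(d_r) treatment of the truncated `s²_r` is approximate (see above).
* The Satterthwaite flavor is anticonservative at small `n_r` — that regime
  change is itself a benchmark finding, not a defect, but users testing with
  `fmt-sat` at `n_r ≤ 4` should expect inflated false positives.
* Hyperparameter smoothing assumes enough genes (≥ ~100 with positive
  variance) to estimate trends; tiny panels fall back to a global linear fit.
* Comparators are simplified reimplementations; conclusions about the real
  limma/variancePartition packages transfer only qualitatively.
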