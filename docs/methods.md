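# Methods

## Model

The package fits a linear model `y = Xβ + ε`, `ε ~ N(0, σ²Iₙ)`, to a
standardized expression matrix `X` (each gene column mean 0, sd 1), with
a shrinkage prior on the coefficients that encodes a gene-interaction
network.  Writing `L` for the network's normalized Laplacian and
`Λ = diag(1/τ₁², …, 1/τ_p²) + L`, the hierarchy is

```
β  | σ², τ², r  ~  N_p(0, (σ²/r) Λ⁻¹)
τ_j² | λ²       ~  (λ²/2) exp(−λ² τ_j²/2),  j = 1..p   (with a |Λ|^{−1/2} factor, below)
σ² ~ InvGamma(a, b)      r ~ Gamma(c, d)      λ² ~ Gamma(e, f)
```

All gamma/inverse-gamma laws are shape–rate.  The quadratic form
decomposes as

```
βᵀΛβ = Σ_j β_j²/τ_j²  +  Σ_{u∼v} w(u,v) (β_u/√d_u − β_v/√d_v)² ,
```

so the prior combines per-gene scale mixtures (which integrate to an ℓ1
penalty, as in the Bayesian lasso) with a smoothness penalty on
degree-scaled coefficients of interacting genes.  Λ is positive definite
for any positive finite τ², because `L` is positive semidefinite — this
guarantees every full conditional is proper.

Two deliberate conventions resolve internal tensions in this model
family and are worth stating explicitly:

* **Λ's diagonal uses 1/τ_j², not 1/τ_j.**  Only this choice makes the
  degree-scaled decomposition above hold with `D = diag(τ_j²)` and
  yields the generalized-inverse-Gaussian conditional for τ_j² used by
  the sampler.
* **The priors on `r` and `λ²` are shape–rate gammas with density
  ∝ x^{α−1}e^{−rate·x}.**  This is what makes the conditional shapes
  `p/2 + c` and `p + e` (below) exact.

The τ² prior carries a `|Λ(τ²)|^{−1/2}` factor that exactly cancels the
`|Λ|^{1/2}` normalizer of the Gaussian β prior, so neither determinant
appears in the joint.  Its normalizing constant `C_τ` depends on λ and
`L` but is treated as constant when deriving the λ² conditional — an
approximation inherited by this whole model family; the practical
consequence is that λ² is updated from the un-tilted exponential kernel.
The prior remains proper: `|Λ|^{−1/2} ≤ Πτ_j` bounds the integrand by
integrable gamma kernels (verified by quadrature in the test suite for
p = 1, 2).

## Gibbs sampler

Every conditional is closed-form; one sweep updates, in order:

1. `β | ·  ~  N(μ, Σ)`, `μ = (XᵀX + rΛ)⁻¹Xᵀy`, `Σ = σ²(XᵀX + rΛ)⁻¹`.
   One Cholesky factorization of the p×p matrix per draw; a singular
   system raises with a condition-number diagnostic rather than being
   silently regularized.
2. `σ² | ·  ~  InvGamma((n+p)/2 + a, [‖y−Xβ‖² + rβᵀΛβ]/2 + b)`.
3. `τ_j² | ·` independently GIG with `χ_j = rβ_j²/σ²`, `ψ = λ²`:
   density ∝ `x^{idx−1} exp(−(ψx + χ_j/x)/2)`.  The index implied by the
   joint is **1** (no power of τ_j² survives the determinant
   cancellation) and is the default; the 1/2 variant sometimes quoted
   for this conditional is available via `gig_index` but targets a
   slightly different joint.  At `β_j = 0` the law degenerates to
   `Exponential(λ²/2)` and is sampled directly.
4. `r | ·  ~  Gamma(p/2 + c, βᵀΛβ/(2σ²) + d)`.  (The rate ends in the
   prior rate `d`; a `+ b` occasionally seen in this conditional is
   inconsistent with `r ~ Gamma(c, d)`.)
5. `λ² | ·  ~  Gamma(p + e, Στ_j²/2 + f)`.

Defaults follow common practice for this model family: `a–f = 0.01`
(weakly informative), 6000 iterations with the second half retained,
no thinning, posterior estimates by averaging the retained draws.
Initialization is `β = 0, σ² = τ_j² = r = λ² = 1`.  Chains are bitwise
reproducible from `(seed, config)`.

### GIG sampling

Generic GIG generators are numerically fragile when `ω = √(χψ)` is tiny
(a near-zero coefficient makes χ underflow).  The package samples the
conditional on the log scale: with `t = log x` the density is
∝ `exp(idx·t − ω cosh t)`, strictly log-concave, so a rejection sampler
with a uniform center piece and two exponential tails anchored where the
log-density drops one unit below its mode (`t* = asinh(idx/ω)`) is exact
and uniformly fast over the entire parameter range.  Draws with
`χψ < 1e−24` are routed to the exact `Gamma(idx, ψ/2)` limit, whose
total-variation distance from the GIG is negligible at that point.

### Probit extension

Binary labels are handled by latent-variable augmentation: `y_i = 1` iff
`z_i = X_iβ + ε_i > 0`.  Given the state, each `z_i` is truncated normal
`N(X_iβ, σ²)` on `(0,∞)` or `(−∞,0]`, drawn independently per
observation (the conditional factorizes, so no joint truncated
multivariate sampler is needed); the five updates above then run with
`z` in place of `y`.  Truncated draws use a tail-safe routine that
remains exact for `|X_iβ|/σ` far beyond 6.  Predicted probabilities are
`Φ(X_iβ/σ)` — the link the augmentation implies.  σ² is sampled by
default (retaining the model's σ² layer); `fix_sigma2=True` pins it at 1
for the conventional probit identification.

### MAP / penalized-loss equivalence

With σ² fixed and the τ² scales integrated out, the β posterior density
is ∝ `exp(−[‖y−Xβ‖² + rλ‖β‖₁ + rβᵀLβ]/(2σ²))`; its mode is the
network-constrained penalized least-squares estimate.  In this family's
literature the quadratic penalty is sometimes printed with coefficient λ
instead of r; the form above is the one the prior hierarchy actually
implies, and is what `penalized_objective` computes.  The test suite
verifies the equivalence by maximizing a quadrature-evaluated
scale-mixture marginal (the Laplace mixture with rate `rλ/(2σ²)` per
coordinate, the representation under which the mixture identity is
exact) against the numeric minimizer of the penalty.

## Graph handling

Edge lists are whitespace/tab-delimited `gene_a gene_b [weight]` text;
weights default to 1 (interaction present/absent), duplicate pairs
collapse keeping the last weight, self-loops are dropped with a warning.
The node order of the Laplacian is always dictated by the expression
matrix's gene order; genes absent from the network stay as isolated
nodes with a zero Laplacian row, so their prior reduces to pure ℓ1-type
shrinkage instead of silently shrinking the feature set.
Standardization uses the sample standard deviation (ddof = 1), exposed
as a flag.

## Synthetic data generator

`simulate` emulates the structure the prior is designed for, with known
ground truth:

* **Network**: star topology per pathway — one hub wired to each
  satellite, unit weights, no cross-pathway edges.  Stars exercise
  degree-heterogeneous Laplacian entries (hub degree g−1, satellites 1).
* **Expression**: rows i.i.d. multivariate normal, unit variances,
  equicorrelation ρ within a pathway (default 0.5), independence across
  pathways, then standardized.
* **Coefficients**: active hubs get `hub_effect` (default 1.0), active
  satellites `satellite_effect/√(hub degree)`; with equal effects the
  degree-scaled smoothness penalty is exactly zero within an active
  star, i.e. the truth is network-smooth in the model's own metric.
* **Responses**: Gaussian `y = Xβ + N(0, noise_sd²)` (default sd 1.0,
  putting the signal-to-noise ratio of the default design around 16),
  or binary via the model's own probit mechanism.
* **Defaults**: 10 pathways × 5 genes (p = 50), 3 active, n = 100.

What this generator does **not** emulate: probe-level noise, batch
effects, heavy-tailed expression, mis-specified networks (edges absent
from truth or wrong), or p ≫ n regimes in the thousands of genes.
Passing recovery tests therefore demonstrate correctness of the
inference machinery under the model's own assumptions, not robustness to
the full messiness of microarray data.

## Problem sizes and numerical choices

The validation suite runs desk-scale problems chosen to make exact
checks feasible: quadrature-normalized KS tests of each 1-D conditional
(10⁴ draws), Gaussian moment checks of the β conditional
(5×10⁴ draws at n = 30, p = 10), a simulator-calibration (Geweke-style)
comparison of marginal-conditional vs successive-conditional simulation
at n = 10, p = 5 over 2×10⁴ sweeps, and full-length (6000-iteration)
recovery runs at p = 50.  The Geweke check uses informative
hyperparameters (a = b = c = d = 3–6, e = 30, f = 15) because the
compared moments must be finite and the exact prior sampler for the
`|Λ|^{−1/2}`-tilted τ² marginal (rejection with acceptance probability
`|I + √D L √D|^{−1/2}`) needs `e > p/2`; the default 0.01 priors are far
too heavy-tailed for a moment-matching test to be well posed.

Equal-tailed empirical-quantile credible intervals are reported (not
HPD).  Ranking ties in |posterior mean| are broken lexicographically by
gene identifier for cross-platform determinism.

## Limitations

* Single chain; no convergence diagnostics beyond the exported log-joint
  trace (the draws are plain arrays — `arviz` applies directly if
  desired).
* No intercept: both `X` and (implicitly) the response are assumed
  centered; supply a centered `y` for regression.
* The p×p Cholesky per sweep scales to a few thousand genes, not tens of
  thousands; the intended workflow restricts to genes present in the
  pathway database first.
* No missing-value imputation, probe-to-gene collapsing, or pathway-file
  (KGML) parsing — the package consumes a pre-extracted edge list.
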