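# Methods

## Model

`semsire` fits the multi-trait sire model

```
y = Xβ + Zu + ε,    u | A, G0 ~ N(0, A ⊗ G0),    ε ~ N(0, I ⊗ R0),
```

where `y` stacks `p` trait records per animal, `β` holds the fixed effects
(contemporary group, age at scanning, dam age), `u` holds one `p`-vector of
transmitting abilities per sire, `A` is Wright's numerator relationship
matrix among the sires, and `G0`/`R0` are the `p×p` genetic and residual
trait covariance matrices. Offspring of a sire are paternal half-sibs, so
animal-scale heritability uses the standard sire-model conversion
`h² = 4σ²_s/(σ²_s + σ²_e)`.

Each of `G0` and `R0` can take one of three parameterizations:

* **unstructured (UNS)** — all `p(p+1)/2` entries free, inverse-Wishart
  prior;
* **factor-analytic (FA)** — `Σ = ΛΛ' + Ψ` with `m` common factors.
  Identifiability is resolved by the echelon constraint (`λ_jk = 0` for
  `k > j`) together with non-negative pivots `λ_kk ≥ 0`; the pivot signs are
  imposed by a deterministic column-sign relabeling after each loading draw,
  which is measure-preserving because the posterior is symmetric under joint
  column sign flips. Free-parameter count: `p + mp − m(m−1)/2`.
* **recursive (REC)** — `Σ = (I−Π)⁻¹ Γ (I−Π)⁻ᵀ` with `Π` strictly lower
  triangular along a fixed causal trait ordering (the `TraitSet` order,
  default LMA, BF, RF, BW, HH, SC) and `Γ` diagonal. With all lower entries
  free ("fully recursive", FRM) this is a one-to-one reparameterization of
  the unstructured matrix — the unit-lower-triangular (LDL) factorization —
  with exactly `p(p+1)/2` free parameters; masks fix chosen entries to zero
  for parsimony.

A note on FA counting: the count formula above gives 17 parameters per
matrix for `p = 6, m = 2` and 21 for `m = 3`. Published per-model totals in
this literature sometimes quote smaller numbers for the two-factor model
(e.g. 12 per matrix); we implement the formula, which is the count actually
consistent with the echelon-constrained sampler.

## Priors

The inverse-Wishart hyperparameters are resolved from the data scale unless
given explicitly: with a prior heritability guess `h²₀ = 0.4`, the
sire-variance guess per trait is `h²₀/4 ≈ 0.1` of the observed phenotypic
variance and the residual guess is the remainder. Degrees of freedom default
to `ν = p + 2` and the diagonal scale matrix is chosen so the prior mean
equals the guess. A half/half split would be implausible for a sire model —
the sire component carries only a quarter of the additive variance — and
would center the genetic prior far above any realistic value.

Fixed effects get `β ~ N(0, 100² I)`. FA loadings get independent
`N(0, 100²)` priors and specific variances scaled-inverse-chi-square priors
(df 4, scale = the variance guess).

**Recursive priors are IW-matched by default.** For a diagonal IW scale
matrix `S`, the inverse-Wishart `IW(ν, S)` induces on the triangular
factorization exactly

```
γ_j ~ scaled-inv-χ²(ν − p + j, S_jj / (ν − p + j)),
π_jk | γ_j ~ N(0, γ_j / S_kk),
```

(verified in this package by simulation against an independent IW sampler).
Using this law as the prior on `(Π, Γ)` makes the full-mask recursive model
*the same Bayesian model* as the unstructured one, which is what the
reparameterization argument promises: posterior summaries of `G0`, `R0` and
EBVs then agree between FRM and the unstructured baseline up to Monte Carlo
error. With independent `N(0, 100²)` coefficient priors instead
(`ModelSpec(rec_prior="independent")`, also provided), the induced prior on
the marginal variances of late-ordered traits is far more diffuse than the
IW, and for weakly-informed traits (such as a male-only trait) the FRM and
unstructured posteriors separate noticeably — a real prior-sensitivity
effect, not a sampler defect. Masked (pruned) recursive models keep the same
row-wise prior family.

## Gibbs sampler

Systematic scan per iteration: impute missing records → `β` → `u` →
G-structure parameters → R-structure parameters. All kernels are exact full
conditionals:

* **Missing records** are latent: each animal's unobserved trait components
  are drawn from `N(y_mis | y_obs, β, u, R0)`, grouped by missingness
  pattern for vectorization. The stored model-comparison likelihood is
  always the *observed-data* likelihood given `(β, u, R0)`.
* **β** is updated in per-trait Gaussian blocks (class-effect dummies are
  kept sparse).
* **u** is drawn jointly for all sires from the Gaussian with precision
  `A⁻¹⊗G0⁻¹ + D⊗R0⁻¹` (`D` = progeny counts). The draw uses the canonical
  transformation `T` with `T'R0⁻¹T = I`, `T'G0⁻¹T = diag(λ)` (a generalized
  eigendecomposition), which splits the `s·p` system into `p` independent
  `s×s` systems — and into scalar updates when `A = I`.
* **UNS**: conjugate inverse-Wishart draws via the Bartlett decomposition.
* **FA**: latent factors (per-sire, `A`-correlated across sires on the
  genetic side; per-record on the residual side), then free loadings row by
  row (Gaussian generalized regressions under the echelon constraint, then
  the sign relabeling), then `Ψ` (scaled-inverse-chi-square). The `u`/`β`
  draws use the assembled `ΛΛ'+Ψ` with the factors integrated out, then the
  factors are refreshed from their conditional — a partially collapsed, and
  exact, scheme.
* **REC**: row `j` of `Π` is the Gaussian full-conditional regression of
  trait-`j` effects on their predecessors (`A`-weighted on the genetic
  side), then `γ_j` from its scaled-inverse-chi-square conditional (with the
  matched prior, the coefficient prior contributes `Σ π²_jk S_kk` and `f_j`
  extra degrees of freedom). Masked entries remain exactly zero.

One seeded `numpy` generator drives everything in fixed kernel order, so
chains are bit-reproducible given (seed, spec, data). `Ψ` and `Γ` draws are
floored at `1e−8 ×` the per-trait variance guess; assembled draws are
therefore positive definite by construction, and the unstructured IW draws
are PD with probability one.

Kernel correctness is verified three ways: closed-form conditionals (GLS
limit for `β`, shrinkage means and dense joint-Gaussian conditioning for
`u`, grid-integrated exact posterior for the single-trait variance
components), recovery experiments on synthetic data, and a
simulator-consistency (joint distribution) check that alternates parameter
updates with data redraws and compares moments against the prior-predictive
sampler — run for both the UNS and the REC kernel sets.

## Model comparison

`Mean(L)` is the posterior mean of the stored observed-data log-likelihood;
`D̄ = −2·Mean(L)`; `D̂` plugs the posterior means of `(β, u, R0)` into the
same likelihood; `pD = D̄ − D̂`; `DIC = D̄ + pD`. Because the likelihood is
conditional on `u`, `pD` reflects the effective number of fixed plus random
effect parameters (hundreds for data of this shape). Posterior summaries
report heritabilities (×4 sire conversion) on the diagonal, genetic
correlations above and residual correlations below it, as posterior means ±
posterior SDs ("standard errors" in the field's table convention). EBV
agreement between two fits of the same sires is measured by per-trait
Pearson and Spearman correlations of posterior-mean sire effects (scale
factors such as ×2 do not affect either). Convergence diagnostics are
effective sample size (via `arviz`) and a Geweke z computed from
batch-mean spectral variance estimates; the Raftery–Lewis chain-length
procedure used in some field analyses is out of scope, replaced by
configurable burn-in plus these diagnostics.

## Structure selection

From a fitted FRM posterior: REC1 fixes to zero every *residual* structural
coefficient with `|mean|/sd < 1.96` (strict inequality; the genetic side
stays full); REC2 fixes to zero every coefficient, genetic or residual, with
`|mean| < 0.15`. Both thresholds are arguments with those defaults. Applied
to the published six-trait posterior summary table shipped in
`semsire.datasets`, REC1 removes exactly 6 residual paths and REC2 removes
15 (10 residual + 5 genetic). One caveat documented rather than resolved:
with the printed (two-decimal) means and SDs, the REC1 *count* is stable but
the removed *set* is sensitive to rounding — the ratio for one pair sits
exactly at 2.0 and another at 1.67, so recomputation from rounded values can
swap one member relative to a computation on unrounded posteriors.

## Synthetic data

The generator emulates the shape of the motivating Nellore field study:
2942 animals from 236 sires (overdispersed progeny-group sizes), 302
single-sex contemporary groups (mean ≈ 9.7 animals), 45.5% males, ages at
scanning uniform on 480–629 days, dam ages uniform on 2–15 years, the six
traits on their published scales, per-trait MCAR missingness reproducing the
published record counts, and scrotal circumference structurally missing for
females. The default true `(G0, R0)` are backed out of the published
sire-model heritabilities and correlations (diagonal h² × phenotypic
variance / 4, etc.); contemporary-group effects consume a fixed share of
the phenotypic variance budget (`cg_sd_frac = 0.35` of phenotypic SD) so
observed SDs track the published ones. Sire effects are drawn through the
Cholesky factors of `A` and `G0`; when the truth is specified in FA or REC
form, the draw goes through the native construction (factors + specifics,
or the triangular structural system), tying the generator's conventions to
the inference code's.

What the generator does *not* emulate: selection and genetic trend across
years, non-MCAR dropout, heterogeneous variances across herds, maternal and
permanent-environment effects, and real pedigree depth (only optional
grandsire links). Passing recovery tests therefore demonstrate correctness
of the estimator under the model's own assumptions, not robustness to these
real-data features.

## Test problem sizes

The test suite scales everything to desk size as its own design choice:

* credible-interval coverage: p = 3, 200 sires × 20 progeny, 20 replicates,
  6000 iterations (burn-in 1000, thin 5) each; 95% intervals cover ≥ 90% of
  the 240 parameter-replicate pairs.
* structured-truth recovery (REC and FA): same design, strong signal
  (h² ≈ 0.6, chosen so the check measures the sampler rather than the
  shrinkage floor — at 200 sires the sampling noise of the realized sire
  effects alone contributes ≈ 11% relative Frobenius error); mean relative
  Frobenius error of the posterior-mean `G0` over 5 replicates below 15%.
* FRM ≡ unstructured equivalence: p = 6, study shape scaled to 100 sires
  (~1250 animals), 4000 iterations; per-trait EBV Pearson ≥ 0.98 and all
  `G0` entries within 3 combined Monte Carlo standard errors.
* joint-distribution check: p = 2, 3 sires, 6 records, 5000 cycles; all
  moment z-statistics within ±4.
* zero-recovery pipeline: p = 4, 200 sires × 40 progeny (40 so that `Π` is
  estimated precisely enough for the magnitude rule to act on signal).

Default production MCMC settings mirror a full field analysis (1.5M
iterations, 40k burn-in, thin 10 → 146k kept draws); tests and the analysis
scripts use far shorter chains.

## Numerical choices and degenerate inputs

Dense linear algebra throughout (≤ a few hundred sires); pedigree `A` built
by the tabular method over the ancestor closure, dam links included when
present, inbreeding on the diagonal. Unknown sires referenced by phenotype
files become unrelated founders with a warning. Covariates are centered per
trait on observed records; class effects use full-rank treatment coding
with the first-observed level as reference and an explicit intercept.
Dam-age classes are whole-year bins pooled at configurable extremes (3 and
10 years by default); units for dam age are a config knob. Contemporary
groups with fewer observed records than a configurable minimum (default 1,
i.e. no dropping) are dropped with a warning. Ties at selection thresholds
are retained (strict `<`). Degenerate chains (zero variance) are flagged in
the diagnostics rather than crashing.

## Known limitations

Sire model only (no animal model); no maternal or repeated-record effects;
no REML/EM estimation; no marginal-likelihood or WAIC/LOO comparison; no
automated search over causal orderings — the recursive ordering is fixed by
the `TraitSet`, as appropriate when all traits are recorded simultaneously.
`pD` compares models on the conditional-likelihood scale; it is not
comparable to a marginal-likelihood `pD`.
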