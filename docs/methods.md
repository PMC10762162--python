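# Methods

This note records the statistical model the package implements, the
numerical choices behind it, what the synthetic-data generator does and
does not emulate, and the known limits of the approach at the problem
sizes the test suite runs.

## Model

**Notation.** For SNP m, f₀,m and f₁,m are the frequencies of the
counted allele among controls and cases; genotypes are binomial, so the
group genotype variances are s_j,m² = 2 f_j,m (1 − f_j,m). The GWAS
z-score of the allele-frequency-difference test is

    z_m = (f̂₁,m − f̂₀,m) / s_m,
    s_m = sqrt( s₁,m²/(4 n₁) + s₀,m²/(4 n₀) ),

with n₀, n₁ the group sample sizes, and z | β̃ ~ N(R β̃, R) where
β̃ = β/s is the standardized effect vector and R the genotype
correlation (LD) matrix. The marginal frequency difference is
δ = S R S⁻¹ β (δ = β for independent SNPs).

**AUC of a weight set.** PRS_i = Σ_m ω_m g_i,m is treated as normal
within each group (CLT over SNPs), giving AUC = Φ(Δ) with
Δ = 2 Σ ω_m δ_m / sqrt(τ₀² + τ₁²) and τ_j² = ωᵀ S_j R S_j ω. τ_j² uses
observed frequencies (group frequencies when carried; otherwise the
pooled frequency for both groups — a logged approximation that many
public summary files force).

**Prior.** β̃_m ~ iid (1 − π) δ₀ + π N(0, σ²). π is the proportion of
risk SNPs; σ² the variance of standardized risk effects. The liability
conversion σ² = N_e h²_l φ(Φ⁻¹(κ))² / (4 M π κ²(1−κ)²) with
N_e = 4n₀n₁/(n₀+n₁) is provided for users who prefer to anchor σ² to a
heritability estimate.

**Independent SNPs (EM).** The marginal mixture
z ~ (1−π)N(0,1) + πN(0,1+σ²) is fitted by EM; the posterior of δ_m is
the closed-form spike-slab (1−h_m)δ₀ + h_m N(λ z_m s_m, λ s_m²),
λ = 1/(1+1/σ²). Monte-Carlo draws of δ plugged into Φ(Δ) give the
posterior AUC. Because h_m, λ < 1, |E[δ_m | z_m]| ≤ |z_m s_m| with
equality only in the no-shrinkage limit: this deflation is what removes
the winner's-curse inflation of the plug-in ("unadjusted") AUC.

**LD-linked SNPs (SAME Gibbs).** The marginal likelihood P(z | π, σ²)
sums over 2^M spike/slab configurations, so its maximizer is found
stochastically: the sampler carries D replicated copies of the latent
(β̃, γ), D incremented by one per sweep, making the hyperparameter draws
target a density ∝ P(z | π, σ²)^D that concentrates on the MLE as D
grows. Conditional updates (per replicate and SNP):

    μ_m  = λ (z_m − Σ_{m'≠m} R_mm' β̃_m')
    γ_m ~ Bernoulli(h_m),  h_m = r_m / ((1−π) + r_m),
                           log r_m = log π + ½ log(λ/σ²) + μ_m²/(2λ)
    β̃_m ~ N(μ_m, λ) if γ_m = 1, else 0

followed by conjugate refreshes π ~ Beta(Σγ + D, MD − Σγ + D) and
σ⁻² ~ Gamma(Σγ/2 + D, Σβ̃²γ/2). Two deliberate choices here:

* *Update order.* γ_m is drawn from its conditional with β̃_m integrated
  out, then β̃_m | γ_m — a partially collapsed scan. The alternative
  order (sample β̃ under the pre-update γ, then refresh γ) leaves every
  freshly activated SNP paired with β̃ = 0, which systematically deflates
  the Gamma rate Σβ̃²γ and collapses σ² to zero within tens of sweeps;
  we verified this empirically at R = I against the EM solution.
* *Scale.* The sampler runs on β̃ = β/s throughout, so the Gamma rate is
  dimensionally consistent with σ² = Var(β/s); raw-scale β is recovered
  as s·β̃ only when δ is formed.

**Sweep scheduling.** Within a block whose bandwidth is at most 64,
SNPs are partitioned into bandwidth+1 "colors" whose members never
neighbor each other; a whole color class is conditionally independent
given the rest and is updated in one vectorized step (wide blocks fall
back to a per-SNP scan). Random numbers are drawn once per sweep and
indexed by global SNP column, so independent blocks produce bit-identical
results under any partitioning. All spike/slab odds are computed in
log-space (safe for |μ| into the hundreds).

**Convergence and posterior draws.** The sampler stops when the
20-sweep windowed means of π and σ² both change by < 5·10⁻³ relative
(the draw noise floor scales like 1/sqrt(MD), so a much tighter
tolerance would never trigger before the 500-sweep cap); the estimate is
the final-sweep draw. Posterior δ draws at the frozen estimate come from
continuing `n_posterior_draws` (default 1000) replicate chains in
parallel for a 30-sweep decorrelation run and taking their final states —
the same target distribution as sequential thinning of one chain, but
vectorized over draws.

## LD estimation

The genome is split into approximately independent blocks (a BED-like
block file, or fixed 1000-SNP windows broken at chromosome boundaries);
within each block the correlation of the standardized (mean-imputed)
genotypes is estimated by Ledoit–Wolf shrinkage toward the scaled
identity, then rescaled to unit diagonal. The textbook single-intensity
estimator (`ledoit_wolf_correlation`, verified to machine precision
against an independent implementation) is used when no LD radius is
requested.

When an LD radius r is given, entries beyond r SNPs are structurally
zero, and including them in the shrinkage intensity lets their pure
estimation noise swamp the weak band signal: with a genuinely banded,
weak correlation (e.g. AR(1) with ρ = 0.2) the single-intensity
estimator shrinks the band almost entirely away at any practical block
size (intensity 0.96 at p = 2000, 0.57 at p = 100, from n = 1000
samples). The banded variant therefore computes the Ledoit–Wolf
trade-off b²/d² per band offset k — the squared estimation noise of that
diagonal's sample correlations over their squared dispersion — keeping
signal-dominated offsets nearly intact and zeroing noise-dominated ones
(adjacent-SNP correlation 0.189 estimated vs 0.195 realized truth in the
AR(1) design). Banding is followed by PSD repair via eigenvalue clipping
at 10⁻⁸ (deterministic and cheap; banding is an approximation already)
and diagonal re-unitization.

## Synthetic studies

One replicate draws population frequencies f ~ U(0.05, 0.95), risk
indicators Bernoulli(π), standardized effects N(0, σ²) with s evaluated
at the null (f₀ = f₁ = f; this breaks the circular dependence of s on
the group frequencies with negligible error for small δ), and sets
f₀ = f, f₁ = clip(f + δ, 0.01, 0.99) with δ = S R S⁻¹ β — the
retrospective construction matching the model the estimators assume
(prevalence enters only through the liability conversion). Defaults are
the validated study conditions: π = 0.05, σ² = 0.001·n (independent) or
0.0005·n (AR(1), ρ = 0.2), κ = 0.01, balanced training GWAS, 1000+1000
testing cohort, 1000-sample reference panel.

* *Independent SNPs*: training group frequencies are binomial
  proportions f̂_j ~ Bin(2n_j, f_j)/(2n_j); no genotype matrices are
  materialized for training.
* *AR(1) SNPs*: genotypes are sums of two haplotypes, each a Markov
  chain of correlated Bernoullis with lag-1 correlation ρ (hence lag-k
  correlation ρ^k). Two Bernoullis with very different frequencies
  cannot support correlation ρ (Fréchet bounds), so offending adjacent
  pairs are clipped to 0.999× their feasible bound; with
  f ~ U(0.05, 0.95) and ρ = 0.2 this touches roughly 10% of pairs. The
  truth LD matrix is the realized Markov structure (correlations
  multiply along the chain), not the nominal ρ^|i−j|.
* *Heterogeneity scenarios* perturb the testing cohort only: pooled
  frequency shifts N(0, 0.01²), risk-effect shifts N(0, 0.0002·n) on the
  standardized scale, or a different testing ρ (0.15).

What the generator does **not** emulate: realistic minor-allele-frequency
spectra and LD beyond first-order-Markov structure, genotyping error and
missingness in the training GWAS, covariate/population structure,
meta-analysis sample-size heterogeneity (reported n overstating per-SNP
n, which the AUC estimator is known to translate into underprediction),
and case/control ascertainment beyond the retrospective frequency model.
Passing tests therefore demonstrate correctness of the machinery under
its own assumptions, not calibration on real cohorts.

## PRS weight fitters

The in-repo fitters generate candidate grids; they do not claim numeric
parity with published tools. P+T prunes greedily in position order (keep
a SNP iff r² < 0.1 with every kept SNP within a 250-SNP window — both
configurable; the pruned-in set is association-agnostic) and then masks
by p-value threshold {1, 5e-1, 5e-2, 5e-3, 5e-4, 5e-5, 5e-6}; C+T clumps
the SNPs passing each threshold greedily by ascending p-value. Both use
ω = z·s, the observed standardized effect on the frequency-difference
scale — any monotone per-SNP rescaling yields the same AUC ordering for
these methods. The LDpred-style fitter runs a spike-and-slab Gibbs chain
per candidate π ∈ {1, 3e-1, ..., 1e-5} (all chains vectorized together;
burn-in 100, 500 kept sweeps), with per-π slab variance σ²_total/π,
σ²_total = max(mean(z²) − 1, 10⁻³) estimated from the z-scores, and
reports posterior-mean weights; a split-half drift check warns on
unconverged chains.

## Tuning and evaluation

One prior fit serves every weight set of a grid (the prior describes the
training data, not the PRS), and one δ-draw set is shared across the
grid so predicted AUCs carry common Monte-Carlo noise — rankings are
stable to re-seeding at the 0.005 level with 1000 draws. For methods
whose pre-selected SNPs are genome-wide (C+T, LDpred-style), the SAME
fit runs on all harmonized SNPs and each weight set simply zeroes ω
outside its support. The posterior AUC summary is the mean of per-draw
AUCs (the Monte-Carlo posterior expectation), not Φ of the mean Δ.

Against a testing cohort the package reports ρ_AUC (Pearson correlation
of predicted and testing AUCs across the grid; undefined with a warning
when either vector is constant) and rd_AUC. Two readings of rd_AUC
exist; the default is the performance-shortfall one,
(AUC_test(best) − AUC_test(selected)) / AUC_test(best), because small
values then mean the selected and truly best parameters perform
comparably; the literal alternative
|AUC_pred(selected) − AUC_test(best)| / AUC_test(best) is available via
a flag.

## Problem sizes and reproducibility

The replicated validation runs use M = 10,000 SNPs, n = 10,000 and
n = 4,000 with 20 replicates for the independent design, and M = 2,000,
n = 10,000 with 10 replicates, LD radius 5, for the AR(1) design —
sizes chosen so the full suite completes on a single CPU in well under
half an hour. All randomness flows from explicit seeds; identical seeds
give bit-identical studies, fits and reports (the CLI derives per-stage
substreams from one master seed).

## Known limitations

* At M = 2,000 the π/σ² split is weakly identified: the likelihood is
  flat along the ridge π·σ² ≈ const, and with only ~100 risk SNPs the
  split estimate can land far from the generating values even when two
  independent estimators agree (the product, which drives most of the
  AUC prediction, is estimated much better).
* Per-replicate ρ_AUC at this scale is noise-limited: the testing-AUC
  spread across a grid is ~0.04–0.06 while a 1000+1000 testing cohort
  contributes ~0.011 sd per grid point, and single replicates can
  realize architectures whose testing curve peaks at a different grid
  point than any correctly calibrated posterior predicts. Substituting
  the generating (oracle) prior for the fitted one raises the
  10-replicate mean ρ_AUC only to ~0.79 (C+T) and ~0.85 (LDpred-style)
  — an intrinsic ceiling of the scaled design, not an estimation
  failure; rd_AUC (~1%) is unaffected, i.e. parameter *selection*
  remains accurate even when curve *correlation* is noisy.
* The AUC model assumes within-group normality of the PRS (poor for
  very sparse scores), a homogeneous population shared by training and
  testing data, and correct per-SNP sample sizes; meta-analysed inputs
  with overstated n lead to systematic AUC underprediction.
* Strand-ambiguous (A/T, C/G) SNPs are dropped by default during
  harmonization; multi-allelic and duplicated-position SNPs are dropped
  with logged counts.
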