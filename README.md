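# prstuning

Tuning-parameter selection for polygenic risk scores (PRS) **without a
validation cohort**: the package predicts the out-of-sample AUC of a PRS
weight set using only case/control GWAS summary statistics from the
training data, and picks the tuning parameter with the best predicted AUC.

## The problem

Most PRS methods (p-value thresholding after pruning, clumping +
thresholding, LDpred-style spike-and-slab fitters, ...) have tuning
parameters that are normally chosen by scoring each candidate on an
individual-level validation cohort. Such cohorts are often unavailable,
and carving one out of the training data costs power. Plugging the
training summary statistics straight into a summary-statistics AUC
formula does not work either: the allele-frequency differences of the
apparently strongest SNPs are overestimated (winner's curse), so the
"unadjusted" AUC is badly inflated exactly for the candidates that look
best.

## The method

For a weight vector ω over M SNPs, PRS = Σ_m ω_m g_m is approximately
normal within cases and controls, so

    AUC = Φ(Δ),    Δ = 2 Σ_m ω_m δ_m / sqrt(τ₀² + τ₁²),

where δ_m = f₁,m − f₀,m is the case/control allele-frequency difference
and τ_j² = ωᵀ S_j R S_j ω are the group PRS variances (S_j holds the
group genotype SDs, R is the LD matrix). Everything except δ is directly
computable from summary statistics and a reference panel. For δ the
package is empirical-Bayes: the standardized effects β_m/s_m carry a
point-normal prior (1−π)δ₀ + πN(0, σ²) whose hyperparameters are
estimated from the z-scores themselves —

* **independent SNPs** (the P+T situation): EM on the marginal mixture
  z ~ (1−π)N(0,1) + πN(0,1+σ²), then the closed-form posterior
  δ_m | z_m ~ (1−h_m)δ₀ + h_m N(λ z_m s_m, λ s_m²) with λ = 1/(1+1/σ²);
* **SNPs linked by LD** (C+T, LDpred-style grids): a
  state-augmentation-for-marginal-estimation (SAME) Gibbs sampler whose
  growing replicate count drives (π, σ²) to the marginal MLE, followed by
  posterior draws of the effects and δ = S R S⁻¹ β, with R estimated
  from a reference panel by blockwise Ledoit–Wolf shrinkage.

Monte-Carlo draws of δ give a posterior distribution of the AUC per
candidate weight set; because λ < 1 and h_m < 1 the posterior mean is
always shrunk below the plug-in estimate, which removes the winner's
curse inflation. The package also contains the full synthetic-study
generator (independent and AR(1)-correlated genotypes, testing cohorts,
reference panels, heterogeneity scenarios) and minimal P+T / C+T /
LDpred-style weight fitters, so the whole pipeline is testable
end-to-end without any external data.

## Worked example

Simulate a balanced 10,000-sample training GWAS over 10,000 independent
SNPs (5% risk SNPs, slab variance 0.001·n, prevalence 1%), fit the prior
from its summary statistics alone, and tune the P+T p-value threshold:

```python
import prstuning as pt

cfg = pt.preset("study_independent", n=10_000, seed=7, n_ref=0)
study = pt.simulate_study(cfg)

model = pt.PRSTuning(study.stats, mode="independent")
res = model.fit(n_draws=1000, seed=8)
print(res.summary())

wsets = pt.pt_weights(study.stats, None, pt.GridSpec(method="PT"))
report = res.tune(wsets)
test = [pt.empirical_auc(study.test_cases @ w.omega,
                         study.test_controls @ w.omega) for w in wsets]
print(pt.evaluate_against_testing(report, test))
```

```
PRS tuning prior fit
============================================
mode:              independent
SNPs (M):          10000
n0 / n1:           5000 / 5000
pi (risk frac):    0.04215
sigma2 (slab var): 9.897
shrinkage lambda:  0.9082
converged:         True (71 iterations)
posterior draws:   1000
E[#risk SNPs | z]: 421.5

method       param  auc_pred  ci_lo  ci_hi  auc_unadjusted  auc_test
    PT      pval=1    0.6839 0.6768 0.6915          0.9460    0.7001
    PT    pval=0.5    0.6877 0.6805 0.6955          0.9416    0.7048
    PT   pval=0.05    0.7405 0.7312 0.7496          0.8714    0.7516
    PT  pval=0.005    0.7698 0.7603 0.7787          0.8161    0.7790
    PT pval=0.0005    0.7663 0.7574 0.7744          0.7907    0.7696
    PT  pval=5e-05    0.7582 0.7498 0.7665          0.7803    0.7532
    PT  pval=5e-06    0.7432 0.7348 0.7519          0.7640    0.7414
selected: pval=0.005
rho_AUC = 0.980
rd_AUC  = 0.00%
```

The EM estimate recovers the generating architecture (π̂ = 0.042 vs 0.05,
σ̂² = 9.9 vs 10). The unadjusted column shows the winner's-curse
inflation (0.95 "AUC" for the densest score whose true testing AUC is
0.70), while the empirical-Bayes prediction tracks the held-out testing
AUC across the grid (ρ_AUC = 0.98) and the selected threshold (p ≤ 0.005)
is exactly the best-performing threshold on the testing cohort
(rd_AUC = 0).

For LD-linked SNPs the only changes are an LD matrix and the SAME fit:

```python
cfg = pt.preset("study_ar1", n=10_000, seed=3)       # AR(1), rho = 0.2
study = pt.simulate_study(cfg)
R = pt.build_ld(study.panel, blocks="single-block", radius=5)
res = pt.PRSTuning(study.stats, ld=R).fit(n_draws=1000, seed=4)
report = res.tune(pt.ct_weights(study.stats, R, pt.GridSpec(method="CT")))
```

A command-line interface mirrors the library
(`prstuning simulate | align | ld | fit-em | fit-same | fit-prs |
predict-auc | tune`); identical invocations with the same `--seed`
produce byte-identical outputs.

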