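"""Summary-statistics AUC for a PRS weight set.

With PRS = sum_m omega_m g_m approximately normal within each disease
group, the AUC of the score is Phi(Delta) with

    Delta = (eta_1 - eta_0) / sqrt(tau_0^2 + tau_1^2)
          = 2 sum_m omega_m delta_m / sqrt(tau_0^2 + tau_1^2),

where eta_j = sum_m 2 omega_m f_{j,m} are the group PRS means,
tau_j^2 = omega^T S_j R S_j omega the group PRS variances (S_j diagonal
with the group genotype standard deviations, R the LD matrix), and
delta_m = f_{1,m} - f_{0,m} the case-control allele-frequency difference.
Plugging observed frequency differences in directly gives the overfit
"unadjusted" AUC; plugging in posterior draws of delta gives the
empirical-Bayes predicted AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu, norm

from .ld import LDMatrix

__all__ = [
    "GroupMoments",
    "AUCEstimate",
    "HeritabilityParams",
    "compute_tau_sq",
    "compute_auc",
    "predicted_auc",
    "unadjusted_auc",
    "empirical_auc",
    "youden_sensitivity",
    "sigma2_from_h2",
]


@dataclass
class GroupMoments:
    """Group-wise PRS means and variances."""

    eta0: float
    eta1: float
    tau0_sq: float
    tau1_sq: float


@dataclass
class AUCEstimate:
    """Point AUC, its Delta statistic, and optional posterior draws."""

    delta_stat: float
    auc_point: float
    auc_draws: np.ndarray | None = None
    ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.auc_point < 1.0:
            raise ValueError(f"AUC {self.auc_point} outside (0, 1)")


@dataclass
class HeritabilityParams:
    """Inputs of the liability-scale heritability <-> sigma2 conversion."""

    h2_liability: float
    kappa: float
    M: int
    pi: float
    n0: int
    n1: int

    @property
    def n_eff(self) -> float:
        return 4.0 * self.n0 * self.n1 / (self.n0 + self.n1)


def compute_tau_sq(omega, s0_sq, s1_sq, R: LDMatrix | None = None):
    """Group PRS variances tau_j^2 = (omega * s_j)^T R (omega * s_j).

    ``s0_sq``/``s1_sq`` are per-SNP genotype variances 2 f_j (1 - f_j);
    ``R=None`` means independent SNPs (identity LD).
    """
    omega = np.asarray(omega, dtype=float)
    s0_sq = np.asarray(s0_sq, dtype=float)
    s1_sq = np.asarray(s1_sq, dtype=float)
    if not omega.shape == s0_sq.shape == s1_sq.shape:
        raise ValueError("omega and genotype variances must share shape")
    nz = omega != 0
    if np.any(s0_sq[nz] <= 0) or np.any(s1_sq[nz] <= 0):
        raise ValueError("genotype variance must be positive where omega != 0")
    if R is None:
        return float(omega ** 2 @ s0_sq), float(omega ** 2 @ s1_sq)
    v0 = omega * np.sqrt(s0_sq)
    v1 = omega * np.sqrt(s1_sq)
    return R.quad_form(v0), R.quad_form(v1)


def compute_auc(omega, delta, tau0_sq: float, tau1_sq: float) -> AUCEstimate:
    """AUC = Phi(2 sum omega*delta / sqrt(tau0^2 + tau1^2))."""
    total_var = tau0_sq + tau1_sq
    if total_var <= 0:
        raise ValueError("degenerate PRS: zero total variance")
    omega = np.asarray(omega, dtype=float)
    delta = np.asarray(delta, dtype=float)
    d = 2.0 * float(omega @ delta) / np.sqrt(total_var)
    return AUCEstimate(delta_stat=d, auc_point=float(norm.cdf(d)))


def predicted_auc(omega, delta_draws, s0_sq, s1_sq,
                  R: LDMatrix | None = None) -> AUCEstimate:
    """Posterior AUC from Monte-Carlo draws of delta.

    The point estimate is the mean of the per-draw AUCs (the Monte-Carlo
    posterior expectation, not Phi of the mean Delta) and the interval the
    (2.5%, 97.5%) empirical quantiles.
    """
    delta_draws = np.asarray(delta_draws, dtype=float)
    if delta_draws.ndim != 2 or delta_draws.shape[0] == 0:
        raise ValueError("delta_draws must be a nonempty (n_draws, M) matrix")
    omega = np.asarray(omega, dtype=float)
    tau0_sq, tau1_sq = compute_tau_sq(omega, s0_sq, s1_sq, R)
    d = 2.0 * (delta_draws @ omega) / np.sqrt(tau0_sq + tau1_sq)
    draws = norm.cdf(d)
    lo, hi = np.quantile(draws, [0.025, 0.975])
    return AUCEstimate(delta_stat=float(np.mean(d)),
                       auc_point=float(np.mean(draws)),
                       auc_draws=draws, ci=(float(lo), float(hi)))


def unadjusted_auc(summary, omega, R: LDMatrix | None = None) -> AUCEstimate:
    """Overfit baseline: plug the observed differences z*s in as delta."""
    s0_sq, s1_sq = summary.group_variances()
    tau0_sq, tau1_sq = compute_tau_sq(np.asarray(omega, float), s0_sq, s1_sq, R)
    return compute_auc(omega, summary.z * summary.s, tau0_sq, tau1_sq)


def empirical_auc(prs_cases, prs_controls) -> float:
    """Probability a random case PRS exceeds a random control PRS
    (Mann-Whitney U / (n1 n0), ties counted one half)."""
    x = np.asarray(prs_cases, dtype=float)
    y = np.asarray(prs_controls, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    u = mannwhitneyu(x, y, alternative="two-sided").statistic
    return float(u) / (x.size * y.size)


def youden_sensitivity(prs_cases, prs_controls):
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    The search runs over the observed PRS values (predict case when
    PRS >= cutoff); ties in J break toward the smaller cutoff.  Returns
    (cutoff, sensitivity, specificity).
    """
    x = np.asarray(prs_cases, dtype=float)
    y = np.asarray(prs_controls, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    cuts = np.unique(np.concatenate([x, y]))
    sens = np.array([(x >= c).mean() for c in cuts])
    spec = np.array([(y < c).mean() for c in cuts])
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax returns the first (smallest) maximizer
    return float(cuts[best]), float(sens[best]), float(spec[best])


def sigma2_from_h2(h: HeritabilityParams) -> float:
    """Convert liability-scale heritability to the prior slab variance:

        sigma2 = (N_e h2_l / (4 M pi)) * phi(Phi^-1(kappa))^2
                 / (kappa^2 (1 - kappa)^2).
    """
    if not 0.0 < h.kappa < 1.0:
        raise ValueError("prevalence kappa must be in (0, 1)")
    if h.pi <= 0 or h.pi > 1:
        raise ValueError("pi must be in (0, 1]: no risk SNPs means no slab")
    if h.M < 1:
        raise ValueError("M must be >= 1")
    thr = norm.ppf(h.kappa)
    factor = norm.pdf(thr) ** 2 / (h.kappa ** 2 * (1 - h.kappa) ** 2)
    return float(h.n_eff * h.h2_liability / (4.0 * h.M * h.pi) * factor)
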