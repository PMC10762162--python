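"""Synthetic case/control GWAS studies with a point-normal architecture.

The generator produces, for one replicate: training summary statistics
(allele-frequency-difference z-scores), the generating truth, an
individual-level testing cohort, and (for correlated SNPs) a reference
panel.  Two LD regimes are supported:

* ``independent`` — SNP genotypes are independent binomials; training
  group frequencies are drawn as binomial proportions, so summary
  statistics are simulated without materializing training genotypes.
* ``ar1(rho)`` — genotypes are sums of two haplotypes, each a Markov
  chain of correlated Bernoulli draws whose lag-1 correlation is ``rho``,
  giving the AR(1) LD profile ``corr(g_i, g_j) = rho^|i-j|``.

Defaults follow the study conditions used throughout the package's
validation: population frequencies U(0.05, 0.95), risk-SNP proportion
``pi = 0.05``, slab variance ``sigma2 = 0.001 n`` (independent SNPs) or
``0.0005 n`` (AR(1), ``rho = 0.2``), prevalence ``kappa = 0.01``, a
balanced training GWAS, a 1000+1000 testing cohort, and a 1000-sample
reference panel.  Optional heterogeneity settings perturb the testing
cohort's pooled frequencies, risk effects, or LD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import PanelGenotypes, SummaryStats
from .ld import LDMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimStudy",
    "Heterogeneity",
    "ar1_ld_matrix",
    "feasible_adjacent_rho",
    "effective_adjacent_rho",
    "markov_corr_matrix",
    "simulate_ar1_haplotypes",
    "simulate_study",
    "preset",
]

FREQ_CLIP = (0.01, 0.99)


@dataclass
class Heterogeneity:
    """Training/testing heterogeneity scenarios (testing side perturbed)."""

    freq_shift_sd: float = 0.0     # pooled-frequency shift ~ N(0, sd^2)
    effect_shift_var: float = 0.0  # risk-effect shift ~ N(0, var), z-scale
    test_rho: float | None = None  # different AR(1) coefficient in testing


@dataclass
class SimConfig:
    """Study-design parameters for one synthetic replicate."""

    M: int = 10_000
    n0: int = 5_000
    n1: int = 5_000
    kappa: float = 0.01
    pi_true: float = 0.05
    sigma2_true: float | None = None  # default: 0.001*n indep, 0.0005*n AR(1)
    ld: str = "independent"           # "independent" or "ar1"
    rho: float = 0.2
    n_test_cases: int = 1_000
    n_test_controls: int = 1_000
    n_ref: int = 1_000
    heterogeneity: Heterogeneity | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ld not in ("independent", "ar1"):
            raise ValueError(f"unknown LD regime {self.ld!r}")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("AR(1) rho must lie in (-1, 1)")
        if not 0.0 < self.kappa < 1.0:
            raise ValueError("prevalence kappa must lie in (0, 1)")
        if not 0.0 <= self.pi_true <= 1.0:
            raise ValueError("pi_true must lie in [0, 1]")
        for name in ("M", "n0", "n1", "n_test_cases", "n_test_controls"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def n(self) -> int:
        return self.n0 + self.n1

    @property
    def sigma2(self) -> float:
        if self.sigma2_true is not None:
            return self.sigma2_true
        return (0.001 if self.ld == "independent" else 0.0005) * self.n


def preset(name: str, n: int = 10_000, **overrides) -> SimConfig:
    """Named study designs; ``n`` is the total training sample size."""
    base = dict(n0=n // 2, n1=n - n // 2)
    presets = {
        "study_independent": dict(M=10_000, ld="independent", **base),
        "study_ar1": dict(M=2_000, ld="ar1", rho=0.2, **base),
        "study_het_freq": dict(M=2_000, ld="ar1", rho=0.2,
                               heterogeneity=Heterogeneity(freq_shift_sd=0.01),
                               **base),
        "study_het_effect": dict(M=2_000, ld="ar1", rho=0.2,
                                 heterogeneity=Heterogeneity(
                                     effect_shift_var=0.0002 * n),
                                 **base),
        "study_het_ld": dict(M=2_000, ld="ar1", rho=0.2,
                             heterogeneity=Heterogeneity(test_rho=0.15),
                             **base),
    }
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    cfg = presets[name]
    cfg.update(overrides)
    return SimConfig(**cfg)


@dataclass
class SimTruth:
    """Generating quantities of one replicate."""

    f: np.ndarray            # population allele frequencies
    gamma_true: np.ndarray   # risk indicators
    beta_true: np.ndarray    # per-SNP effects p1 - p0 (frequency scale)
    delta_true: np.ndarray   # marginal differences S R S^-1 beta
    f0: np.ndarray           # control group frequencies
    f1: np.ndarray           # case group frequencies
    s_null: np.ndarray       # z denominators at f0 = f1 = f
    R_true: LDMatrix | None  # analytic LD (None = independent)


@dataclass
class SimStudy:
    """One synthetic study: training summaries, truth, testing, panel."""

    stats: SummaryStats
    truth: SimTruth
    test_cases: np.ndarray      # (n_test_cases, M) dosages
    test_controls: np.ndarray   # (n_test_controls, M)
    panel: PanelGenotypes | None = None


def ar1_ld_matrix(M: int, rho: float) -> np.ndarray:
    """Analytic AR(1) correlation matrix R_ij = rho^|i-j|."""
    if not -1.0 < rho < 1.0:
        raise ValueError("|rho| must be < 1")
    k = np.arange(M)
    return rho ** np.abs(np.subtract.outer(k, k))


def feasible_adjacent_rho(freqs) -> np.ndarray:
    """Largest correlation each adjacent Bernoulli pair can support.

    For marginals (p, p') the Frechet bounds cap the correlation at
    ``min(sqrt(p q' / (q p')), sqrt(p' q / (q' p)))`` — two very different
    frequencies cannot be strongly positively correlated.
    """
    p = np.asarray(freqs, dtype=float)
    q = 1.0 - p
    odds = p / q
    ratio = odds[:-1] / odds[1:]
    return np.sqrt(np.minimum(ratio, 1.0 / ratio))


def effective_adjacent_rho(freqs, rho: float,
                           safety: float = 0.999) -> np.ndarray:
    """Per-pair Markov correlation: the target ``rho`` clipped to slightly
    inside each pair's feasible bound."""
    if rho < 0:
        raise ValueError("feasibility clipping supports nonnegative rho only")
    return np.minimum(rho, safety * feasible_adjacent_rho(freqs))


def markov_corr_matrix(adjacent_rhos: np.ndarray, tol: float = 1e-14
                       ) -> np.ndarray:
    """Correlation matrix of a Markov chain with the given lag-1
    correlations: correlations multiply along the chain,
    ``R_ij = prod_{k=i..j-1} rho_k`` (entries below ``tol`` set to 0)."""
    r = np.asarray(adjacent_rhos, dtype=float)
    if np.any(r <= 0):
        raise ValueError("adjacent correlations must be positive")
    M = r.size + 1
    logc = np.concatenate([[0.0], np.cumsum(np.log(r))])
    R = np.eye(M)
    for k in range(1, M):
        vals = np.exp(logc[k:] - logc[:-k])
        if vals.max() < tol:
            break
        vals[vals < tol] = 0.0
        i = np.arange(M - k)
        R[i, i + k] = vals
        R[i + k, i] = vals
    return R


def simulate_ar1_haplotypes(n: int, freqs, rho: float, rng,
                            clip_to_feasible: bool = False) -> np.ndarray:
    """Binary haplotypes as a Markov chain of correlated Bernoulli draws.

    Column ``m`` has marginal frequency ``freqs[m]``; adjacent columns have
    correlation ``rho`` (hence lag-k correlation ``rho^k``).  The required
    transition probabilities must lie in [0, 1]; architectures violating
    that are rejected with the offending SNP pair named, unless
    ``clip_to_feasible`` lowers the offending pairs' correlation to just
    inside the feasible bound.
    """
    rng = np.random.default_rng(rng)
    p = np.asarray(freqs, dtype=float)
    M = p.size
    q = 1.0 - p
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("haplotype frequencies must lie strictly in (0, 1)")
    rhos = (effective_adjacent_rho(p, rho) if clip_to_feasible
            else np.full(M - 1, rho))
    # transition terms: cov(X_m, X_{m+1}) = rho_m * sqrt(p_m q_m p_{m+1} q_{m+1})
    cov = rhos * np.sqrt(p[:-1] * q[:-1] * p[1:] * q[1:])
    p11 = p[1:] + cov / p[:-1]     # P(X_{m+1}=1 | X_m=1)
    p01 = p[1:] - cov / q[:-1]     # P(X_{m+1}=1 | X_m=0)
    bad = np.where((p11 < -1e-12) | (p11 > 1 + 1e-12)
                   | (p01 < -1e-12) | (p01 > 1 + 1e-12))[0]
    if bad.size:
        m = int(bad[0])
        raise ValueError(
            f"invalid Markov transition between SNPs {m} and {m + 1} "
            f"(freqs {p[m]:.3f}, {p[m + 1]:.3f}, rho={rho})")
    p11, p01 = np.clip(p11, 0, 1), np.clip(p01, 0, 1)
    H = np.empty((n, M), dtype=np.int8)
    u = rng.random((n, M))
    H[:, 0] = u[:, 0] < p[0]
    for m in range(1, M):
        prob = np.where(H[:, m - 1] == 1, p11[m - 1], p01[m - 1])
        H[:, m] = u[:, m] < prob
    return H


def _ar1_genotypes(n: int, freqs, rho: float, rng) -> np.ndarray:
    """Dosages as the sum of two independent haplotypes (feasibility-clipped)."""
    return (simulate_ar1_haplotypes(n, freqs, rho, rng, clip_to_feasible=True)
            .astype(np.int16)
            + simulate_ar1_haplotypes(n, freqs, rho, rng, clip_to_feasible=True))


def simulate_study(cfg: SimConfig) -> SimStudy:
    """Generate one synthetic study under ``cfg``.

    Effects are drawn on the standardized scale
    ``beta/s ~ (1-pi) delta_0 + pi N(0, sigma2)`` with ``s`` evaluated at
    the null (``f0 = f1 = f``), then mapped to group frequencies by the
    retrospective construction ``f0 = f``, ``f1 = f + delta`` with
    ``delta = S R S^-1 beta`` (equal to ``beta`` for independent SNPs),
    clipped to [0.01, 0.99].
    """
    rng = np.random.default_rng(cfg.seed)
    M = cfg.M
    f = rng.uniform(0.05, 0.95, size=M)
    s_null = np.sqrt(2 * f * (1 - f) * (1.0 / (4 * cfg.n0) + 1.0 / (4 * cfg.n1)))

    gamma = rng.random(M) < cfg.pi_true
    beta_std = np.where(gamma, np.sqrt(cfg.sigma2) * rng.standard_normal(M), 0.0)
    beta = beta_std * s_null

    if cfg.ld == "independent":
        R_true = None
        delta = beta.copy()
    else:
        # correlations clipped to the per-pair feasible bound, so the truth
        # LD matrix is the realized Markov structure, not plain rho^|i-j|
        R_dense = markov_corr_matrix(effective_adjacent_rho(f, cfg.rho))
        R_true = LDMatrix.from_dense(R_dense)
        delta = s_null * (R_dense @ beta_std)

    f0 = f.copy()
    f1 = f + delta
    clipped = (f1 < FREQ_CLIP[0]) | (f1 > FREQ_CLIP[1])
    n_clip = int(clipped.sum())
    if n_clip > 0.01 * M:
        warnings.warn(
            f"{n_clip} of {M} case frequencies clipped: the simulated "
            "architecture is too strong for the allele-frequency scale",
            RuntimeWarning)
    f1 = np.clip(f1, *FREQ_CLIP)
    # only clipped entries get a recomputed delta; elsewhere delta (and, for
    # independent SNPs, beta) is preserved bit-exactly
    delta = np.where(clipped, f1 - f0, delta)

    truth = SimTruth(f=f, gamma_true=gamma, beta_true=beta, delta_true=delta,
                     f0=f0, f1=f1, s_null=s_null, R_true=R_true)

    het = cfg.heterogeneity or Heterogeneity()

    if cfg.ld == "independent":
        f0_hat = rng.binomial(2 * cfg.n0, f0) / (2 * cfg.n0)
        f1_hat = rng.binomial(2 * cfg.n1, f1) / (2 * cfg.n1)
        stats = _stats_from_freqs(f0_hat, f1_hat, cfg, M)
        f0_t, f1_t = _testing_freqs(f0, f1, cfg, het, rng, s_null, gamma, f)
        test_cases = rng.binomial(2, f1_t, size=(cfg.n_test_cases, M)).astype(np.int16)
        test_controls = rng.binomial(2, f0_t, size=(cfg.n_test_controls, M)).astype(np.int16)
        panel = None
        if cfg.n_ref > 0:
            panel = _panel_from_matrix(
                rng.binomial(2, f, size=(cfg.n_ref, M)).astype(np.int16), M)
    else:
        g_ctrl = _ar1_genotypes(cfg.n0, f0, cfg.rho, rng)
        g_case = _ar1_genotypes(cfg.n1, f1, cfg.rho, rng)
        f0_hat = np.clip(g_ctrl.mean(axis=0) / 2.0, 1e-4, 1 - 1e-4)
        f1_hat = np.clip(g_case.mean(axis=0) / 2.0, 1e-4, 1 - 1e-4)
        stats = _stats_from_freqs(f0_hat, f1_hat, cfg, M)
        f0_t, f1_t = _testing_freqs(f0, f1, cfg, het, rng, s_null, gamma, f)
        rho_t = het.test_rho if het.test_rho is not None else cfg.rho
        test_cases = _ar1_genotypes(cfg.n_test_cases, f1_t, rho_t, rng)
        test_controls = _ar1_genotypes(cfg.n_test_controls, f0_t, rho_t, rng)
        panel = _panel_from_matrix(_ar1_genotypes(cfg.n_ref, f, cfg.rho, rng), M) \
            if cfg.n_ref > 0 else None

    return SimStudy(stats=stats, truth=truth, test_cases=test_cases,
                    test_controls=test_controls, panel=panel)


def _testing_freqs(f0, f1, cfg, het: Heterogeneity, rng, s_null, gamma, f):
    """Group frequencies of the testing cohort under the heterogeneity
    scenarios (identical to training when no scenario is active)."""
    f0_t, f1_t = f0, f1
    if het.effect_shift_var > 0:
        shift_std = np.where(
            gamma, np.sqrt(het.effect_shift_var) * rng.standard_normal(f0.size), 0.0)
        f1_t = np.clip(f0 + (f1 - f0) + shift_std * s_null, *FREQ_CLIP)
    if het.freq_shift_sd > 0:
        e = rng.normal(0.0, het.freq_shift_sd, size=f0.size)
        f0_t = np.clip(f0_t + e, *FREQ_CLIP)
        f1_t = np.clip(f1_t + e, *FREQ_CLIP)
    return f0_t, f1_t


def _stats_from_freqs(f0_hat, f1_hat, cfg: SimConfig, M: int) -> SummaryStats:
    eps = 1.0 / (4 * max(cfg.n0, cfg.n1))
    f0_hat = np.clip(f0_hat, eps, 1 - eps)
    f1_hat = np.clip(f1_hat, eps, 1 - eps)
    s0_sq = 2 * f0_hat * (1 - f0_hat)
    s1_sq = 2 * f1_hat * (1 - f1_hat)
    s = np.sqrt(s1_sq / (4 * cfg.n1) + s0_sq / (4 * cfg.n0))
    z = (f1_hat - f0_hat) / s
    ids = np.array([f"snp{i}" for i in range(M)], dtype=object)
    return SummaryStats(snp_id=ids, z=z, n0=cfg.n0, n1=cfg.n1,
                        chrom=np.repeat("1", M).astype(object),
                        pos=np.arange(1, M + 1, dtype=float),
                        f0_hat=f0_hat, f1_hat=f1_hat,
                        f_pooled=(cfg.n0 * f0_hat + cfg.n1 * f1_hat) / cfg.n)


def _panel_from_matrix(G: np.ndarray, M: int) -> PanelGenotypes:
    ids = np.array([f"snp{i}" for i in range(M)], dtype=object)
    return PanelGenotypes(genotypes=G, snp_id=ids,
                          chrom=np.repeat("1", M).astype(object),
                          pos=np.arange(1, M + 1, dtype=float))
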