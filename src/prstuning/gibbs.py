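"""State-Augmentation-for-Marginal-Estimation (SAME) Gibbs sampler.

When the pre-selected SNPs are linked by LD, the z-scores are jointly
normal given the standardized effects beta~ = beta/s:

    z | beta~  ~  N(R beta~, R),

with R the SNP correlation (LD) matrix, and each beta~_m carries the
spike-and-slab prior (1-pi) delta_0 + pi N(0, sigma2).  The marginal
likelihood P(z | pi, sigma2) sums over 2^M spike/slab configurations, so
its maximizer is found stochastically: the sampler carries D replicated
copies of the latent (beta~, gamma), incremented by one every sweep, so
that the hyperparameters are effectively drawn from a density proportional
to P(z | pi, sigma2)^D — a distribution that concentrates on the maximum
likelihood estimate as D grows.

One sweep, for every replicate d and SNP m (replicates never interact, so
the implementation vectorizes over d):

    mu_m    = lam (z_m - sum_{m' != m} R_mm' beta~_m')
    log r_m = log pi + (log(lam/sigma2))/2 + mu_m^2/(2 lam)
    h_m     = r_m / ((1 - pi) + r_m)
    gamma_m ~ Bernoulli(h_m)         (beta~_m integrated out)
    beta~_m ~ N(mu_m, lam) if gamma_m = 1, else beta~_m = 0

— a partially collapsed scan that keeps every (beta~_m, gamma_m) pair
consistent within the visit — with lam = 1/(1 + 1/sigma2), followed by
conjugate refreshes

    pi        ~ Beta(sum gamma + D, MD - sum gamma + D)
    sigma^-2  ~ Gamma(sum(gamma)/2 + D, sum(beta~^2 gamma)/2).

All spike/slab odds are computed in log-space, so the sampler is
overflow-safe for |mu| into the hundreds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .em import PointNormalPrior
from .ld import LDMatrix

__all__ = ["GibbsConfig", "SAMEDraws", "same_fit", "delta_from_beta"]


@dataclass
class GibbsConfig:
    """Sampler schedule and convergence rule."""

    max_sweeps: int = 500
    burn_in: int = 50            # sweeps before convergence checks start
    conv_window: int = 20        # sliding-window length for the stop rule
    conv_tol: float = 5e-3       # relative change of windowed pi, sigma2
    seed: int = 0
    n_posterior_draws: int = 1000
    decorrelation_sweeps: int = 30

    def __post_init__(self) -> None:
        if self.max_sweeps < self.burn_in + self.conv_window:
            raise ValueError("max_sweeps must be >= burn_in + conv_window")
        if self.n_posterior_draws < 1:
            raise ValueError("n_posterior_draws must be >= 1")


@dataclass
class SAMEDraws:
    """Posterior draws of the latent effects at the fitted (pi, sigma2)."""

    beta_std: np.ndarray   # (n_draws, M) standardized effects beta/s
    gamma: np.ndarray      # (n_draws, M) spike/slab indicators
    pi_trace: np.ndarray
    sigma2_trace: np.ndarray


_MAX_CHROMATIC_BW = 64


class _BlockState:
    """Per-block sweep plan.

    For banded blocks (bandwidth <= 64) the scan is chromatic: SNPs are
    partitioned into ``bandwidth + 1`` color classes whose members never
    neighbor each other, so a whole class is conditionally independent
    given the rest and can be updated in one vectorized step.  Wide/dense
    blocks fall back to a per-SNP scan.
    """

    __slots__ = ("idx", "R", "z", "bandwidth", "colors", "diags", "spans")

    def __init__(self, idx: np.ndarray, R: np.ndarray, z: np.ndarray):
        self.idx = idx
        self.R = R
        self.z = z[idx]
        bs = R.shape[0]
        nz_i, nz_j = np.nonzero(R)
        self.bandwidth = int(np.max(np.abs(nz_i - nz_j))) if nz_i.size else 0
        if self.bandwidth <= _MAX_CHROMATIC_BW:
            nc = self.bandwidth + 1
            self.colors = [np.arange(c0, bs, nc) for c0 in range(nc)]
            # diags[k][i] = R[i, i+k]
            self.diags = [np.diagonal(R, k).copy()
                          for k in range(1, self.bandwidth + 1)]
            self.spans = None
        else:
            self.colors = None
            self.diags = None
            spans = []
            for j in range(bs):
                nz = np.nonzero(R[:, j])[0]
                lo, hi = (int(nz[0]), int(nz[-1]) + 1) if nz.size else (j, j + 1)
                spans.append((lo, hi, R[lo:hi, j].copy()))
            self.spans = spans


def _sweep(blocks, B, G, resid, lam, pi, sigma2, rng):
    """One scan over all SNPs, vectorized over replicates/chains.

    ``lam``, ``pi`` and ``sigma2`` may be scalars or per-row (chain)
    vectors of length ``B.shape[0]``; the update is the partially
    collapsed move: gamma_m from its conditional with beta_m integrated
    out, then beta_m | gamma_m, keeping every (beta, gamma) pair
    consistent.
    """
    log_odds0 = np.log(pi) - np.log1p(-pi) + 0.5 * (np.log(lam) - np.log(sigma2))
    sqrt_lam = np.sqrt(lam)
    D = B.shape[0]
    if np.ndim(lam):  # per-chain parameters: give them a column axis
        lam_c, sqrt_lam_c, log_odds0_c = (lam[:, None], sqrt_lam[:, None],
                                          log_odds0[:, None])
    else:
        lam_c, sqrt_lam_c, log_odds0_c = lam, sqrt_lam, log_odds0
    # one RNG batch per sweep, indexed by global SNP column: the random
    # numbers a SNP consumes do not depend on the block layout, so
    # independent blocks give bit-identical results in any partitioning
    unif = rng.random((D, B.shape[1]))
    norm = rng.standard_normal((D, B.shape[1]))
    for blk in blocks:
        idx = blk.idx
        if blk.colors is not None:
            bs = blk.R.shape[0]
            for cls in blk.colors:
                cols = idx[cls]
                bc = B[:, cols]
                mu = lam_c * (blk.z[cls] - (resid[:, cols] - bc))
                h = expit(log_odds0_c + mu * mu / (2.0 * lam_c))
                g_new = unif[:, cols] < h
                new = np.where(g_new, mu + sqrt_lam_c * norm[:, cols], 0.0)
                d = new - bc
                B[:, cols] = new
                G[:, cols] = g_new
                resid[:, cols] += d
                for k, vals in enumerate(blk.diags, start=1):
                    m = cls >= k
                    if m.any():
                        tgt = cls[m] - k
                        resid[:, idx[tgt]] += vals[tgt] * d[:, m]
                    m = cls + k < bs
                    if m.any():
                        tgt = cls[m] + k
                        resid[:, idx[tgt]] += vals[cls[m]] * d[:, m]
        else:
            for j, (lo, hi, col) in enumerate(blk.spans):
                gcol = idx[j]
                bj = B[:, gcol]
                mu = lam * (blk.z[j] - (resid[:, gcol] - bj))
                h = expit(log_odds0 + mu * mu / (2.0 * lam))
                g_new = unif[:, gcol] < h
                new = np.where(g_new, mu + sqrt_lam * norm[:, gcol], 0.0)
                d = new - bj
                B[:, gcol] = new
                G[:, gcol] = g_new
                resid[:, idx[lo:hi]] += d[:, None] * col[None, :]


def _init_resid(blocks, B):
    resid = np.empty_like(B)
    for blk in blocks:
        resid[:, blk.idx] = B[:, blk.idx] @ blk.R
    return resid


def same_fit(z, s, R: LDMatrix, config: GibbsConfig | None = None
             ) -> tuple[PointNormalPrior, SAMEDraws]:
    """Estimate (pi, sigma2) by SAME and draw posterior effects under LD.

    Returns the hyperparameter estimate (the final-sweep draw, which the
    growing replicate count pins to the MLE) and ``config.n_posterior_draws``
    draws of the standardized effects (beta/s, gamma) generated at the
    frozen estimate for downstream delta and AUC sampling.
    """
    cfg = config or GibbsConfig()
    z = np.asarray(z, dtype=float)
    s = np.asarray(s, dtype=float)
    if z.shape != s.shape or z.ndim != 1:
        raise ValueError("z and s must be aligned vectors")
    if R.n_snps != z.size:
        raise ValueError(
            f"LD matrix covers {R.n_snps} SNPs, summary statistics {z.size}")
    if not np.all(np.isfinite(z)):
        raise ValueError("z contains non-finite values")
    M = z.size
    rng = np.random.default_rng(cfg.seed)
    blocks = [_BlockState(idx, Rb, z) for idx, Rb in R.blocks]

    pi = 0.1
    sigma2 = max(float(np.mean(z ** 2)) - 1.0, 0.5)
    lam = sigma2 / (1.0 + sigma2)

    G = rng.random((1, M)) < pi
    B = np.where(G, np.sqrt(sigma2) * rng.standard_normal((1, M)), 0.0)
    resid = _init_resid(blocks, B)

    pi_trace, sigma2_trace = [], []
    converged = False
    sweep = 0
    rate_floored = False
    for sweep in range(1, cfg.max_sweeps + 1):
        D = B.shape[0]
        _sweep(blocks, B, G, resid, lam, pi, sigma2, rng)

        sum_gamma = float(G.sum())
        sum_b2 = float((B * B * G).sum())
        pi = rng.beta(sum_gamma + D, M * D - sum_gamma + D)
        pi = min(max(pi, 1e-12), 1 - 1e-12)
        rate = 0.5 * sum_b2
        if rate <= 0:
            rate = 1e-12
            rate_floored = True
        inv_sigma2 = rng.gamma(0.5 * sum_gamma + D, 1.0 / rate)
        sigma2 = float(np.clip(1.0 / inv_sigma2, 1e-10, 1e10))
        lam = sigma2 / (1.0 + sigma2)
        pi_trace.append(pi)
        sigma2_trace.append(sigma2)

        if sweep >= max(cfg.burn_in, 2 * cfg.conv_window):
            w = cfg.conv_window
            p_new, p_old = np.mean(pi_trace[-w:]), np.mean(pi_trace[-2 * w:-w])
            s_new, s_old = np.mean(sigma2_trace[-w:]), np.mean(sigma2_trace[-2 * w:-w])
            if (abs(p_new - p_old) / max(p_old, 1e-12) < cfg.conv_tol
                    and abs(s_new - s_old) / max(s_old, 1e-12) < cfg.conv_tol):
                converged = True
                break

        # grow the replicate population: D <- D + 1
        src = int(rng.integers(B.shape[0]))
        B = np.vstack([B, B[src]])
        G = np.vstack([G, G[src]])
        resid = np.vstack([resid, resid[src]])

    if rate_floored:
        warnings.warn("all spike/slab indicators were zero in some sweep; "
                      "sigma^-2 rate floored at 1e-12", RuntimeWarning)
    if not converged:
        warnings.warn(f"SAME sampler hit max_sweeps={cfg.max_sweeps} without "
                      "meeting the convergence rule", RuntimeWarning)

    prior = PointNormalPrior(pi=float(pi), sigma2=float(sigma2),
                             converged=converged, n_iter=sweep)

    # posterior draws at the frozen estimate: continue n_posterior_draws
    # independent replicate chains for a short decorrelation run
    n_draws = cfg.n_posterior_draws
    take = rng.integers(B.shape[0], size=n_draws)
    Bd, Gd = B[take].copy(), G[take].copy()
    resid_d = resid[take].copy()
    for _ in range(cfg.decorrelation_sweeps):
        _sweep(blocks, Bd, Gd, resid_d, lam, pi, sigma2, rng)

    draws = SAMEDraws(beta_std=Bd * Gd, gamma=Gd,
                      pi_trace=np.asarray(pi_trace),
                      sigma2_trace=np.asarray(sigma2_trace))
    return prior, draws


def delta_from_beta(beta_draws, s, R: LDMatrix) -> np.ndarray:
    """Map effect draws to allele-frequency differences: delta = S R S^-1 beta.

    ``beta_draws`` is (n_draws, M) on the raw frequency-difference scale;
    the product is computed block-wise.  With R = I this is the identity.
    """
    beta_draws = np.asarray(beta_draws, dtype=float)
    s = np.asarray(s, dtype=float)
    if beta_draws.ndim != 2 or beta_draws.shape[1] != s.size:
        raise ValueError("beta_draws must be (n_draws, M) matching s")
    if R.n_snps != s.size:
        raise ValueError("LD matrix does not match the number of SNPs")
    if all(np.array_equal(Rb, np.eye(Rb.shape[0])) for _, Rb in R.blocks):
        return beta_draws.copy()  # delta = beta, bit-exactly
    return R.matvec(beta_draws / s) * s
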