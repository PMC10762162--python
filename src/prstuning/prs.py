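"""Minimal in-repo PRS weight fitters used to generate candidate weight
grids: p-value thresholding after LD pruning (P+T), LD clumping plus
thresholding (C+T), and an LDpred-style spike-and-slab Gibbs fitter.

These produce the weight sets whose AUC the tuner predicts; they make no
claim of numeric parity with the published P+T/C+T/LDpred tools.  For
P+T and C+T the per-SNP weight is the observed standardized effect
``z_m s_m`` (the allele-frequency-difference scale); any monotone per-SNP
rescaling gives the same AUC ordering for these methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from .gibbs import _BlockState, _init_resid, _sweep
from .io import PRSWeightSet, SummaryStats
from .ld import LDMatrix

__all__ = ["GridSpec", "pt_weights", "ct_weights", "ldpred_style_weights",
           "PT_THRESHOLDS", "LDPRED_PI_GRID"]

#: p-value threshold grid for P+T / C+T
PT_THRESHOLDS = (1.0, 5e-1, 5e-2, 5e-3, 5e-4, 5e-5, 5e-6)
#: risk-SNP proportion grid for the LDpred-style fitter
LDPRED_PI_GRID = (1.0, 3e-1, 1e-1, 3e-2, 1e-2, 3e-3, 1e-3, 3e-4, 1e-4, 3e-5, 1e-5)


@dataclass
class GridSpec:
    """Tuning grid of one PRS method."""

    method: str                     # "PT", "CT" or "LDPRED_STYLE"
    values: tuple = PT_THRESHOLDS   # p thresholds (PT/CT) or pi values
    r2_threshold: float = 0.1
    window: int = 250               # pruning/clumping window, in SNPs
    ld_radius: int | None = None    # LDPRED_STYLE only

    def __post_init__(self) -> None:
        if self.method not in ("PT", "CT", "LDPRED_STYLE"):
            raise ValueError(f"unknown method {self.method!r}")
        vals = np.asarray(self.values, dtype=float)
        if np.any((vals <= 0) | (vals > 1)):
            raise ValueError("grid values must lie in (0, 1]")
        if not 0.0 <= self.r2_threshold <= 1.0:
            raise ValueError("r2_threshold must lie in [0, 1]")


def _r2_lookup(R: LDMatrix | None):
    """Map global index -> (block id, within-block position); returns a
    pairwise-r2 accessor that is 0 across blocks."""
    if R is None:
        return lambda i, j: 0.0
    where = {}
    for b, (idx, _) in enumerate(R.blocks):
        for k, g in enumerate(idx):
            where[int(g)] = (b, k)
    mats = [Rb for _, Rb in R.blocks]

    def r2(i, j):
        bi, ki = where[i]
        bj, kj = where[j]
        if bi != bj:
            return 0.0
        return mats[bi][ki, kj] ** 2

    return r2


def _threshold_sets(summary: SummaryStats, kept: np.ndarray, grid: GridSpec,
                    method_label: str) -> list[PRSWeightSet]:
    """One weight set per p-value threshold, omega = z*s on surviving SNPs."""
    p = summary.pvalues()
    base = summary.z * summary.s
    out = []
    for t in grid.values:
        omega = np.where(kept & (p <= t), base, 0.0)
        label = f"pval={t:g}"
        if not np.any(omega != 0):
            warnings.warn(f"{method_label}: no SNP passes threshold {t:g}; "
                          "weight set skipped", RuntimeWarning)
            continue
        out.append(PRSWeightSet(snp_id=summary.snp_id, omega=omega,
                                method_label=method_label, param_label=label,
                                a1=None if summary.a1 is None else summary.a1))
    return out


def pt_weights(summary: SummaryStats, R: LDMatrix | None,
               grid: GridSpec) -> list[PRSWeightSet]:
    """P+T: association-agnostic LD pruning, then p-value thresholding.

    Greedy pruning in input (chrom, pos) order keeps a SNP iff its r^2
    with every previously kept SNP inside the window stays below
    ``grid.r2_threshold``.  The pruned-in set is identical for every
    threshold; thresholds only mask it.
    """
    M = summary.n_snps
    r2 = _r2_lookup(R)
    kept_idx: list[int] = []
    kept = np.zeros(M, dtype=bool)
    for m in range(M):
        ok = True
        for k in reversed(kept_idx):
            if m - k > grid.window:
                break
            if r2(m, k) >= grid.r2_threshold:
                ok = False
                break
        if ok:
            kept_idx.append(m)
            kept[m] = True
    return _threshold_sets(summary, kept, grid, "PT")


def ct_weights(summary: SummaryStats, R: LDMatrix | None,
               grid: GridSpec) -> list[PRSWeightSet]:
    """C+T: per threshold, clump the passing SNPs by ascending p-value.

    The most significant SNP is kept and all passing SNPs within the
    window with r^2 >= ``grid.r2_threshold`` to it are removed; repeat.
    """
    p = summary.pvalues()
    base = summary.z * summary.s
    r2 = _r2_lookup(R)
    out = []
    for t in grid.values:
        cand = np.where(p <= t)[0]
        order = cand[np.lexsort((cand, p[cand]))]  # p ascending, index tie-break
        removed = set()
        kept: list[int] = []
        for m in order:
            m = int(m)
            if m in removed:
                continue
            kept.append(m)
            lo = int(np.searchsorted(cand, m - grid.window))
            hi = int(np.searchsorted(cand, m + grid.window, side="right"))
            for j in cand[lo:hi]:
                j = int(j)
                if j != m and j not in removed \
                        and r2(m, j) >= grid.r2_threshold:
                    removed.add(j)
        omega = np.zeros(summary.n_snps)
        omega[kept] = base[kept]
        label = f"pval={t:g}"
        if not np.any(omega != 0):
            warnings.warn(f"CT: no SNP passes threshold {t:g}; weight set "
                          "skipped", RuntimeWarning)
            continue
        out.append(PRSWeightSet(snp_id=summary.snp_id, omega=omega,
                                method_label="CT", param_label=label,
                                a1=None if summary.a1 is None else summary.a1))
    return out


def ldpred_style_weights(summary: SummaryStats, R: LDMatrix | None,
                         pi_values=LDPRED_PI_GRID,
                         sigma2_total: float | None = None,
                         burn_in: int = 100, n_iter: int = 500,
                         seed=0) -> list[PRSWeightSet]:
    """Spike-and-slab Gibbs posterior-mean weights, one set per pi.

    For each candidate risk proportion ``pi`` the slab variance is
    ``sigma2_total / pi`` with the total standardized signal
    ``sigma2_total = max(mean(z^2) - 1, 1e-3)`` estimated from the
    z-scores (supply ``sigma2_total`` to override, e.g. from a
    heritability estimate).  A Gibbs chain over the standardized effects
    runs per pi — all chains vectorized together — and the weight is the
    posterior mean effect mapped back to the frequency-difference scale.
    Pass ``R`` banded to the desired LD radius beforehand.
    """
    z = summary.z
    s = summary.s
    M = z.size
    if R is None:
        R = LDMatrix.identity(M)
    pis = np.asarray(pi_values, dtype=float)
    if np.any((pis <= 0) | (pis > 1)):
        raise ValueError("pi values must lie in (0, 1]")
    if sigma2_total is None:
        sigma2_total = max(float(np.mean(z ** 2)) - 1.0, 1e-3)
    sigma2 = sigma2_total / pis                 # per-chain slab variance
    lam = sigma2 / (1.0 + sigma2)
    pis_clipped = np.minimum(pis, 1 - 1e-12)    # keep log-odds finite at pi=1

    K = pis.size
    rng = np.random.default_rng(seed)
    G = rng.random((K, M)) < pis[:, None]
    B = np.where(G, np.sqrt(sigma2)[:, None] * rng.standard_normal((K, M)), 0.0)

    blocks = [_BlockState(idx, Rb, z) for idx, Rb in R.blocks]
    resid = _init_resid(blocks, B)

    mean_B = np.zeros((K, M))
    half_sums = np.zeros((2, K))
    n_kept = 0
    for it in range(burn_in + n_iter):
        _sweep(blocks, B, G, resid, lam, pis_clipped, sigma2, rng)
        if it >= burn_in:
            mean_B += B
            half_sums[0 if n_kept < n_iter // 2 else 1] += (B ** 2).sum(axis=1)
            n_kept += 1
    mean_B /= n_kept

    # crude split-half stationarity check on the chain energy
    h1, h2 = half_sums[0] / max(n_iter // 2, 1), half_sums[1] / max(n_iter - n_iter // 2, 1)
    drift = np.abs(h2 - h1) / np.maximum(np.maximum(h1, h2), 1e-12)
    if np.any(drift > 0.5):
        warnings.warn("LDpred-style chain(s) show a large first/second half "
                      f"drift (max {drift.max():.2f}); weights may be "
                      "unconverged", RuntimeWarning)

    out = []
    for k, pi_k in enumerate(pis):
        omega = mean_B[k] * s
        label = f"pi={pi_k:g}"
        if not np.any(omega != 0):
            warnings.warn(f"LDPRED_STYLE: all-zero posterior mean at pi={pi_k:g}; "
                          "weight set skipped", RuntimeWarning)
            continue
        out.append(PRSWeightSet(snp_id=summary.snp_id, omega=omega,
                                method_label="LDPRED_STYLE", param_label=label,
                                a1=None if summary.a1 is None else summary.a1))
    return out
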