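"""Block-diagonal LD (SNP correlation) matrices from a reference panel.

The genome is partitioned into approximately independent blocks (an
LDetect-style block file, or fixed windows when none is given); within each
block the correlation matrix of the standardized genotypes is estimated
with the Ledoit-Wolf shrinkage estimator, optionally banded to an LD
radius and repaired to positive semi-definiteness by eigenvalue clipping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GwasValidationError, PanelGenotypes

__all__ = ["LDBlockSet", "LDMatrix", "ledoit_wolf_correlation",
           "banded_ledoit_wolf_correlation", "band_and_repair", "build_ld"]

PSD_TOL = 1e-8
DEFAULT_WINDOW_SNPS = 1000


@dataclass
class LDBlockSet:
    """Half-open genomic intervals [start, end) partitioning the SNPs."""

    intervals: list  # of (chrom: str, start: int, end: int)

    def __post_init__(self) -> None:
        by_chrom: dict[str, list] = {}
        for chrom, start, end in self.intervals:
            if end <= start:
                raise GwasValidationError(
                    f"empty/inverted block {chrom}:{start}-{end}")
            by_chrom.setdefault(str(chrom), []).append((int(start), int(end)))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, _) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise GwasValidationError(
                        f"overlapping blocks on chromosome {chrom} at {s2}")
        self._by_chrom = by_chrom

    @classmethod
    def from_bed(cls, path) -> "LDBlockSet":
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                         names=["chrom", "start", "end"])
        return cls(list(df.itertuples(index=False, name=None)))

    def assign(self, chrom, pos) -> np.ndarray:
        """Block index for each SNP; raises if any SNP falls outside."""
        keys = [(str(c), int(s), int(e)) for c, s, e in self.intervals]
        index = {k: i for i, k in enumerate(keys)}
        out = np.full(len(pos), -1, dtype=int)
        for i, (c, p) in enumerate(zip(chrom, pos)):
            for s, e in self._by_chrom.get(str(c), ()):
                if s <= p < e:
                    out[i] = index[(str(c), s, e)]
                    break
        if np.any(out < 0):
            bad = [f"{c}:{int(p)}" for c, p, o in zip(chrom, pos, out) if o < 0][:5]
            raise GwasValidationError(f"SNP(s) outside all LD blocks: {bad}")
        return out


class LDMatrix:
    """Block-diagonal SNP correlation matrix.

    Stored as a list of ``(global index array, dense correlation matrix)``
    pairs; correlations across blocks are exactly zero.  Provides the
    block-wise linear algebra (matrix-vector products and quadratic forms)
    that AUC prediction and the Gibbs sampler need, without ever forming
    the dense M x M matrix.
    """

    def __init__(self, blocks: list[tuple[np.ndarray, np.ndarray]], n_snps: int):
        self.blocks = [(np.asarray(idx, dtype=int), np.asarray(R, dtype=float))
                       for idx, R in blocks]
        self.n_snps = int(n_snps)
        covered = np.concatenate([idx for idx, _ in self.blocks]) if self.blocks \
            else np.empty(0, dtype=int)
        if covered.size != n_snps or set(covered.tolist()) != set(range(n_snps)):
            raise GwasValidationError("blocks must partition all SNP indices")
        for idx, R in self.blocks:
            if R.shape != (idx.size, idx.size):
                raise GwasValidationError("block matrix shape mismatch")

    # -- constructors --------------------------------------------------
    @classmethod
    def identity(cls, n_snps: int) -> "LDMatrix":
        return cls([(np.arange(n_snps), np.eye(n_snps))], n_snps)

    @classmethod
    def from_dense(cls, R: np.ndarray) -> "LDMatrix":
        R = np.asarray(R, dtype=float)
        return cls([(np.arange(R.shape[0]), R)], R.shape[0])

    # -- linear algebra ------------------------------------------------
    def matvec(self, x: np.ndarray) -> np.ndarray:
        """R @ x (x may be a vector or a stack of row vectors, shape (..., M))."""
        x = np.asarray(x, dtype=float)
        out = np.empty_like(x)
        for idx, R in self.blocks:
            out[..., idx] = x[..., idx] @ R.T
        return out

    def quad_form(self, v: np.ndarray) -> float:
        """v^T R v computed block-wise."""
        v = np.asarray(v, dtype=float)
        total = 0.0
        for idx, R in self.blocks:
            vb = v[idx]
            total += float(vb @ R @ vb)
        return total

    def to_dense(self) -> np.ndarray:
        out = np.zeros((self.n_snps, self.n_snps))
        for idx, R in self.blocks:
            out[np.ix_(idx, idx)] = R
        return out

    def subset_dense(self, i: int) -> np.ndarray:
        return self.blocks[i][1]

    def validate(self, tol: float = 1e-10) -> None:
        """Check symmetry, unit diagonal, and PSD up to tolerance."""
        for idx, R in self.blocks:
            if np.max(np.abs(R - R.T)) > 1e-12:
                raise GwasValidationError("block matrix not symmetric")
            if np.max(np.abs(np.diag(R) - 1)) > 1e-12:
                raise GwasValidationError("block diagonal not unit")
            if R.shape[0] > 1 and np.linalg.eigvalsh(R)[0] < -PSD_TOL:
                raise GwasValidationError("block matrix not PSD")


def ledoit_wolf_correlation(X: np.ndarray) -> np.ndarray:
    """Ledoit-Wolf shrinkage correlation of standardized genotypes.

    ``X`` is n x p with columns scaled to mean 0 and unit (biased) sample
    variance.  The sample covariance is shrunk toward the scaled identity
    ``mu I`` with the closed-form optimal intensity of Ledoit & Wolf
    (2004), then rescaled to unit diagonal.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    n, p = X.shape
    if p == 0:
        return np.zeros((0, 0))
    if n < 2:
        raise ValueError("need at least 2 individuals")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise GwasValidationError(
            f"constant column(s) at index {np.where(sd == 0)[0][:5].tolist()}")

    S = X.T @ X / n
    mu = np.trace(S) / p
    # squared distances in the Frobenius norm scaled by 1/p
    d2 = float(((S - mu * np.eye(p)) ** 2).sum()) / p
    if d2 <= 0:
        return _rescale_correlation(S)
    sq_norms = (X ** 2).sum(axis=1)          # x_k . x_k per individual
    b2_bar = (float((sq_norms ** 2).sum()) / n ** 2
              - float((S ** 2).sum()) / n) / p
    b2 = min(max(b2_bar, 0.0), d2)
    shrinkage = b2 / d2
    shrunk = shrinkage * mu * np.eye(p) + (1.0 - shrinkage) * S
    return _rescale_correlation(shrunk)


def _rescale_correlation(C: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(C))
    R = C / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return (R + R.T) / 2.0


def banded_ledoit_wolf_correlation(X: np.ndarray, radius: int) -> np.ndarray:
    """Ledoit-Wolf-style shrinkage restricted to a banded correlation.

    When correlations beyond ``radius`` SNPs are zeroed by construction,
    those entries should not contribute estimation noise to the shrinkage
    intensity.  Each band offset ``k`` gets its own optimal intensity
    ``b_k^2 / d_k^2`` — the squared estimation noise of the offset's
    sample correlations over their squared dispersion, exactly the
    Ledoit-Wolf trade-off computed per diagonal.  Offsets whose true
    correlation dominates sampling noise (adjacent SNPs in tight LD) are
    kept nearly intact, while noise-dominated far offsets shrink to zero;
    the result is repaired to PSD by eigenvalue clipping.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if p == 0:
        return np.zeros((0, 0))
    if p == 1:
        return np.ones((1, 1))
    radius = min(radius, p - 1)
    R = np.eye(p)
    for k in range(1, radius + 1):
        Y = X[:, :-k] * X[:, k:]           # products x_i x_{i+k} per sample
        Sk = Y.mean(axis=0)
        d2 = float((Sk ** 2).sum())
        b2 = float(((Y - Sk) ** 2).sum()) / n ** 2
        shrink = min(b2 / d2, 1.0) if d2 > 0 else 1.0
        vals = (1.0 - shrink) * Sk
        i = np.arange(p - k)
        R[i, i + k] = vals
        R[i + k, i] = vals
    return band_and_repair(R, radius)


def band_and_repair(R: np.ndarray, radius: int) -> np.ndarray:
    """Zero entries beyond ``radius`` off the diagonal, then restore PSD by
    eigenvalue clipping and re-unitize the diagonal."""
    p = R.shape[0]
    i, j = np.indices((p, p), sparse=True)
    banded = np.where(np.abs(i - j) > radius, 0.0, R)
    if radius >= p - 1:
        return banded
    w, V = np.linalg.eigh(banded)
    if w[0] >= -PSD_TOL:
        return banded
    w = np.clip(w, PSD_TOL, None)
    repaired = (V * w) @ V.T
    return _rescale_correlation(repaired)


def build_ld(panel: PanelGenotypes,
             blocks: LDBlockSet | str | None = None,
             radius: int | None = None) -> LDMatrix:
    """Estimate the block-diagonal LD matrix of a panel.

    ``blocks`` may be an :class:`LDBlockSet`, ``"single-block"``, or None
    (fixed windows of 1000 SNPs, broken at chromosome boundaries).  When
    ``radius`` is given, only correlations within that many SNPs are
    estimated (the Ledoit-Wolf intensity is then computed over the banded
    entries, see :func:`banded_ledoit_wolf_correlation`) and each block is
    projected back to PSD.
    """
    M = panel.n_snps
    if blocks == "single-block" or (blocks is None and panel.pos is None):
        groups = [np.arange(M)]
    elif blocks is None:
        groups = _window_blocks(panel, DEFAULT_WINDOW_SNPS)
    else:
        labels = blocks.assign(panel.chrom, panel.pos)
        groups = [np.where(labels == b)[0] for b in np.unique(labels)]
    X = panel.standardized()
    out = []
    for idx in groups:
        if idx.size == 0:
            continue
        if radius is not None and radius == 0:
            R = np.eye(idx.size)
        elif radius is not None:
            R = banded_ledoit_wolf_correlation(X[:, idx], radius)
        else:
            R = ledoit_wolf_correlation(X[:, idx])
        out.append((idx, R))
    ld = LDMatrix(out, M)
    ld.validate()
    return ld


def _window_blocks(panel: PanelGenotypes, window: int) -> list[np.ndarray]:
    if panel.chrom is None:
        edges = np.arange(0, panel.n_snps, window)
        return [np.arange(s, min(s + window, panel.n_snps)) for s in edges]
    groups = []
    chroms = np.asarray(panel.chrom)
    for c in pd.unique(chroms):
        idx = np.where(chroms == c)[0]
        for s in range(0, idx.size, window):
            groups.append(idx[s:s + window])
    return groups
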