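"""Reading, validation, and harmonization of GWAS summary statistics, PRS
weight files, and reference-panel genotypes.

The central container is :class:`SummaryStats`, which stores per-SNP
allele-frequency-difference z-scores together with the case/control sample
sizes.  The z-score of SNP ``m`` is

    z_m = (f1_m - f0_m) / s_m,    s_m = sqrt(s1_m^2/(4 n1) + s0_m^2/(4 n0)),

where ``f_j`` is the observed allele frequency in group ``j`` (0 = controls,
1 = cases) and ``s_j^2 = 2 f_j (1 - f_j)`` the binomial genotype variance.
All downstream inference (empirical-Bayes prior fitting, AUC prediction)
consumes this representation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "SummaryStats",
    "PRSWeightSet",
    "PanelGenotypes",
    "read_summary_stats",
    "read_weight_sets",
    "read_panel",
    "harmonize",
    "GwasFormatError",
    "GwasValidationError",
]

#: complementary-base map used to detect strand-ambiguous SNPs
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class GwasFormatError(ValueError):
    """A required column or field is missing or malformed."""


class GwasValidationError(ValueError):
    """Input values violate a container invariant."""


def _as_float(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


@dataclass
class SummaryStats:
    """Per-SNP case/control GWAS summary statistics.

    Parameters
    ----------
    snp_id : array of str
    z : array
        Allele-frequency-difference test z-scores.
    n0, n1 : int
        Control and case sample sizes.
    f0_hat, f1_hat : array, optional
        Observed group allele frequencies of allele ``a1``.
    f_pooled : array, optional
        Pooled allele frequency; used as a fallback for the group variances
        when group frequencies are unavailable.
    """

    snp_id: np.ndarray
    z: np.ndarray
    n0: int
    n1: int
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None
    a1: np.ndarray | None = None
    a2: np.ndarray | None = None
    f0_hat: np.ndarray | None = None
    f1_hat: np.ndarray | None = None
    f_pooled: np.ndarray | None = None
    p_value: np.ndarray | None = None
    s: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.z = _as_float(self.z)
        for name in ("f0_hat", "f1_hat", "f_pooled", "p_value", "pos"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, _as_float(v))
        for name in ("chrom", "a1", "a2"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=object))
        if self.n0 <= 0 or self.n1 <= 0:
            raise GwasValidationError("sample sizes n0 and n1 must be positive")
        if not np.all(np.isfinite(self.z)):
            raise GwasValidationError("z contains non-finite values")
        M = len(self.z)
        for name in ("snp_id", "f0_hat", "f1_hat", "f_pooled", "p_value",
                     "chrom", "pos", "a1", "a2"):
            v = getattr(self, name)
            if v is not None and len(v) != M:
                raise GwasValidationError(f"{name} has length {len(v)}, expected {M}")
        if self.s is None:
            self.s = self.compute_s()
        else:
            self.s = _as_float(self.s)
        if np.any(self.s <= 0):
            raise GwasValidationError("standard errors s must be strictly positive")

    # ------------------------------------------------------------------
    @property
    def n_snps(self) -> int:
        return len(self.z)

    @property
    def n_eff(self) -> float:
        """Effective GWAS sample size 4 n0 n1 / (n0 + n1)."""
        return 4.0 * self.n0 * self.n1 / (self.n0 + self.n1)

    def group_variances(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-group genotype variances ``s_j^2 = 2 f_j (1 - f_j)``.

        Falls back to the pooled frequency for both groups when group
        frequencies are not carried (a documented approximation).
        """
        if self.f0_hat is not None and self.f1_hat is not None:
            return 2 * self.f0_hat * (1 - self.f0_hat), 2 * self.f1_hat * (1 - self.f1_hat)
        if self.f_pooled is None:
            raise GwasValidationError(
                "neither group nor pooled allele frequencies are available")
        logger.info("using pooled allele frequency for both group variances "
                    "(s0 = s1 approximation)")
        v = 2 * self.f_pooled * (1 - self.f_pooled)
        return v, v

    def compute_s(self) -> np.ndarray:
        """Standard error of the observed frequency difference per SNP."""
        s0_sq, s1_sq = self.group_variances()
        return np.sqrt(s1_sq / (4 * self.n1) + s0_sq / (4 * self.n0))

    def pvalues(self) -> np.ndarray:
        """Two-sided p-values; derived from z when not stored."""
        if self.p_value is not None:
            return self.p_value
        return 2 * norm.sf(np.abs(self.z))

    def take(self, idx: np.ndarray) -> "SummaryStats":
        """Row subset/reorder, preserving all carried columns."""
        kw = {}
        for name in ("snp_id", "z", "chrom", "pos", "a1", "a2",
                     "f0_hat", "f1_hat", "f_pooled", "p_value", "s"):
            v = getattr(self, name)
            kw[name] = None if v is None else v[idx]
        return SummaryStats(n0=self.n0, n1=self.n1, **kw)


@dataclass
class PRSWeightSet:
    """SNP weights of one PRS-method/tuning-parameter combination."""

    snp_id: np.ndarray
    omega: np.ndarray
    method_label: str = ""
    param_label: str = ""
    a1: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.omega = _as_float(self.omega)
        if self.a1 is not None:
            self.a1 = np.asarray(self.a1, dtype=object)
        if self.omega.size == 0:
            raise GwasValidationError(f"no weights in set '{self.param_label}'")
        if not np.all(np.isfinite(self.omega)):
            raise GwasValidationError("weights contain non-finite values")
        if not np.any(self.omega != 0):
            raise GwasValidationError(
                f"all weights are zero in set '{self.param_label}'")
        if len(set(self.snp_id)) != len(self.snp_id):
            raise GwasValidationError(
                f"duplicate SNP ids in weight set '{self.param_label}'")

    def take(self, idx: np.ndarray) -> "PRSWeightSet":
        return PRSWeightSet(
            snp_id=self.snp_id[idx], omega=self.omega[idx],
            method_label=self.method_label, param_label=self.param_label,
            a1=None if self.a1 is None else self.a1[idx])


@dataclass
class PanelGenotypes:
    """Reference-panel genotype dosages (individuals x SNPs, 0/1/2).

    Missing entries are NaN; they are mean-imputed per SNP on
    standardization.
    """

    genotypes: np.ndarray
    snp_id: np.ndarray
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None
    a1: np.ndarray | None = None
    a2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        if self.genotypes.ndim != 2:
            raise GwasValidationError("genotype matrix must be 2-D")
        if self.genotypes.shape[1] != len(self.snp_id):
            raise GwasValidationError("genotype columns do not match SNP map")
        obs = self.genotypes[~np.isnan(self.genotypes)]
        if obs.size and not np.all(np.isin(obs, (0.0, 1.0, 2.0))):
            raise GwasValidationError("genotype dosages must be 0, 1 or 2")
        if np.any(np.all(np.isnan(self.genotypes), axis=0)):
            raise GwasValidationError("panel contains fully missing SNPs")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def standardized(self) -> np.ndarray:
        """Mean-impute missing dosages, then scale columns to mean 0 and
        unit (biased) sample variance.  Constant columns are an error."""
        G = self.genotypes.copy()
        means = np.nanmean(G, axis=0)
        nan_r, nan_c = np.where(np.isnan(G))
        G[nan_r, nan_c] = means[nan_c]
        G -= G.mean(axis=0)
        sd = G.std(axis=0)
        bad = np.where(sd == 0)[0]
        if bad.size:
            raise GwasValidationError(
                f"constant genotype column(s) in panel: {list(self.snp_id[bad[:5]])}")
        return G / sd

    def take(self, idx: np.ndarray) -> "PanelGenotypes":
        return PanelGenotypes(
            genotypes=self.genotypes[:, idx], snp_id=self.snp_id[idx],
            chrom=None if self.chrom is None else self.chrom[idx],
            pos=None if self.pos is None else self.pos[idx],
            a1=None if self.a1 is None else self.a1[idx],
            a2=None if self.a2 is None else self.a2[idx])

    def flip_allele(self, idx: np.ndarray) -> None:
        """Recode columns ``idx`` to count the other allele (g -> 2 - g)."""
        self.genotypes[:, idx] = 2.0 - self.genotypes[:, idx]
        if self.a1 is not None and self.a2 is not None:
            a1 = self.a1.copy()
            self.a1[idx], self.a2[idx] = self.a2[idx], a1[idx]


# ----------------------------------------------------------------------
# readers
# ----------------------------------------------------------------------

_ROLES = ("snp", "chrom", "pos", "a1", "a2", "z", "beta", "se", "or",
          "f0", "f1", "f", "n0", "n1", "p")


def read_summary_stats(path, column_map: dict[str, str],
                       n0: int | None = None, n1: int | None = None,
                       sep: str | None = None) -> SummaryStats:
    """Read whitespace/tab-delimited summary statistics with a header.

    ``column_map`` maps roles to column names, e.g.
    ``{"snp": "SNP", "a1": "A1", "a2": "A2", "f0": "F_CONTROL", ...}``.
    Recognized roles: snp, chrom, pos, a1, a2, z, beta, se, or, f0, f1, f,
    n0, n1, p.  The z-score is taken directly, or computed as
    ``(f1 - f0)/s``, ``beta/se`` or ``log(or)/se``.  Sample sizes may come
    from columns (first row) or the ``n0``/``n1`` arguments.
    """
    unknown = set(column_map) - set(_ROLES)
    if unknown:
        raise GwasFormatError(f"unknown column roles: {sorted(unknown)}")
    df = pd.read_csv(path, sep=sep if sep is not None else r"\s+",
                     float_precision="round_trip")
    missing = [c for c in column_map.values() if c not in df.columns]
    if missing:
        raise GwasFormatError(f"missing column(s) in {path}: {missing}")
    col = {role: df[name] for role, name in column_map.items()}

    if "snp" not in col:
        raise GwasFormatError("column_map must name a 'snp' column")
    if n0 is None:
        if "n0" not in col:
            raise GwasFormatError("control sample size: pass n0= or map an 'n0' column")
        n0 = int(col["n0"].iloc[0])
    if n1 is None:
        if "n1" not in col:
            raise GwasFormatError("case sample size: pass n1= or map an 'n1' column")
        n1 = int(col["n1"].iloc[0])
    if n0 <= 0 or n1 <= 0:
        raise GwasValidationError("sample sizes n0 and n1 must be positive")

    f0 = _as_float(col["f0"]) if "f0" in col else None
    f1 = _as_float(col["f1"]) if "f1" in col else None
    fp = _as_float(col["f"]) if "f" in col else None

    if "z" in col:
        z = _as_float(col["z"])
    elif f0 is not None and f1 is not None:
        s0_sq, s1_sq = 2 * f0 * (1 - f0), 2 * f1 * (1 - f1)
        z = (f1 - f0) / np.sqrt(s1_sq / (4 * n1) + s0_sq / (4 * n0))
    elif "beta" in col and "se" in col:
        z = _as_float(col["beta"]) / _as_float(col["se"])
    elif "or" in col and "se" in col:
        z = np.log(_as_float(col["or"])) / _as_float(col["se"])
    else:
        raise GwasFormatError(
            "need a 'z' column, or (f0, f1), or (beta, se), or (or, se)")

    keep = np.isfinite(z)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dropped %d row(s) with non-finite z from %s", n_drop, path)

    def _sub(v):
        return None if v is None else v[keep]

    return SummaryStats(
        snp_id=np.asarray(col["snp"], dtype=object)[keep],
        z=z[keep], n0=n0, n1=n1,
        chrom=_sub(np.asarray(col["chrom"], dtype=object)) if "chrom" in col else None,
        pos=_sub(_as_float(col["pos"])) if "pos" in col else None,
        a1=_sub(np.asarray(col["a1"], dtype=object)) if "a1" in col else None,
        a2=_sub(np.asarray(col["a2"], dtype=object)) if "a2" in col else None,
        f0_hat=_sub(f0), f1_hat=_sub(f1), f_pooled=_sub(fp),
        p_value=_sub(_as_float(col["p"])) if "p" in col else None)


def read_weight_sets(paths, method_label: str = "",
                     param_labels: list[str] | None = None) -> list[PRSWeightSet]:
    """Read tab-delimited ``{SNP, A1, WEIGHT}`` files, one weight set each.

    ``param_labels`` overrides the default labels taken from file names.
    """
    out = []
    for i, path in enumerate(paths):
        df = pd.read_csv(path, sep=r"\s+")
        cols = {c.upper(): c for c in df.columns}
        for want in ("SNP", "WEIGHT"):
            if want not in cols:
                raise GwasFormatError(f"{path}: missing column {want}")
        if df.shape[0] == 0:
            raise GwasFormatError(f"{path}: no weights")
        label = (param_labels[i] if param_labels is not None
                 else Path(path).stem)
        out.append(PRSWeightSet(
            snp_id=df[cols["SNP"]].to_numpy(dtype=object),
            omega=df[cols["WEIGHT"]].to_numpy(dtype=float),
            method_label=method_label, param_label=label,
            a1=df[cols["A1"]].to_numpy(dtype=object) if "A1" in cols else None))
    return out


def read_panel(matrix_path, map_path) -> PanelGenotypes:
    """Read a plain-text dosage matrix (rows = individuals) and its SNP map.

    The map is whitespace-delimited with header columns SNP, CHROM, POS,
    A1, A2 (case-insensitive); NA entries in the matrix mark missing
    dosages.
    """
    G = pd.read_csv(matrix_path, sep=r"\s+", header=None,
                    na_values=["NA", "nan"]).to_numpy(dtype=float)
    m = pd.read_csv(map_path, sep=r"\s+")
    cols = {c.upper(): c for c in m.columns}
    if "SNP" not in cols:
        raise GwasFormatError(f"{map_path}: missing column SNP")

    def _get(name):
        return m[cols[name]].to_numpy(dtype=object) if name in cols else None

    return PanelGenotypes(
        genotypes=G, snp_id=m[cols["SNP"]].to_numpy(dtype=object),
        chrom=_get("CHROM"),
        pos=m[cols["POS"]].to_numpy(dtype=float) if "POS" in cols else None,
        a1=_get("A1"), a2=_get("A2"))


# ----------------------------------------------------------------------
# harmonization
# ----------------------------------------------------------------------

def _is_ambiguous(a1, a2) -> np.ndarray:
    out = np.zeros(len(a1), dtype=bool)
    for i, (x, y) in enumerate(zip(a1, a2)):
        x, y = str(x).upper(), str(y).upper()
        out[i] = _COMPLEMENT.get(x) == y
    return out


def harmonize(stats: SummaryStats,
              weights: PRSWeightSet | list[PRSWeightSet] | None = None,
              panel: PanelGenotypes | None = None,
              keep_ambiguous: bool = False):
    """Intersect and allele-align summary statistics, weight sets, and a
    reference panel.

    The panel's allele orientation (or, without a panel, the summary
    statistics') is the reference.  Flipped sources have ``z`` and ``omega``
    negated and frequencies mapped ``f -> 1 - f``.  Strand-ambiguous (A/T,
    C/G) SNPs are removed unless ``keep_ambiguous``.  SNPs are returned in
    (chrom, pos) order when coordinates are available, else in the
    reference source's order.

    Returns ``(stats, weights, panel, report)`` with
    ``report = {"n_matched", "n_flipped", "n_ambiguous_removed"}``.
    """
    single = isinstance(weights, PRSWeightSet)
    wlist = [weights] if single else list(weights or [])

    ids = [set(stats.snp_id)]
    ids += [set(w.snp_id) for w in wlist]
    if panel is not None:
        ids.append(set(panel.snp_id))
    common = set.intersection(*ids)
    if not common:
        raise GwasValidationError("no overlapping SNPs between inputs")

    ref = panel if panel is not None else stats
    ref_idx = np.array([i for i, sid in enumerate(ref.snp_id) if sid in common])
    # deterministic (chrom, pos) order when available
    if ref.chrom is not None and ref.pos is not None:
        order = np.lexsort((ref.pos[ref_idx], _chrom_key(ref.chrom[ref_idx])))
        ref_idx = ref_idx[order]
    ref_ids = ref.snp_id[ref_idx]

    n_ambiguous = 0
    if not keep_ambiguous and ref.a1 is not None and ref.a2 is not None:
        amb = _is_ambiguous(ref.a1[ref_idx], ref.a2[ref_idx])
        n_ambiguous = int(amb.sum())
        ref_idx, ref_ids = ref_idx[~amb], ref_ids[~amb]
    if ref_ids.size == 0:
        raise GwasValidationError("no overlapping SNPs after ambiguity filter")

    ref_a1 = ref.a1[ref_idx] if ref.a1 is not None else None

    def _locate(src_ids):
        lut = {sid: i for i, sid in enumerate(src_ids)}
        return np.array([lut[sid] for sid in ref_ids])

    n_flipped = 0

    # --- summary statistics ---
    sidx = _locate(stats.snp_id)
    stats_out = stats.take(sidx)
    if ref is not stats and ref_a1 is not None and stats_out.a1 is not None:
        flip = _match_flip(stats_out.a1, stats_out.a2, ref_a1, "summary statistics")
        n_flipped += int(flip.sum())
        stats_out = flip_stats(stats_out, flip)

    # --- weights ---
    wout = []
    for w in wlist:
        widx = _locate(w.snp_id)
        w2 = w.take(widx)
        if ref_a1 is not None and w2.a1 is not None:
            flip = np.array([str(a).upper() != str(r).upper()
                             for a, r in zip(w2.a1, ref_a1)])
            if flip.any():
                n_flipped += int(flip.sum())
                w2.omega = np.where(flip, -w2.omega, w2.omega)
                w2.a1 = ref_a1.copy()
        wout.append(w2)

    # --- panel ---
    panel_out = None
    if panel is not None:
        panel_out = panel.take(ref_idx) if ref is panel else panel.take(_locate(panel.snp_id))

    report = {"n_matched": int(ref_ids.size), "n_flipped": n_flipped,
              "n_ambiguous_removed": n_ambiguous}
    return stats_out, (wout[0] if single else wout), panel_out, report


def _chrom_key(chrom) -> np.ndarray:
    """Sortable numeric chromosome key (X/Y/MT after autosomes)."""
    special = {"X": 23, "Y": 24, "MT": 25, "M": 25}
    out = np.empty(len(chrom), dtype=float)
    for i, c in enumerate(chrom):
        c = re.sub("^chr", "", str(c), flags=re.I).upper()
        out[i] = special.get(c, None) or (float(c) if c.replace(".", "").isdigit() else 99)
    return out


def _match_flip(a1, a2, ref_a1, what: str) -> np.ndarray:
    flip = np.zeros(len(a1), dtype=bool)
    for i, (x, y, r) in enumerate(zip(a1, a2, ref_a1)):
        x, y, r = str(x).upper(), str(y).upper(), str(r).upper()
        if x == r:
            continue
        if y == r:
            flip[i] = True
        else:
            raise GwasValidationError(
                f"allele mismatch in {what} at index {i}: {x}/{y} vs reference {r}")
    return flip


def flip_stats(stats: SummaryStats, flip: np.ndarray) -> SummaryStats:
    """Re-orient summary statistics to the other allele where ``flip``."""
    kw = dict(z=np.where(flip, -stats.z, stats.z))
    for name in ("f0_hat", "f1_hat", "f_pooled"):
        v = getattr(stats, name)
        kw[name] = None if v is None else np.where(flip, 1 - v, v)
    a1, a2 = stats.a1, stats.a2
    if a1 is not None and a2 is not None:
        kw["a1"] = np.where(flip, a2, a1).astype(object)
        kw["a2"] = np.where(flip, a1, a2).astype(object)
    return replace(stats, **kw)
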