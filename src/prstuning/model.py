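"""Model/results interface tying the pipeline together.

:class:`PRSTuning` is constructed from harmonized GWAS summary statistics
(plus an LD matrix when the pre-selected SNPs are linked by LD); ``fit()``
estimates the point-normal prior — by EM for independent SNPs, by the SAME
Gibbs sampler under LD — and returns a :class:`PRSTuningResults` carrying
the hyperparameter estimates and Monte-Carlo posterior draws of the
allele-frequency differences.  The results object predicts the
out-of-sample AUC of any candidate weight set, computes the overfit
plug-in baseline, and tunes a parameter grid by predicted AUC.

One prior fit serves every weight set of a grid: the prior describes the
training data, not the PRS, and sharing one set of delta draws across the
grid gives the predicted AUCs common Monte-Carlo noise, which makes their
ranking stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import auc as auc_mod
from .em import PointNormalPrior, em_fit, posterior_components, \
    sample_delta_independent
from .gibbs import GibbsConfig, same_fit
from .io import PRSWeightSet, SummaryStats
from .ld import LDMatrix

__all__ = ["PRSTuning", "PRSTuningResults", "TuningReport",
           "evaluate_against_testing"]


@dataclass
class TuningReport:
    """Per-parameter predicted/unadjusted (and optionally testing) AUCs."""

    table: pd.DataFrame          # method, param, auc_pred, ci_lo, ci_hi, auc_unadj
    selected_param: str
    rho_auc: float | None = None
    rd_auc: float | None = None

    def __str__(self) -> str:
        lines = [self.table.to_string(index=False, float_format="%.4f")]
        lines.append(f"selected: {self.selected_param}")
        if self.rho_auc is not None:
            lines.append(f"rho_AUC = {self.rho_auc:.3f}")
        if self.rd_auc is not None:
            lines.append(f"rd_AUC  = {100 * self.rd_auc:.2f}%")
        return "\n".join(lines)


class PRSTuning:
    """Summary-statistics AUC predictor for PRS tuning.

    Parameters
    ----------
    sumstats : SummaryStats
        Harmonized training GWAS summary statistics over the pre-selected
        SNPs.
    ld : LDMatrix, optional
        Block-diagonal LD matrix over the same SNPs; required in ``"ld"``
        mode.
    mode : {"independent", "ld"}
        Whether the pre-selected SNPs may be treated as independent (the
        P+T situation) or are linked by LD (C+T, LDpred-style grids).
        Defaults to ``"ld"`` when an LD matrix is supplied.
    """

    def __init__(self, sumstats: SummaryStats, ld: LDMatrix | None = None,
                 mode: str | None = None):
        if mode is None:
            mode = "ld" if ld is not None else "independent"
        if mode not in ("independent", "ld"):
            raise ValueError(f"unknown mode {mode!r}")
        if mode == "ld" and ld is None:
            raise ValueError("mode='ld' requires an LD matrix")
        if ld is not None and ld.n_snps != sumstats.n_snps:
            raise ValueError("LD matrix and summary statistics disagree on M")
        self.sumstats = sumstats
        self.ld = ld
        self.mode = mode

    def fit(self, n_draws: int = 1000, seed=0,
            gibbs_config: GibbsConfig | None = None,
            em_tol: float = 1e-6, em_max_iter: int = 10_000
            ) -> "PRSTuningResults":
        """Estimate the prior and draw the delta posterior.

        ``seed`` drives all Monte Carlo; the returned results are
        bit-reproducible for a fixed seed.
        """
        z, s = self.sumstats.z, self.sumstats.s
        if self.mode == "independent":
            prior = em_fit(z, tol=em_tol, max_iter=em_max_iter)
            post = sample_delta_independent(z, s, prior, n_draws, seed=seed)
            delta_draws = post.delta_draws
            h = post.h
        else:
            cfg = gibbs_config or GibbsConfig(seed=seed, n_posterior_draws=n_draws)
            prior, draws = same_fit(z, s, self.ld, cfg)
            # delta = S R S^-1 beta; draws carry beta/s directly
            delta_draws = self.ld.matvec(draws.beta_std) * s
            h = draws.gamma.mean(axis=0)
        return PRSTuningResults(model=self, prior=prior,
                                delta_draws=delta_draws, h=h, seed=seed)


@dataclass
class PRSTuningResults:
    """Fitted prior plus posterior delta draws; predicts AUC per weight set."""

    model: PRSTuning
    prior: PointNormalPrior
    delta_draws: np.ndarray       # (n_draws, M)
    h: np.ndarray                 # posterior risk probabilities
    seed: int = 0
    _s_sq: tuple = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._s_sq = self.model.sumstats.group_variances()

    # ------------------------------------------------------------------
    @property
    def params(self) -> dict:
        return {"pi": self.prior.pi, "sigma2": self.prior.sigma2}

    def _omega(self, weights) -> np.ndarray:
        if isinstance(weights, PRSWeightSet):
            ss = self.model.sumstats
            if weights.omega.size != ss.n_snps or \
                    not np.array_equal(weights.snp_id, ss.snp_id):
                raise ValueError(
                    f"weight set '{weights.param_label}' is not aligned to "
                    "the summary statistics; harmonize first")
            return weights.omega
        omega = np.asarray(weights, dtype=float)
        if omega.size != self.model.sumstats.n_snps:
            raise ValueError("weight vector length does not match M")
        return omega

    def predict_auc(self, weights) -> auc_mod.AUCEstimate:
        """Posterior predicted AUC of one weight set (mean of per-draw
        AUCs, with 95% quantile interval)."""
        omega = self._omega(weights)
        s0_sq, s1_sq = self._s_sq
        return auc_mod.predicted_auc(omega, self.delta_draws, s0_sq, s1_sq,
                                     self.model.ld)

    def unadjusted_auc(self, weights) -> auc_mod.AUCEstimate:
        """Overfit baseline: observed differences plugged in as delta."""
        return auc_mod.unadjusted_auc(self.model.sumstats,
                                      self._omega(weights), self.model.ld)

    def tune(self, weight_sets: list[PRSWeightSet]) -> TuningReport:
        """Predict AUC for every candidate weight set and select the best.

        All weight sets share this fit's delta draws; ties in predicted
        AUC resolve to the earliest grid entry.
        """
        if not weight_sets:
            raise ValueError("empty weight-set grid")
        rows = []
        for ws in weight_sets:
            pred = self.predict_auc(ws)
            unadj = self.unadjusted_auc(ws)
            rows.append({"method": ws.method_label, "param": ws.param_label,
                         "auc_pred": pred.auc_point,
                         "ci_lo": pred.ci[0], "ci_hi": pred.ci[1],
                         "auc_unadjusted": unadj.auc_point})
        table = pd.DataFrame(rows)
        best = int(np.argmax(table["auc_pred"].to_numpy()))
        return TuningReport(table=table,
                            selected_param=table["param"].iloc[best])

    def summary(self) -> str:
        """Plain-text fit summary."""
        ss = self.model.sumstats
        lines = [
            "PRS tuning prior fit",
            "=" * 44,
            f"mode:              {self.model.mode}",
            f"SNPs (M):          {ss.n_snps}",
            f"n0 / n1:           {ss.n0} / {ss.n1}",
            f"pi (risk frac):    {self.prior.pi:.4g}",
            f"sigma2 (slab var): {self.prior.sigma2:.4g}",
            f"shrinkage lambda:  {self.prior.shrinkage:.4g}",
            f"converged:         {self.prior.converged} "
            f"({self.prior.n_iter} iterations)",
            f"posterior draws:   {self.delta_draws.shape[0]}",
            f"E[#risk SNPs | z]: {self.h.sum():.1f}",
        ]
        return "\n".join(lines)


def evaluate_against_testing(report: TuningReport, testing_aucs,
                             literal: bool = False) -> TuningReport:
    """Fill in the evaluation metrics given testing-cohort AUCs per grid
    point (same order as the report table).

    rho_AUC is the Pearson correlation of predicted and testing AUCs.
    rd_AUC (default) is the relative testing-AUC shortfall of the selected
    parameter versus the best testing parameter,
    ``(auc_test(best) - auc_test(selected)) / auc_test(best)``; with
    ``literal=True`` it is instead
    ``|auc_pred(selected) - auc_test(best)| / auc_test(best)``.
    """
    test = np.asarray(testing_aucs, dtype=float)
    pred = report.table["auc_pred"].to_numpy()
    if test.size != pred.size:
        raise ValueError("testing AUC vector does not match the grid")
    table = report.table.copy()
    table["auc_test"] = test

    if np.std(pred) == 0 or np.std(test) == 0:
        warnings.warn("zero variance in an AUC vector; rho_AUC undefined",
                      RuntimeWarning)
        rho = float("nan")
    elif test.size < 3:
        rho = float("nan")
    else:
        rho = float(np.corrcoef(pred, test)[0, 1])

    sel = int(np.argmax(pred))
    best = int(np.argmax(test))
    if literal:
        rd = abs(pred[sel] - test[best]) / test[best]
    else:
        rd = (test[best] - test[sel]) / test[best]
    return TuningReport(table=table, selected_param=report.selected_param,
                        rho_auc=rho, rd_auc=float(rd))
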