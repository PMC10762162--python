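"""Replicated end-to-end validation experiments.

Each runner simulates one synthetic study, builds a candidate weight grid,
predicts every candidate's AUC from the training summary statistics alone,
scores the same candidates on the held-out testing cohort, and reports the
evaluation metrics:

* ``rho_auc`` — Pearson correlation between predicted and testing AUCs
  across the grid;
* ``rd_auc`` — relative testing-AUC shortfall of the selected parameter
  versus the best testing parameter.

These runners are what the acceptance script and the long-running tests
call; they exist in the package so the validation settings live in one
place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .auc import empirical_auc
from .gibbs import GibbsConfig
from .io import PRSWeightSet
from .ld import build_ld
from .model import PRSTuning, TuningReport, evaluate_against_testing
from .prs import GridSpec, ct_weights, ldpred_style_weights, pt_weights
from .simulate import SimStudy, preset, simulate_study

__all__ = ["StudyResult", "run_independent_study", "run_ar1_study",
           "testing_aucs", "summarize_metrics"]


@dataclass
class StudyResult:
    """Metrics of one simulated replicate for one PRS method grid."""

    report: TuningReport
    rho_auc: float
    rd_auc: float
    auc_pred: np.ndarray
    auc_test: np.ndarray
    auc_unadjusted: np.ndarray


def testing_aucs(study: SimStudy, weight_sets: list[PRSWeightSet]) -> np.ndarray:
    """Empirical testing-cohort AUC of every weight set."""
    out = []
    for ws in weight_sets:
        prs_case = study.test_cases @ ws.omega
        prs_ctrl = study.test_controls @ ws.omega
        out.append(empirical_auc(prs_case, prs_ctrl))
    return np.asarray(out)


def _result(res, weight_sets, study) -> StudyResult:
    report = res.tune(weight_sets)
    test = testing_aucs(study, weight_sets)
    report = evaluate_against_testing(report, test)
    return StudyResult(report=report, rho_auc=report.rho_auc,
                       rd_auc=report.rd_auc,
                       auc_pred=report.table["auc_pred"].to_numpy(),
                       auc_test=test,
                       auc_unadjusted=report.table["auc_unadjusted"].to_numpy())


def run_independent_study(n: int = 10_000, M: int = 10_000, seed: int = 0,
                          n_draws: int = 1000) -> StudyResult:
    """One independent-SNP replicate: EM prior fit, P+T threshold grid.

    Study conditions: pi = 0.05, sigma2 = 0.001 n, kappa = 0.01, balanced
    training GWAS, 1000+1000 testing cohort, thresholds
    {1, 5e-1, ..., 5e-6}.
    """
    cfg = preset("study_independent", n=n, M=M, seed=seed, n_ref=0)
    study = simulate_study(cfg)
    model = PRSTuning(study.stats, mode="independent")
    res = model.fit(n_draws=n_draws, seed=seed + 1)
    wsets = pt_weights(study.stats, None, GridSpec(method="PT"))
    return _result(res, wsets, study)


def run_ar1_study(n: int = 10_000, M: int = 2_000, seed: int = 0,
                  n_draws: int = 1000, radius: int = 5,
                  methods: tuple = ("CT", "LDPRED_STYLE"),
                  gibbs_config: GibbsConfig | None = None
                  ) -> dict[str, StudyResult]:
    """One AR(1) replicate: SAME prior fit shared by a C+T threshold grid
    and an LDpred-style pi grid.

    Study conditions: rho = 0.2, pi = 0.05, sigma2 = 0.0005 n, balanced
    training GWAS, 1000+1000 testing cohort, 1000-sample reference panel,
    LD radius 5 (pairwise correlations beyond it fall below
    0.2^5 ~ 3e-4).
    """
    cfg = preset("study_ar1", n=n, M=M, seed=seed)
    study = simulate_study(cfg)
    R = build_ld(study.panel, blocks="single-block", radius=radius)
    model = PRSTuning(study.stats, ld=R)
    res = model.fit(n_draws=n_draws, seed=seed + 1,
                    gibbs_config=gibbs_config)
    out = {}
    for method in methods:
        if method == "CT":
            wsets = ct_weights(study.stats, R, GridSpec(method="CT"))
        elif method == "LDPRED_STYLE":
            wsets = ldpred_style_weights(study.stats, R, seed=seed + 2)
        else:
            raise ValueError(f"unknown method {method!r}")
        out[method] = _result(res, wsets, study)
    return out


def summarize_metrics(results: list[StudyResult]) -> dict:
    """Replicate means of the evaluation metrics (rd_auc in percent)."""
    return {
        "mean_rho_auc": float(np.mean([r.rho_auc for r in results])),
        "mean_rd_auc_pct": float(np.mean([100 * r.rd_auc for r in results])),
        "n_replicates": len(results),
    }
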