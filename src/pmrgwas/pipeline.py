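"""End-to-end recommended workflow: impute, scan, screen, fit, rank.

The pipeline wires the pieces together in the recommended order:

1. mean-impute sporadic missing genotypes;
2. single-marker scan with covariates, plus the genomic-control
   inflation factor (the scan must be well calibrated before a
   penalized analysis is meaningful);
3. pre-screen markers at a marginal p-value cutoff (default 0.01);
4. penalized fit on the screened markers — a convex regularization
   path for lasso / adaptive lasso, a 1D/2D tuning grid with random
   update-order restarts for MCP / LOG / NEG;
5. min-AIC model selection under the sqrt(n / log n) size bound;
6. post-hoc refit, correlation pruning and min-p scoring into the
   ranked association report;
7. residual-QQ overfitting diagnostic on the non-selected markers.

Every stage's artifact can be written to an output directory as
tab-separated text plus a JSON sidecar recording seeds, grid sizes and
model counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .glm import ScanResult, genomic_inflation, prescreen, single_marker_scan
from .io import (CovariateMatrix, GenotypeDataset, PhenotypeVector,
                 impute_missing_mean, write_results_table)
from .model import ModelPath, PenalizedGLM, PenalizedGLMResults, model_size_bound
from .posthoc import AssociationReport, prune_and_score, residual_qq_diagnostic

logger = logging.getLogger(__name__)

#: default reporting thresholds on the post-hoc p-value score
SIGNIFICANCE_2D_MCP = 1e-7
SIGNIFICANCE_DEFAULT = 1e-5


@dataclass
class RunConfig:
    """Settings for one pipeline run (defaults = recommended usage)."""

    penalty: str = "mcp"
    mode: str = "2D"                  # grid mode for non-convex families
    prescreen_cutoff: float = 0.01
    n_orders: int = 100               # update-order restarts (non-convex)
    k_max: int | None = None          # override of the model-size bound
    n_warm: int = 5                   # warm-start model sizes in the grid
    shapes: tuple | None = None       # override of the shape schedule
    rate_factor: float = 0.8          # multiplicative rate-path step
    significance: float | None = None
    corr_cutoff: float = 0.1
    seed: int = 0
    out_dir: str | None = None

    @property
    def report_threshold(self) -> float:
        if self.significance is not None:
            return self.significance
        if self.penalty == "mcp" and self.mode == "2D":
            return SIGNIFICANCE_2D_MCP
        return SIGNIFICANCE_DEFAULT


@dataclass
class PipelineResult:
    """Artifacts of a full run."""

    scan: ScanResult
    scan_inflation: float
    screened: np.ndarray              # marker indices passing the pre-screen
    path: ModelPath
    selected: PenalizedGLMResults
    selected_markers: np.ndarray      # full-dataset indices of the selection
    selected_coefs: np.ndarray        # penalized coefficients, same order
    report: AssociationReport
    diag_inflation: float
    config: RunConfig

    def significant(self):
        return self.report.significant(self.config.report_threshold)

    def log_dict(self) -> dict:
        return {
            "config": asdict(self.config),
            "n_markers_screened": int(self.screened.size),
            "scan_inflation": self.scan_inflation,
            "n_models": self.path.n_models,
            "n_unique_models": self.path.n_unique_models,
            "selected_k": self.selected.k,
            "selected_aic": self.selected.aic,
            "diag_inflation": self.diag_inflation,
            "n_significant": int(len(self.significant())),
        }


def run_pipeline(g: GenotypeDataset, y: PhenotypeVector,
                 C: CovariateMatrix | None = None,
                 cfg: RunConfig | None = None) -> PipelineResult:
    """Execute the full recommended workflow on one dataset."""
    cfg = cfg or RunConfig()
    C = C or CovariateMatrix.intercept_only(g.n)

    stage = "imputation"
    try:
        g = impute_missing_mean(g)
        stage = "single-marker scan"
        scan = single_marker_scan(g, y, C)
        lam = genomic_inflation(scan) if g.p >= 100 else float("nan")
        stage = "pre-screen"
        keep = prescreen(scan, cfg.prescreen_cutoff)
        screened = g.subset_markers(keep)
        stage = "penalized fit"
        mdl = PenalizedGLM(y, screened, C)
        k_max = cfg.k_max or model_size_bound(g.n)
        if cfg.penalty in ("lasso", "adaptive_lasso"):
            path = mdl.fit_path(cfg.penalty, k_max=k_max,
                                rate_factor=cfg.rate_factor)
        else:
            path = mdl.fit_grid(cfg.penalty, k_max=k_max,
                                n_orders=cfg.n_orders, mode=cfg.mode,
                                seed=cfg.seed, n_warm=cfg.n_warm,
                                shapes=cfg.shapes,
                                rate_factor=cfg.rate_factor)
        stage = "model selection"
        best = path.select(g.n, cfg.k_max)
        sel_local = np.flatnonzero(best.beta)
        # the refit requires full rank: among (numerically) identical
        # selected columns keep the larger-|coefficient| one; the
        # pruning loop handles all sub-perfect correlation itself
        sel_local = _drop_exact_duplicates(
            screened.dosages, sel_local, best.beta)
        sel_full = keep[sel_local]
        stage = "post-hoc report"
        if sel_full.size:
            report = prune_and_score(sel_full, g, y, C, cfg.corr_cutoff)
        else:
            report = AssociationReport(
                table=_empty_report_table(), corr_cutoff=cfg.corr_cutoff)
        stage = "residual diagnostic"
        _, diag_lam = residual_qq_diagnostic(sel_full, g, y, C)
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {e}") from e

    result = PipelineResult(scan, lam, keep, path, best, sel_full,
                            best.beta[sel_local], report, diag_lam, cfg)
    if cfg.out_dir:
        _write_artifacts(result, g)
    return result


def _drop_exact_duplicates(dosages: np.ndarray, sel: np.ndarray,
                           beta: np.ndarray, tol: float = 1 - 1e-9
                           ) -> np.ndarray:
    if sel.size < 2:
        return sel
    X = dosages[:, sel]
    corr = np.corrcoef(X, rowvar=False)
    keep = np.ones(sel.size, dtype=bool)
    order = np.argsort(-np.abs(beta[sel]), kind="stable")
    for a_pos, a in enumerate(order):
        if not keep[a]:
            continue
        for b in order[a_pos + 1:]:
            if keep[b] and abs(corr[a, b]) >= tol:
                keep[b] = False
                logger.info("dropped exact duplicate of a selected marker "
                            "(column %d)", sel[b])
    return sel[keep]


def _empty_report_table():
    import pandas as pd
    return pd.DataFrame(columns=["id", "chrom", "bp", "coef", "score",
                                 "retained", "iteration"])


def _write_artifacts(result: PipelineResult, g: GenotypeDataset) -> None:
    out = Path(result.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.scan.to_tsv(out / "scan.tsv")
    result.report.to_tsv(out / "report.tsv")
    import pandas as pd
    models = pd.DataFrame(
        [{"rate": f.spec.rate, "shape": f.spec.shape, "k": f.k,
          "loglik": f.loglik, "aic": f.aic, "converged": f.converged,
          "order_seed": f.order_seed} for f in result.path.fits])
    write_results_table(models, out / "models.tsv")
    sel = pd.DataFrame({
        "id": g.markers["id"].to_numpy()[result.selected_markers],
        "coef": result.selected_coefs})
    write_results_table(sel, out / "selected.tsv")
    with open(out / "run.json", "w") as fh:
        json.dump(result.log_dict(), fh, indent=2)
    logger.info("pipeline artifacts written to %s", out)
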