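"""End-to-end federated feature-selection and survival-modelling pipeline.

Order of battle, mirroring the deployed analysis:

1. every node splits 80/20 into train/test (seeded, deterministic);
2. one moments round -> pooled correlations and standardization;
3. CFS best-first search over the correlation bundle;
4. LASSO-Cox regularization path over the CFS survivors -> entry order;
5. nested candidate sets, leave-one-node-out CV, best set by mean C-index;
6. unpenalized node-stratified Cox fit of the best set on all training data;
7. per-node test C-index, median-of-medians risk threshold, stratified
   Kaplan-Meier curves and log-rank tests.

Every inter-node message passes through the federation transcript, so a
single audit call certifies that nothing patient-sized ever crossed a node
boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cox
from .cfs import CFSResult, best_first_search
from .data_io import NodeDataset, split_node
from .exceptions import SizeError
from .federation import Federation, NodeHandle, PrivacyPolicy
from .fedstats import (
    CorrelationBundle,
    StandardizationParams,
    correlations_from_moments,
    federated_moments,
    standardization_params,
)
from .evaluation import EvaluationReport, evaluate_final
from .model_selection import CVReport, candidate_sets, cross_validate

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 0
    fraction_test: float = 0.2
    outcome_encoding: str = "time"  # or "event"
    cfs_max_stale: int = 5
    lambda_grid_size: int = 100
    lambda_min_ratio: float = 0.01
    tol_inner: float = 1e-7
    tol_outer: float = 1e-6
    threshold_partition: str = "test"


@dataclass
class PipelineResult:
    config: PipelineConfig
    correlations: CorrelationBundle
    standardization: StandardizationParams
    cfs: CFSResult
    path: cox.RegularizationPath | None
    entry_order: list[str]
    cv_report: CVReport | None
    best_set: list[str]
    final_model: cox.FinalModel
    evaluation: EvaluationReport
    federation: Federation = field(repr=False, default=None)


def build_federation(
    datasets: list[NodeDataset], config: PipelineConfig
) -> Federation:
    """Assign deterministic per-node splits and wrap datasets in handles."""
    handles = []
    for i, data in enumerate(datasets):
        node_seed = int(
            np.random.SeedSequence([config.seed, i]).generate_state(1)[0] % (2**31)
        )
        handles.append(
            NodeHandle(data, split_node(data, config.fraction_test, node_seed))
        )
    p = datasets[0].n_features
    policy = PrivacyPolicy(n_features=p, grid_size=config.lambda_grid_size)
    return Federation(handles, policy)


def run_pipeline(
    datasets: list[NodeDataset], config: PipelineConfig | None = None
) -> PipelineResult:
    config = config or PipelineConfig()
    fed = build_federation(datasets, config)
    logger.info("pipeline start: %d nodes, outcome encoding '%s'",
                len(datasets), config.outcome_encoding)

    # federated moments -> correlations + standardization
    agg = federated_moments(fed, outcome_encoding=config.outcome_encoding)
    feature_names = datasets[0].feature_names
    bundle = correlations_from_moments(agg, feature_names)
    std = standardization_params(agg, feature_names)
    abs_rcf = np.abs(bundle.outcome_corr)
    logger.info(
        "feature-outcome correlation: median |r| %.3f, IQR [%.3f, %.3f]",
        float(np.median(abs_rcf)),
        float(np.percentile(abs_rcf, 25)),
        float(np.percentile(abs_rcf, 75)),
    )

    cfs_result = best_first_search(bundle, max_stale=config.cfs_max_stale)
    selected = cfs_result.selected

    path = None
    cv_report = None
    if len(selected) >= 2:
        grid = cox.lambda_grid(
            fed, selected, std,
            K=config.lambda_grid_size, eps=config.lambda_min_ratio,
        )
        path = cox.regularization_path(
            fed, selected, std, grid,
            tol_inner=config.tol_inner, tol_outer=config.tol_outer,
        )
        order = cox.entry_order(path)
        cands = candidate_sets(order)
        cv_report = cross_validate(fed, cands, config.outcome_encoding)
        best_set = cv_report.selected_set or order[:2]
    else:
        # a single CFS survivor: nothing to rank or cross-validate
        logger.warning("CFS selected a single feature; skipping path and CV")
        order = list(selected)
        best_set = list(selected)

    final_model = cox.fit_unpenalized(fed, best_set, std)
    evaluation = evaluate_final(
        fed, final_model, threshold_partition=config.threshold_partition
    )
    return PipelineResult(
        config=config,
        correlations=bundle,
        standardization=std,
        cfs=cfs_result,
        path=path,
        entry_order=order,
        cv_report=cv_report,
        best_set=best_set,
        final_model=final_model,
        evaluation=evaluation,
        federation=fed,
    )


# -- report writers ------------------------------------------------------


def write_outputs(result: PipelineResult, outdir) -> None:
    """CSV deliverables: correlations, path, CV table, final model, KM tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    b = result.correlations
    pd.DataFrame(b.feature_corr, index=b.feature_names, columns=b.feature_names).to_csv(
        outdir / "correlation_matrix.csv"
    )
    pd.DataFrame(
        {"feature": b.feature_names, "outcome_corr": b.outcome_corr}
    ).to_csv(outdir / "outcome_correlations.csv", index=False)
    pd.DataFrame(
        {
            "feature": result.cfs.selected,
            "abs_outcome_corr": [
                abs(b.outcome_corr[b.indices([f])[0]]) for f in result.cfs.selected
            ],
        }
    ).assign(merit=result.cfs.merit).to_csv(outdir / "cfs_selected.csv", index=False)

    if result.path is not None:
        path = result.path
        pd.DataFrame(
            path.coef_matrix,
            index=path.feature_names,
            columns=[f"{lam:.6g}" for lam in path.lambda_grid],
        ).to_csv(outdir / "regularization_path.csv")

    if result.cv_report is not None:
        rows = []
        for ev in result.cv_report.candidates:
            set_name = " + ".join(ev.features)
            for fr in ev.folds:
                if fr.failed:
                    rows.append(
                        {"feature_set": set_name, "valid_node": fr.valid_node_id,
                         "status": "failed", "error": fr.error}
                    )
                    continue
                for j, f in enumerate(fr.features):
                    rows.append(
                        {
                            "feature_set": set_name,
                            "valid_node": fr.valid_node_id,
                            "feature": f,
                            "hr": round(float(fr.hr[j]), 2),
                            "hr_ci_low": round(float(fr.hr_ci_low[j]), 2),
                            "hr_ci_high": round(float(fr.hr_ci_high[j]), 2),
                            "fold_c_index": round(fr.c_index, 2),
                        }
                    )
            if not ev.failed:
                rows.append(
                    {
                        "feature_set": set_name,
                        "feature": "(summary)",
                        "mean_c_index": round(ev.mean_c, 2),
                        "ci_low": round(ev.ci_low, 2),
                        "ci_high": round(ev.ci_high, 2),
                    }
                )
        pd.DataFrame(rows).to_csv(outdir / "cv_report.csv", index=False)

    m = result.final_model
    pd.DataFrame(
        {
            "feature": m.features,
            "beta_per_sd": m.beta,
            "se": m.se,
            "hr_per_sd": m.hr,
            "hr_ci_low": m.hr_ci_low,
            "hr_ci_high": m.hr_ci_high,
            "wald_p": m.wald_p,
            "beta_raw": m.beta_raw,
        }
    ).to_csv(outdir / "final_model.csv", index=False)

    ev = result.evaluation
    summary_rows = []
    for node_id, strat in ev.stratification.per_node.items():
        summary_rows.append(
            {
                "node": node_id,
                "test_c_index": ev.test_c_index.get(node_id),
                "n_low": strat.n_low,
                "n_high": strat.n_high,
                "logrank_chi2": strat.logrank_chi2,
                "logrank_p": strat.logrank_p,
            }
        )
        for group in ("low", "high"):
            km = getattr(strat, f"km_{group}")
            if km is None:
                continue
            pd.DataFrame(
                {
                    "time": km.event_times,
                    "n_at_risk": km.n_at_risk,
                    "n_events": km.n_events,
                    "survival": km.survival,
                }
            ).to_csv(outdir / f"km_{node_id}_{group}.csv", index=False)
    pd.DataFrame(summary_rows).to_csv(outdir / "evaluation_summary.csv", index=False)
    if result.federation is not None:
        result.federation.save_transcript(outdir / "transcript.jsonl")


def check_pipeline_privacy(result: PipelineResult) -> list[str]:
    """Audit every message exchanged during the run (empty list = clean)."""
    if result.federation is None:
        raise SizeError("pipeline result carries no federation transcript")
    return result.federation.audit()
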