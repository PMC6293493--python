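"""End-to-end driver: detect candidate dropouts, refine, impute.

Stages, in order: split genes into richly-expressed (training) and the
rest (test); build element-wise samples; optionally cross-validate and
then train the linear classifier; score every zero element of the test
genes and derive the threshold eta from the classifier's positive rate;
run the false-negative-curve detector and, when count data and
subpopulation labels allow, the zero-inflated mixture detector; cut each
probability matrix at its top eta fraction; intersect the candidate sets;
train the linear SVR on the richly-expressed samples with value labels
and impute the intersected positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import ensemble, fnc, linear_models, sample_builder, zim
from .candidates import MissingPositionSet, MissingProbabilityMatrix
from .io_matrix import ExpressionMatrix, GeneList

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunable pipeline parameters with their recorded defaults."""

    objective: str = "lr_l2"
    C: float = 1.0
    tol: float = 1e-4
    log1p: bool = True   # fit classifier/SVR on log1p values (see methods note)
    cv_folds: int = 5            # 0 skips cross-validation
    detectors: tuple[str, ...] | None = None  # None = fnc + zim when counts allow
    lambda0: float = 0.1
    amplified_threshold: float = 0.2
    pair_budget: int = 150
    zim_force: bool = False
    svr_p: int = 2
    svr_formulation: str = "primal"
    svr_C: float = 1.0
    svr_epsilon: float = 0.1
    eta_override: float | None = None
    lenient: bool = False
    seed: int = 0


@dataclass
class PipelineResult:
    imputed: ExpressionMatrix
    missing: MissingPositionSet
    report: pd.DataFrame
    summary: dict
    detector_probabilities: dict[str, MissingProbabilityMatrix]
    detector_candidates: dict[str, MissingPositionSet]
    classifier: linear_models.LinearModel
    svr: linear_models.LinearModel
    eta: float


def _resolve_detectors(config: RunConfig, matrix: ExpressionMatrix,
                       groups: dict[str, str] | None) -> tuple[str, ...]:
    if config.detectors is not None:
        return tuple(d for d in config.detectors if d != "llc")
    if matrix.unit == "rpkm" and not config.zim_force:
        logger.info("unit is rpkm: falling back to the FNC-only refinement")
        return ("fnc",)
    return ("zim", "fnc")


def run_pipeline(
    matrix: ExpressionMatrix,
    richly_genes: GeneList,
    config: RunConfig | None = None,
    groups: dict[str, str] | None = None,
) -> PipelineResult:
    config = config or RunConfig()
    summary: dict = {"config": asdict(config)}

    partition = sample_builder.partition_genes(matrix, richly_genes)
    if partition.non_richly is None:
        raise ValueError("richly list covers every gene; nothing to detect")
    summary["n_richly"] = len(partition.richly)
    summary["n_test_genes"] = len(partition.non_richly)

    train = sample_builder.build_samples(
        matrix, partition.richly, label_mode="sign", role="train",
        log1p=config.log1p,
    )
    if config.cv_folds >= 2:
        cv = linear_models.cross_validate(
            train, config.objective, config.C, k=config.cv_folds,
            seed=config.seed, tol=config.tol,
        )
        summary["cv_mean_accuracy"] = cv.mean_accuracy
        summary["cv_per_fold"] = cv.per_fold_accuracy
        logger.info("%d-fold CV accuracy %.3f", cv.k, cv.mean_accuracy)
    classifier = linear_models.train_classifier(
        train, config.objective, config.C, tol=config.tol
    )

    test_rows = matrix.gene_index(partition.non_richly.ids)
    llc_prob, llc_set, eta = ensemble.llc_missing_probabilities(
        classifier, matrix, test_rows, log1p=config.log1p
    )
    if config.eta_override is not None:
        eta = config.eta_override
    summary["eta"] = eta

    probabilities: dict[str, MissingProbabilityMatrix] = {"llc": llc_prob}
    candidates: dict[str, MissingPositionSet] = {"llc": llc_set}
    test_row_set = set(int(r) for r in test_rows)

    for det in _resolve_detectors(config, matrix, groups):
        if det == "fnc":
            mu = fnc.expected_expression(matrix)
            curves = fnc.fit_detection_curves(
                matrix, partition.richly, mu
            )
            prob = fnc.fnc_missing_probabilities(matrix, curves, mu)
        elif det == "zim":
            prob = zim.zim_missing_probabilities(
                matrix, subpop_labels=groups, lambda0=config.lambda0,
                amplified_threshold=config.amplified_threshold,
                pair_budget=config.pair_budget, seed=config.seed,
                force=config.zim_force,
            ).probability
        else:
            raise ValueError(f"unknown detector {det!r}")
        keep = np.array([int(r) in test_row_set for r in prob.rows], dtype=bool)
        prob = MissingProbabilityMatrix(
            prob.source, prob.rows[keep], prob.cols[keep], prob.scores[keep]
        )
        probabilities[det] = prob
        candidates[det] = ensemble.top_candidates(prob, eta)

    summary["candidate_counts"] = {d: len(s) for d, s in candidates.items()}

    if config.lenient:
        # per element, require agreement only among detectors covering it
        domains = {d: p.positions() for d, p in probabilities.items() if d != "llc"}
        final_positions = {
            pos for pos in llc_set.positions
            if all(pos in candidates[d].positions
                   for d in domains if pos in domains[d])
        }
        missing = MissingPositionSet(
            final_positions, tuple(candidates), eta
        )
    else:
        missing = ensemble.intersect_missing(list(candidates.values()))
    summary["intersection_size"] = len(missing)
    summary["missing_rate"] = ensemble.missing_rate(missing, matrix)
    logger.info("final missing set: %d positions (rate %.4f)",
                len(missing), summary["missing_rate"])

    train_value = sample_builder.build_samples(
        matrix, partition.richly, label_mode="value", role="train",
        log1p=config.log1p,
    )
    if config.log1p:
        # regression runs entirely in log space; imputation inverts it
        train_value.labels = np.log1p(train_value.labels)
    svr = linear_models.train_svr(
        train_value, p=config.svr_p, formulation=config.svr_formulation,
        C=config.svr_C, epsilon=config.svr_epsilon, tol=config.tol,
    )
    imputed, imp_report = ensemble.impute(
        matrix, missing, svr, log1p=config.log1p, expm1_values=config.log1p,
    )

    score_maps = {d: p.as_dict() for d, p in probabilities.items()}
    rows = []
    gene_idx = {g: i for i, g in enumerate(matrix.gene_ids)}
    cell_idx = {c: j for j, c in enumerate(matrix.cell_ids)}
    for _, rec in imp_report.table.iterrows():
        key = (gene_idx[rec.gene_id], cell_idx[rec.cell_id])
        rows.append({
            "gene_id": rec.gene_id,
            "cell_id": rec.cell_id,
            "llc_score": score_maps["llc"].get(key, float("nan")),
            "zim_prob": score_maps.get("zim", {}).get(key, float("nan")),
            "fnc_prob": score_maps.get("fnc", {}).get(key, float("nan")),
            "imputed_value": rec.imputed_value,
        })
    report = pd.DataFrame(
        rows, columns=["gene_id", "cell_id", "llc_score", "zim_prob",
                       "fnc_prob", "imputed_value"],
    )
    return PipelineResult(
        imputed=imputed, missing=missing, report=report, summary=summary,
        detector_probabilities=probabilities, detector_candidates=candidates,
        classifier=classifier, svr=svr, eta=eta,
    )
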