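"""Refinement of missing-position calls and final imputation.

The linear classifier's pass over the test-set zeros fixes the threshold
``eta`` — the fraction of zero elements it predicts as missing.  Each
remaining detector's probability matrix is cut at its top ``ceil(eta * D)``
elements (D = the detector's available zero elements), and the detectors'
candidate sets are intersected: a position counts as missing only when
every contributing detector flags it, which trades recall for specificity.
Values at the refined positions are finally recovered with the linear SVR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .candidates import MissingPositionSet, MissingProbabilityMatrix
from .io_matrix import ExpressionMatrix
from .linear_models import LinearModel, decision_matrix


def compute_eta(predictions: np.ndarray) -> float:
    """eta = (# zero elements predicted missing) / (# zero elements).

    ``predictions`` are the classifier's +-1 labels over every zero-valued
    element of the test set.
    """
    predictions = np.asarray(predictions)
    if predictions.size == 0:
        raise ValueError("no zero elements: eta is undefined")
    return float(np.mean(predictions == 1))


def llc_missing_probabilities(
    model: LinearModel,
    matrix: ExpressionMatrix,
    gene_rows: np.ndarray,
    log1p: bool = False,
) -> tuple[MissingProbabilityMatrix, MissingPositionSet, float]:
    """Score and label every zero element of the given genes with the LLC.

    Returns the probability matrix (logistic of the decision value for LR,
    min-max scaled decision for the SVM), the classifier's own candidate
    set (its positive-predicted zeros), and eta.
    """
    gene_rows = np.asarray(gene_rows)
    decisions = decision_matrix(model, matrix, gene_rows, log1p=log1p)
    row_pos = {int(g): k for k, g in enumerate(gene_rows)}
    rows_out, cols_out, dec_out = [], [], []
    for g, zero_cols in matrix.iter_zero_positions(gene_rows):
        if len(zero_cols) == 0:
            continue
        rows_out.append(np.full(len(zero_cols), g))
        cols_out.append(zero_cols)
        dec_out.append(decisions[row_pos[int(g)], zero_cols])
    if not rows_out:
        raise ValueError("test set has no zero elements")
    rows = np.concatenate(rows_out)
    cols = np.concatenate(cols_out)
    dec = np.concatenate(dec_out)
    labels = np.where(dec > 0, 1, -1)
    eta = compute_eta(labels)
    if model.objective == "lr_l2":
        scores = 1.0 / (1.0 + np.exp(-dec))
    else:
        lo, hi = dec.min(), dec.max()
        scores = (dec - lo) / (hi - lo) if hi > lo else np.full(dec.shape, 0.5)
    prob = MissingProbabilityMatrix("llc", rows, cols, scores)
    positive = MissingPositionSet(
        positions={(int(r), int(c)) for r, c, l in zip(rows, cols, labels) if l == 1},
        provenance=("llc",), eta=eta,
    )
    return prob, positive, eta


def top_candidates(
    probabilities: MissingProbabilityMatrix, eta: float
) -> MissingPositionSet:
    """The ceil(eta * D) highest-scoring available elements of one detector.

    Ties are broken by ascending (gene_row, cell_col) so results are
    deterministic.
    """
    if not 0.0 <= eta <= 1.0:
        raise ValueError("eta must lie in [0, 1]")
    d = len(probabilities)
    k = math.ceil(eta * d)
    if k == 0:
        return MissingPositionSet(set(), (probabilities.source,), eta)
    order = np.lexsort(
        (probabilities.cols, probabilities.rows, -probabilities.scores)
    )
    chosen = order[:k]
    return MissingPositionSet(
        positions={
            (int(probabilities.rows[i]), int(probabilities.cols[i])) for i in chosen
        },
        provenance=(probabilities.source,),
        eta=eta,
    )


def intersect_missing(sets: list[MissingPositionSet]) -> MissingPositionSet:
    """Strict intersection of 2 or 3 detector candidate sets."""
    if len(sets) < 2:
        raise ValueError("need at least 2 candidate sets to intersect")
    positions = set.intersection(*(set(s.positions) for s in sets))
    provenance = tuple(dict.fromkeys(p for s in sets for p in s.provenance))
    etas = [s.eta for s in sets if s.eta is not None]
    return MissingPositionSet(positions, provenance, etas[0] if etas else None)


@dataclass
class ImputationReport:
    table: pd.DataFrame  # gene_id, cell_id, old_value, imputed_value


def impute(
    matrix: ExpressionMatrix,
    missing: MissingPositionSet,
    svr: LinearModel,
    log1p: bool = False,
    expm1_values: bool = False,
) -> tuple[ExpressionMatrix, ImputationReport]:
    """Recover values at the refined missing positions with the fitted SVR.

    Output equals the input everywhere else (bit-equal); raw negative
    predictions are clamped to 0; the unit tag is preserved.  When the SVR
    was trained on log1p labels, ``expm1_values`` maps predictions back to
    the expression scale.
    """
    positions = missing.sorted_positions()
    out = matrix.values.tolil(copy=True)
    records = []
    if positions:
        rows = np.array(sorted({g for g, _ in positions}), dtype=int)
        dec = decision_matrix(svr, matrix, rows, log1p=log1p)
        row_pos = {int(g): k for k, g in enumerate(rows)}
        for g, c in positions:
            if matrix.values[g, c] != 0:
                raise ValueError(
                    f"position ({matrix.gene_ids[g]}, {matrix.cell_ids[c]}) is "
                    "not zero in the observed matrix; refusing to overwrite"
                )
            raw = float(dec[row_pos[g], c])
            if expm1_values:
                raw = float(np.expm1(raw))
            val = max(0.0, raw)
            out[g, c] = val
            records.append(
                (matrix.gene_ids[g], matrix.cell_ids[c], 0.0, val)
            )
    imputed = ExpressionMatrix(
        list(matrix.gene_ids), list(matrix.cell_ids), out.tocsr(), matrix.unit
    )
    report = ImputationReport(
        table=pd.DataFrame(
            records, columns=["gene_id", "cell_id", "old_value", "imputed_value"]
        )
    )
    return imputed, report


def missing_rate(missing: MissingPositionSet, matrix: ExpressionMatrix) -> float:
    """|missing| over all matrix elements (the scale of the reported rates)."""
    return len(missing) / (matrix.n_genes * matrix.n_cells)
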