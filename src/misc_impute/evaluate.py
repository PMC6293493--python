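"""Scoring of detected positions and imputed values against a known truth."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .candidates import MissingPositionSet
from .io_matrix import ExpressionMatrix


@dataclass
class PositionScores:
    precision: float
    recall: float
    f1: float
    n_called: int
    n_true: int


def score_positions(
    called: MissingPositionSet | set[tuple[int, int]],
    true_mask: set[tuple[int, int]],
) -> PositionScores:
    """Precision/recall/F1 of called positions against the true dropout mask."""
    pos = called.positions if isinstance(called, MissingPositionSet) else called
    tp = len(pos & true_mask)
    precision = tp / len(pos) if pos else 0.0
    recall = tp / len(true_mask) if true_mask else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return PositionScores(precision, recall, f1, len(pos), len(true_mask))


def rmse_at_mask(
    candidate: ExpressionMatrix,
    truth: ExpressionMatrix,
    mask: np.ndarray,
) -> float:
    """RMSE between a matrix and the truth over the dropout mask positions."""
    if len(mask) == 0:
        return 0.0
    rows = np.asarray(mask)[:, 0]
    cols = np.asarray(mask)[:, 1]
    cand = np.asarray(candidate.values[rows, cols]).ravel()
    true = np.asarray(truth.values[rows, cols]).ravel()
    return float(np.sqrt(np.mean((cand - true) ** 2)))
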