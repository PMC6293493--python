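"""False-negative detection curves from housekeeping genes.

Housekeeping genes are expected to be expressed in essentially every cell,
so an undetected housekeeping gene in a cell is evidence of a technical
failure.  Per cell c, a logistic curve F_c(mu) — detection probability as a
function of the gene's expected expression mu* on the log scale — is
fitted over the housekeeping genes.  For any gene g with expected
expression mu*_g (the mean of its nonzero values, i.e. conditioned on
detection), ``1 - F_c(mu*_g)`` is then the missing probability of a zero
at (g, c).

Cells whose housekeeping genes are all detected (or all undetected), or
with fewer than 5 usable points, cannot support a logistic fit; they get a
degenerate constant curve equal to the observed detection rate clipped to
[0.01, 0.99].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from .candidates import MissingProbabilityMatrix
from .io_matrix import ExpressionMatrix, GeneList

logger = logging.getLogger(__name__)

_MIN_POINTS = 5
_CLIP = (0.01, 0.99)
#: ridge strength for per-cell fits; moderate regularization corrects the
#: separation-driven slope bias of small-sample logistic fits
_RIDGE_C = 10.0


@dataclass
class DetectionCurve:
    """Per-cell logistic detection-efficiency curve on log expected expression."""

    cell: int
    intercept: float
    slope: float
    n_points: int
    degenerate: bool = False
    constant_rate: float | None = None

    def detection_probability(self, mu_star: np.ndarray) -> np.ndarray:
        mu_star = np.asarray(mu_star, dtype=float)
        if self.degenerate:
            return np.full(mu_star.shape, float(self.constant_rate))
        z = self.intercept + self.slope * np.log(mu_star)
        return expit(z)


@dataclass
class ExpectedExpression:
    """Per-gene expected expression conditioned on detection (mu*)."""

    mu: dict[int, float]  # gene_row -> mu* (> 0); undefined genes absent

    def defined_rows(self) -> np.ndarray:
        return np.array(sorted(self.mu), dtype=int)


def expected_expression(
    matrix: ExpressionMatrix, genes: GeneList | None = None
) -> ExpectedExpression:
    """mu*_g = mean of gene g's nonzero values across all cells.

    All-zero genes have no defined mu* and are excluded with a warning.
    """
    rows = (
        np.arange(matrix.n_genes)
        if genes is None
        else matrix.gene_index(genes.ids)
    )
    csr = matrix.values
    mu: dict[int, float] = {}
    skipped = 0
    for g in rows:
        vals = csr.data[csr.indptr[g]:csr.indptr[g + 1]]
        if len(vals) == 0:
            skipped += 1
            continue
        mu[int(g)] = float(vals.mean())
    if skipped:
        logger.warning("%d all-zero genes have undefined expected expression", skipped)
    if not mu:
        raise ValueError("no gene has a nonzero observation; mu* undefined everywhere")
    return ExpectedExpression(mu=mu)


def _degenerate(cell: int, rate: float, n: int) -> DetectionCurve:
    return DetectionCurve(
        cell=cell, intercept=0.0, slope=0.0, n_points=n,
        degenerate=True, constant_rate=float(np.clip(rate, *_CLIP)),
    )


def fit_detection_curves(
    matrix: ExpressionMatrix,
    housekeeping: GeneList,
    mu_star: ExpectedExpression,
) -> list[DetectionCurve]:
    """Fit one logistic detection curve per cell over the housekeeping genes."""
    hk_rows = matrix.gene_index(housekeeping.ids)
    usable = np.array([g for g in hk_rows if int(g) in mu_star.mu], dtype=int)
    if len(usable) == 0:
        raise ValueError("no housekeeping gene has a defined expected expression")
    log_mu = np.log([mu_star.mu[int(g)] for g in usable])
    hk_dense = np.asarray(matrix.values[usable, :].todense())
    curves: list[DetectionCurve] = []
    est = LogisticRegression(C=_RIDGE_C, solver="lbfgs", max_iter=1000)
    X = log_mu.reshape(-1, 1)
    for c in range(matrix.n_cells):
        detected = (hk_dense[:, c] > 0).astype(int)
        n = len(detected)
        if n < _MIN_POINTS:
            logger.warning("cell %s: only %d usable housekeeping genes",
                           matrix.cell_ids[c], n)
            curves.append(_degenerate(c, detected.mean() if n else 0.5, n))
            continue
        if detected.min() == detected.max():
            curves.append(_degenerate(c, float(detected.mean()), n))
            continue
        est.fit(X, detected)
        curves.append(DetectionCurve(
            cell=c, intercept=float(est.intercept_[0]),
            slope=float(est.coef_[0, 0]), n_points=n,
        ))
    return curves


def fnc_missing_probabilities(
    matrix: ExpressionMatrix,
    curves: list[DetectionCurve],
    mu_star: ExpectedExpression,
) -> MissingProbabilityMatrix:
    """1 - F_c(mu*_g) at every zero-valued element with defined mu*_g."""
    if len(curves) != matrix.n_cells:
        raise ValueError("need exactly one detection curve per cell")
    order = sorted(curves, key=lambda cv: cv.cell)
    intercepts = np.array([cv.intercept for cv in order])
    slopes = np.array([cv.slope for cv in order])
    degenerate = np.array([cv.degenerate for cv in order])
    constants = np.array([cv.constant_rate if cv.degenerate else 0.0 for cv in order])
    rows_out: list[np.ndarray] = []
    cols_out: list[np.ndarray] = []
    scores_out: list[np.ndarray] = []
    for g, zero_cols in matrix.iter_zero_positions():
        if int(g) not in mu_star.mu or len(zero_cols) == 0:
            continue
        log_mu = np.log(mu_star.mu[int(g)])
        z = intercepts[zero_cols] + slopes[zero_cols] * log_mu
        p_detect = expit(z)
        p_detect = np.where(degenerate[zero_cols], constants[zero_cols], p_detect)
        rows_out.append(np.full(len(zero_cols), g))
        cols_out.append(zero_cols)
        scores_out.append(1.0 - p_detect)
    if not rows_out:
        return MissingProbabilityMatrix("fnc", np.empty(0, int), np.empty(0, int),
                                        np.empty(0))
    return MissingProbabilityMatrix(
        "fnc",
        np.concatenate(rows_out),
        np.concatenate(cols_out),
        np.concatenate(scores_out),
    )
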