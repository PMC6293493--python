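"""Zero-inflated mixture detector for dropout events in count data.

For each pair of cells (c_i, c_j) of the same subpopulation, the pair of
read counts (r_i, r_j) of every gene expressed in at least one of the two
cells is modelled as a three-component mixture:

* ``dropout_in_i``: r_i ~ Poisson(lambda0), a low-magnitude background
  (default lambda0 = 0.1), while the counterpart r_j is genuinely amplified;
* ``amplified``:    both counts negative-binomial, each with mean linked to
  the counterpart cell's count scaled by the library-size ratio;
* ``dropout_in_j``: the mirror image.

Component priors follow a multinomial logistic function of the mixing
covariate ``m = log(r_i + 1) + log(r_j + 1)`` (a pseudocount of 1 keeps the
log defined at zero counts).  The mixture is fitted by EM: responsibilities
in the E-step; the logistic coefficients and a single shared NB dispersion
in the M-step.  Both M-step pieces maximize the expected complete-data
log-likelihood, so the observed log-likelihood is non-decreasing across
iterations up to optimizer tolerance.

Genes whose posterior argmax is "amplified" in at least 20% of a
subpopulation's pair comparisons form the amplified gene set; dropout
posteriors at zero-valued elements of those genes, averaged over all
fitted pairs involving the cell, are the detector's missing probabilities.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammaln, logsumexp

from .candidates import MissingProbabilityMatrix
from .io_matrix import ExpressionMatrix, GeneList

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA0 = 0.1
_MEAN_FLOOR = 0.1
_THETA_BOUNDS = (np.log(0.05), np.log(1e4))


@dataclass
class PairMixtureFit:
    cell_i: int
    cell_j: int
    gene_rows: np.ndarray
    lambda0: float
    theta: float
    mixing_coeffs: np.ndarray  # (2, 2): rows = components 1,2 vs 0; cols = (intercept, slope)
    posteriors: np.ndarray     # (n_genes, 3): dropout_in_i, amplified, dropout_in_j
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = True


@dataclass
class ZimResult:
    amplified_genes: dict[str, GeneList]
    probability: MissingProbabilityMatrix


def _pois_logpmf(x: np.ndarray, lam: float) -> np.ndarray:
    return x * np.log(lam) - lam - gammaln(x + 1)


def _nb_logpmf(x: np.ndarray, mu: np.ndarray, theta: float) -> np.ndarray:
    mu = np.maximum(mu, _MEAN_FLOOR)
    return (
        gammaln(x + theta) - gammaln(theta) - gammaln(x + 1)
        + theta * np.log(theta / (theta + mu))
        + x * np.log(mu / (theta + mu))
    )


def _component_loglik(a, b, rho, lambda0, theta) -> np.ndarray:
    """(G, 3) per-gene log-likelihood of the three components."""
    out = np.empty((len(a), 3))
    # dropout in c_i: background count in i, counterpart genuinely detected
    out[:, 0] = _pois_logpmf(a, lambda0) + _nb_logpmf(b, b, theta)
    # amplified: cross-linked NB means, scaled by library-size ratio
    out[:, 1] = _nb_logpmf(a, rho * b, theta) + _nb_logpmf(b, a / rho, theta)
    # dropout in c_j
    out[:, 2] = _pois_logpmf(b, lambda0) + _nb_logpmf(a, a, theta)
    return out


def _mixing_logprior(m: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """(G, 3) log of the multinomial-logistic component priors."""
    z = np.zeros((len(m), 3))
    z[:, 1] = coeffs[0, 0] + coeffs[0, 1] * m
    z[:, 2] = coeffs[1, 0] + coeffs[1, 1] * m
    return z - logsumexp(z, axis=1, keepdims=True)


def _fit_mixing(m: np.ndarray, resp: np.ndarray, x0: np.ndarray) -> np.ndarray:
    """Weighted multinomial logistic M-step (expected complete-data loglik)."""

    def negloglik(params):
        coeffs = params.reshape(2, 2)
        logp = _mixing_logprior(m, coeffs)
        nll = -float((resp * logp).sum())
        p = np.exp(logp)
        diff = p - resp  # (G, 3); gradient wrt logits of classes 1 and 2
        grad = np.array(
            [diff[:, 1].sum(), (diff[:, 1] * m).sum(),
             diff[:, 2].sum(), (diff[:, 2] * m).sum()]
        )
        return nll, grad

    res = minimize(negloglik, x0.ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": 200, "ftol": 1e-12})
    return res.x.reshape(2, 2)


def _fit_theta(a, b, rho, resp, lambda0, current: float) -> float:
    """Shared NB dispersion maximizing the expected complete-data loglik.

    Falls back to the current value if the bounded search returns a worse
    point, preserving EM monotonicity.
    """

    def neg_q(log_theta):
        theta = float(np.exp(log_theta))
        ll = _component_loglik(a, b, rho, lambda0, theta)
        return -float((resp * ll).sum())

    res = minimize_scalar(neg_q, bounds=_THETA_BOUNDS, method="bounded",
                          options={"xatol": 1e-3})
    if res.fun > neg_q(np.log(current)):
        return current
    return float(np.exp(res.x))


def fit_pair(
    matrix: ExpressionMatrix,
    cell_i: int,
    cell_j: int,
    lambda0: float = DEFAULT_LAMBDA0,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> PairMixtureFit:
    """Fit the three-component mixture to one pair of cells by EM.

    Only genes expressed in at least one of the two cells enter the fit.
    Non-integer values are rounded with a warning (the model is for counts).
    """
    col_i = np.asarray(matrix.values[:, cell_i].todense()).ravel()
    col_j = np.asarray(matrix.values[:, cell_j].todense()).ravel()
    for col, cell in ((col_i, cell_i), (col_j, cell_j)):
        if not (col > 0).any():
            raise ValueError(
                f"cell {matrix.cell_ids[cell]!r} has no nonzero gene; "
                "cannot fit a pair mixture"
            )
    if not (np.allclose(col_i, np.rint(col_i)) and np.allclose(col_j, np.rint(col_j))):
        logger.warning("non-integer values rounded for mixture fitting")
    a_full, b_full = np.rint(col_i), np.rint(col_j)
    gene_rows = np.flatnonzero((a_full > 0) | (b_full > 0))
    a, b = a_full[gene_rows], b_full[gene_rows]
    rho = max(a_full.sum(), 1.0) / max(b_full.sum(), 1.0)
    m = np.log(a + 1) + np.log(b + 1)

    # hard initialization: a near-zero count starts on its dropout side
    resp = np.zeros((len(a), 3))
    resp[a < 1, 0] = 1.0
    resp[b < 1, 2] = 1.0
    resp[(a >= 1) & (b >= 1), 1] = 1.0

    coeffs = np.zeros((2, 2))
    theta = 2.0
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        # M-step from current responsibilities
        coeffs = _fit_mixing(m, resp, coeffs)
        theta = _fit_theta(a, b, rho, resp, lambda0, theta)
        # E-step
        log_joint = _mixing_logprior(m, coeffs) + _component_loglik(a, b, rho, lambda0, theta)
        norm = logsumexp(log_joint, axis=1, keepdims=True)
        resp = np.exp(log_joint - norm)
        ll = float(norm.sum())
        trace.append(ll)
        if len(trace) > 1 and abs(ll - trace[-2]) < tol * (abs(trace[-2]) + 1e-12):
            converged = True
            break
    if not converged:
        logger.warning("pair (%d, %d): EM hit max_iter=%d", cell_i, cell_j, max_iter)
    return PairMixtureFit(
        cell_i=cell_i, cell_j=cell_j, gene_rows=gene_rows, lambda0=lambda0,
        theta=theta, mixing_coeffs=coeffs, posteriors=resp,
        loglik_trace=trace, converged=converged,
    )


def select_amplified_genes(
    fits: list[PairMixtureFit], matrix: ExpressionMatrix, threshold: float = 0.2
) -> GeneList:
    """Genes with posterior-argmax 'amplified' in >= threshold of their fits."""
    if not fits:
        raise ValueError("no pair fits supplied")
    amplified = np.zeros(matrix.n_genes)
    evaluable = np.zeros(matrix.n_genes)
    for fit in fits:
        evaluable[fit.gene_rows] += 1
        is_amp = fit.posteriors.argmax(axis=1) == 1
        amplified[fit.gene_rows[is_amp]] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(evaluable > 0, amplified / np.maximum(evaluable, 1), -1.0)
    keep = np.flatnonzero((evaluable > 0) & (frac >= threshold))
    if len(keep) == 0:
        raise ValueError("no gene passed the amplified-fraction threshold")
    return GeneList([matrix.gene_ids[g] for g in keep])


def _sample_pairs(cells: np.ndarray, budget: int, rng: np.random.Generator):
    """All pairs if affordable, else random perfect matchings until budget.

    Matching rounds guarantee every cell of the subpopulation appears in
    roughly ``budget // (n/2)`` pairs, so per-cell aggregation never starves.
    """
    n = len(cells)
    total = n * (n - 1) // 2
    if total <= budget:
        return list(itertools.combinations(cells.tolist(), 2))
    pairs: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    while len(pairs) < budget:
        perm = rng.permutation(cells)
        for k in range(0, n - 1, 2):
            pair = (int(perm[k]), int(perm[k + 1]))
            key = (min(pair), max(pair))
            if key not in seen:
                seen.add(key)
                pairs.append(pair)
            if len(pairs) >= budget:
                break
    return pairs


def zim_missing_probabilities(
    matrix: ExpressionMatrix,
    subpop_labels: dict[str, str] | None = None,
    lambda0: float = DEFAULT_LAMBDA0,
    amplified_threshold: float = 0.2,
    pair_budget: int = 500,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 100,
    force: bool = False,
) -> ZimResult:
    """Run pair fits per subpopulation and aggregate dropout posteriors.

    The missing probability of a zero-valued element (g, c) is the mean of
    the dropout-in-c posteriors of gene g over every fitted pair involving
    cell c in which g was evaluable, restricted to that subpopulation's
    amplified gene set.
    """
    if matrix.unit == "rpkm" and not force:
        raise ValueError(
            "the zero-inflated mixture needs count-like data; unit is 'rpkm' "
            "(pass force=True to override)"
        )
    if subpop_labels is None:
        groups = {"all": np.arange(matrix.n_cells)}
    else:
        missing = [c for c in matrix.cell_ids if c not in subpop_labels]
        if missing:
            raise ValueError(
                f"cells without subpopulation label: {', '.join(missing[:5])}"
            )
        groups = {}
        for idx, cid in enumerate(matrix.cell_ids):
            groups.setdefault(str(subpop_labels[cid]), []).append(idx)
        groups = {g: np.asarray(v) for g, v in groups.items()}
    rng = np.random.default_rng(seed)

    dense_zero = None  # lazy; only columns are touched below
    prob_sum = {}
    prob_cnt = {}
    amplified_per_group: dict[str, GeneList] = {}
    for group, cells in groups.items():
        if len(cells) < 2:
            raise ValueError(f"subpopulation {group!r} has fewer than 2 cells")
        pairs = _sample_pairs(np.asarray(cells), pair_budget, rng)
        fits = [fit_pair(matrix, i, j, lambda0, tol, max_iter) for i, j in pairs]
        amp = select_amplified_genes(fits, matrix, amplified_threshold)
        amplified_per_group[group] = amp
        amp_rows = set(matrix.gene_index(amp.ids).tolist())
        for fit in fits:
            col_i = np.asarray(matrix.values[:, fit.cell_i].todense()).ravel()
            col_j = np.asarray(matrix.values[:, fit.cell_j].todense()).ravel()
            for cell, col, comp in ((fit.cell_i, col_i, 0), (fit.cell_j, col_j, 2)):
                zero_here = col[fit.gene_rows] == 0
                for g, post in zip(fit.gene_rows[zero_here],
                                   fit.posteriors[zero_here, comp]):
                    if int(g) in amp_rows:
                        key = (int(g), int(cell))
                        prob_sum[key] = prob_sum.get(key, 0.0) + float(post)
                        prob_cnt[key] = prob_cnt.get(key, 0) + 1

    keys = sorted(prob_sum)
    rows = np.array([k[0] for k in keys], dtype=int)
    cols = np.array([k[1] for k in keys], dtype=int)
    scores = np.array([prob_sum[k] / prob_cnt[k] for k in keys])
    return ZimResult(
        amplified_genes=amplified_per_group,
        probability=MissingProbabilityMatrix("zim", rows, cols, scores),
    )
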