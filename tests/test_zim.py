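import numpy as np
import pytest

from misc_impute.io_matrix import ExpressionMatrix
from misc_impute.zim import (
    PairMixtureFit,
    _sample_pairs,
    fit_pair,
    select_amplified_genes,
    zim_missing_probabilities,
)


def simulate_pair(n_genes=600, mean=50.0, disp=2.0, drop_each_side=0.3,
                  lambda0=0.1, seed=0):
    """Draw genes from the three-component generative model.

    Returns (matrix with 2 cells, component labels 0/1/2).
    """
    rng = np.random.default_rng(seed)
    p_amp = 1.0 - 2 * drop_each_side
    labels = rng.choice(3, size=n_genes, p=[drop_each_side, p_amp, drop_each_side])
    nb = lambda size: rng.negative_binomial(disp, disp / (disp + mean), size)
    a = np.where(labels == 0, rng.poisson(lambda0, n_genes), nb(n_genes))
    b = np.where(labels == 2, rng.poisson(lambda0, n_genes), nb(n_genes))
    keep = (a > 0) | (b > 0)
    values = np.column_stack([a, b]).astype(float)[keep]
    genes = [f"g{i}" for i in np.flatnonzero(keep)]
    mat = ExpressionMatrix(genes, ["ci", "cj"], values, unit="counts")
    return mat, labels[keep]


class TestFitPair:
    def test_loglik_monotone_nondecreasing(self):
        mat, _ = simulate_pair(seed=3)
        fit = fit_pair(mat, 0, 1)
        trace = np.array(fit.loglik_trace)
        assert len(trace) >= 2
        diffs = np.diff(trace)
        assert (diffs >= -1e-6 * (np.abs(trace[:-1]) + 1)).all()

    def test_posteriors_are_distributions(self):
        mat, _ = simulate_pair(seed=3)
        fit = fit_pair(mat, 0, 1)
        np.testing.assert_allclose(fit.posteriors.sum(axis=1), 1.0, atol=1e-8)
        assert (fit.posteriors >= 0).all()

    def test_recovers_dropout_fractions(self):
        mat, labels = simulate_pair(n_genes=800, seed=7)
        fit = fit_pair(mat, 0, 1)
        argmax = fit.posteriors.argmax(axis=1)
        for comp in (0, 2):
            truth_frac = np.mean(labels == comp)
            est_frac = np.mean(argmax == comp)
            assert est_frac == pytest.approx(truth_frac, abs=0.05)

    def test_extreme_count_pair_flags_dropout_side(self):
        mat, _ = simulate_pair(n_genes=300, seed=5)
        values = np.vstack([mat.dense(), [[0.0, 120.0], [40.0, 45.0]]])
        genes = mat.gene_ids + ["planted_drop", "planted_amp"]
        mat2 = ExpressionMatrix(genes, mat.cell_ids, values, unit="counts")
        fit = fit_pair(mat2, 0, 1)
        pos = {int(g): k for k, g in enumerate(fit.gene_rows)}
        drop_row = pos[mat2.gene_index(["planted_drop"])[0]]
        amp_row = pos[mat2.gene_index(["planted_amp"])[0]]
        assert fit.posteriors[drop_row, 0] > 0.5
        assert fit.posteriors[amp_row].argmax() == 1

    def test_vanishing_lambda0_kills_dropout_posteriors(self):
        rng = np.random.default_rng(2)
        values = rng.integers(5, 60, size=(100, 2)).astype(float)
        mat = ExpressionMatrix([f"g{i}" for i in range(100)], ["ci", "cj"],
                               values, unit="counts")
        fit = fit_pair(mat, 0, 1, lambda0=1e-9)
        assert fit.posteriors[:, [0, 2]].max() < 1e-3

    def test_all_zero_cell_rejected(self):
        values = np.array([[1.0, 0.0], [2.0, 0.0]])
        mat = ExpressionMatrix(["g1", "g2"], ["ci", "cj"], values, unit="counts")
        with pytest.raises(ValueError, match="cj"):
            fit_pair(mat, 0, 1)


def _fake_fit(matrix, amplified_rows, evaluated_rows):
    post = np.zeros((len(evaluated_rows), 3))
    for k, g in enumerate(evaluated_rows):
        post[k, 1 if g in amplified_rows else 0] = 1.0
    return PairMixtureFit(
        cell_i=0, cell_j=1, gene_rows=np.asarray(evaluated_rows),
        lambda0=0.1, theta=2.0, mixing_coeffs=np.zeros((2, 2)),
        posteriors=post,
    )


class TestAmplifiedSelection:
    def test_threshold_rule(self):
        mat = ExpressionMatrix(["gA", "gB"], ["c1", "c2"],
                               np.ones((2, 2)), unit="counts")
        # gA amplified in 3/10 fits, gB in 1/10
        fits = [_fake_fit(mat, {0} if k < 3 else set(), [0, 1]) for k in range(10)]
        for f in fits[:1]:
            pass
        kept = select_amplified_genes(fits, mat, threshold=0.2)
        assert kept.ids == ["gA"]

    def test_zero_threshold_keeps_every_evaluable_gene(self):
        mat = ExpressionMatrix(["gA", "gB"], ["c1", "c2"],
                               np.ones((2, 2)), unit="counts")
        fits = [_fake_fit(mat, set(), [0, 1])]
        kept = select_amplified_genes(fits, mat, threshold=0.0)
        assert kept.ids == ["gA", "gB"]


class TestPairSampling:
    def test_two_cells_give_single_pair(self):
        pairs = _sample_pairs(np.array([3, 9]), 100, np.random.default_rng(0))
        assert pairs == [(3, 9)]

    def test_budget_respected_and_cells_covered(self):
        cells = np.arange(40)
        pairs = _sample_pairs(cells, 60, np.random.default_rng(1))
        assert len(pairs) == 60
        covered = {c for p in pairs for c in p}
        assert covered == set(cells.tolist())


@pytest.fixture(scope="module")
def zim_result(small_dataset):
    return zim_missing_probabilities(
        small_dataset.observed, subpop_labels=small_dataset.groups,
        pair_budget=30, seed=5,
    )


class TestZimProbabilities:
    def test_probabilities_only_at_zero_elements(self, small_dataset, zim_result):
        dense = small_dataset.observed.dense()
        prob = zim_result.probability
        assert (dense[prob.rows, prob.cols] == 0).all()
        assert (prob.scores >= 0).all() and (prob.scores <= 1).all()

    def test_true_dropout_zeros_score_higher_than_biological(self, small_dataset,
                                                             zim_result):
        mask = small_dataset.mask_set()
        prob = zim_result.probability
        is_drop = np.array([(int(g), int(c)) in mask
                            for g, c in zip(prob.rows, prob.cols)])
        assert is_drop.any() and (~is_drop).any()
        assert prob.scores[is_drop].mean() > prob.scores[~is_drop].mean()

    def test_rpkm_matrix_refused_without_force(self, small_dataset):
        mat = small_dataset.observed
        rpkm = ExpressionMatrix(list(mat.gene_ids), list(mat.cell_ids),
                                mat.values.copy(), unit="rpkm")
        with pytest.raises(ValueError, match="count-like"):
            zim_missing_probabilities(rpkm, subpop_labels=small_dataset.groups)

    def test_unlabelled_cells_rejected(self, small_dataset):
        labels = dict(small_dataset.groups)
        labels.pop(small_dataset.observed.cell_ids[0])
        with pytest.raises(ValueError, match="without subpopulation"):
            zim_missing_probabilities(small_dataset.observed,
                                      subpop_labels=labels)
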