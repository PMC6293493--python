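"""Seeded synthetic scRNA-seq datasets with a known dropout ground truth.

The generator emulates the structure the detection models assume:

* true expression is negative-binomial per gene, with gene means
  log-uniform over a configurable range and group-specific mean shifts for
  a configurable fraction of genes (subpopulation structure);
* a housekeeping subset is drawn from the top of the mean range, receives
  no group shifts, and gets an extra detection-efficiency boost, so its
  observed zero rate is lower than other genes' at matched expression;
* each expressed element is detected with probability
  ``sigmoid(intercept + slope * log(truth) [+ boost])`` — the logistic
  detection-efficiency model — and a dropped element is replaced by a
  low-magnitude Poisson(lambda0) background count (usually 0);
* everything is reproducible from a single seed, with per-stage child
  seeds so one stage's draws never shift another's.

The default configuration (2,000 genes x 300 cells) is calibrated so that
roughly 30% of the expressed elements drop out, the regime that motivates
dropout imputation in the first place.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .baseline import CellOrdering
from .io_matrix import ExpressionMatrix, GeneList, write_expression_matrix, write_gene_list


@dataclass
class SyntheticConfig:
    n_genes: int = 2000
    n_cells: int = 300
    n_housekeeping: int = 100
    nb_mean_log_range: tuple[float, float] = (np.log(0.3), np.log(80.0))
    nb_dispersion: float = 2.0
    dropout_intercept: float = -1.1
    dropout_slope: float = 1.2
    cell_intercept_sd: float = 0.7
    hk_efficiency_boost: float = 1.0
    lambda0: float = 0.1
    group_count: int = 3
    group_shift_fraction: float = 0.3
    group_shift_sd: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.n_housekeeping >= self.n_genes:
            raise ValueError("n_housekeeping must be smaller than n_genes")
        if min(self.n_genes, self.n_cells, self.n_housekeeping,
               self.group_count) <= 0:
            raise ValueError("all counts must be positive")
        if self.nb_dispersion <= 0 or self.lambda0 < 0:
            raise ValueError("nb_dispersion must be > 0 and lambda0 >= 0")
        if self.nb_mean_log_range[0] >= self.nb_mean_log_range[1]:
            raise ValueError("nb_mean_log_range must be an increasing pair")
        if self.n_cells < 2 * self.group_count:
            raise ValueError("need at least 2 cells per subpopulation")


@dataclass
class SyntheticDataset:
    truth: ExpressionMatrix
    observed: ExpressionMatrix
    mask: np.ndarray  # (k, 2) dropped (gene_row, cell_col) positions
    config: SyntheticConfig
    cell_intercepts: np.ndarray = field(default=None)
    housekeeping: GeneList = field(default=None)
    groups: dict[str, str] = field(default=None)  # cell_id -> group label
    ordering: CellOrdering = field(default=None)

    def mask_set(self) -> set[tuple[int, int]]:
        return {(int(g), int(c)) for g, c in self.mask}


def detection_probability(
    truth: np.ndarray,
    config: SyntheticConfig,
    is_housekeeping: np.ndarray,
    cell_intercepts: np.ndarray,
) -> np.ndarray:
    """Per-element probability that an expressed element is detected.

    Each cell has its own logistic efficiency curve: a shared slope on log
    true expression and a per-cell intercept (cell quality), plus a boost
    for housekeeping genes.
    """
    with np.errstate(divide="ignore"):
        logt = np.where(truth > 0, np.log(np.maximum(truth, 1e-300)), 0.0)
    z = (
        cell_intercepts[None, :]
        + config.dropout_slope * logt
        + config.hk_efficiency_boost * is_housekeeping[:, None]
    )
    return expit(z)


def expected_dropout_fraction(dataset: SyntheticDataset) -> float:
    """Analytic dropout expectation given the realized true expression.

    Averages ``1 - P(detect)`` over the expressed elements of the drawn
    truth matrix — the quantity the realized mask fraction estimates.
    """
    truth = dataset.truth.dense()
    is_hk = np.isin(np.array(dataset.truth.gene_ids),
                    np.array(dataset.housekeeping.ids))
    p = detection_probability(truth, dataset.config, is_hk,
                              dataset.cell_intercepts)
    expressed = truth > 0
    return float((1.0 - p[expressed]).mean())


def generate(config: SyntheticConfig | None = None, seed: int | None = None) -> SyntheticDataset:
    """Draw one seeded dataset; identical seeds give identical datasets."""
    config = config or SyntheticConfig()
    if seed is not None:
        config = SyntheticConfig(**{**asdict(config), "seed": seed})
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_mean, rng_group, rng_truth, rng_cell, rng_drop, rng_bg = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )
    m, n = config.n_genes, config.n_cells
    lo, hi = config.nb_mean_log_range

    gene_ids = [f"G{i:05d}" for i in range(m)]
    cell_ids = [f"C{j:04d}" for j in range(n)]

    hk_rows = np.sort(rng_mean.choice(m, size=config.n_housekeeping, replace=False))
    is_hk = np.zeros(m, dtype=bool)
    is_hk[hk_rows] = True
    log_mean = rng_mean.uniform(lo, hi, size=m)
    # housekeeping genes sit in the top quarter of the mean range
    log_mean[hk_rows] = rng_mean.uniform(hi - 0.25 * (hi - lo), hi,
                                         size=config.n_housekeeping)
    base_mean = np.exp(log_mean)

    group_of_cell = rng_group.integers(0, config.group_count, size=n)
    shift = np.ones((config.group_count, m))
    for g in range(config.group_count):
        shifted = rng_group.random(m) < config.group_shift_fraction
        shifted &= ~is_hk  # housekeeping expression is stable across groups
        shift[g, shifted] = np.exp(
            rng_group.normal(0.0, config.group_shift_sd, size=int(shifted.sum()))
        )

    mean = base_mean[:, None] * shift[group_of_cell, :].T
    k = config.nb_dispersion
    truth = rng_truth.negative_binomial(k, k / (k + mean)).astype(float)

    cell_intercepts = config.dropout_intercept + rng_cell.normal(
        0.0, config.cell_intercept_sd, size=n
    )
    p_detect = detection_probability(truth, config, is_hk, cell_intercepts)
    dropped = (rng_drop.random((m, n)) >= p_detect) & (truth > 0)
    observed = truth.copy()
    observed[dropped] = rng_bg.poisson(config.lambda0, size=int(dropped.sum()))
    mask = np.argwhere(dropped)

    groups = {cell_ids[j]: f"g{group_of_cell[j]}" for j in range(n)}
    # a simple trajectory surrogate: cells ordered by group, then library size
    lib = observed.sum(axis=0)
    order = np.lexsort((lib, group_of_cell))
    ordering = CellOrdering([cell_ids[j] for j in order])

    return SyntheticDataset(
        truth=ExpressionMatrix(gene_ids, cell_ids, truth, unit="counts"),
        observed=ExpressionMatrix(gene_ids, cell_ids, observed, unit="counts"),
        mask=mask,
        config=config,
        cell_intercepts=cell_intercepts,
        housekeeping=GeneList([gene_ids[g] for g in hk_rows]),
        groups=groups,
        ordering=ordering,
    )


def write_dataset(dataset: SyntheticDataset, out_prefix) -> dict[str, Path]:
    """Write truth.mtx, observed.mtx, mask.tsv, housekeeping.txt, groups.tsv,
    ordering.txt under the given prefix directory."""
    out = Path(out_prefix)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "truth": out / "truth.mtx",
        "observed": out / "observed.mtx",
        "mask": out / "mask.tsv",
        "housekeeping": out / "housekeeping.txt",
        "groups": out / "groups.tsv",
        "ordering": out / "ordering.txt",
    }
    write_expression_matrix(dataset.truth, paths["truth"])
    write_expression_matrix(dataset.observed, paths["observed"])
    pd.DataFrame(
        [
            (dataset.truth.gene_ids[g], dataset.truth.cell_ids[c])
            for g, c in dataset.mask
        ],
        columns=["gene_id", "cell_id"],
    ).to_csv(paths["mask"], sep="\t", index=False)
    write_gene_list(dataset.housekeeping, paths["housekeeping"])
    pd.DataFrame(
        sorted(dataset.groups.items()), columns=["cell_id", "group"]
    ).to_csv(paths["groups"], sep="\t", index=False, header=False)
    paths["ordering"].write_text("\n".join(dataset.ordering.cell_ids) + "\n")
    return paths
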