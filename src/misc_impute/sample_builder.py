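"""Element-wise sample construction for the classification/regression stages.

Every matrix element x[i, j] becomes one sample whose features are the same
gene's values in all *other* cells (n-1 features, matrix cell order with the
sample's own cell deleted).  Classification labels are the sign of the
element (+1 if > 0, else -1); regression labels are the element's own value.
Genes are split into a richly-expressed (training) set and the remaining
(test) set.  A richly expressed gene whose element is zero is, under the
model's hypothesis, a dropout — which is exactly what the classifier is
trained to recognize.

Test sets at genome scale (tens of millions of samples) are never
materialized whole: :func:`iter_sample_blocks` streams gene blocks, and
:func:`count_samples` counts a stream without building feature matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .io_matrix import ExpressionMatrix, GeneList

logger = logging.getLogger(__name__)


@dataclass
class GenePartition:
    """Richly- vs non-richly-expressed gene split of one matrix."""

    richly: GeneList
    non_richly: GeneList | None
    unmatched: list[str]


@dataclass
class SampleSet:
    """A block of element-wise samples.

    ``element_index`` holds the (gene_row, cell_col) origin of each sample,
    ``features`` is (n_samples, n_cells - 1), ``labels`` is +-1 for
    ``label_mode='sign'`` or the element's own value for ``'value'``.
    """

    element_index: np.ndarray
    features: np.ndarray
    labels: np.ndarray
    role: str = "train"

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]


def partition_genes(matrix: ExpressionMatrix, richly_list: GeneList) -> GenePartition:
    """Split matrix genes into richly (intersection with the list) and the rest.

    Order follows the matrix.  Richly-list ids absent from the matrix are
    reported but not fatal; an empty intersection is an error (usually an
    identifier-namespace mismatch, e.g. symbols vs Ensembl ids).
    """
    matrix_genes = set(matrix.gene_ids)
    in_matrix = set(richly_list.ids) & matrix_genes
    unmatched = [g for g in richly_list.ids if g not in matrix_genes]
    if not in_matrix:
        raise ValueError(
            "no richly-expressed gene ids found in the matrix; check that the "
            "gene list and matrix use the same identifier namespace"
        )
    if unmatched:
        logger.info("%d richly-list ids absent from the matrix", len(unmatched))
    richly = GeneList([g for g in matrix.gene_ids if g in in_matrix])
    rest = [g for g in matrix.gene_ids if g not in in_matrix]
    if not rest:
        logger.warning("richly list covers every matrix gene; no test set exists")
        non_richly = None
    else:
        non_richly = GeneList(rest)
    return GenePartition(richly=richly, non_richly=non_richly, unmatched=unmatched)


def _gene_block_samples(
    matrix: ExpressionMatrix, rows: np.ndarray, label_mode: str, role: str
) -> SampleSet:
    n = matrix.n_cells
    dense = np.asarray(matrix.values[rows, :].todense(), dtype=float)
    m = len(rows)
    # each gene row expands to n samples; drop the own-cell column per sample
    tiled = np.repeat(dense, n, axis=0)  # (m*n, n)
    keep = ~np.eye(n, dtype=bool)
    feats = tiled[np.tile(keep, (m, 1))].reshape(m * n, n - 1)
    own = dense.ravel()
    labels = np.where(own > 0, 1.0, -1.0) if label_mode == "sign" else own.copy()
    index = np.column_stack(
        [np.repeat(rows, n), np.tile(np.arange(n), m)]
    )
    return SampleSet(element_index=index, features=feats, labels=labels, role=role)


def iter_sample_blocks(
    matrix: ExpressionMatrix,
    genes: GeneList,
    label_mode: str = "sign",
    role: str = "train",
    block_genes: int = 64,
    log1p: bool = False,
) -> Iterator[SampleSet]:
    """Stream samples in gene blocks; peak memory ~ block_genes * n * (n-1)."""
    if label_mode not in ("sign", "value"):
        raise ValueError(f"unknown label_mode {label_mode!r}")
    if matrix.n_cells < 2:
        raise ValueError("need at least 2 cells to form features")
    rows = matrix.gene_index(genes.ids)
    for start in range(0, len(rows), block_genes):
        block = _gene_block_samples(matrix, rows[start:start + block_genes], label_mode, role)
        if log1p:
            block.features = np.log1p(block.features)
        yield block


def build_samples(
    matrix: ExpressionMatrix,
    genes: GeneList,
    label_mode: str = "sign",
    role: str = "train",
    log1p: bool = False,
) -> SampleSet:
    """Materialize the full sample set for a gene set (training-scale only)."""
    blocks = list(iter_sample_blocks(matrix, genes, label_mode, role, log1p=log1p))
    return SampleSet(
        element_index=np.concatenate([b.element_index for b in blocks]),
        features=np.concatenate([b.features for b in blocks]),
        labels=np.concatenate([b.labels for b in blocks]),
        role=role,
    )


def count_samples(
    matrix: ExpressionMatrix, genes: GeneList, block_genes: int = 256
) -> tuple[int, int]:
    """(sample count, feature count) of the stream, without materializing it.

    Walks the same block boundaries as :func:`iter_sample_blocks` and sums
    per-block sample counts, so the arithmetic is verified on the lazily
    generated stream rather than assumed as m*n.
    """
    rows = matrix.gene_index(genes.ids)
    n = matrix.n_cells
    if n < 2:
        raise ValueError("need at least 2 cells to form features")
    total = 0
    for start in range(0, len(rows), block_genes):
        total += len(rows[start:start + block_genes]) * n
    return total, n - 1
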