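"""Neighbor-cell mean-smoothing along a trajectory: the comparison method.

Given a 1-D ordering of cells (a trajectory / pseudotime ranking computed
elsewhere), a missing value at (gene, cell) is replaced by the mean of the
gene's values in up to ``gamma`` preceding and ``gamma`` following cells
in the ordering (gamma = 3 by default; the window truncates at the ends).
Zeros of neighboring cells are included in the window mean unless
``exclude_zeros`` is set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .candidates import MissingPositionSet
from .io_matrix import ExpressionMatrix


@dataclass
class CellOrdering:
    """A permutation of the matrix's cell ids in trajectory order."""

    cell_ids: list[str]

    def positions_for(self, matrix: ExpressionMatrix) -> np.ndarray:
        """position-in-ordering for each matrix cell column."""
        pos = {c: k for k, c in enumerate(self.cell_ids)}
        missing = [c for c in matrix.cell_ids if c not in pos]
        if missing:
            raise ValueError(f"cells absent from ordering: {', '.join(missing[:5])}")
        if len(self.cell_ids) != matrix.n_cells or len(pos) != matrix.n_cells:
            raise ValueError("ordering is not a permutation of the matrix's cells")
        return np.array([pos[c] for c in matrix.cell_ids], dtype=int)


def read_cell_ordering(path) -> CellOrdering:
    from pathlib import Path

    ids = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    return CellOrdering(ids)


def mean_smooth_impute(
    matrix: ExpressionMatrix,
    ordering: CellOrdering,
    positions: MissingPositionSet,
    gamma: int = 3,
    exclude_zeros: bool = False,
) -> ExpressionMatrix:
    """Impute each listed position with its trajectory-window mean."""
    if gamma < 1:
        raise ValueError("gamma must be >= 1")
    pos_in_order = ordering.positions_for(matrix)
    # column index of the matrix cell at each ordering slot
    col_at_slot = np.empty(matrix.n_cells, dtype=int)
    col_at_slot[pos_in_order] = np.arange(matrix.n_cells)
    out = matrix.values.tolil(copy=True)
    n = matrix.n_cells
    for g, c in positions.sorted_positions():
        slot = pos_in_order[c]
        lo, hi = max(0, slot - gamma), min(n, slot + gamma + 1)
        window_slots = [s for s in range(lo, hi) if s != slot]
        cols = col_at_slot[window_slots]
        vals = np.asarray(matrix.values[g, cols].todense()).ravel()
        if exclude_zeros:
            vals = vals[vals > 0]
        out[g, c] = float(vals.mean()) if len(vals) else 0.0
    return ExpressionMatrix(
        list(matrix.gene_ids), list(matrix.cell_ids), out.tocsr(), matrix.unit
    )
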