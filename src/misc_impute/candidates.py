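"""Shared candidate containers for the three missing-data detectors.

Each detector (llc, zim, fnc) emits a :class:`MissingProbabilityMatrix`:
a sparse map from zero-valued (gene_row, cell_col) positions to a score in
[0, 1].  Positions a detector cannot score (e.g. a gene outside the ZIM
amplified set) are simply absent.  Thresholding a probability matrix gives
a :class:`MissingPositionSet`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DETECTOR_SOURCES = ("llc", "zim", "fnc")


@dataclass
class MissingProbabilityMatrix:
    source: str
    rows: np.ndarray
    cols: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        if self.source not in DETECTOR_SOURCES:
            raise ValueError(f"source must be one of {DETECTOR_SOURCES}")
        self.rows = np.asarray(self.rows, dtype=int)
        self.cols = np.asarray(self.cols, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if not (len(self.rows) == len(self.cols) == len(self.scores)):
            raise ValueError("rows, cols and scores must have equal length")
        if len(self.scores) and (
            (self.scores < -1e-12).any() or (self.scores > 1 + 1e-12).any()
        ):
            raise ValueError("scores must lie in [0, 1]")
        self.scores = np.clip(self.scores, 0.0, 1.0)

    def __len__(self) -> int:
        return len(self.scores)

    def positions(self) -> set[tuple[int, int]]:
        return set(zip(self.rows.tolist(), self.cols.tolist()))

    def as_dict(self) -> dict[tuple[int, int], float]:
        return {
            (int(r), int(c)): float(s)
            for r, c, s in zip(self.rows, self.cols, self.scores)
        }


@dataclass
class MissingPositionSet:
    """A refined set of (gene_row, cell_col) positions declared missing."""

    positions: set[tuple[int, int]]
    provenance: tuple[str, ...]
    eta: float | None = None

    def __post_init__(self) -> None:
        self.positions = {(int(g), int(c)) for g, c in self.positions}
        self.provenance = tuple(self.provenance)

    def __len__(self) -> int:
        return len(self.positions)

    def sorted_positions(self) -> list[tuple[int, int]]:
        return sorted(self.positions)
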