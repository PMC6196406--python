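"""4x4 nucleotide substitution count and probability matrices.

The count matrix tallies every classified event by (ancestral base,
derived base). Two normalizations are exported side by side because both
are in common use and they answer different questions:

* conditional — each row divided by its own sum: the probability of the
  derived base given the ancestral base (a Markov transition row);
* joint — every cell divided by the total event count: the relative
  frequency of each specific base change among all substitutions.

Rows of the conditional matrix with no observed events stay all-zero and
are flagged in ``empty_rows`` rather than being filled with NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import SubstitutionEvent
from .genetic_code import DNA_BASES

BASES = tuple(DNA_BASES)
_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Counts plus (optionally) conditional and joint normalizations."""

    counts: np.ndarray  # (4, 4) int, zero diagonal
    conditional: np.ndarray | None = None  # row-stochastic on populated rows
    joint: np.ndarray | None = None  # sums to 1 over all cells
    empty_rows: np.ndarray | None = None  # bool (4,), True where row sum == 0

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def _frame(self, arr: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(arr, index=list(BASES), columns=list(BASES))

    def counts_frame(self) -> pd.DataFrame:
        return self._frame(self.counts)

    def conditional_frame(self) -> pd.DataFrame:
        return self._frame(self.conditional)

    def joint_frame(self) -> pd.DataFrame:
        return self._frame(self.joint)


def count_matrix(events: list[SubstitutionEvent]) -> SubstitutionMatrix:
    """Tally events into a 4x4 (from, to) count matrix."""
    counts = np.zeros((4, 4), dtype=int)
    for ev in events:
        counts[_INDEX[ev.from_base], _INDEX[ev.to_base]] += 1
    return SubstitutionMatrix(counts=counts)


def conditional_probabilities(matrix: SubstitutionMatrix) -> SubstitutionMatrix:
    """Fill both normalizations of a count matrix.

    Returns a new matrix whose ``conditional`` rows each sum to 1 where the
    count row is populated (zero rows are flagged, not NaN-filled) and
    whose ``joint`` cells sum to 1 over the whole table when any events
    exist.
    """
    counts = matrix.counts
    row_sums = counts.sum(axis=1)
    empty = row_sums == 0
    conditional = np.zeros((4, 4), dtype=float)
    populated = ~empty
    conditional[populated] = counts[populated] / row_sums[populated, None]
    total = counts.sum()
    joint = counts / total if total > 0 else np.zeros((4, 4), dtype=float)
    return SubstitutionMatrix(
        counts=counts, conditional=conditional, joint=joint, empty_rows=empty
    )


def transition_mass(matrix: SubstitutionMatrix) -> float:
    """Fraction of all events that are transitions (A<->G, C<->T)."""
    c = matrix.counts
    ts = (
        c[_INDEX["A"], _INDEX["G"]] + c[_INDEX["G"], _INDEX["A"]]
        + c[_INDEX["C"], _INDEX["T"]] + c[_INDEX["T"], _INDEX["C"]]
    )
    total = c.sum()
    return float(ts / total) if total else float("nan")
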