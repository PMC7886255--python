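"""Attractors and attractor sets.

An attractor of a synchronous Boolean network is a directed cycle of
global states (gene activity profiles): a fixed point (*singleton*,
period 1) or a cyclic attractor of period ``p >= 2``.  An
:class:`AttractorSet` collects the ``m`` attractors of one network over
a shared gene count ``n``; it is the input of the observability solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import prod
from typing import Iterable, Sequence

import numpy as np

__all__ = ["Attractor", "AttractorSet"]


def _as_state_matrix(states: object) -> np.ndarray:
    """Coerce states to a 2-D uint8 matrix of 0/1 entries."""
    arr = np.asarray(states)
    if arr.ndim == 1:
        arr = arr.reshape(1, -1)
    if arr.ndim != 2 or arr.shape[1] == 0:
        raise ValueError("states must form a non-empty 2-D binary matrix")
    if arr.dtype.kind in "US":
        # rows given as binary strings, e.g. "010110"
        rows = [list(s) for s in arr.ravel()]
        arr = np.asarray(rows)
    arr = arr.astype(np.uint8)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("state entries must be 0 or 1")
    return arr


@dataclass(frozen=True)
class Attractor:
    """One singleton or cyclic attractor.

    Parameters
    ----------
    states
        Ordered cyclic list of global states, one per row (period x n).
        Rows follow the cycle: under one synchronous step, row ``k``
        maps to row ``(k + 1) mod period``.  Rows may also be given as
        binary strings.
    """

    states: np.ndarray

    def __init__(self, states: object) -> None:
        arr = _as_state_matrix(states)
        if len({row.tobytes() for row in arr}) != arr.shape[0]:
            raise ValueError("states within an attractor must be pairwise distinct")
        arr.setflags(write=False)
        object.__setattr__(self, "states", arr)

    @property
    def period(self) -> int:
        """Number of global states in the cycle (1 for a fixed point)."""
        return self.states.shape[0]

    @property
    def n_genes(self) -> int:
        return self.states.shape[1]

    @property
    def is_singleton(self) -> bool:
        return self.period == 1

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Attractor):
            return NotImplemented
        return self.states.shape == other.states.shape and bool(
            (self.states == other.states).all()
        )

    def __hash__(self) -> int:
        return hash(self.states.tobytes())


@dataclass(frozen=True)
class AttractorSet:
    """The ``m`` attractors of a network over ``n`` genes.

    All global states across the whole set must be pairwise distinct:
    attractors of a deterministic network are disjoint state sets, and
    a duplicated state would make two attractors inherently
    indistinguishable.
    """

    attractors: tuple[Attractor, ...] = field()

    def __init__(self, attractors: Iterable[Attractor]) -> None:
        atts = tuple(attractors)
        if not atts:
            raise ValueError("an AttractorSet needs at least one attractor")
        n = atts[0].n_genes
        if any(a.n_genes != n for a in atts):
            raise ValueError("all attractors must share the same gene count")
        seen: set[bytes] = set()
        for a in atts:
            for row in a.states:
                key = row.tobytes()
                if key in seen:
                    raise ValueError(
                        "global states must be pairwise distinct across the set"
                    )
                seen.add(key)
        object.__setattr__(self, "attractors", atts)

    @classmethod
    def from_matrix(cls, matrix: object) -> "AttractorSet":
        """Build a set of singleton attractors, one per matrix row."""
        arr = _as_state_matrix(matrix)
        return cls(Attractor(row) for row in arr)

    @classmethod
    def from_state_lists(cls, groups: Sequence[object]) -> "AttractorSet":
        """Build from one state list (or string list) per attractor."""
        return cls(Attractor(g) for g in groups)

    @property
    def m(self) -> int:
        """Number of attractors."""
        return len(self.attractors)

    @property
    def n(self) -> int:
        """Number of genes."""
        return self.attractors[0].n_genes

    @property
    def sizes(self) -> tuple[int, ...]:
        """Periods ``l_1 ... l_m``."""
        return tuple(a.period for a in self.attractors)

    @property
    def max_period(self) -> int:
        return max(self.sizes)

    @property
    def n_combinations(self) -> int:
        """Number of phase combinations ``L = l_1 * l_2 * ... * l_m``."""
        return prod(self.sizes)

    def __len__(self) -> int:
        return self.m

    def __iter__(self):
        return iter(self.attractors)

    def __getitem__(self, i: int) -> Attractor:
        return self.attractors[i]
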