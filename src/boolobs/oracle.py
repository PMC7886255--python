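"""Brute-force reference solver.

Independent cross-check for the zero-run solver on small instances: it
materialises every phase combination and tests every window of every
length directly, by comparing the restricted rows for pairwise
distinctness.  It deliberately shares no machinery with the run-based
algorithm — no XOR matrices, no run analysis — so agreement between
the two is evidence of correctness rather than a tautology.  Cost is
O(L * n^2 * m^2) and therefore exponential in m via L; a budget guard
refuses instances beyond small scale.
"""

from __future__ import annotations

import itertools

import numpy as np

from boolobs.attractors import AttractorSet
from boolobs.solver import PhaseCombination

__all__ = ["window_distinguishes", "brute_force_min", "OracleBudgetError"]

#: Default cap on L * n^2 * m^2 work units.
DEFAULT_BUDGET = 500_000_000


class OracleBudgetError(ValueError):
    """Instance too large for exhaustive window scanning."""


def window_distinguishes(A: PhaseCombination | np.ndarray, start: int, w: int) -> bool:
    """True iff the rows restricted to columns [start, start+w-1]
    (1-based, inclusive) are pairwise distinct."""
    mat = A.matrix if isinstance(A, PhaseCombination) else np.asarray(A)
    m, n = mat.shape
    if start < 1 or w < 1 or start + w - 1 > n:
        raise ValueError(f"window [{start}, {start + w - 1}] out of range 1..{n}")
    sub = mat[:, start - 1 : start - 1 + w]
    return len({row.tobytes() for row in sub}) == m


def brute_force_min(
    aset: AttractorSet, budget: int = DEFAULT_BUDGET
) -> tuple[int | None, list[tuple[int, int, int]]]:
    """Smallest window length distinguishing some phase combination.

    Scans lengths ``w = 1..n`` ascending; for each, every combination
    and every start.  Returns ``(w, windows)`` where windows are all
    achieving ``(combination_id, start, end)`` triples at the minimal
    ``w``, or ``(None, [])`` if even full-length windows fail (possible
    only with duplicated rows, which :class:`AttractorSet` forbids).
    """
    m, n, L = aset.m, aset.n, aset.n_combinations
    work = L * n * n * m * m
    if work > budget:
        raise OracleBudgetError(
            f"instance needs ~{work} window checks, above budget {budget}"
        )
    if m == 1:
        return 0, []
    mats = [
        np.stack([a.states[p] for a, p in zip(aset, choice)])
        for choice in itertools.product(*(range(a.period) for a in aset))
    ]
    for w in range(1, n + 1):
        hits = []
        for cid, mat in enumerate(mats, start=1):
            for a in range(1, n - w + 2):
                if window_distinguishes(mat, a, w):
                    hits.append((cid, a, a + w - 1))
        if hits:
            return w, hits
    return None, []
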