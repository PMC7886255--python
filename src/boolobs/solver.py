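"""Minimal consecutive-node windows distinguishing attractors.

The attractor-observability (AO) problem: given ``m`` singleton or
cyclic attractors over ``n`` genes, find the smallest ``w`` such that
observing some window of ``w`` consecutive genes identifies which
attractor the network occupies.

The algorithm works per *phase combination*: an m x n binary matrix
``A`` choosing one global state (phase) from each attractor, of which
there are ``L = l_1 * ... * l_m``.  For one combination:

1. XOR every unordered pair of rows of ``A`` into the C(m,2) x n
   pairwise difference matrix (``biState``).  A zero entry marks a
   column on which that pair of attractors agrees.
2. Collect every maximal run of consecutive zeros of length at least
   ``ceil(log2 m)`` — shorter runs cannot swallow a candidate window.
3. If the runs do not cover all ``n`` columns, any window of length
   ``ceil(log2 m)`` containing an uncovered column distinguishes all
   pairs, so the per-combination minimum is exactly that lower bound.
4. Otherwise sort the runs by start, drop runs contained in another
   run, and take

       minL = max( min_j [ B(j, end) - B(j+1, start) + 3 ],
                   ceil(log2 m) )

   over adjacent surviving runs: the inner expression is the length of
   the shortest window poking out of both run ``j`` (one column past
   its end) and run ``j+1`` (one column before its start), hence
   contained in neither.

The answer is the minimum of ``minL`` over the ``L`` combinations; a
window is deemed sufficient if *some* phase assignment makes the
restricted row patterns pairwise distinct.  A combination with two
identical rows (an all-zero XOR row) cannot be distinguished by any
window and is skipped as infeasible.

All reported column indices are 1-based closed intervals ``[start,
end]``, matching the gene numbering x1..xn used in reports.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np

from boolobs.attractors import AttractorSet

__all__ = [
    "PhaseCombination",
    "PairDifferenceMatrix",
    "RunTable",
    "AOResult",
    "min_required_length",
    "enumerate_combinations",
    "pair_xor_matrix",
    "find_zero_runs",
    "coverage_gap",
    "prune_runs",
    "min_window_length",
    "recover_windows",
    "solve",
]

logger = logging.getLogger(__name__)

#: Sentinel for a combination no window can distinguish.
INFEASIBLE = math.inf


def min_required_length(m: int) -> int:
    """Information-theoretic lower bound ceil(log2 m): m distinct
    binary patterns need at least that many positions."""
    if m < 1:
        raise ValueError("m must be positive")
    return (m - 1).bit_length()


@dataclass(frozen=True)
class PhaseCombination:
    """One m x n matrix choosing a single phase from every attractor.

    ``index`` is the 1-based combination id A_1 .. A_L in lexicographic
    order of ``phase_choice`` (attractor 1 slowest-varying).
    """

    matrix: np.ndarray
    phase_choice: tuple[int, ...]
    index: int

    @property
    def m(self) -> int:
        return self.matrix.shape[0]

    @property
    def n(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class PairDifferenceMatrix:
    """C(m,2) x n matrix of pairwise XORs of a phase combination.

    ``pair_index[t]`` holds the 1-based attractor pair (i, k), i < k,
    in lexicographic pair order, whose XOR is row ``t``.
    """

    rows: np.ndarray
    pair_index: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class RunTable:
    """Zero-run bookkeeping for one pairwise difference matrix.

    ``runs`` are the maximal zero runs of length >= ``threshold``,
    pooled over all rows in row order (duplicates retained); each run
    is a 1-based closed interval.  ``covered`` is their column union.
    ``pruned`` (populated by :func:`prune_runs`) is the sorted,
    containment-pruned run list with strictly increasing starts and
    ends.
    """

    runs: tuple[tuple[int, int], ...]
    covered: frozenset[int]
    threshold: int
    pruned: tuple[tuple[int, int], ...] | None = None


@dataclass(frozen=True)
class AOResult:
    """Outcome of the AO solve.

    ``windows`` lists every achieving ``(combination_id, start, end)``
    with 1-based inclusive columns, sorted by combination then start.
    ``per_combination`` holds minL_i for every combination (``inf``
    for infeasible ones) when solved exhaustively, else ``None``.
    """

    min_length: int | None
    feasible: bool
    windows: tuple[tuple[int, int, int], ...] = ()
    per_combination: tuple[float, ...] | None = None


def enumerate_combinations(aset: AttractorSet) -> Iterator[PhaseCombination]:
    """Yield all L = l_1 * ... * l_m phase combinations.

    Lexicographic order of the phase choice, attractor 1 slowest-
    varying, so the ids match the conventional A_1 .. A_L numbering.
    """
    for idx, choice in enumerate(
        itertools.product(*(range(a.period) for a in aset)), start=1
    ):
        matrix = np.stack([a.states[p] for a, p in zip(aset, choice)])
        yield PhaseCombination(matrix, tuple(choice), idx)


def pair_xor_matrix(A: PhaseCombination) -> PairDifferenceMatrix:
    """XOR every unordered row pair (i, k), i < k, of the combination."""
    if A.m < 2:
        raise ValueError("need at least two attractors to form pairs")
    pairs = tuple((i + 1, k + 1) for i, k in itertools.combinations(range(A.m), 2))
    rows = np.stack([A.matrix[i - 1] ^ A.matrix[k - 1] for i, k in pairs])
    return PairDifferenceMatrix(rows, pairs)


def _zero_runs_of_row(row: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of consecutive zeros in one row, 1-based inclusive."""
    z = np.concatenate(([0], (row == 0).astype(np.int8), [0]))
    d = np.diff(z)
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def find_zero_runs(bi: PairDifferenceMatrix, threshold: int) -> RunTable:
    """Pool zero runs of length >= threshold over all rows.

    Runs appear in row order (within a row, left to right) and
    duplicates across rows are retained.
    """
    if threshold < 1:
        raise ValueError("threshold must be at least 1")
    runs: list[tuple[int, int]] = []
    for row in bi.rows:
        for s, e in _zero_runs_of_row(row):
            if e - s + 1 >= threshold:
                runs.append((s, e))
    covered = frozenset(c for s, e in runs for c in range(s, e + 1))
    return RunTable(tuple(runs), covered, threshold)


def coverage_gap(rt: RunTable, n: int) -> set[int]:
    """Columns of U = {1..n} not covered by any collected run.

    A nonempty gap certifies that the per-combination minimum equals
    the lower bound ceil(log2 m): any window of that length containing
    an uncovered column pokes out of every disqualifying zero run.
    """
    return set(range(1, n + 1)) - rt.covered


def prune_runs(rt: RunTable) -> RunTable:
    """Sort runs by start and drop runs contained in another run.

    Among runs sharing a start only the longest survives; a run
    strictly inside another constrains no window the containing run
    does not, and removing it keeps every adjacent-pair candidate
    window of the length formula inside the column range.  The result
    has strictly increasing starts *and* ends.
    """
    ordered = sorted(rt.runs, key=lambda r: r[0])  # stable
    by_start: list[tuple[int, int]] = []
    for s, e in ordered:
        if by_start and by_start[-1][0] == s:
            if e > by_start[-1][1]:
                by_start[-1] = (s, e)
        else:
            by_start.append((s, e))
    pruned: list[tuple[int, int]] = []
    max_end = 0
    for s, e in by_start:
        if e > max_end:
            pruned.append((s, e))
            max_end = e
    return replace(rt, pruned=tuple(pruned))


def min_window_length(rt: RunTable, m: int) -> float:
    """Per-combination minimum when the zero runs cover every column.

    Adjacent surviving runs j, j+1 admit a window from one column
    before run j+1's start to one column past run j's end, of length
    ``end_j - start_{j+1} + 3``; the minimum over j, floored at
    ceil(log2 m), is the answer.  A single surviving run spans the
    whole row range (an all-zero XOR row): no window distinguishes
    that pair and the combination is infeasible (returned as ``inf``).
    """
    if rt.pruned is None:
        raise ValueError("call prune_runs first")
    lower = min_required_length(m)
    B = rt.pruned
    if len(B) < 2:
        return INFEASIBLE
    candidate = min(B[j][1] - B[j + 1][0] + 3 for j in range(len(B) - 1))
    return float(max(candidate, lower))


def recover_windows(A: PhaseCombination, w: int) -> list[tuple[int, int]]:
    """All length-w windows whose restricted rows are pairwise distinct.

    Returns 1-based closed intervals in ascending start order; may be
    empty.
    """
    if w < 1:
        raise ValueError("window length must be at least 1")
    m, n = A.matrix.shape
    out = []
    for a in range(1, n - w + 2):
        sub = A.matrix[:, a - 1 : a - 1 + w]
        if len({row.tobytes() for row in sub}) == m:
            out.append((a, a + w - 1))
    return out


def _min_length_for_combination(A: PhaseCombination, m: int, n: int) -> float:
    lower = min_required_length(m)
    bi = pair_xor_matrix(A)
    rt = find_zero_runs(bi, lower)
    if coverage_gap(rt, n):
        return float(lower)
    return min_window_length(prune_runs(rt), m)


def solve(aset: AttractorSet, exhaustive: bool = False) -> AOResult:
    """Minimum consecutive-node count distinguishing every attractor.

    Scans the ``L`` phase combinations, keeping the smallest
    per-combination minimum.  By default the scan stops as soon as a
    combination attains the lower bound ceil(log2 m), which no other
    combination can beat; with ``exhaustive=True`` every combination
    is evaluated and its minL_i reported.

    A single attractor needs nothing to be identified: ``min_length``
    is 0.  If every combination is infeasible (impossible for a set of
    pairwise-distinct states) the result is flagged infeasible.
    """
    m, n = aset.m, aset.n
    if m == 1:
        return AOResult(0, True, (), (0.0,) if exhaustive else None)
    lower = min_required_length(m)
    L = aset.n_combinations
    logger.info("solving AO: m=%d, n=%d, L=%d, lower bound %d", m, n, L, lower)
    best = INFEASIBLE
    achievers: list[PhaseCombination] = []
    per: list[float] = []
    for A in enumerate_combinations(aset):
        minL = _min_length_for_combination(A, m, n)
        per.append(minL)
        logger.debug("combination %d/%d: minL=%s", A.index, L, minL)
        if minL < best:
            best = minL
            achievers = [A]
        elif minL == best and math.isfinite(minL):
            achievers.append(A)
        if not exhaustive and best == lower:
            logger.info("early stop at combination %d: lower bound reached", A.index)
            break
    if not math.isfinite(best):
        return AOResult(None, False, (), tuple(per) if exhaustive else None)
    w = int(best)
    windows = sorted(
        (A.index, a, b) for A in achievers for a, b in recover_windows(A, w)
    )
    return AOResult(w, True, tuple(windows), tuple(per) if exhaustive else None)
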