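"""Bundled worked examples and the Drosophila segment-polarity data.

The Drosophila fixture is the published set of ten steady states of
the 60-variable Boolean model of the segment-polarity gene network
(four cell compartments of 15 genes/proteins each), stored verbatim as
60-character binary strings in a packaged data file.  Each steady
state is one stable expression pattern of the embryonic parasegment;
distinguishing them with few contiguous variables suggests compact
biomarker panels.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from boolobs.attractors import AttractorSet
from boolobs.network import BooleanNetwork

__all__ = [
    "FIXTURES",
    "load_fixture",
    "GeneNameMap",
    "drosophila_gene_map",
    "name_window",
]

# 3-node demonstration network: one fixed point plus a period-2 cycle.
_EXAMPLE1_RULES = """\
# 3-node Boolean network
v1, !v2
v2, !v1 | v3
v3, v1
"""

# Two 4x6 singleton-attractor matrices exercising the two branches of
# the solver: the first leaves a column uncovered by zero runs, the
# second covers all columns and needs the adjacent-run formula.
_EXAMPLE2_FIRST = ("010101", "101000", "010010", "111110")
_EXAMPLE2_SECOND = ("100101", "011011", "101010", "010001")

# Two singletons plus two period-2 cycles over 6 genes (4 phase
# combinations, per-combination minima 4, 6, 3 and 2).
_EXAMPLE3 = (
    ("010110",),
    ("001010",),
    ("001011", "110101"),
    ("010010", "101010"),
)

# 7-gene illustration: observing genes 3 and 4 alone separates all
# four attractors as (1,1), (0,0), (0,1), (1,0).
_SEVEN_GENE = (
    ("0011011",),
    ("1100010",),
    ("1101010", "0011100"),
    ("0010011", "1101110"),
)

#: Names accepted by :func:`load_fixture`.
FIXTURES = (
    "example1_bn",
    "example2_first",
    "example2_second",
    "example3_attractors",
    "seven_gene",
    "drosophila",
)


def _drosophila_states() -> list[str]:
    text = (
        resources.files("boolobs") / "data" / "drosophila_steady_states.txt"
    ).read_text()
    rows = [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    return rows


def load_fixture(name: str) -> AttractorSet | BooleanNetwork:
    """Return a bundled example by name.

    ``example1_bn`` is a :class:`BooleanNetwork`; all other fixtures
    are :class:`AttractorSet` instances.
    """
    if name == "example1_bn":
        return BooleanNetwork.from_rule_text(_EXAMPLE1_RULES)
    if name == "example2_first":
        return AttractorSet.from_matrix(_EXAMPLE2_FIRST)
    if name == "example2_second":
        return AttractorSet.from_matrix(_EXAMPLE2_SECOND)
    if name == "example3_attractors":
        return AttractorSet.from_state_lists(_EXAMPLE3)
    if name == "seven_gene":
        return AttractorSet.from_state_lists(_SEVEN_GENE)
    if name == "drosophila":
        return AttractorSet.from_matrix(_drosophila_states())
    raise KeyError(f"unknown fixture {name!r}; available: {', '.join(FIXTURES)}")


@dataclass(frozen=True)
class GeneNameMap:
    """1-based column index -> human-readable gene/protein label."""

    labels: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.labels)

    def __getitem__(self, column: int) -> str:
        if not 1 <= column <= self.n:
            raise KeyError(f"column {column} outside map range 1..{self.n}")
        return self.labels[column - 1]


# Per-compartment variable order of the segment-polarity model:
# lowercase = gene (mRNA), uppercase = protein.
_SP_SYMBOLS = (
    "SLP", "wg", "WG", "en", "EN", "hh", "HH", "ptc", "PTC", "PH",
    "SMO", "ci", "CI", "CIA", "CIR",
)


def drosophila_gene_map() -> GeneNameMap:
    """Variable-to-name map of the 60-variable segment-polarity model:
    x1..x15 are compartment 1, x16..x30 compartment 2, and so on."""
    labels = tuple(
        f"compartment {c} {sym}" for c in range(1, 5) for sym in _SP_SYMBOLS
    )
    return GeneNameMap(labels)


def name_window(window: tuple[int, int], gene_map: GeneNameMap) -> list[str]:
    """Labels of every column in a 1-based closed window."""
    if gene_map.n == 0:
        raise ValueError("gene map is empty")
    start, end = window
    if not (1 <= start <= end <= gene_map.n):
        raise ValueError(f"window [{start}, {end}] outside map range 1..{gene_map.n}")
    return [gene_map[c] for c in range(start, end + 1)]
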