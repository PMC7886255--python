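"""Synchronous Boolean networks.

A Boolean network G(V, F) has n binary nodes (genes).  Node i is
updated by a Boolean function f_i of its h_i input nodes (the
*indegree*), and all nodes update simultaneously:

    v_i(t + 1) = f_i(v(t)),   i = 1 .. n.

The global state [v_1(t), ..., v_n(t)] is the gene activity profile
(GAP).  For small n the full 2^n transition table can be enumerated and
every attractor (cycle of the functional graph of the update map) found
exhaustively.

Update rules are stored as explicit truth tables.  They can be built
from logic expressions over node names using ``&`` (and), ``|`` (or),
``!`` (not), ``^`` (xor) and parentheses, either programmatically or
from a plain-text rule file with one ``name, expression`` line per node
(``#`` starts a comment).  Truth tables are addressed little-endian:
the first listed input of a node is the lowest-order bit of the table
index.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from boolobs.attractors import Attractor, AttractorSet

__all__ = [
    "BooleanNetwork",
    "UpdateRule",
    "step",
    "transition_table",
    "enumerate_attractors",
    "StateSpaceTooLargeError",
]

#: Default cap on exhaustive 2^n state-space traversal.
DEFAULT_MAX_NODES = 20


class StateSpaceTooLargeError(ValueError):
    """Raised when an exhaustive operation would enumerate 2^n states
    beyond the configured node limit."""


@dataclass(frozen=True)
class UpdateRule:
    """Truth table of one node's update function.

    ``inputs`` are node indices (0-based); ``table`` has 2^len(inputs)
    entries, addressed with the first input as the lowest-order bit.
    """

    inputs: tuple[int, ...]
    table: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.table) != 1 << len(self.inputs):
            raise ValueError("truth table must have exactly 2^h entries")
        if any(b not in (0, 1) for b in self.table):
            raise ValueError("truth table entries must be 0 or 1")

    def evaluate(self, state: Sequence[int]) -> int:
        addr = 0
        for j, idx in enumerate(self.inputs):
            addr |= int(state[idx]) << j
        return self.table[addr]


_ALLOWED_BINOPS = {ast.BitAnd: "and", ast.BitOr: "or", ast.BitXor: "xor"}


def _eval_expr(node: ast.AST, env: dict[str, int]) -> int:
    if isinstance(node, ast.Expression):
        return _eval_expr(node.body, env)
    if isinstance(node, ast.Name):
        return env[node.id]
    if isinstance(node, ast.Constant):
        if node.value in (0, 1):
            return int(node.value)
        raise ValueError(f"constant {node.value!r} is not a Boolean")
    if isinstance(node, ast.UnaryOp) and isinstance(node.op, ast.Invert):
        return 1 - _eval_expr(node.operand, env)
    if isinstance(node, ast.BinOp) and type(node.op) in _ALLOWED_BINOPS:
        a = _eval_expr(node.left, env)
        b = _eval_expr(node.right, env)
        op = _ALLOWED_BINOPS[type(node.op)]
        if op == "and":
            return a & b
        if op == "or":
            return a | b
        return a ^ b
    raise ValueError(
        "rule expressions may only use node names, 0/1, '&', '|', '^', '!' "
        "and parentheses"
    )


def _collect_names(node: ast.AST, order: list[str]) -> None:
    for child in ast.walk(node):
        if isinstance(child, ast.Name) and child.id not in order:
            order.append(child.id)


def _compile_expression(expr: str, name_to_index: dict[str, int]) -> UpdateRule:
    """Turn a logic expression into an UpdateRule.

    Inputs are listed in order of first appearance in the expression;
    the first appearing name becomes the lowest-order table bit.
    """
    tree = ast.parse(expr.replace("!", "~"), mode="eval")
    names: list[str] = []
    _collect_names(tree, names)
    unknown = [nm for nm in names if nm not in name_to_index]
    if unknown:
        raise ValueError(f"rule references unknown node(s): {', '.join(unknown)}")
    h = len(names)
    table = []
    for addr in range(1 << h):
        env = {nm: (addr >> j) & 1 for j, nm in enumerate(names)}
        table.append(_eval_expr(tree, env))
    return UpdateRule(tuple(name_to_index[nm] for nm in names), tuple(table))


@dataclass(frozen=True)
class BooleanNetwork:
    """A synchronous Boolean network: node names plus per-node rules."""

    node_names: tuple[str, ...]
    rules: tuple[UpdateRule, ...]

    def __post_init__(self) -> None:
        n = len(self.node_names)
        if len(self.rules) != n:
            raise ValueError("need exactly one update rule per node")
        if len(set(self.node_names)) != n:
            raise ValueError("node names must be unique")
        for rule in self.rules:
            if any(not 0 <= i < n for i in rule.inputs):
                raise ValueError("rule input index out of range")

    @property
    def n(self) -> int:
        return len(self.node_names)

    @property
    def max_indegree(self) -> int:
        """H = max_i h_i, the maximum number of inputs of any node."""
        return max(len(r.inputs) for r in self.rules)

    @classmethod
    def from_expressions(
        cls, rules: Sequence[tuple[str, str]] | dict[str, str]
    ) -> "BooleanNetwork":
        """Build a network from ``(name, expression)`` pairs."""
        pairs = list(rules.items()) if isinstance(rules, dict) else list(rules)
        names = [nm for nm, _ in pairs]
        index = {nm: i for i, nm in enumerate(names)}
        compiled = tuple(_compile_expression(expr, index) for _, expr in pairs)
        return cls(tuple(names), compiled)

    @classmethod
    def from_rule_text(cls, text: str) -> "BooleanNetwork":
        """Parse the plain-text rule format: ``name, expression`` lines,
        ``#`` comments and blank lines ignored."""
        pairs = []
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            name, sep, expr = line.partition(",")
            if not sep or not expr.strip():
                raise ValueError(f"line {lineno}: expected 'name, expression'")
            pairs.append((name.strip(), expr.strip()))
        if not pairs:
            raise ValueError("rule file defines no nodes")
        return cls.from_expressions(pairs)

    @classmethod
    def from_rule_file(cls, path: str | Path) -> "BooleanNetwork":
        return cls.from_rule_text(Path(path).read_text())


def step(network: BooleanNetwork, state: Sequence[int]) -> np.ndarray:
    """One synchronous update: every node reads the same input state."""
    arr = np.asarray(state, dtype=np.uint8)
    if arr.shape != (network.n,):
        raise ValueError(
            f"state length {arr.size} does not match network size {network.n}"
        )
    return np.array([rule.evaluate(arr) for rule in network.rules], dtype=np.uint8)


def _state_to_int(state: Sequence[int]) -> int:
    # v_1 is the most significant bit, so integer order == lexicographic
    # order of GAPs and ascending binary order of the truth table.
    code = 0
    for b in state:
        code = (code << 1) | int(b)
    return code


def _int_to_state(code: int, n: int) -> np.ndarray:
    return np.array([(code >> (n - 1 - i)) & 1 for i in range(n)], dtype=np.uint8)


def _check_size(network: BooleanNetwork, max_nodes: int, what: str) -> None:
    if network.n > max_nodes:
        raise StateSpaceTooLargeError(
            f"{what} needs 2^{network.n} = {1 << network.n} states; "
            f"refusing above {max_nodes} nodes (pass max_nodes to override)"
        )


def _successor_codes(network: BooleanNetwork) -> list[int]:
    n = network.n
    return [
        _state_to_int(step(network, _int_to_state(code, n))) for code in range(1 << n)
    ]


def transition_table(
    network: BooleanNetwork, max_nodes: int = DEFAULT_MAX_NODES
) -> pd.DataFrame:
    """Full 2^n truth table of the synchronous dynamics.

    Rows enumerate every global state in ascending binary order
    (index 1..2^n); columns give the state bits at t and at t+1.
    """
    _check_size(network, max_nodes, "transition table")
    n = network.n
    cols_t = [f"{nm}(t)" for nm in network.node_names]
    cols_t1 = [f"{nm}(t+1)" for nm in network.node_names]
    rows = []
    for code in range(1 << n):
        state = _int_to_state(code, n)
        rows.append(np.concatenate([state, step(network, state)]))
    frame = pd.DataFrame(rows, columns=cols_t + cols_t1, dtype=np.uint8)
    frame.index = pd.RangeIndex(1, (1 << n) + 1, name="state")
    return frame


def enumerate_attractors(
    network: BooleanNetwork, max_nodes: int = DEFAULT_MAX_NODES
) -> AttractorSet:
    """Find every attractor by exhaustive trajectory-following.

    Walks the functional graph of the update map with a visited map
    (no 2^n x 2^n
    matrices).  Each cycle is reported once, rotated to
    start at its lexicographically smallest state; attractors are
    sorted by that state.
    """
    _check_size(network, max_nodes, "attractor enumeration")
    n = network.n
    succ = _successor_codes(network)
    status = bytearray(1 << n)  # 0 unvisited, 1 on current path, 2 done
    cycles: list[list[int]] = []
    for start in range(1 << n):
        path: list[int] = []
        code = start
        while status[code] == 0:
            status[code] = 1
            path.append(code)
            code = succ[code]
        if status[code] == 1:  # closed a new cycle on the current path
            at = path.index(code)
            cycles.append(path[at:])
        for visited in path:
            status[visited] = 2
    attractors = []
    for cycle in cycles:
        k = cycle.index(min(cycle))
        rotated = cycle[k:] + cycle[:k]
        attractors.append(Attractor(np.stack([_int_to_state(c, n) for c in rotated])))
    attractors.sort(key=lambda a: tuple(a.states[0]))
    return AttractorSet(attractors)
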