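"""Random-instance experiments.

Generates random attractor sets (every bit independent and
equiprobable, all global states forced pairwise distinct) and measures
the distribution of the minimal distinguishing window length
("numNode") across instance sizes.  Cyclic attractors are random
distinct state lists, not cycles of an actual network: the solver only
ever sees the states, so the dynamics generating them are irrelevant
to the measured quantity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from boolobs.attractors import Attractor, AttractorSet
from boolobs.solver import solve

__all__ = ["ExperimentConfig", "ExperimentResult", "random_attractor_set", "run_experiment", "sweep"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExperimentConfig:
    """One experiment grid point.

    n genes, m attractors of the given period, averaged over ``trials``
    independently generated sets (ten in the original experiments; more
    trials tighten the mean).
    """

    n: int
    m: int
    period: int = 1
    trials: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.trials < 1 or self.period < 1 or self.m < 2:
            raise ValueError("need trials >= 1, period >= 1, m >= 2")


def random_attractor_set(
    n: int,
    m: int,
    period: int = 1,
    rng: np.random.Generator | int | None = None,
) -> AttractorSet:
    """m random attractors of equal period over n genes.

    Every bit is an independent fair coin flip; the draw is repeated
    until all ``m * period`` states are pairwise distinct (a collision
    is vanishingly rare at the sizes of interest).  Distinct states
    guarantee feasibility: every phase combination has distinct rows,
    so the full-length window always discriminates.
    """
    if 2**n < m * period:
        raise ValueError(f"cannot place {m * period} distinct states in 2^{n}")
    rng = np.random.default_rng(rng)
    resamples = 0
    while True:
        states = rng.integers(0, 2, size=(m * period, n), dtype=np.uint8)
        if len({row.tobytes() for row in states}) == m * period:
            break
        resamples += 1
    if resamples:
        logger.info("resampled %d time(s) to obtain distinct states", resamples)
    return AttractorSet(
        Attractor(states[i * period : (i + 1) * period]) for i in range(m)
    )


@dataclass(frozen=True)
class ExperimentResult:
    config: ExperimentConfig
    values: tuple[int, ...] = field(default=())

    @property
    def mean(self) -> float:
        """Mean minimal window length over the trials (numNode)."""
        return float(np.mean(self.values))


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Solve ``trials`` independent random sets; report per-trial
    minimal window lengths and their mean."""
    rng = np.random.default_rng(config.seed)
    values = []
    for t in range(config.trials):
        aset = random_attractor_set(config.n, config.m, config.period, rng)
        res = solve(aset)
        values.append(res.min_length)
        logger.debug("trial %d/%d: numNode=%d", t + 1, config.trials, res.min_length)
    return ExperimentResult(config, tuple(values))


def sweep(
    axis: str,
    values: list[int],
    fixed: dict[str, int],
    trials: int = 10,
    seed: int | None = None,
) -> pd.DataFrame:
    """numNode distribution along a grid of n or m.

    ``axis`` is ``"n"`` or ``"m"``; ``fixed`` supplies the other size
    (and optionally ``period``).  Returns a long-format frame with one
    row per (grid point, trial), suitable for histogramming.
    """
    if axis not in ("n", "m"):
        raise ValueError("axis must be 'n' or 'm'")
    seeds = np.random.SeedSequence(seed).spawn(len(values))
    records = []
    for point, ss in zip(values, seeds):
        params = {"period": 1, **fixed, axis: point}
        cfg = ExperimentConfig(
            n=params["n"],
            m=params["m"],
            period=params["period"],
            trials=trials,
            seed=int(ss.generate_state(1)[0] % 2**31),
        )
        result = run_experiment(cfg)
        for trial, v in enumerate(result.values):
            records.append({axis: point, "trial": trial + 1, "num_node": v})
    return pd.DataFrame.from_records(records)
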