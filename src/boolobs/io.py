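"""File formats and report writers.

Attractor sets travel as TSV with columns ``attractor_id``, ``phase``
and either a single ``state`` column of n binary characters or one 0/1
column per gene.  Solver results serialize to a small versioned JSON
schema or a flat TSV; all column indices in reports are 1-based
closed intervals, matching the gene numbering x1..xn.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import TextIO

import numpy as np
import pandas as pd

from boolobs.attractors import Attractor, AttractorSet
from boolobs.fixtures import GeneNameMap, name_window
from boolobs.solver import AOResult

__all__ = [
    "read_attractor_tsv",
    "write_attractor_tsv",
    "write_report",
    "REPORT_SCHEMA_VERSION",
]

REPORT_SCHEMA_VERSION = 1


def write_attractor_tsv(aset: AttractorSet, path: str | Path | TextIO) -> None:
    """One row per global state: attractor_id, phase (both 1-based) and
    the state as an n-character binary string."""
    records = []
    for aid, att in enumerate(aset, start=1):
        for phase, row in enumerate(att.states, start=1):
            records.append(
                {
                    "attractor_id": aid,
                    "phase": phase,
                    "state": "".join(map(str, row.tolist())),
                }
            )
    pd.DataFrame.from_records(records).to_csv(path, sep="\t", index=False)


def read_attractor_tsv(path: str | Path | TextIO) -> AttractorSet:
    """Inverse of :func:`write_attractor_tsv`; also accepts one 0/1
    column per gene instead of the ``state`` string column."""
    frame = pd.read_csv(path, sep="\t", dtype={"state": str})
    if "attractor_id" not in frame.columns:
        raise ValueError("attractor TSV needs an 'attractor_id' column")
    if "phase" not in frame.columns:
        frame["phase"] = frame.groupby("attractor_id").cumcount() + 1
    attractors = []
    for _, group in frame.groupby("attractor_id", sort=True):
        group = group.sort_values("phase")
        if "state" in frame.columns:
            states = np.array([list(s) for s in group["state"]], dtype=np.uint8)
        else:
            gene_cols = [c for c in frame.columns if c not in ("attractor_id", "phase")]
            states = group[gene_cols].to_numpy(dtype=np.uint8)
        attractors.append(Attractor(states))
    return AttractorSet(attractors)


def _result_payload(result: AOResult, gene_map: GeneNameMap | None) -> dict:
    windows = []
    for cid, start, end in result.windows:
        entry: dict = {"combination": cid, "start": start, "end": end}
        if gene_map is not None:
            entry["genes"] = name_window((start, end), gene_map)
        windows.append(entry)
    payload = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "min_length": result.min_length,
        "feasible": result.feasible,
        "windows": windows,
    }
    if result.per_combination is not None:
        payload["per_combination"] = [
            v if np.isfinite(v) else None for v in result.per_combination
        ]
        payload["per_combination"] = [
            int(v) if v is not None else None for v in payload["per_combination"]
        ]
    return payload


def write_report(
    result: AOResult,
    gene_map: GeneNameMap | None = None,
    format: str = "json",
) -> str:
    """Serialize an :class:`AOResult` to ``"json"`` or ``"tsv"``."""
    payload = _result_payload(result, gene_map)
    if format == "json":
        return json.dumps(payload, indent=2) + "\n"
    if format == "tsv":
        lines = [
            f"min_length\t{payload['min_length']}",
            f"feasible\t{str(payload['feasible']).lower()}",
        ]
        if "per_combination" in payload:
            joined = "\t".join(
                "inf" if v is None else str(v) for v in payload["per_combination"]
            )
            lines.append(f"per_combination\t{joined}")
        lines.append("combination\tstart\tend\tgenes")
        for w in payload["windows"]:
            genes = ",".join(w.get("genes", []))
            lines.append(f"{w['combination']}\t{w['start']}\t{w['end']}\t{genes}")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown report format {format!r} (use 'json' or 'tsv')")
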