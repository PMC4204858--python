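"""Configuration files, delimited-text outputs, and run manifests.

Formats are deliberately plain: CSV with a header row (UTF-8, LF) for
agent tables and density profiles, pretty-printed JSON with sorted keys
for manifests and matrix reports, and a flat YAML/JSON mapping mirroring
:class:`~cortexsim.params.ModelParams` field names for configuration.
A manifest plus the package is sufficient to reproduce every output
byte-for-byte.
"""
from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .engine import CompletedSim
from .params import ConfigurationError, ModelParams

_COMP_NAMES = {0: "unborn", 1: "IZ", 2: "queue", 3: "CP"}


def load_config(path) -> ModelParams:
    """Read a flat YAML (or JSON, a YAML subset) mapping into ModelParams."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"config file {path} must hold a flat mapping")
    return ModelParams.from_dict(data)


def agent_table(completed: CompletedSim, run_id: str = "run") -> pd.DataFrame:
    """One record per agent: identity, batch, state, and final position.

    ``row`` uses the distance-from-Layer-1 convention (1 = adjacent to
    Layer 1); for agents not settled in the CP (possible only in
    non-terminated runs) ``row``/``column`` are empty and ``compartment``
    tells where the agent was.
    """
    st = completed.state
    n = st.params.n_agents
    comp = np.array([_COMP_NAMES[c] for c in st.comp])
    in_cp = st.comp == 3
    row = np.where(in_cp, st.arow + 1, -1)
    col = np.where(st.arow >= 0, st.acol + 1, -1)
    df = pd.DataFrame({
        "run_id": run_id,
        "seed": completed.seed,
        "agent_id": np.arange(n),
        "batch": st.batch,
        "state": np.where(st.active == 1, "active", "passive"),
        "compartment": comp,
        "row": row,
        "column": np.where(in_cp, col, -1),
    })
    return df


def write_agent_table(completed: CompletedSim, path, run_id: str = "run") -> Path:
    path = Path(path)
    agent_table(completed, run_id).to_csv(path, index=False, lineterminator="\n")
    return path


def read_agent_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def lattice_from_agent_table(df: pd.DataFrame) -> np.ndarray:
    """Rebuild the final CP batch-label lattice (row 0 adjacent to Layer 1)."""
    cp = df[df["compartment"] == "CP"]
    n_rows = int(cp["row"].max())
    width = int(cp["column"].max())
    grid = np.zeros((n_rows, width), np.int32)
    grid[cp["row"] - 1, cp["column"] - 1] = cp["batch"]
    return grid


def write_profile(profile, path) -> Path:
    path = Path(path)
    profile.to_frame().to_csv(path, index=False, lineterminator="\n")
    return path


def write_manifest(path, params: ModelParams, seeds, statuses, outputs,
                   steps=None) -> Path:
    """JSON sidecar with everything needed to reproduce the run(s)."""
    manifest = {
        "params": dataclasses.asdict(params),
        "seeds": list(map(int, seeds)),
        "statuses": list(statuses),
        "steps": None if steps is None else list(map(int, steps)),
        "outputs": [str(p) for p in outputs],
        "version": _version,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def write_matrix_report(matrix, path) -> Path:
    """Structured-text report of the 16-combination screen."""
    report = {
        "n_realizations": matrix.n_realizations,
        "genotypes": matrix.genotypes,
        "cells": matrix.to_records(),
        "full_success_pairs": matrix.full_success_pairs,
        "single_failure_pairs": matrix.single_failure_pairs,
        "definitive_failure_pairs": matrix.definitive_failure_pairs,
    }
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def format_matrix_table(matrix) -> str:
    """Human-readable table mirroring the published matrix layout."""
    genos = matrix.genotypes
    head = {"wild_type": "WT", "reeler": "R", "dab1": "D", "dab1_conditional": "Dc"}
    lines = ["conv | " + " | ".join(f"movement ({m})".ljust(4 * len(genos) + 2)
                                    for m in "abcd"),
             "     | " + " | ".join("  ".join(head[g].ljust(2) for g in genos)
                                    for _ in "abcd")]
    for cv in ["i", "ii", "iii", "iv"]:
        marks = []
        for mv in "abcd":
            cell_marks = []
            for g in genos:
                c = matrix.cells.get((mv, cv, g))
                cell_marks.append(("+" if c.success else "x").ljust(2))
            marks.append("  ".join(cell_marks))
        lines.append(f"{cv:4s} | " + " | ".join(marks))
    lines.append("legend: + phenotype reproduced, x not reproduced")
    return "\n".join(lines)
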