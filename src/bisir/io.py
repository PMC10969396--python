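"""File I/O: edge lists, trajectory tables, reproducibility manifests."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .core import ParameterError, Trajectory
from .netsim import ContactNetwork

__all__ = ["read_edge_list", "write_trajectory_table", "read_trajectory_table", "write_manifest"]

logger = logging.getLogger("bisir")


def read_edge_list(path: Union[str, Path]) -> ContactNetwork:
    """Parse a whitespace-separated undirected edge list.

    One edge per line as two integer node ids; ``#`` starts a comment.
    Self-loops and duplicate edges are dropped (with a logged count) and
    node ids are remapped to 0..n-1 preserving sorted original order.
    """
    path = Path(path)
    edges = []
    n_loops = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            parts = body.split()
            if len(parts) != 2:
                raise ParameterError(f"{path}:{lineno}: expected two node ids, got {body!r}")
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise ParameterError(f"{path}:{lineno}: non-integer node id in {body!r}") from exc
            if u == v:
                n_loops += 1
                continue
            edges.append((u, v))
    if not edges:
        raise ParameterError(f"{path}: no edges found")
    nodes = sorted({u for e in edges for u in e})
    relabel = {u: i for i, u in enumerate(nodes)}
    edge_set = {tuple(sorted((relabel[u], relabel[v]))) for u, v in edges}
    n_dupes = len(edges) - len(edge_set)
    if n_loops:
        logger.warning("%s: dropped %d self-loop(s)", path, n_loops)
    if n_dupes:
        logger.info("%s: collapsed %d duplicate edge(s)", path, n_dupes)
    return ContactNetwork.from_edges(len(nodes), edge_set)


def write_trajectory_table(trajectory: Trajectory, path: Union[str, Path]) -> None:
    """Write ``time,S,I,R`` as CSV at full float precision (round-trip exact)."""
    df = pd.DataFrame(
        {"time": trajectory.times, "S": trajectory.S, "I": trajectory.I, "R": trajectory.R}
    )
    if trajectory.mode == "count":
        for col in ("S", "I", "R"):
            df[col] = df[col].astype(np.int64)
    df.to_csv(path, index=False, float_format="%.17g")


def read_trajectory_table(path: Union[str, Path], mode: str = "density") -> Trajectory:
    df = pd.read_csv(path, float_precision="round_trip")
    return Trajectory(
        times=df["time"].to_numpy(),
        S=df["S"].to_numpy(),
        I=df["I"].to_numpy(),
        R=df["R"].to_numpy(),
        mode=mode,
    )


def write_manifest(path: Union[str, Path], payload: dict) -> None:
    """Reproducibility manifest: every parameter and seed of a run, as JSON."""
    from . import __version__

    record = {"bisir_version": __version__, **payload}
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True, default=str) + "\n")
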