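"""CSV readers/writers and run manifests.

User-facing formats (all plain text):

* matrix CSV — square numeric table, first row and first column hold
  1-based node ids;
* edge-list CSV — columns ``node_i, node_j, weight``, undirected, each
  unordered pair at most once, 1-based ids;
* node-attribute CSV — column ``node_id`` plus one column per attribute,
  aligned to the accompanying network by id, not by row order.

Numeric output uses full double precision (``repr`` round-trip), so
re-summarising written records reproduces summaries exactly.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .net import DyadMatrix

__all__ = [
    "read_matrix_csv",
    "write_matrix_csv",
    "read_edgelist_csv",
    "write_edgelist_csv",
    "read_node_attributes_csv",
    "RunManifest",
]

_SYM_TOL = 1e-9


def read_matrix_csv(path) -> DyadMatrix:
    """Read a square matrix CSV into a :class:`DyadMatrix`.

    The two triangles are averaged; asymmetry beyond 1e-9 is an error, not
    a warning.
    """
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    if df.shape[0] != df.shape[1]:
        raise FormatError(f"{path}: table is {df.shape[0]}x{df.shape[1]}, not square")
    w = df.to_numpy()
    if not np.issubdtype(w.dtype, np.number):
        raise FormatError(f"{path}: non-numeric entries present")
    w = w.astype(float)
    if np.any(np.isnan(w)):
        i, j = np.argwhere(np.isnan(w))[0]
        raise FormatError(f"{path}: NaN entry at row {i + 1}, column {j + 1}")
    asym = np.abs(w - w.T)
    if asym.max() > _SYM_TOL:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise FormatError(
            f"{path}: asymmetric at ({df.index[i]}, {df.columns[j]}): "
            f"{w[i, j]!r} vs {w[j, i]!r}"
        )
    return DyadMatrix((w + w.T) / 2.0)


def write_matrix_csv(path, net: DyadMatrix) -> None:
    ids = [str(i + 1) for i in range(net.n)]
    pd.DataFrame(net.values, index=ids, columns=ids).to_csv(
        path, float_format=None, index_label=""
    )


def read_edgelist_csv(path, n: int | None = None) -> DyadMatrix:
    """Read an undirected edge list (1-based ids, each unordered pair once)."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    required = {"node_i", "node_j", "weight"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    i = df["node_i"].to_numpy(dtype=int) - 1
    j = df["node_j"].to_numpy(dtype=int) - 1
    wt = df["weight"].to_numpy(dtype=float)
    if np.any(i == j):
        raise FormatError(f"{path}: self-edges are not allowed")
    size = int(max(i.max(initial=-1), j.max(initial=-1)) + 1) if n is None else n
    lo, hi = np.minimum(i, j), np.maximum(i, j)
    if len(set(zip(lo.tolist(), hi.tolist()))) != len(lo):
        raise FormatError(f"{path}: duplicate unordered pair in edge list")
    w = np.zeros((size, size))
    w[lo, hi] = wt
    w[hi, lo] = wt
    return DyadMatrix(w)


def write_edgelist_csv(path, net: DyadMatrix) -> None:
    i, j = np.triu_indices(net.n, k=1)
    pd.DataFrame(
        {"node_i": i + 1, "node_j": j + 1, "weight": net.values[i, j]}
    ).to_csv(path, index=False)


def read_node_attributes_csv(path, n: int | None = None) -> dict[str, np.ndarray]:
    """Read node attributes keyed by 1-based ``node_id``; returns one vector
    per attribute column, aligned to node order regardless of row order."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    if "node_id" not in df.columns:
        raise FormatError(f"{path}: missing node_id column")
    ids = df["node_id"].to_numpy(dtype=int)
    if len(np.unique(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate node_id")
    size = int(ids.max()) if n is None else n
    expected = set(range(1, size + 1))
    if set(ids.tolist()) != expected:
        missing = sorted(expected - set(ids.tolist()))
        raise FormatError(f"{path}: node ids do not cover 1..{size} (missing {missing})")
    order = np.argsort(ids)
    out: dict[str, np.ndarray] = {}
    for col in df.columns:
        if col == "node_id":
            continue
        out[col] = df[col].to_numpy(dtype=float)[order]
    return out


@dataclass
class RunManifest:
    """Provenance record written next to every CLI output.

    Captures everything needed to reproduce the output bit-for-bit with the
    same software version: the command line, the fully resolved config, the
    master seed, and the seed-derivation rule.
    """

    command: str
    config: dict
    master_seed: int
    seed_rule: str = (
        "replicate k of scenario s uses numpy SeedSequence(master_seed, "
        "spawn_key=(scenario_code, k)), spawned into (simulation, permutation) streams"
    )
    version: str = "0.1.0"
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat(timespec="seconds")
    )

    def write(self, path) -> None:
        payload = {
            "command": self.command,
            "config": self.config,
            "master_seed": self.master_seed,
            "seed_rule": self.seed_rule,
            "version": self.version,
            "timestamp": self.timestamp,
            "python": sys.version.split()[0],
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
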