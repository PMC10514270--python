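"""Skeleton file I/O: CSV edge-lists (canonical) and GraphML.

The CSV dialect is a single self-contained file with a ``[nodes]`` and an
``[edges]`` section::

    # lymphtile skeleton v1
    # units: um; origin: stalk flat-edge midpoint; y >= 0
    [nodes]
    id,x_um,y_um
    0,0.0,0.0
    [edges]
    node_a,node_b,alive,tree_id
    0,1,1,0

Output ordering is deterministic (sorted ids), so identical networks produce
byte-identical files.  Provenance (version, seed, config hash) goes into
comment headers.
"""

from __future__ import annotations

import hashlib
import io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .network import VesselNetwork

__all__ = ["read_skeleton", "write_skeleton", "read_annotations", "config_hash"]

_VERSION = "lymphtile skeleton v1"


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _infer_dialect(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("csv-edgelist", "graphml"):
            raise ValueError(f"unknown dialect {dialect!r}")
        return dialect
    return "graphml" if path.suffix.lower() == ".graphml" else "csv-edgelist"


def write_skeleton(network: VesselNetwork, path, dialect: str | None = None,
                   seed=None, config: dict | None = None) -> None:
    """Write a network skeleton; deterministic ordering for byte-identity."""
    path = Path(path)
    dialect = _infer_dialect(path, dialect)
    if dialect == "graphml":
        import networkx as nx

        g = nx.Graph()
        for nid in range(network.n_nodes):
            x, y = network.coords[nid]
            g.add_node(int(nid), x=float(x), y=float(y))
        order = np.lexsort((network.segments[:, 1], network.segments[:, 0]))
        for sid in order:
            a, b = (int(v) for v in network.segments[sid])
            g.add_edge(a, b, alive=bool(network.seg_alive[sid]),
                       tree_id=int(network.seg_tree[sid]))
        nx.write_graphml(g, path)
        return
    lines = [f"# {_VERSION}",
             "# units: um; origin: stalk flat-edge midpoint; y >= 0"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        lines.append(f"# config_hash: {config_hash(config)}")
    lines.append("[nodes]")
    lines.append("id,x_um,y_um")
    for nid in range(network.n_nodes):
        x, y = network.coords[nid]
        lines.append(f"{nid},{float(x)!r},{float(y)!r}")
    lines.append("[edges]")
    lines.append("node_a,node_b,alive,tree_id")
    order = np.lexsort((network.segments[:, 1], network.segments[:, 0]))
    for sid in order:
        a, b = (int(v) for v in network.segments[sid])
        lines.append(f"{a},{b},{int(network.seg_alive[sid])},{int(network.seg_tree[sid])}")
    path.write_text("\n".join(lines) + "\n")


def read_skeleton(path, dialect: str | None = None) -> VesselNetwork:
    """Read a skeleton file into a :class:`VesselNetwork`.

    Malformed rows raise with their line number; non-finite coordinates and
    duplicate edges are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = _infer_dialect(path, dialect)
    if dialect == "graphml":
        import networkx as nx

        g = nx.read_graphml(path)
        nodes = sorted(g.nodes, key=lambda n: int(n))
        remap = {n: i for i, n in enumerate(nodes)}
        coords = np.array([[float(g.nodes[n]["x"]), float(g.nodes[n]["y"])]
                           for n in nodes])
        edges, alive, tree = [], [], []
        for a, b, data in g.edges(data=True):
            edges.append((remap[a], remap[b]))
            alive.append(bool(data.get("alive", True)))
            tree.append(int(data.get("tree_id", 0)))
        return VesselNetwork.from_arrays(coords, np.array(edges, dtype=np.int64).reshape(-1, 2),
                                         alive=alive, tree=tree)
    section = None
    node_rows, edge_rows = [], []
    node_lines, edge_lines = [], []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line == "[nodes]":
            section = "nodes"
            continue
        if line == "[edges]":
            section = "edges"
            continue
        if section is None:
            raise ValueError(f"{path}:{lineno}: content before a section header")
        (node_rows if section == "nodes" else edge_rows).append(line)
        (node_lines if section == "nodes" else edge_lines).append(lineno)
    if not node_rows:
        raise ValueError(f"{path}: missing [nodes] section")

    def parse(rows, linenos, what):
        try:
            return pd.read_csv(io.StringIO("\n".join(rows)))
        except Exception as exc:
            raise ValueError(f"{path}: malformed {what} section "
                             f"(lines {linenos[0]}-{linenos[-1]}): {exc}") from exc

    nodes = parse(node_rows, node_lines, "nodes")
    for col in ("id", "x_um", "y_um"):
        if col not in nodes.columns:
            raise ValueError(f"{path}: nodes section lacks column {col!r}")
    try:
        coords_raw = nodes[["x_um", "y_um"]].to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: malformed nodes section "
                         f"(lines {node_lines[0]}-{node_lines[-1]}): {exc}") from exc
    if not np.all(np.isfinite(coords_raw)):
        bad = int(np.flatnonzero(~np.isfinite(coords_raw).all(axis=1))[0])
        raise ValueError(f"{path}: non-finite coordinate at node row {bad} "
                         f"(line {node_lines[bad + 1]})")
    ids = nodes["id"].to_numpy(dtype=np.int64)
    remap = {int(i): k for k, i in enumerate(ids)}
    if len(remap) != len(ids):
        raise ValueError(f"{path}: duplicate node ids")
    if not edge_rows or len(edge_rows) <= 1:
        return VesselNetwork.from_arrays(coords_raw, np.empty((0, 2), np.int64))
    edges = parse(edge_rows, edge_lines, "edges")
    for col in ("node_a", "node_b"):
        if col not in edges.columns:
            raise ValueError(f"{path}: edges section lacks column {col!r}")
    try:
        pairs = np.array([[remap[int(a)], remap[int(b)]]
                          for a, b in zip(edges["node_a"], edges["node_b"])],
                         dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"{path}: edge references unknown node {exc}") from exc
    alive = edges["alive"].astype(bool).tolist() if "alive" in edges else None
    tree = edges["tree_id"].astype(int).tolist() if "tree_id" in edges else None
    return VesselNetwork.from_arrays(coords_raw, pairs, alive=alive, tree=tree)


def read_annotations(path) -> list[tuple[int, int]]:
    """Read a sprout annotation CSV: columns sprout_id, root_node_id, tip_node_id."""
    df = pd.read_csv(path)
    for col in ("root_node_id", "tip_node_id"):
        if col not in df.columns:
            raise ValueError(f"{path}: annotation file lacks column {col!r}")
    return list(zip(df["root_node_id"].astype(int), df["tip_node_id"].astype(int)))
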