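"""File I/O for LCN networks and flow solutions.

The canonical on-disk format is LCN-JSON: a single JSON document with
``nodes``, ``edges`` and ``metadata`` keys (units µm throughout) plus a
``format_version``.  GraphML and a nodes/edges CSV pair are provided for
interoperability with graph and spreadsheet tools.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import TYPE_CHECKING, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .network import OsteonMetadata, OsteonNetwork

if TYPE_CHECKING:  # pragma: no cover
    from .hydraulics import FlowSolution

FORMAT_VERSION = "1.0"

__all__ = [
    "write_network_json",
    "read_network_json",
    "network_to_json_str",
    "write_network_csv",
    "read_network_csv",
    "to_networkx",
    "write_graphml",
    "write_solution_json",
    "read_solution_json",
]


def network_to_json_str(net: OsteonNetwork) -> str:
    """Serialize to the canonical LCN-JSON string (deterministic byte-wise)."""
    doc = {
        "format_version": FORMAT_VERSION,
        "metadata": net.metadata.to_dict(),
        "nodes": net.node_records(),
        "edges": net.edge_records(),
    }
    return json.dumps(doc, indent=1, sort_keys=True)


def write_network_json(net: OsteonNetwork, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(network_to_json_str(net))
    return path


def read_network_json(path: str | Path) -> OsteonNetwork:
    doc = json.loads(Path(path).read_text())
    return OsteonNetwork.from_records(
        doc["nodes"], doc["edges"], metadata=doc["metadata"]
    )


def write_network_csv(
    net: OsteonNetwork,
    nodes_path: str | Path,
    edges_path: str | Path,
    metadata_path: str | Path | None = None,
) -> None:
    """Write the nodes/edges CSV pair (and optionally a metadata JSON sidecar)."""
    nodes = pd.DataFrame(
        {
            "id": net.node_ids,
            "x": net.positions[:, 0],
            "y": net.positions[:, 1],
            "z": net.positions[:, 2],
            "kind": net.kinds,
            "boundary": net.boundary,
        }
    )
    edges = pd.DataFrame(
        {
            "id": net.edge_ids,
            "tail": net.edge_nodes[:, 0],
            "head": net.edge_nodes[:, 1],
            "length": net.lengths,
        }
    )
    nodes.to_csv(nodes_path, index=False, float_format="%.12g")
    edges.to_csv(edges_path, index=False, float_format="%.12g")
    if metadata_path is not None:
        Path(metadata_path).write_text(
            json.dumps(net.metadata.to_dict(), indent=1, sort_keys=True)
        )


def read_network_csv(
    nodes_path: str | Path,
    edges_path: str | Path,
    metadata: OsteonMetadata | Mapping | str | Path | None = None,
) -> OsteonNetwork:
    """Read a nodes/edges CSV pair; ``metadata`` may be a sidecar path or mapping."""
    nodes = pd.read_csv(nodes_path)
    edges = pd.read_csv(edges_path)
    if isinstance(metadata, (str, Path)):
        metadata = json.loads(Path(metadata).read_text())
    if metadata is None:
        metadata = OsteonMetadata()
    elif not isinstance(metadata, OsteonMetadata):
        metadata = OsteonMetadata.from_dict(metadata)
    return OsteonNetwork(
        node_ids=nodes["id"].to_numpy(),
        positions=nodes[["x", "y", "z"]].to_numpy(dtype=np.float64),
        kinds=nodes["kind"].to_numpy(dtype=object),
        boundary=nodes["boundary"].to_numpy(dtype=object),
        edge_ids=edges["id"].to_numpy(),
        edge_nodes=edges[["tail", "head"]].to_numpy(dtype=np.int64),
        lengths=edges["length"].to_numpy(dtype=np.float64),
        metadata=metadata,
    )


def to_networkx(net: OsteonNetwork) -> nx.MultiGraph:
    """Convert to a networkx MultiGraph with node/edge attributes."""
    g = nx.MultiGraph(**net.metadata.to_dict())
    for rec in net.node_records():
        x, y, z = rec["position"]
        g.add_node(rec["id"], x=x, y=y, z=z, kind=rec["kind"], boundary=rec["boundary"])
    for rec in net.edge_records():
        t, h = rec["nodes"]
        g.add_edge(t, h, key=rec["id"], edge_id=rec["id"], length=rec["length"])
    return g


def write_graphml(net: OsteonNetwork, path: str | Path) -> Path:
    g = to_networkx(net)
    # GraphML attributes must be scalars
    g.graph["center"] = f"{net.metadata.center[0]},{net.metadata.center[1]}"
    nx.write_graphml(g, str(path))
    return Path(path)


def write_solution_json(
    solution: "FlowSolution", net: OsteonNetwork, path: str | Path
) -> Path:
    """Serialize a flow solution as an LCN-JSON sidecar (per-node pressures,
    per-edge flows/velocities, boundary flux and the applied loading)."""

    def _arr(a: np.ndarray) -> list:
        return [None if not np.isfinite(x) else float(x) for x in a]

    doc = {
        "format_version": FORMAT_VERSION,
        "approach": solution.approach,
        "applied": {k: float(v) for k, v in solution.applied.items()},
        "boundary_flux": float(solution.boundary_flux),
        "leak_flux": float(solution.leak_flux),
        "node_ids": [int(i) for i in net.node_ids],
        "node_pressure": _arr(solution.node_pressure),
        "edge_ids": [int(i) for i in net.edge_ids],
        "edge_flow": _arr(solution.edge_flow),
        "edge_velocity": _arr(solution.edge_velocity),
        "excluded_nodes": [int(i) for i in solution.excluded_nodes],
    }
    path = Path(path)
    path.write_text(json.dumps(doc, indent=1, sort_keys=True))
    return path


def read_solution_json(path: str | Path) -> "FlowSolution":
    """Read a flow-solution sidecar back into a :class:`FlowSolution`."""
    from .hydraulics import FlowSolution

    doc = json.loads(Path(path).read_text())

    def _arr(values: list) -> np.ndarray:
        return np.array(
            [np.nan if v is None else float(v) for v in values], dtype=np.float64
        )

    return FlowSolution(
        approach=doc["approach"],
        node_pressure=_arr(doc["node_pressure"]),
        edge_flow=_arr(doc["edge_flow"]),
        edge_velocity=_arr(doc["edge_velocity"]),
        boundary_flux=float(doc["boundary_flux"]),
        excluded_nodes=np.array(doc["excluded_nodes"], dtype=np.int64),
        applied=doc["applied"],
        leak_flux=float(doc.get("leak_flux", 0.0)),
    )
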