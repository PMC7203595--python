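"""Spatial-graph representation of the lacunocanalicular network (LCN) of an osteon.

An osteon is modeled as a weighted spatial multigraph: nodes are osteocyte
lacunae, canalicular branch points or endpoints, each with a 3D position in
micrometres; edges are canaliculi with an arc length that may exceed the
straight chord between the endpoints (tortuosity >= 1).  Nodes touching the
Haversian canal carry the ``haversian`` boundary tag (the low-pressure
reservoir the flow drains into); nodes on the cement line carry ``cement``
(the hydraulically sealed outer boundary).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph

NODE_KINDS = ("lacuna", "branch", "endpoint")
BOUNDARY_TAGS = ("none", "haversian", "cement")

__all__ = [
    "OsteonMetadata",
    "OsteonNetwork",
    "StructuralSummary",
    "NetworkValidationError",
    "validate_network",
    "incidence_matrix",
    "structural_summary",
    "shortest_paths_to_canal",
    "sector_partition",
    "normalized_distance",
]


class NetworkValidationError(ValueError):
    """Raised when an osteon network violates a structural invariant.

    ``problems`` lists every violated invariant, not just the first.
    """

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("invalid osteon network:\n- " + "\n- ".join(self.problems))


@dataclass(frozen=True)
class OsteonMetadata:
    """Geometry of the imaged osteon volume.

    center
        xy position of the osteon (Haversian canal) axis, µm.
    haversian_radius, osteon_radius
        Inner (canal surface) and outer (cement line) radii, µm.
    slab_thickness
        Extent of the evaluated slab along the osteon axis (z), µm.
    evaluated_volume
        Bulk volume BV used to normalize densities, µm³.  Defaults to the
        annular slab volume when not given.
    """

    center: tuple[float, float] = (0.0, 0.0)
    haversian_radius: float = 36.0
    osteon_radius: float = 104.0
    slab_thickness: float = 40.0
    osteon_type: str = "ordinary"
    evaluated_volume: float | None = None

    def __post_init__(self) -> None:
        if self.evaluated_volume is None:
            bv = (
                np.pi
                * (self.osteon_radius**2 - self.haversian_radius**2)
                * self.slab_thickness
            )
            object.__setattr__(self, "evaluated_volume", float(bv))

    @property
    def wall_thickness(self) -> float:
        """Radial span from canal surface to cement line, µm."""
        return self.osteon_radius - self.haversian_radius

    def to_dict(self) -> dict:
        return {
            "center": [float(self.center[0]), float(self.center[1])],
            "haversian_radius": float(self.haversian_radius),
            "osteon_radius": float(self.osteon_radius),
            "slab_thickness": float(self.slab_thickness),
            "osteon_type": self.osteon_type,
            "evaluated_volume": float(self.evaluated_volume),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "OsteonMetadata":
        return cls(
            center=tuple(d["center"]),
            haversian_radius=d["haversian_radius"],
            osteon_radius=d["osteon_radius"],
            slab_thickness=d["slab_thickness"],
            osteon_type=d.get("osteon_type", "ordinary"),
            evaluated_volume=d.get("evaluated_volume"),
        )


@dataclass
class OsteonNetwork:
    """LCN as a spatial multigraph with boundary tags.

    Arrays are parallel: ``node_ids[i]`` has position ``positions[i]`` etc.
    ``edge_nodes[j] = (tail_id, head_id)`` stores the orientation reference
    for signed flows; the physics is orientation-covariant.
    """

    node_ids: np.ndarray  # (N,) int64
    positions: np.ndarray  # (N, 3) float64, µm
    kinds: np.ndarray  # (N,) str
    boundary: np.ndarray  # (N,) str
    edge_ids: np.ndarray  # (E,) int64
    edge_nodes: np.ndarray  # (E, 2) int64 node ids (tail, head)
    lengths: np.ndarray  # (E,) float64, µm
    metadata: OsteonMetadata = field(default_factory=OsteonMetadata)
    polylines: dict[int, np.ndarray] | None = None  # edge id -> (k, 3) µm

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=np.float64).reshape(-1, 3)
        self.kinds = np.asarray(self.kinds, dtype=object)
        self.boundary = np.asarray(self.boundary, dtype=object)
        self.edge_ids = np.asarray(self.edge_ids, dtype=np.int64)
        self.edge_nodes = np.asarray(self.edge_nodes, dtype=np.int64).reshape(-1, 2)
        self.lengths = np.asarray(self.lengths, dtype=np.float64)
        self._id_to_index: dict[int, int] | None = None

    # -- bookkeeping ------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edge_ids)

    @property
    def id_to_index(self) -> dict[int, int]:
        if self._id_to_index is None or len(self._id_to_index) != self.n_nodes:
            self._id_to_index = {int(i): k for k, i in enumerate(self.node_ids)}
        return self._id_to_index

    @property
    def edge_indices(self) -> np.ndarray:
        """(E, 2) array of node *indices* (tail, head) for each edge."""
        lut = self.id_to_index
        return np.array(
            [[lut[int(t)], lut[int(h)]] for t, h in self.edge_nodes], dtype=np.int64
        ).reshape(-1, 2)

    def haversian_mask(self) -> np.ndarray:
        return self.boundary == "haversian"

    def cement_mask(self) -> np.ndarray:
        return self.boundary == "cement"

    def total_length(self) -> float:
        return float(self.lengths.sum())

    def copy(self) -> "OsteonNetwork":
        return OsteonNetwork(
            node_ids=self.node_ids.copy(),
            positions=self.positions.copy(),
            kinds=self.kinds.copy(),
            boundary=self.boundary.copy(),
            edge_ids=self.edge_ids.copy(),
            edge_nodes=self.edge_nodes.copy(),
            lengths=self.lengths.copy(),
            metadata=replace(self.metadata),
            polylines=None
            if self.polylines is None
            else {k: v.copy() for k, v in self.polylines.items()},
        )

    def with_metadata(self, **changes) -> "OsteonNetwork":
        net = self.copy()
        net.metadata = replace(net.metadata, **changes)
        return net

    # -- construction -----------------------------------------------------
    @classmethod
    def from_records(
        cls,
        nodes: Iterable[Mapping],
        edges: Iterable[Mapping],
        metadata: OsteonMetadata | Mapping | None = None,
    ) -> "OsteonNetwork":
        """Build a network from per-node / per-edge mappings.

        Node records need ``id``, ``position`` and optionally ``kind`` and
        ``boundary``; edge records need ``id``, ``nodes`` (tail, head) and
        ``length`` with an optional ``polyline``.
        """
        nodes = list(nodes)
        edges = list(edges)
        if metadata is None:
            metadata = OsteonMetadata()
        elif not isinstance(metadata, OsteonMetadata):
            metadata = OsteonMetadata.from_dict(metadata)
        polylines = {
            int(e["id"]): np.asarray(e["polyline"], dtype=np.float64)
            for e in edges
            if e.get("polyline") is not None
        }
        return cls(
            node_ids=[n["id"] for n in nodes],
            positions=np.array([n["position"] for n in nodes], dtype=np.float64).reshape(
                -1, 3
            ),
            kinds=[n.get("kind", "branch") for n in nodes],
            boundary=[n.get("boundary", "none") for n in nodes],
            edge_ids=[e["id"] for e in edges],
            edge_nodes=np.array([e["nodes"] for e in edges], dtype=np.int64).reshape(
                -1, 2
            ),
            lengths=[e["length"] for e in edges],
            metadata=metadata,
            polylines=polylines or None,
        )

    def node_records(self) -> list[dict]:
        return [
            {
                "id": int(i),
                "position": [float(x) for x in p],
                "kind": str(k),
                "boundary": str(b),
            }
            for i, p, k, b in zip(self.node_ids, self.positions, self.kinds, self.boundary)
        ]

    def edge_records(self) -> list[dict]:
        recs = []
        for i, (t, h), l in zip(self.edge_ids, self.edge_nodes, self.lengths):
            rec = {"id": int(i), "nodes": [int(t), int(h)], "length": float(l)}
            if self.polylines and int(i) in self.polylines:
                rec["polyline"] = [[float(x) for x in p] for p in self.polylines[int(i)]]
            recs.append(rec)
        return recs


@dataclass(frozen=True)
class StructuralSummary:
    """The six network parameters characterizing an osteonal LCN.

    Densities are normalized by the evaluated bulk volume BV; the weighted
    node degree of a node is the summed length of its incident canaliculi;
    the shortest-path statistic is the Dijkstra distance from each node to
    the (merged) Haversian canal, averaged over reachable nodes.
    """

    node_density: float  # µm⁻³
    canalicular_number_density: float  # µm⁻³
    canalicular_length_density: float  # µm µm⁻³ (Can.Dn)
    mean_node_degree: float
    mean_weighted_node_degree: float  # µm
    mean_shortest_path_to_canal: float  # µm
    n_unreachable: int = 0

    def to_dict(self) -> dict:
        return {
            "node_density": self.node_density,
            "canalicular_number_density": self.canalicular_number_density,
            "canalicular_length_density": self.canalicular_length_density,
            "mean_node_degree": self.mean_node_degree,
            "mean_weighted_node_degree": self.mean_weighted_node_degree,
            "mean_shortest_path_to_canal": self.mean_shortest_path_to_canal,
            "n_unreachable": self.n_unreachable,
        }


# ---------------------------------------------------------------------------
# validation


def _polyline_length(poly: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(poly, axis=0), axis=1).sum())


def validate_network(
    net: OsteonNetwork,
    *,
    require_haversian: bool = True,
    geometry_tol: float = 1e-6,
) -> OsteonNetwork:
    """Check every structural invariant; return the network unchanged if valid.

    Raises :class:`NetworkValidationError` listing all violations: duplicate
    ids, dangling or self-loop edges, non-positive lengths, arc length below
    the endpoint chord, positions outside the osteon cylinder/slab, polyline
    arc-length mismatch, and (optionally) a missing Haversian boundary tag.
    ``geometry_tol`` is the relative slack for the cylinder/chord checks.
    """
    problems: list[str] = []
    ids = net.node_ids
    if len(np.unique(ids)) != len(ids):
        problems.append("duplicate node ids")
    if len(np.unique(net.edge_ids)) != len(net.edge_ids):
        problems.append("duplicate edge ids")

    known = set(int(i) for i in ids)
    for eid, (t, h) in zip(net.edge_ids, net.edge_nodes):
        if int(t) not in known or int(h) not in known:
            problems.append(f"edge {int(eid)} references a missing node")
        if int(t) == int(h):
            problems.append(f"edge {int(eid)} is a self-loop")

    if np.any(net.lengths <= 0):
        bad = net.edge_ids[net.lengths <= 0]
        problems.append(f"non-positive edge length for edges {bad.tolist()}")

    if not problems:  # chord check needs resolvable endpoints
        idx = net.edge_indices
        chords = np.linalg.norm(
            net.positions[idx[:, 1]] - net.positions[idx[:, 0]], axis=1
        )
        short = net.lengths < chords * (1.0 - geometry_tol)
        if np.any(short):
            bad = net.edge_ids[short]
            problems.append(
                f"edge length below endpoint distance (tortuosity < 1) for edges "
                f"{bad.tolist()[:10]}"
            )

    if net.polylines:
        for eid, poly in net.polylines.items():
            j = np.flatnonzero(net.edge_ids == eid)
            if len(j) == 0:
                problems.append(f"polyline for unknown edge {eid}")
                continue
            arc = _polyline_length(poly)
            if not np.isclose(arc, net.lengths[j[0]], rtol=1e-9, atol=0.0):
                problems.append(
                    f"edge {eid}: stored length {net.lengths[j[0]]:.9g} != polyline "
                    f"arc length {arc:.9g}"
                )

    if require_haversian and not np.any(net.haversian_mask()):
        problems.append("no reference boundary: no node tagged 'haversian'")

    md = net.metadata
    if net.n_nodes:
        xy = net.positions[:, :2] - np.asarray(md.center)
        r = np.linalg.norm(xy, axis=1)
        r_max = md.osteon_radius * (1.0 + geometry_tol) + 1e-9
        if np.any(r > r_max):
            problems.append(
                f"{int(np.sum(r > r_max))} node(s) outside the osteon radius "
                f"{md.osteon_radius} µm"
            )
        z = net.positions[:, 2]
        z_tol = md.slab_thickness * geometry_tol + 1e-9
        if np.any((z < -z_tol) | (z > md.slab_thickness + z_tol)):
            problems.append("node position outside the imaged slab thickness")

    if problems:
        raise NetworkValidationError(problems)
    return net


# ---------------------------------------------------------------------------
# structural metrics


def incidence_matrix(net: OsteonNetwork) -> sparse.csr_matrix:
    """Oriented edge–node incidence matrix (E × N, sparse).

    Row j has −1 at the edge's tail node and +1 at its head node, taking the
    orientation from the stored endpoint order.  The sign choice is an
    arbitrary but fixed reference for signed flows.
    """
    idx = net.edge_indices
    e = np.arange(net.n_edges)
    rows = np.concatenate([e, e])
    cols = np.concatenate([idx[:, 0], idx[:, 1]])
    vals = np.concatenate(
        [-np.ones(net.n_edges), np.ones(net.n_edges)]
    )
    return sparse.csr_matrix(
        (vals, (rows, cols)), shape=(net.n_edges, net.n_nodes)
    )


def _min_length_adjacency(net: OsteonNetwork) -> sparse.csr_matrix:
    """Symmetric node adjacency weighted by edge length.

    Parallel edges are collapsed to the minimum length (the relevant weight
    for shortest paths on a multigraph).
    """
    idx = net.edge_indices
    if len(idx) == 0:
        return sparse.csr_matrix((net.n_nodes, net.n_nodes))
    lo = np.minimum(idx[:, 0], idx[:, 1])
    hi = np.maximum(idx[:, 0], idx[:, 1])
    order = np.lexsort((net.lengths, hi, lo))
    lo, hi, w = lo[order], hi[order], net.lengths[order]
    first = np.ones(len(lo), dtype=bool)
    first[1:] = (lo[1:] != lo[:-1]) | (hi[1:] != hi[:-1])
    lo, hi, w = lo[first], hi[first], w[first]
    a = sparse.csr_matrix(
        (
            np.concatenate([w, w]),
            (np.concatenate([lo, hi]), np.concatenate([hi, lo])),
        ),
        shape=(net.n_nodes, net.n_nodes),
    )
    return a


def shortest_paths_to_canal(net: OsteonNetwork) -> np.ndarray:
    """Dijkstra distance (µm) from every node to the Haversian canal.

    The distance is the minimum summed edge length over paths to any
    haversian-tagged node (equivalently, to the merged canal supernode at
    distance 0).  Nodes with no path to the canal get ``inf``.
    """
    hav = np.flatnonzero(net.haversian_mask())
    if len(hav) == 0:
        raise NetworkValidationError(["no reference boundary: no haversian node"])
    adj = _min_length_adjacency(net)
    dist = csgraph.dijkstra(adj, directed=False, indices=hav, min_only=True)
    return np.asarray(dist)


def structural_summary(net: OsteonNetwork) -> StructuralSummary:
    """Compute the six structural parameters of an osteonal LCN."""
    bv = net.metadata.evaluated_volume
    if bv is None or bv <= 0:
        raise ValueError("metadata.evaluated_volume (BV) must be positive")
    n, e = net.n_nodes, net.n_edges
    idx = net.edge_indices
    weighted = np.zeros(n)
    np.add.at(weighted, idx[:, 0], net.lengths)
    np.add.at(weighted, idx[:, 1], net.lengths)
    dist = shortest_paths_to_canal(net)
    finite = np.isfinite(dist)
    return StructuralSummary(
        node_density=n / bv,
        canalicular_number_density=e / bv,
        canalicular_length_density=net.total_length() / bv,
        mean_node_degree=2.0 * e / n if n else 0.0,
        mean_weighted_node_degree=float(weighted.mean()) if n else 0.0,
        mean_shortest_path_to_canal=float(dist[finite].mean()) if finite.any() else np.inf,
        n_unreachable=int(np.sum(~finite)),
    )


def sector_partition(net: OsteonNetwork, n_sectors: int = 36) -> np.ndarray:
    """Assign every node to an angular sector around the osteon center.

    Sectors are half-open intervals ``[k·2π/n, (k+1)·2π/n)`` of the polar
    angle in the xy-plane, so an angle exactly on a boundary belongs to the
    higher sector's lower edge; sector indices run 0..n_sectors−1.
    """
    if n_sectors < 1:
        raise ValueError("n_sectors must be >= 1")
    xy = net.positions[:, :2] - np.asarray(net.metadata.center)
    theta = np.mod(np.arctan2(xy[:, 1], xy[:, 0]), 2.0 * np.pi)
    sector = np.floor(n_sectors * theta / (2.0 * np.pi)).astype(np.int64)
    return np.minimum(sector, n_sectors - 1)


def normalized_distance(net: OsteonNetwork, points: np.ndarray | None = None) -> np.ndarray:
    """Radial coordinate rescaled to 0 at the canal surface, 1 at the cement line.

    For the concentric-cylinder geometry used throughout, this is
    ``(r − HCa.Rd) / (On.Rd − HCa.Rd)`` clipped to [0, 1].
    """
    md = net.metadata
    if points is None:
        points = net.positions
    xy = np.asarray(points)[:, :2] - np.asarray(md.center)
    r = np.linalg.norm(xy, axis=1)
    return np.clip((r - md.haversian_radius) / md.wall_thickness, 0.0, 1.0)
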