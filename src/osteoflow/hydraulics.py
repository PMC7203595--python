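"""Hydraulic-circuit solver for fluid flow through the LCN.

The canalicular network is treated as a resistor network: each canaliculus
is an annular Darcy channel with conductivity C = (k_p,eff/µ)·A/l, and node
pressures follow from Kirchhoff's current law, L p = f with L = AᵀCA the
weighted graph Laplacian.  All haversian-tagged nodes are merged into one
grounded supernode representing the Haversian canal as a constant
low-pressure reservoir; the reduced system (supernode row/column removed)
is symmetric positive definite on each component connected to the canal.

Two loading modes are provided:

* ``solve_fixed_pressure`` — a trans-osteonal pressure difference is applied
  between the cement line (Dirichlet, Δp_osteon) and the canal (0); used to
  infer the intrinsic permeability of the osteon.
* ``solve_strain_sources`` — homogeneous volumetric compression at strain
  rate ε̇ squeezes fluid out of every pore: each node injects
  ε̇·(deg_i/2·A + V_lacuna if lacuna), where deg_i is the weighted node
  degree, and the canal absorbs the total ε̇·V_OLCN.

Internal units: µm, Pa, s (velocities in µm/s); permeabilities are reported
in m².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph
from scipy.sparse.linalg import splu

from .network import OsteonNetwork

#: conversion factor from µm² to m²
M2_PER_UM2 = 1e-12

__all__ = [
    "HydraulicParams",
    "FlowSolution",
    "AssembledSystem",
    "edge_conductivity",
    "assemble_system",
    "solve_fixed_pressure",
    "node_source_volumes",
    "solve_strain_sources",
    "leaky_cement_variant",
    "conservation_residuals",
]


@dataclass(frozen=True)
class HydraulicParams:
    """Physical constants of the canalicular flow model.

    mu : Pa·s
        Viscosity of the interstitial bone fluid.
    canaliculus_radius, process_radius : µm
        Radii of the canaliculus (Ca.Rd = 157.5 nm) and of the osteocyte
        cell process running inside it (CP.Rd = 73 nm); fluid moves only in
        the annulus between them.
    annulus_area : µm²
        Annular cross section A = π(Ca.Rd² − CP.Rd²); derived from the radii
        when not supplied, and checked against them (2% slack) when it is.
    k_p_eff : m²
        Effective permeability of the fiber-filled pericellular annulus
        (Brinkman-model literature value).
    shear_constant : µm⁻¹
        K in τ = µ·K·v, relating mean canalicular velocity to wall shear
        stress at the cell-process membrane.
    strain_rate : s⁻¹
        Default volumetric strain rate (0.015 ≈ peak during vigorous
        exercise; 0.0015 ≈ walking).
    lacuna_volume : µm³
        Fluid volume attributed to each osteocyte lacuna.
    """

    mu: float = 1.06e-3
    canaliculus_radius: float = 0.1575
    process_radius: float = 0.073
    annulus_area: float | None = None
    k_p_eff: float = 1.53e-17
    shear_constant: float = 465.0
    strain_rate: float = 0.015
    lacuna_volume: float = 350.0

    def __post_init__(self) -> None:
        if not (0 < self.process_radius < self.canaliculus_radius):
            raise ValueError("need 0 < process_radius < canaliculus_radius")
        for name in ("mu", "k_p_eff", "shear_constant", "strain_rate", "lacuna_volume"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        derived = float(
            np.pi * (self.canaliculus_radius**2 - self.process_radius**2)
        )
        if self.annulus_area is None:
            object.__setattr__(self, "annulus_area", derived)
        elif abs(self.annulus_area - derived) > 0.02 * derived:
            raise ValueError(
                f"annulus_area override {self.annulus_area} µm² differs by more than "
                f"2% from the value derived from the radii ({derived:.4g} µm²)"
            )

    @property
    def k_p_eff_um2(self) -> float:
        """Canalicular permeability in internal units (µm²)."""
        return self.k_p_eff / M2_PER_UM2


def edge_conductivity(length: float | np.ndarray, params: HydraulicParams) -> np.ndarray:
    """Hydraulic conductivity of a canaliculus of given arc length.

    C = (k_p,eff/µ)·A/l in µm³/(Pa·s).  Stored positive; the sign of the
    flow is carried by the orientation convention q = C·(p_tail − p_head),
    so fluid always runs from high to low pressure.
    """
    length = np.asarray(length, dtype=np.float64)
    if np.any(length <= 0):
        raise ValueError("canaliculus length must be positive")
    return (params.k_p_eff_um2 / params.mu) * params.annulus_area / length


@dataclass
class AssembledSystem:
    """Weighted Laplacian of the merged network plus reference bookkeeping.

    Merged index 0 is the Haversian supernode i₀ (all haversian-tagged nodes
    collapsed); merged index k ≥ 1 corresponds to non-haversian node
    ``nonhav_nodes[k−1]`` (an index into the network's node arrays).
    ``connected`` marks merged nodes with a path to the supernode; nodes
    outside that component are excluded from the solve.
    """

    net: OsteonNetwork
    params: HydraulicParams
    conductivities: np.ndarray  # (E,)
    merged_of_node: np.ndarray  # (N,) merged index per node
    nonhav_nodes: np.ndarray  # (M,) node indices for merged 1..M
    laplacian: sparse.csr_matrix  # (M+1, M+1)
    connected: np.ndarray  # (M+1,) bool
    canal_edges: np.ndarray  # (E,) bool, both endpoints haversian

    @property
    def excluded_node_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.connected[self.merged_of_node])

    def reduced(self) -> tuple[sparse.csc_matrix, np.ndarray]:
        """Reduced Laplacian L₀ over connected non-reference merged nodes.

        Returns (L₀ in CSC form, merged indices of its rows).
        """
        unknown = np.flatnonzero(self.connected)
        unknown = unknown[unknown != 0]
        l0 = self.laplacian[np.ix_(unknown, unknown)].tocsc()
        return l0, unknown


def assemble_system(net: OsteonNetwork, params: HydraulicParams) -> AssembledSystem:
    """Build conductivities and the weighted Laplacian L = AᵀCA.

    All haversian-tagged nodes are linked into the supernode i₀ before
    assembly; edges running between two haversian nodes become internal to
    the canal and drop out of the system (they carry no pressure difference).
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    hav = net.haversian_mask()
    if not np.any(hav):
        raise ValueError("no reference boundary: no node tagged 'haversian'")

    merged_of_node = np.zeros(net.n_nodes, dtype=np.int64)
    nonhav_nodes = np.flatnonzero(~hav)
    merged_of_node[nonhav_nodes] = np.arange(1, len(nonhav_nodes) + 1)
    m = len(nonhav_nodes) + 1

    cond = edge_conductivity(net.lengths, params)
    idx = net.edge_indices
    tails = merged_of_node[idx[:, 0]]
    heads = merged_of_node[idx[:, 1]]
    canal_edges = (tails == 0) & (heads == 0)
    keep = ~canal_edges

    t, h, c = tails[keep], heads[keep], cond[keep]
    rows = np.concatenate([t, h, t, h])
    cols = np.concatenate([h, t, t, h])
    vals = np.concatenate([-c, -c, c, c])
    lap = sparse.csr_matrix((vals, (rows, cols)), shape=(m, m))

    n_comp, labels = csgraph.connected_components(lap, directed=False)
    connected = labels == labels[0]

    return AssembledSystem(
        net=net,
        params=params,
        conductivities=cond,
        merged_of_node=merged_of_node,
        nonhav_nodes=nonhav_nodes,
        laplacian=lap,
        connected=connected,
        canal_edges=canal_edges,
    )


@dataclass
class FlowSolution:
    """Steady-state solution of one hydraulic solve.

    Pressures are relative to the Haversian canal (supernode fixed at 0 Pa);
    flows are signed along each edge's stored tail→head orientation;
    ``boundary_flux`` is the total volumetric flow into the canal (µm³/s).
    Nodes with no path to the canal are excluded from the solve and carry
    NaN pressure (undefined, not zero), as do their edges.
    """

    approach: str
    node_pressure: np.ndarray  # (N,) Pa, NaN for excluded
    edge_flow: np.ndarray  # (E,) µm³/s
    edge_velocity: np.ndarray  # (E,) µm/s
    boundary_flux: float  # µm³/s into the canal
    excluded_nodes: np.ndarray  # node ids
    applied: dict = field(default_factory=dict)
    leak_flux: float = 0.0
    leaked_nodes: np.ndarray | None = None

    @property
    def solved_edges(self) -> np.ndarray:
        return np.isfinite(self.edge_flow)


def _solve_spd(l0: sparse.csc_matrix, rhs: np.ndarray, use_rcm: bool) -> np.ndarray:
    """Direct sparse solve of the reduced SPD system, optionally after
    reverse Cuthill–McKee reordering (a bandwidth optimization that must not
    change the result)."""
    if l0.shape[0] == 0:
        return np.zeros(0)
    if use_rcm:
        perm = csgraph.reverse_cuthill_mckee(l0.tocsr(), symmetric_mode=True)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        lp = l0[np.ix_(perm, perm)].tocsc()
        return splu(lp).solve(rhs[perm])[inv]
    return splu(l0).solve(rhs)


def _finish_solution(
    system: AssembledSystem,
    merged_pressure: np.ndarray,
    approach: str,
    applied: dict,
) -> FlowSolution:
    net, params = system.net, system.params
    node_p = merged_pressure[system.merged_of_node]
    idx = net.edge_indices
    p_tail = node_p[idx[:, 0]]
    p_head = node_p[idx[:, 1]]
    flow = system.conductivities * (p_tail - p_head)
    flow[system.canal_edges] = 0.0  # internal to the canal reservoir
    velocity = flow / params.annulus_area

    # flux into the supernode: edges with exactly one haversian endpoint
    t0 = system.merged_of_node[idx[:, 0]] == 0
    h0 = system.merged_of_node[idx[:, 1]] == 0
    with np.errstate(invalid="ignore"):
        flux = np.nansum(flow[h0 & ~t0]) - np.nansum(flow[t0 & ~h0])

    return FlowSolution(
        approach=approach,
        node_pressure=node_p,
        edge_flow=flow,
        edge_velocity=velocity,
        boundary_flux=float(flux),
        excluded_nodes=net.node_ids[system.excluded_node_indices],
        applied=applied,
    )


def solve_fixed_pressure(
    net: OsteonNetwork,
    params: HydraulicParams | None = None,
    delta_p: float = 13_000.0,
    *,
    system: AssembledSystem | None = None,
    use_rcm: bool = False,
) -> FlowSolution:
    """Approach 1: trans-osteonal pressure difference (intrinsic permeability).

    Dirichlet conditions: all cement-line nodes fixed at ``delta_p`` (Pa),
    the Haversian supernode grounded at 0; interior pressures solve the
    reduced Kirchhoff system with no sources.  With no interior sources the
    discrete maximum principle holds: every pressure lies in [0, delta_p].
    """
    params = params or HydraulicParams()
    if system is None:
        system = assemble_system(net, params)

    merged_p = np.full(system.laplacian.shape[0], np.nan)
    merged_p[0] = 0.0
    cement_nodes = np.flatnonzero(net.cement_mask() & ~net.haversian_mask())
    cement_merged = system.merged_of_node[cement_nodes]
    cement_merged = cement_merged[system.connected[cement_merged]]
    merged_p[cement_merged] = delta_p

    fixed = np.zeros(system.laplacian.shape[0], dtype=bool)
    fixed[0] = True
    fixed[cement_merged] = True
    unknown = np.flatnonzero(system.connected & ~fixed)

    if len(cement_merged) == 0:
        warnings.warn(
            "no cement-line node is connected to the Haversian canal; "
            "returning the zero-flow solution",
            RuntimeWarning,
            stacklevel=2,
        )
        merged_p[unknown] = 0.0
    elif len(unknown):
        l_uu = system.laplacian[np.ix_(unknown, unknown)].tocsc()
        rhs = -system.laplacian[np.ix_(unknown, cement_merged)].sum(axis=1).A1 * delta_p
        merged_p[unknown] = _solve_spd(l_uu, rhs, use_rcm)

    return _finish_solution(
        system, merged_p, "fixed_pressure", {"delta_p": float(delta_p)}
    )


def node_source_volumes(
    net: OsteonNetwork,
    params: HydraulicParams | None = None,
    lacuna_volumes: dict[int, float] | None = None,
) -> np.ndarray:
    """Fluid-filled pore volume attributed to each node, µm³.

    A canaliculus is shared between its two end nodes, so each node owns
    half the volume of its incident canaliculi, (deg_i/2)·A with deg_i the
    weighted node degree; lacuna nodes add the lacunar volume (a fixed
    constant by default; ``lacuna_volumes`` maps node id → per-lacuna
    override).
    """
    params = params or HydraulicParams()
    idx = net.edge_indices
    weighted_degree = np.zeros(net.n_nodes)
    np.add.at(weighted_degree, idx[:, 0], net.lengths)
    np.add.at(weighted_degree, idx[:, 1], net.lengths)
    volumes = 0.5 * weighted_degree * params.annulus_area
    lacunae = net.kinds == "lacuna"
    volumes[lacunae] += params.lacuna_volume
    if lacuna_volumes:
        lut = net.id_to_index
        for nid, vol in lacuna_volumes.items():
            i = lut[int(nid)]
            if not lacunae[i]:
                raise ValueError(f"node {nid} is not a lacuna")
            volumes[i] += vol - params.lacuna_volume
    return volumes


def solve_strain_sources(
    net: OsteonNetwork,
    params: HydraulicParams | None = None,
    strain_rate: float | None = None,
    *,
    system: AssembledSystem | None = None,
    use_rcm: bool = False,
    lacuna_volumes: dict[int, float] | None = None,
) -> FlowSolution:
    """Approach 2: deformation-induced flow (squeezed-sponge loading).

    Every node injects fluid at rate ε̇ × (its pore volume); the grounded
    canal absorbs the total ε̇·V_OLCN, where V_OLCN sums the pore volumes of
    all non-reference nodes connected to the canal.  The solve is performed
    with unit sources and scaled by ε̇ afterwards, so the solution is exactly
    linear in the strain rate.
    """
    params = params or HydraulicParams()
    if strain_rate is None:
        strain_rate = params.strain_rate
    if system is None:
        system = assemble_system(net, params)

    volumes = node_source_volumes(net, params, lacuna_volumes)
    l0, unknown = system.reduced()
    merged_vol = np.zeros(system.laplacian.shape[0])
    merged_vol[system.merged_of_node[system.nonhav_nodes]] = volumes[
        system.nonhav_nodes
    ]
    v_olcn = float(merged_vol[unknown].sum())
    if v_olcn <= 0:
        raise ValueError("V_OLCN is zero: network has no pore volume to drain")

    merged_p = np.full(system.laplacian.shape[0], np.nan)
    merged_p[0] = 0.0
    merged_p[unknown] = strain_rate * _solve_spd(l0, merged_vol[unknown], use_rcm)

    applied = {"strain_rate": float(strain_rate), "V_OLCN": v_olcn}
    return _finish_solution(system, merged_p, "strain_sources", applied)


def leaky_cement_variant(
    net: OsteonNetwork,
    params: HydraulicParams | None = None,
    leak_fraction: float = 0.0,
    strain_rate: float | None = None,
    *,
    seed: int = 0,
    system: AssembledSystem | None = None,
) -> FlowSolution:
    """Strain-source solve with a partially leaking cement line.

    A seeded random subset (``leak_fraction`` of the cement-tagged nodes
    connected to the canal) is additionally connected to an external
    zero-pressure reservoir through a virtual canaliculus of standard
    conductivity (mean edge length).  ``leak_fraction=0`` reproduces
    :func:`solve_strain_sources` exactly; at any fraction the canal flux and
    the leak flux together balance ε̇·V_OLCN.
    """
    if not 0.0 <= leak_fraction <= 1.0:
        raise ValueError("leak_fraction must lie in [0, 1]")
    params = params or HydraulicParams()
    if strain_rate is None:
        strain_rate = params.strain_rate
    if system is None:
        system = assemble_system(net, params)
    if leak_fraction == 0.0:
        return solve_strain_sources(net, params, strain_rate, system=system)

    cement_nodes = np.flatnonzero(net.cement_mask() & ~net.haversian_mask())
    cement_nodes = cement_nodes[
        system.connected[system.merged_of_node[cement_nodes]]
    ]
    n_leak = int(round(leak_fraction * len(cement_nodes)))
    rng = np.random.default_rng(seed)
    leaked = rng.choice(cement_nodes, size=n_leak, replace=False) if n_leak else np.array([], dtype=int)

    c_leak = float(edge_conductivity(float(net.lengths.mean()), params))
    volumes = node_source_volumes(net, params)
    l0, unknown = system.reduced()
    merged_vol = np.zeros(system.laplacian.shape[0])
    merged_vol[system.merged_of_node[system.nonhav_nodes]] = volumes[
        system.nonhav_nodes
    ]
    v_olcn = float(merged_vol[unknown].sum())

    # ground the leaked nodes to the external reservoir through C_leak
    pos_in_unknown = np.full(system.laplacian.shape[0], -1, dtype=np.int64)
    pos_in_unknown[unknown] = np.arange(len(unknown))
    leak_rows = pos_in_unknown[system.merged_of_node[leaked]]
    diag = sparse.csc_matrix(
        (np.full(len(leak_rows), c_leak), (leak_rows, leak_rows)),
        shape=l0.shape,
    )
    merged_p = np.full(system.laplacian.shape[0], np.nan)
    merged_p[0] = 0.0
    merged_p[unknown] = strain_rate * _solve_spd(
        (l0 + diag).tocsc(), merged_vol[unknown], use_rcm=False
    )

    sol = _finish_solution(
        system,
        merged_p,
        "strain_sources_leaky",
        {
            "strain_rate": float(strain_rate),
            "V_OLCN": v_olcn,
            "leak_fraction": float(leak_fraction),
        },
    )
    node_p = sol.node_pressure
    sol.leak_flux = float(np.sum(c_leak * node_p[leaked])) if len(leaked) else 0.0
    sol.leaked_nodes = net.node_ids[leaked]
    return sol


def conservation_residuals(
    net: OsteonNetwork, solution: FlowSolution, params: HydraulicParams | None = None
) -> np.ndarray:
    """Kirchhoff residual (net outflow − source) at every solved interior node.

    For the fixed-pressure approach the interior nodes are those that are
    neither boundary-tagged nor excluded and the source term is zero; for
    strain-driven approaches the source is ε̇ × node pore volume (plus the
    leak drain where applicable).  Residuals at solved interior nodes should
    vanish to solver precision.  Returns NaN at boundary/excluded nodes.
    """
    params = params or HydraulicParams()
    idx = net.edge_indices
    net_outflow = np.zeros(net.n_nodes)
    flow = np.where(np.isfinite(solution.edge_flow), solution.edge_flow, 0.0)
    np.add.at(net_outflow, idx[:, 0], flow)  # flow leaves the tail
    np.add.at(net_outflow, idx[:, 1], -flow)  # and enters the head

    residual = np.full(net.n_nodes, np.nan)
    excluded = np.isin(net.node_ids, solution.excluded_nodes)
    interior = ~net.haversian_mask() & ~excluded
    if solution.approach == "fixed_pressure":
        interior &= ~net.cement_mask()
        residual[interior] = net_outflow[interior]
    else:
        strain_rate = solution.applied["strain_rate"]
        volumes = node_source_volumes(net, params)
        res = net_outflow - strain_rate * volumes
        if solution.leaked_nodes is not None and len(solution.leaked_nodes):
            c_leak = float(edge_conductivity(float(net.lengths.mean()), params))
            leak_idx = [net.id_to_index[int(i)] for i in solution.leaked_nodes]
            res[leak_idx] += c_leak * solution.node_pressure[leak_idx]
        residual[interior] = res[interior]
    return residual
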