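import numpy as np
import pytest

import osteoflow as of


@pytest.fixture(scope="session")
def params():
    return of.HydraulicParams()


@pytest.fixture()
def chain5():
    """Sealed 5-segment chain, 10 µm segments, canal at node 5."""
    return of.generate_chain(5, 10.0)


@pytest.fixture(scope="session")
def spoke_net():
    """100 straight radial spokes, 4 µm segments, 36 → 104 µm."""
    return of.generate_spoke_osteon(100, 4.0)


@pytest.fixture(scope="session")
def ordinary_net():
    return of.generate_osteon(of.ordinary_params(seed=1))


@pytest.fixture(scope="session")
def oio_net():
    return of.generate_osteon(of.osteon_in_osteon_params(seed=1))


def random_connected_network(rng: np.random.Generator, n_nodes: int) -> of.OsteonNetwork:
    """Small random connected network with 1-2 haversian tags and a few
    extra (possibly parallel) edges — an oracle workbench, not an osteon."""
    span = 50.0
    positions = np.column_stack(
        [rng.uniform(0, span, n_nodes), rng.uniform(0, span, n_nodes), np.full(n_nodes, 20.0)]
    )
    edges = []
    for k in range(1, n_nodes):  # random spanning tree
        edges.append((int(rng.integers(0, k)), k))
    for _ in range(int(rng.integers(1, n_nodes))):
        i, j = rng.choice(n_nodes, size=2, replace=False)
        edges.append((int(i), int(j)))
    edge_nodes = np.array(edges)
    chords = np.linalg.norm(
        positions[edge_nodes[:, 1]] - positions[edge_nodes[:, 0]], axis=1
    )
    lengths = chords * rng.uniform(1.0, 1.5, len(edges))
    boundary = np.array(["none"] * n_nodes, dtype=object)
    boundary[rng.choice(n_nodes, size=int(rng.integers(1, 3)), replace=False)] = "haversian"
    if rng.random() < 0.7:
        free = np.flatnonzero(boundary == "none")
        if len(free):
            boundary[rng.choice(free)] = "cement"
    kinds = np.array(["branch"] * n_nodes, dtype=object)
    if rng.random() < 0.5:
        kinds[int(rng.integers(0, n_nodes))] = "lacuna"
    return of.OsteonNetwork(
        node_ids=np.arange(n_nodes),
        positions=positions,
        kinds=kinds,
        boundary=boundary,
        edge_ids=np.arange(len(edges)),
        edge_nodes=edge_nodes,
        lengths=lengths,
        metadata=of.OsteonMetadata(
            center=(span / 2, span / 2),
            haversian_radius=1.0,
            osteon_radius=2 * span,
            slab_thickness=40.0,
            osteon_type="synthetic_oracle",
        ),
    )


def dense_reference_pressures(
    net: of.OsteonNetwork,
    params: of.HydraulicParams,
    approach: str,
    delta_p: float = 13_000.0,
    strain_rate: float = 0.015,
) -> np.ndarray:
    """Brute-force dense solve, built from first principles with Python loops.

    Merges haversian nodes into a reference (pressure 0), assembles the full
    Laplacian entry by entry, applies the boundary conditions by row
    substitution and solves with numpy's dense solver.  Independent of the
    sparse reduced-Laplacian path it checks.
    """
    hav = net.haversian_mask()
    merged = {}
    label = 1
    for i in range(net.n_nodes):
        if hav[i]:
            merged[i] = 0
        else:
            merged[i] = label
            label += 1
    m = label
    lap = np.zeros((m, m))
    idx = net.edge_indices
    for (t, h), l in zip(idx, net.lengths):
        c = (params.k_p_eff_um2 / params.mu) * params.annulus_area / l
        a, b = merged[int(t)], merged[int(h)]
        if a == b:
            continue
        lap[a, a] += c
        lap[b, b] += c
        lap[a, b] -= c
        lap[b, a] -= c

    rhs = np.zeros(m)
    fixed = {0: 0.0}
    if approach == "fixed_pressure":
        for i in range(net.n_nodes):
            if net.boundary[i] == "cement" and not hav[i]:
                fixed[merged[i]] = delta_p
    else:
        volumes = of.node_source_volumes(net, params)
        for i in range(net.n_nodes):
            if not hav[i]:
                rhs[merged[i]] += strain_rate * volumes[i]

    a_mat = lap.copy()
    for j, val in fixed.items():
        a_mat[j, :] = 0.0
        a_mat[j, j] = 1.0
        rhs[j] = val
    sol = np.linalg.solve(a_mat, rhs)
    return np.array([sol[merged[i]] for i in range(net.n_nodes)])
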