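import numpy as np
import pytest

from lvhsim import geometry as geo
from lvhsim.pipeline import StudySettings, run_hypertrophy_study
from lvhsim.synthetic_data import fixture_healthy_mesh, fixture_mesh_resolution


@pytest.fixture(scope="session")
def coarse_mesh():
    """Coarse healthy biventricle with fibres (shared, treated as read-only)."""
    return fixture_healthy_mesh()


@pytest.fixture(scope="session")
def coarse_coords(coarse_mesh):
    return geo.compute_ventricular_coordinates(coarse_mesh)


@pytest.fixture(scope="session")
def study():
    """Full 30-model hypertrophy study on the coarse fixture mesh.

    Session-scoped: the growth ladder, activation maps and ECGs are reused by
    several independent checks (mass monotonicity, h/R behaviour, QRS
    duration trends, amplitude trends, criteria bookkeeping).
    """
    settings = StudySettings(resolution=fixture_mesh_resolution())
    df, results = run_hypertrophy_study(settings)
    return df, results


@pytest.fixture(scope="session")
def rod_mesh():
    """Conduction phantom: 6 cm bar with axial fibres."""
    return geo.box_bar_mesh(length=0.06, width=0.01, n=(12, 2, 2))


def dijkstra_oracle(n_nodes, edges, costs, sources, t0):
    """Independent shortest-path reference (binary heap, pure python)."""
    import heapq

    adj = {i: [] for i in range(n_nodes)}
    for (a, b), c in zip(edges, costs):
        adj[int(a)].append((int(b), c))
        adj[int(b)].append((int(a), c))
    dist = np.full(n_nodes, np.inf)
    heap = []
    for s, t in zip(sources, t0):
        if t < dist[s]:
            dist[s] = t
            heapq.heappush(heap, (t, int(s)))
    while heap:
        d, u = heapq.heappop(heap)
        if d > dist[u]:
            continue
        for v, c in adj[u]:
            nd = d + c
            if nd < dist[v]:
                dist[v] = nd
                heapq.heappush(heap, (nd, v))
    return dist
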