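"""Shared fixtures: small banded-ellipsoid meshes and pattern fields."""

import pytest

from mimicaxis import (
    BandedEllipsoidParams,
    align_to,
    make_banded_ellipsoid,
    make_banded_pair,
    segment_colours,
    signed_distance_map,
)


@pytest.fixture(scope="session")
def small_pair():
    """Corresponded banded pair, 290 vertices, phases 0 and 0.5."""
    return make_banded_pair(n_lat=12, n_lon=24)


@pytest.fixture(scope="session")
def small_fields(small_pair):
    """Aligned signed-distance pattern fields of the small pair."""
    ea, eb, _ = small_pair
    fa = signed_distance_map(segment_colours(ea.mesh), ea.mesh)
    fb = align_to(fa, signed_distance_map(segment_colours(eb.mesh), eb.mesh))
    return fa, fb


@pytest.fixture(scope="session")
def medium_pair():
    """Corresponded banded pair at the default 514-vertex tessellation."""
    return make_banded_pair()


@pytest.fixture()
def two_tone_mesh():
    """Noise-free banded ellipsoid with exactly two colours."""
    return make_banded_ellipsoid(BandedEllipsoidParams(n_lat=8, n_lon=16))


def brute_force_hop_distances(mesh):
    """Independent oracle: per-vertex BFS over the edge graph (pure python)."""
    from collections import deque

    n = mesh.n_vertices
    neighbours = [set() for _ in range(n)]
    for a, b, c in mesh.faces:
        neighbours[a].update((b, c))
        neighbours[b].update((a, c))
        neighbours[c].update((a, b))

    def bfs(start):
        dist = [-1] * n
        dist[start] = 0
        queue = deque([start])
        while queue:
            v = queue.popleft()
            for u in neighbours[v]:
                if dist[u] < 0:
                    dist[u] = dist[v] + 1
                    queue.append(u)
        return dist

    return [bfs(v) for v in range(n)]
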