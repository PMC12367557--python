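"""Shape correspondence and interpolation along a mimicry axis.

Two scanned bodies are put into one-to-one vertex correspondence by
projecting a single simplified template onto each: the template keeps its
topology while its vertices are pulled onto the target surface by iterated
closest-surface-point projection with Laplacian smoothing.  Once both
endpoints share a vertex set, intermediate (and extrapolated) shapes are
produced by per-vertex linear interpolation

    V_w = (1 - w) * V_A + w * V_B,

which recovers the endpoints exactly and is the only method defined for
extrapolation (w < 0 or w > 1).  A smoothed displacement-field variant
(``kernel_flow``) is provided for qualitative parity with diffeomorphic
morphing tools: the A-to-B displacement is regressed onto Gaussian kernels
centred on a regular control-point grid, and each vertex travels the
fraction ``w`` of its fitted displacement in fixed small steps.  It is
restricted to w in [0, 1] and recovers B at w = 1 up to the kernel
regression residual (checked to 1e-3 relative to the bounding-box
diagonal).  Wing outlines are interpolated with the same linear rule after
arc-length resampling to a fixed number of points from a common anchor
(the wing root, taken as the point of minimum X).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .mesh_io import ColouredMesh, require_valid, vertex_adjacency
from .pattern_morph import transfer_colours

OUTLINE_POINTS = 200  # fixed resampling count for wing outlines


class ShapeError(ValueError):
    """Raised for invalid correspondence or interpolation inputs."""


class ProjectionError(ShapeError):
    """Raised when template projection fails to reach the target surface."""


def _closest_on_triangles(p: np.ndarray, a: np.ndarray, b: np.ndarray,
                          c: np.ndarray) -> np.ndarray:
    """Closest point to p on each triangle (a, b, c); all inputs (..., 3)."""
    ab, ac, ap = b - a, c - a, p - a
    d1 = (ab * ap).sum(-1)
    d2 = (ac * ap).sum(-1)
    bp = p - b
    d3 = (ab * bp).sum(-1)
    d4 = (ac * bp).sum(-1)
    cp = p - c
    d5 = (ab * cp).sum(-1)
    d6 = (ac * cp).sum(-1)
    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    with np.errstate(divide="ignore", invalid="ignore"):
        t_ab = (d1 / (d1 - d3))[..., None]
        t_ac = (d2 / (d2 - d6))[..., None]
        t_bc = ((d4 - d3) / ((d4 - d3) + (d5 - d6)))[..., None]
        denom = 1.0 / (va + vb + vc)
        v = (vb * denom)[..., None]
        w = (vc * denom)[..., None]

    out = a + ab * v + ac * w  # interior (face) region
    on_bc = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    out = np.where(on_bc[..., None], b + t_bc * (c - b), out)
    on_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    out = np.where(on_ac[..., None], a + t_ac * ac, out)
    on_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    out = np.where(on_ab[..., None], a + t_ab * ab, out)
    out = np.where(((d6 >= 0) & (d5 <= d6))[..., None], c, out)  # vertex C
    out = np.where(((d3 >= 0) & (d4 <= d3))[..., None], b, out)  # vertex B
    out = np.where(((d1 <= 0) & (d2 <= 0))[..., None], a, out)   # vertex A
    return out


def closest_surface_points(target: ColouredMesh, points: np.ndarray,
                           n_candidates: int = 32) -> tuple[np.ndarray, np.ndarray]:
    """Closest point on the target surface for each query point.

    Candidate faces are pre-filtered by a KD-tree over face centroids, then
    resolved exactly by point-triangle projection.  Returns (points, dists).
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    tri = target.vertices[target.faces]  # (m, 3, 3)
    centroids = tri.mean(axis=1)
    k = min(n_candidates, len(centroids))
    _, idx = cKDTree(centroids).query(points, k=k)
    idx = np.atleast_2d(idx.T).T if k == 1 else idx  # (n, k)
    cand = tri[idx]  # (n, k, 3, 3)
    closest = _closest_on_triangles(
        points[:, None, :], cand[:, :, 0], cand[:, :, 1], cand[:, :, 2]
    )
    d2 = ((closest - points[:, None, :]) ** 2).sum(-1)
    pick = np.argmin(d2, axis=1)
    rows = np.arange(len(points))
    return closest[rows, pick], np.sqrt(d2[rows, pick])


@dataclass
class CorrespondedPair:
    """Two meshes with identical topology (shared face list)."""

    meshA: ColouredMesh
    meshB: ColouredMesh
    shared_faces: np.ndarray

    def __post_init__(self) -> None:
        self.shared_faces = np.asarray(self.shared_faces, dtype=np.int64).reshape(-1, 3)
        require_valid(self.meshA)
        require_valid(self.meshB)
        if self.meshA.n_vertices != self.meshB.n_vertices:
            raise ShapeError(
                f"corresponded meshes must share a vertex count "
                f"({self.meshA.n_vertices} != {self.meshB.n_vertices})"
            )
        if not (
            np.array_equal(self.meshA.faces, self.shared_faces)
            and np.array_equal(self.meshB.faces, self.shared_faces)
        ):
            raise ShapeError("both meshes must reference the shared face list")


def project_template(
    template: ColouredMesh,
    target: ColouredMesh,
    iterations: int = 50,
    smoothing: float = 0.5,
) -> ColouredMesh:
    """Wrap the template onto the target surface, keeping template topology.

    Each iteration projects every vertex to its closest point on the target
    surface and then applies one Laplacian smoothing step with weight
    ``smoothing``; a final pure projection leaves all vertices on the
    surface.  Colours are sampled from the target by nearest-vertex lookup.
    Raises :class:`ProjectionError` if the maximum residual distance to the
    target exceeds 1% of the target's bounding-box diagonal.
    """
    require_valid(template)
    require_valid(target)
    if target.n_faces == 0:
        raise ShapeError("target mesh has no faces")
    if iterations < 1:
        raise ShapeError("iterations must be positive")
    if not 0.0 <= smoothing <= 1.0:
        raise ShapeError("smoothing must lie in [0, 1]")

    adj = vertex_adjacency(template)
    degree = np.asarray(adj.sum(axis=1)).ravel()
    verts = template.vertices.copy()
    for _ in range(iterations):
        verts, _ = closest_surface_points(target, verts)
        if smoothing > 0.0:
            neighbour_mean = adj.dot(verts) / degree[:, None]
            verts = (1.0 - smoothing) * verts + smoothing * neighbour_mean
    verts, _ = closest_surface_points(target, verts)
    diag = float(np.linalg.norm(target.vertices.max(axis=0) - target.vertices.min(axis=0)))
    _, dist = closest_surface_points(target, verts)
    max_residual = float(np.max(dist))
    if max_residual > 0.01 * diag:
        raise ProjectionError(
            f"projection did not converge: max residual {max_residual:.4g} "
            f"exceeds 1% of target diagonal {diag:.4g}"
        )
    colours = transfer_colours(target, verts)
    return ColouredMesh(verts, template.faces.copy(), colours, name=f"{target.name}@template")


# -- kernel-flow displacement field -----------------------------------------

def _kernel_matrix(points: np.ndarray, centres: np.ndarray, sigma: float) -> np.ndarray:
    d2 = ((points[:, None, :] - centres[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / (2.0 * sigma * sigma))


def _fit_kernel_displacement(
    pair: CorrespondedPair, grid: int, sigma_factor: float, ridge: float
) -> np.ndarray:
    """Fit per-vertex displacement A->B smoothed through grid kernels."""
    va, vb = pair.meshA.vertices, pair.meshB.vertices
    lo = np.minimum(va.min(axis=0), vb.min(axis=0))
    hi = np.maximum(va.max(axis=0), vb.max(axis=0))
    span = np.maximum(hi - lo, 1e-9)
    axes = [np.linspace(lo[k] - 0.1 * span[k], hi[k] + 0.1 * span[k], grid) for k in range(3)]
    centres = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    sigma = sigma_factor * float(np.max(span)) / max(grid - 1, 1)
    K = _kernel_matrix(va, centres, sigma)
    target = vb - va
    # ridge-regularised least squares for the kernel weights
    A = K.T @ K + ridge * np.eye(K.shape[1])
    alpha = np.linalg.solve(A, K.T @ target)
    return K @ alpha


def interpolate_shape(
    pair: CorrespondedPair,
    w: float,
    method: str = "linear",
    n_steps: int = 10,
    grid: int = 5,
    sigma_factor: float = 1.5,
    ridge: float = 1e-10,
) -> np.ndarray:
    """Vertex coordinates at weight ``w`` of endpoint B.

    ``linear`` permits any real ``w``; ``kernel_flow`` is restricted to
    [0, 1] and moves each vertex along its kernel-smoothed displacement in
    ``n_steps`` equal steps.
    """
    if method == "linear":
        return (1.0 - w) * pair.meshA.vertices + w * pair.meshB.vertices
    if method == "kernel_flow":
        if not 0.0 <= w <= 1.0:
            raise ShapeError("kernel_flow only supports w in [0, 1]")
        displacement = _fit_kernel_displacement(pair, grid, sigma_factor, ridge)
        step = (w / n_steps) * displacement
        verts = pair.meshA.vertices.copy()
        for _ in range(n_steps):
            verts = verts + step
        return verts
    raise ShapeError(f"unknown interpolation method {method!r}")


# -- wing outlines -----------------------------------------------------------

def _check_outline(points: np.ndarray) -> np.ndarray:
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(points) < 3:
        raise ShapeError("an outline needs at least 3 points")
    if np.allclose(points[0], points[-1]) and len(points) > 3:
        points = points[:-1]  # drop an explicit closing point
    from shapely.geometry import LinearRing

    ring = LinearRing(points)
    if not ring.is_valid or not ring.is_simple:
        raise ShapeError("outline is self-intersecting")
    return points


def _signed_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def resample_outline(points: np.ndarray, n: int = OUTLINE_POINTS) -> np.ndarray:
    """Resample a closed loop to ``n`` points, equally spaced by arc length.

    The loop is re-anchored at the wing root (point of minimum X, ties by
    minimum Y) and oriented counter-clockwise, so two resampled outlines
    are point-wise comparable.
    """
    points = _check_outline(points)
    if _signed_area(points) < 0.0:
        points = points[::-1]
    anchor = np.lexsort((points[:, 1], points[:, 0]))[0]
    points = np.roll(points, -anchor, axis=0)
    closed = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cumulative = np.concatenate([[0.0], np.cumsum(seg)])
    total = cumulative[-1]
    targets = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(targets, cumulative, closed[:, 0])
    y = np.interp(targets, cumulative, closed[:, 1])
    return np.column_stack([x, y])


def interpolate_outline(
    outline_a: np.ndarray, outline_b: np.ndarray, w: float, n: int = OUTLINE_POINTS
) -> np.ndarray:
    """Point-wise linear interpolation of two resampled closed outlines."""
    ra = resample_outline(outline_a, n)
    rb = resample_outline(outline_b, n)
    return (1.0 - w) * ra + w * rb
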