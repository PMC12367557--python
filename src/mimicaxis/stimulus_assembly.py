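"""Assembly of complete printable stimuli.

An interpolated body is combined with standardised appendages - cylindrical
legs (0.6 mm diameter, articulated into coxa/femur/tibia/tarsus),
gently curved cylindrical antennae (0.8 mm diameter, length interpolated
between the endpoint specimens), and flat 0.4 mm wings in 50% grey - plus
an optional circular base with a narrow post entering the ventral thorax.
The assembly is finally scaled uniformly so the body's X extent equals the
linearly interpolated body length of the two endpoints; appendage
dimensions are nominal values applied before that final scaling, so all
internal length ratios are preserved.

Legs take whichever of the two body segment colours lies nearer (Euclidean
RGB) to a reference colour measured from the real specimen's legs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components

from .mesh_io import ColouredMesh, require_valid, vertex_adjacency

GREY_50 = (128, 128, 128)
_SECTIONS = 16  # even, so the cross-section width equals the diameter exactly


class AssemblyError(ValueError):
    """Raised for invalid appendage specs or assembly inputs."""


@dataclass
class AppendageSpec:
    """Nominal (pre-scaling) appendage dimensions in millimetres."""

    leg_diameter: float = 0.6
    antenna_diameter: float = 0.8
    wing_thickness: float = 0.4
    wing_grey: tuple[int, int, int] = GREY_50
    antenna_length_A: float = 3.0
    antenna_length_B: float = 3.0
    leg_colour_reference: tuple[int, int, int] = (40, 40, 40)

    def check(self) -> None:
        if min(self.leg_diameter, self.antenna_diameter, self.wing_thickness) <= 0:
            raise AssemblyError("appendage diameters/thicknesses must be positive")
        if min(self.antenna_length_A, self.antenna_length_B) <= 0:
            raise AssemblyError("antenna lengths must be positive")


@dataclass
class BodyMetrics:
    """Body lengths (X extent, mm) of the two axis endpoints."""

    body_length_A: float
    body_length_B: float

    def check(self) -> None:
        if min(self.body_length_A, self.body_length_B) <= 0:
            raise AssemblyError("body lengths must be positive")


@dataclass
class BaseSpec:
    """Circular mounting base: disc plus a narrow vertical post."""

    disc_diameter: float = 10.0
    disc_thickness: float = 1.0
    post_diameter: float = 1.5
    colour: tuple[int, int, int] = GREY_50


def interpolate_scalar(a: float, b: float, w: float) -> float:
    """Linear interpolation (1-w)*a + w*b; extrapolation permitted."""
    return (1.0 - w) * a + w * b


# -- geometric primitives ----------------------------------------------------

def _cylinder(p0: np.ndarray, p1: np.ndarray, radius: float,
              colour: np.ndarray, sections: int = _SECTIONS) -> ColouredMesh:
    """Capped cylinder from p0 to p1; vertices: [c0, c1, ring0, ring1]."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    axis = p1 - p0
    length = np.linalg.norm(axis)
    if length <= 0:
        raise AssemblyError("cylinder endpoints coincide")
    axis = axis / length
    # build an orthonormal frame around the axis
    ref = np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    theta = 2.0 * np.pi * np.arange(sections) / sections
    ring = radius * (np.cos(theta)[:, None] * u + np.sin(theta)[:, None] * v)
    verts = np.vstack([p0, p1, p0 + ring, p1 + ring])
    faces = []
    for k in range(sections):
        nk = (k + 1) % sections
        a0, a1 = 2 + k, 2 + nk
        b0, b1 = 2 + sections + k, 2 + sections + nk
        faces.append([0, a1, a0])        # bottom cap fan
        faces.append([1, b0, b1])        # top cap fan
        faces.append([a0, a1, b1])       # wall
        faces.append([a0, b1, b0])
    colours = np.tile(np.asarray(colour, dtype=np.int64), (len(verts), 1))
    return ColouredMesh(verts, np.array(faces), colours)


def _ear_clip(points: np.ndarray) -> list[list[int]]:
    """Triangulate a simple CCW polygon by ear clipping (indices into points)."""
    n = len(points)
    idx = list(range(n))
    tris: list[list[int]] = []

    def cross(o, a, b):
        return (points[a][0] - points[o][0]) * (points[b][1] - points[o][1]) - (
            points[a][1] - points[o][1]
        ) * (points[b][0] - points[o][0])

    def inside(p, a, b, c):
        d1 = cross(a, b, p)
        d2 = cross(b, c, p)
        d3 = cross(c, a, p)
        return d1 >= -1e-12 and d2 >= -1e-12 and d3 >= -1e-12

    guard = 0
    while len(idx) > 3 and guard < 10 * n * n:
        guard += 1
        m = len(idx)
        clipped = False
        for k in range(m):
            a, b, c = idx[k - 1], idx[k], idx[(k + 1) % m]
            if cross(a, b, c) <= 1e-12:
                continue  # reflex or collinear vertex
            if any(inside(p, a, b, c) for p in idx if p not in (a, b, c)):
                continue
            tris.append([a, b, c])
            idx.pop(k)
            clipped = True
            break
        if not clipped:
            break
    if len(idx) == 3:
        tris.append(list(idx))
    return tris


def _extrude_outline(points: np.ndarray, thickness: float,
                     colour: np.ndarray) -> ColouredMesh:
    """Flat extrusion of a simple closed 2D outline along +Z."""
    from .shape_morph import _check_outline, _signed_area

    points = _check_outline(points)
    if _signed_area(points) < 0.0:
        points = points[::-1]
    n = len(points)
    bottom = np.column_stack([points, np.zeros(n)])
    top = np.column_stack([points, np.full(n, thickness)])
    verts = np.vstack([bottom, top])
    cap = _ear_clip(points)
    faces = []
    for a, b, c in cap:
        faces.append([a, c, b])                   # bottom, flipped to face -Z
        faces.append([n + a, n + b, n + c])       # top
    for k in range(n):
        nk = (k + 1) % n
        faces.append([k, nk, n + nk])
        faces.append([k, n + nk, n + k])
    colours = np.tile(np.asarray(colour, dtype=np.int64), (len(verts), 1))
    return ColouredMesh(verts, np.array(faces), colours)


def _concatenate(meshes: list[ColouredMesh], name: str = "") -> ColouredMesh:
    verts, faces, colours = [], [], []
    offset = 0
    for m in meshes:
        verts.append(m.vertices)
        faces.append(m.faces + offset)
        colours.append(m.vertex_colours)
        offset += m.n_vertices
    return ColouredMesh(np.vstack(verts), np.vstack(faces), np.vstack(colours), name=name)


def component_count(mesh: ColouredMesh) -> int:
    """Number of face-connected components (used for assembly checks)."""
    n_comp, _ = connected_components(vertex_adjacency(mesh), directed=False)
    return int(n_comp)


# -- appendages --------------------------------------------------------------

_LEG_SEGMENTS = (("coxa", 1.2, 0.0), ("femur", 1.6, 0.6), ("tibia", 1.6, -1.2),
                 ("tarsus", 1.0, -0.6))  # (name, length mm, bend angle rad)


def leg_colour(spec: AppendageSpec, segment_colours: np.ndarray) -> np.ndarray:
    """The body segment colour nearer (RGB Euclidean) to the leg reference."""
    segment_colours = np.asarray(segment_colours, dtype=float).reshape(2, 3)
    ref = np.asarray(spec.leg_colour_reference, dtype=float)
    d = np.linalg.norm(segment_colours - ref, axis=1)
    return segment_colours[int(np.argmin(d))]


def make_leg(spec: AppendageSpec, segment_colours: np.ndarray) -> ColouredMesh:
    """Articulated four-segment cylindrical leg, 0.6 mm nominal diameter."""
    spec.check()
    colour = np.asarray(
        np.clip(np.floor(leg_colour(spec, segment_colours) + 0.5), 0, 255), dtype=np.int64
    )
    radius = spec.leg_diameter / 2.0
    parts = []
    point = np.zeros(3)
    direction = np.array([0.0, 0.0, -1.0])  # legs extend ventrally
    for _, seg_len, bend in _LEG_SEGMENTS:
        c, s = np.cos(bend), np.sin(bend)
        # bend within the XZ plane at each articulation
        direction = np.array(
            [c * direction[0] + s * direction[2], 0.0, -s * direction[0] + c * direction[2]]
        )
        nxt = point + seg_len * direction
        parts.append(_cylinder(point, nxt, radius, colour))
        point = nxt
    return _concatenate(parts, name="leg")


def make_antenna(spec: AppendageSpec, length: float) -> ColouredMesh:
    """Gently curved cylindrical antenna with the given axial (X) length."""
    spec.check()
    if length <= 0:
        raise AssemblyError("antenna length must be positive")
    radius = spec.antenna_diameter / 2.0
    n_seg = 8
    x = np.linspace(0.0, length, n_seg + 1)
    z = 0.08 * length * np.sin(np.pi * x / length)  # gentle bow
    centreline = np.column_stack([x, np.zeros_like(x), z])
    colour = np.array([60, 50, 40], dtype=np.int64)  # dark chitin tone
    parts = [
        _cylinder(centreline[k], centreline[k + 1], radius, colour)
        for k in range(n_seg)
    ]
    return _concatenate(parts, name="antenna")


def make_wing(spec: AppendageSpec, outline: np.ndarray) -> ColouredMesh:
    """Flat wing: the outline extruded to 0.4 mm, uniform 50% grey."""
    spec.check()
    mesh = _extrude_outline(outline, spec.wing_thickness, np.asarray(spec.wing_grey))
    mesh.name = "wing"
    return mesh


# -- whole-stimulus assembly -------------------------------------------------

def assemble_stimulus(
    body: ColouredMesh,
    parts: list[ColouredMesh],
    metrics: BodyMetrics,
    w: float,
    with_base: bool = True,
    base: BaseSpec | None = None,
    base_anchor: np.ndarray | None = None,
) -> ColouredMesh:
    """Combine body and posed parts into one mesh, scaled to the axis point.

    The whole body+parts assembly is scaled uniformly about the origin so
    the body X extent equals ``interpolate_scalar(body_length_A,
    body_length_B, w)``.  The optional base (disc plus post reaching the
    ventral thorax anchor) is added after scaling at its physical print
    size.  ``base_anchor`` defaults to 35% along the body from the anterior
    end, on the ventral (minimum Z) side; it must lie within the body
    bounding box.
    """
    require_valid(body)
    metrics.check()
    for p in parts:
        require_valid(p)

    target = interpolate_scalar(metrics.body_length_A, metrics.body_length_B, w)
    if target <= 0:
        raise AssemblyError(f"interpolated body length {target} is not positive")
    extent = body.x_extent()
    if extent <= 0:
        raise AssemblyError("body has zero X extent")
    scale = target / extent

    scaled = [body.copy()] + [p.copy() for p in parts]
    if scale != 1.0:
        for m in scaled:
            m.vertices = m.vertices * scale
    assembly = _concatenate(scaled, name=f"stimulus_w{w:g}")

    if with_base:
        base = base or BaseSpec()
        sbody = scaled[0]
        lo, hi = sbody.vertices.min(axis=0), sbody.vertices.max(axis=0)
        if base_anchor is None:
            anchor = np.array([lo[0] + 0.35 * (hi[0] - lo[0]), (lo[1] + hi[1]) / 2.0, lo[2]])
        else:
            anchor = np.asarray(base_anchor, dtype=float)
            if ((anchor < lo - 1e-9) | (anchor > hi + 1e-9)).any():
                raise AssemblyError(
                    f"base anchor {anchor.tolist()} lies outside the body bounding box"
                )
        colour = np.asarray(base.colour)
        disc_top = anchor[2] - 2.0  # stand-off below the ventral surface
        disc = _cylinder(
            np.array([anchor[0], anchor[1], disc_top - base.disc_thickness]),
            np.array([anchor[0], anchor[1], disc_top]),
            base.disc_diameter / 2.0,
            colour,
        )
        post = _cylinder(
            np.array([anchor[0], anchor[1], disc_top]),
            np.array([anchor[0], anchor[1], anchor[2] + 0.2]),  # enters the thorax
            base.post_diameter / 2.0,
            colour,
        )
        assembly = _concatenate([assembly, disc, post], name=assembly.name)

    require_valid(assembly)
    return assembly
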