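"""Coloured triangle mesh container and I/O.

Every phenotype in the pipeline is carried by a :class:`ColouredMesh`: a
triangle mesh in millimetres with an RGB colour (integer 0-255) attached to
every vertex.  Two interchange formats are supported:

* Wavefront OBJ with a companion MTL file.  OBJ has no canonical per-vertex
  colour, so on write we emit one material per distinct vertex colour *and*
  append the colour to each ``v`` line (a widely supported extension), which
  makes the round trip exact.  On read, ``v``-line colours win when present;
  otherwise per-face material colours are broadcast to incident vertices,
  with conflicts at shared vertices resolved by majority vote (ties broken
  by the lowest material index).
* PLY with ``uchar`` vertex colour properties (read and written through
  :mod:`trimesh`).

Axis convention: anterior-posterior runs along +X and dorsal along +Z, so a
specimen's body length is its X extent.  Face indices are 0-based
internally; the OBJ reader/writer converts at the boundary.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh


class MeshError(ValueError):
    """Raised for unreadable, unwritable or structurally invalid meshes."""


class MeshColourError(MeshError):
    """Raised when a mesh file carries no usable colour channel."""


def quantize_colour(values: np.ndarray) -> np.ndarray:
    """Round real-valued RGB to integers 0-255, half-up, clamped."""
    arr = np.asarray(values, dtype=float)
    return np.clip(np.floor(arr + 0.5), 0, 255).astype(np.int64)


@dataclass
class ColouredMesh:
    """Triangle mesh with per-vertex RGB colour.

    Attributes
    ----------
    vertices : (n, 3) float array, millimetres.
    faces : (m, 3) int array of 0-based vertex indices.
    vertex_colours : (n, 3) int array, RGB in 0-255.
    name : label carried through the pipeline for provenance.
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_colours: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        self.vertex_colours = np.asarray(self.vertex_colours, dtype=np.int64).reshape(-1, 3)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def x_extent(self) -> float:
        """Body length under the anterior-posterior = +X convention."""
        return float(self.vertices[:, 0].max() - self.vertices[:, 0].min())

    def copy(self, name: str | None = None) -> "ColouredMesh":
        return ColouredMesh(
            self.vertices.copy(),
            self.faces.copy(),
            self.vertex_colours.copy(),
            self.name if name is None else name,
        )

    def as_trimesh(self) -> trimesh.Trimesh:
        rgba = np.column_stack(
            [self.vertex_colours, np.full(self.n_vertices, 255, dtype=np.int64)]
        ).astype(np.uint8)
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, vertex_colors=rgba, process=False
        )


def validate_mesh(mesh: ColouredMesh) -> list[str]:
    """Report violated invariants; an empty list means the mesh is valid.

    Reported problems (with offending indices where applicable):
    face indices out of range, degenerate faces repeating a vertex,
    colour/vertex length mismatch, non-finite coordinates.
    """
    report: list[str] = []
    n = mesh.n_vertices
    if mesh.faces.size:
        bad = np.where((mesh.faces < 0) | (mesh.faces >= n))[0]
        if bad.size:
            report.append(f"face index out of range [0, {n}) at faces {bad.tolist()}")
        degen = np.where(
            (mesh.faces[:, 0] == mesh.faces[:, 1])
            | (mesh.faces[:, 1] == mesh.faces[:, 2])
            | (mesh.faces[:, 0] == mesh.faces[:, 2])
        )[0]
        if degen.size:
            report.append(f"degenerate face repeating a vertex at faces {degen.tolist()}")
    if len(mesh.vertex_colours) != n:
        report.append(
            f"vertex_colours length {len(mesh.vertex_colours)} != vertex count {n}"
        )
    if not np.isfinite(mesh.vertices).all():
        bad = np.where(~np.isfinite(mesh.vertices).all(axis=1))[0]
        report.append(f"non-finite coordinates at vertices {bad.tolist()}")
    return report


def require_valid(mesh: ColouredMesh) -> ColouredMesh:
    """Assert an empty validation report at a module boundary."""
    report = validate_mesh(mesh)
    if report:
        raise MeshError("invalid mesh: " + "; ".join(report))
    return mesh


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        fmt = format.lower()
    else:
        fmt = path.suffix.lower().lstrip(".")
    if fmt not in {"obj", "ply"}:
        raise MeshError(f"unsupported mesh format {fmt!r} (expected obj or ply)")
    return fmt


def read_mesh(path: str | Path, format: str | None = None) -> ColouredMesh:
    """Read a coloured mesh from OBJ(+MTL) or PLY.

    Raises :class:`MeshError` for a missing file or unparseable geometry and
    :class:`MeshColourError` when the file carries no colour information.
    """
    path = Path(path)
    if not path.exists():
        raise MeshError(f"mesh file not found: {path}")
    fmt = _infer_format(path, format)
    mesh = _read_obj(path) if fmt == "obj" else _read_ply(path)
    require_valid(mesh)
    return mesh


def write_mesh(mesh: ColouredMesh, path: str | Path, format: str | None = None) -> Path:
    """Write a coloured mesh; OBJ output also emits a companion MTL file."""
    require_valid(mesh)
    if mesh.n_faces == 0:
        raise MeshError("refusing to write a mesh with no faces")
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "obj":
        _write_obj(mesh, path)
    else:
        _write_ply(mesh, path)
    return path


# -- PLY via trimesh ---------------------------------------------------------

def _read_ply(path: Path) -> ColouredMesh:
    try:
        tm = trimesh.load(str(path), file_type="ply", process=False, force="mesh")
    except Exception as exc:  # noqa: BLE001 - normalise parser errors
        raise MeshError(f"unparseable PLY file {path}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.vertices) == 0:
        raise MeshError(f"no triangle geometry in {path}")
    if tm.visual.kind != "vertex":
        raise MeshColourError(
            f"{path} has no per-vertex colour properties (missing RGB channel)"
        )
    colours = np.asarray(tm.visual.vertex_colors)[:, :3]
    return ColouredMesh(tm.vertices, tm.faces, colours, name=path.stem)


def _write_ply(mesh: ColouredMesh, path: Path) -> None:
    mesh.as_trimesh().export(str(path), encoding="ascii")


# -- OBJ + MTL ---------------------------------------------------------------

def _parse_mtl(path: Path) -> dict[str, tuple[int, tuple[int, int, int]]]:
    """Return material name -> (definition index, RGB) from an MTL file."""
    materials: dict[str, tuple[int, tuple[int, int, int]]] = {}
    current = None
    for line in path.read_text().splitlines():
        tokens = line.split()
        if not tokens or tokens[0].startswith("#"):
            continue
        if tokens[0] == "newmtl":
            current = tokens[1]
            materials[current] = (len(materials), (255, 255, 255))
        elif tokens[0] == "Kd" and current is not None:
            rgb = quantize_colour(np.array([float(v) for v in tokens[1:4]]) * 255.0)
            materials[current] = (materials[current][0], tuple(int(v) for v in rgb))
    return materials


def _read_obj(path: Path) -> ColouredMesh:
    vertices: list[list[float]] = []
    v_colours: list[tuple[int, int, int] | None] = []
    faces: list[list[int]] = []
    face_material: list[int] = []
    materials: dict[str, tuple[int, tuple[int, int, int]]] = {}
    current_material = -1

    for line in path.read_text().splitlines():
        tokens = line.split()
        if not tokens or tokens[0].startswith("#"):
            continue
        kind = tokens[0]
        if kind == "mtllib":
            mtl_path = path.parent / tokens[1]
            if mtl_path.exists():
                materials.update(_parse_mtl(mtl_path))
        elif kind == "usemtl":
            name = tokens[1]
            current_material = materials.get(name, (-1, None))[0]
        elif kind == "v":
            values = [float(v) for v in tokens[1:]]
            vertices.append(values[:3])
            if len(values) >= 6:
                v_colours.append(tuple(int(c) for c in quantize_colour(np.array(values[3:6]) * 255.0)))
            else:
                v_colours.append(None)
        elif kind == "f":
            idx = []
            for token in tokens[1:]:
                raw = token.split("/")[0]
                i = int(raw)
                if i <= 0:
                    raise MeshError(f"unsupported non-positive OBJ face index {i} in {path}")
                idx.append(i - 1)  # OBJ is 1-based
            # triangulate fans for polygons with >3 vertices
            for k in range(1, len(idx) - 1):
                faces.append([idx[0], idx[k], idx[k + 1]])
                face_material.append(current_material)

    if not vertices:
        raise MeshError(f"no vertices parsed from {path}")
    n = len(vertices)
    for tri in faces:
        for i in tri:
            if i >= n:
                raise MeshError(f"face index {i + 1} out of range in {path} ({n} vertices)")

    have_vertex_colours = all(c is not None for c in v_colours)
    if have_vertex_colours:
        colours = np.array(v_colours, dtype=np.int64)
    else:
        if not materials or all(m < 0 for m in face_material):
            raise MeshColourError(
                f"{path} has neither vertex colours nor MTL material colours "
                "(missing RGB channel)"
            )
        by_index = {idx: rgb for idx, rgb in materials.values()}
        votes: list[Counter] = [Counter() for _ in range(n)]
        for tri, mat in zip(faces, face_material):
            if mat < 0:
                continue
            for i in tri:
                votes[i][mat] += 1
        colours = np.zeros((n, 3), dtype=np.int64)
        for i, counter in enumerate(votes):
            if not counter:
                raise MeshColourError(
                    f"vertex {i} in {path} is used by no material-bearing face"
                )
            best = max(counter.items(), key=lambda kv: (kv[1], -kv[0]))[0]
            colours[i] = by_index[best]

    return ColouredMesh(np.array(vertices), np.array(faces, dtype=np.int64), colours, name=path.stem)


def _write_obj(mesh: ColouredMesh, path: Path) -> None:
    mtl_path = path.with_suffix(".mtl")
    distinct, inverse = np.unique(mesh.vertex_colours, axis=0, return_inverse=True)

    with mtl_path.open("w") as fh:
        for k, rgb in enumerate(distinct):
            fh.write(f"newmtl mat{k}\n")
            fh.write("Kd {:.8f} {:.8f} {:.8f}\n".format(*(rgb / 255.0)))

    # per-face material: majority colour of its vertices, ties -> lowest index
    face_mat = np.zeros(mesh.n_faces, dtype=np.int64)
    for fi, tri in enumerate(mesh.faces):
        counter = Counter(inverse[tri].tolist())
        face_mat[fi] = max(counter.items(), key=lambda kv: (kv[1], -kv[0]))[0]

    with path.open("w") as fh:
        fh.write(f"mtllib {mtl_path.name}\n")
        if mesh.name:
            fh.write(f"o {mesh.name}\n")
        for xyz, rgb in zip(mesh.vertices, mesh.vertex_colours):
            fh.write(
                "v {:.9g} {:.9g} {:.9g} {:.8f} {:.8f} {:.8f}\n".format(
                    *xyz, *(rgb / 255.0)
                )
            )
        current = -1
        for fi in range(mesh.n_faces):  # original face order preserved
            if face_mat[fi] != current:
                current = int(face_mat[fi])
                fh.write(f"usemtl mat{current}\n")
            a, b, c = mesh.faces[fi] + 1  # back to 1-based
            fh.write(f"f {a} {b} {c}\n")


def vertex_adjacency(mesh: ColouredMesh):
    """Sparse symmetric vertex adjacency (edge graph) of the mesh."""
    from scipy import sparse

    f = mesh.faces
    rows = np.concatenate([f[:, 0], f[:, 1], f[:, 1], f[:, 2], f[:, 2], f[:, 0]])
    cols = np.concatenate([f[:, 1], f[:, 0], f[:, 2], f[:, 1], f[:, 0], f[:, 2]])
    data = np.ones(len(rows), dtype=np.int8)
    adj = sparse.coo_matrix((data, (rows, cols)), shape=(mesh.n_vertices, mesh.n_vertices))
    adj = adj.tocsr()
    adj.data[:] = 1
    return adj
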