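"""Triangle-mesh I/O, closed-mesh volumes, and the CSV table formats.

Volumes use the divergence theorem on consistently oriented watertight
meshes.  No implicit unit conversion happens here: with coordinates in cm,
volumes come out in cm^3 = ml (a global ``unit_scale`` in the pipeline
config rescales other units into cm).

The gold-standard cavity volume is the numeric difference between a sealed
"wrapped" mesh (solid plus cavity) and the bare surface mesh (solid only) —
the mesh-subtraction analog of segmenting air directly from a CT scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh as _trimesh

from .errors import MeshFormatError, NotWatertightError

__all__ = [
    "TriMesh",
    "read_mesh",
    "write_mesh",
    "closed_mesh_volume",
    "cavity_volume_by_subtraction",
    "read_markers_csv",
    "write_markers_csv",
    "read_locators_csv",
    "write_locators_csv",
    "read_rbt_csv",
    "write_rbt_csv",
    "read_framecloud_csv",
    "write_framecloud_csv",
]

_FORMATS = {"obj", "stl", "ply"}


@dataclass
class TriMesh:
    """A triangular surface mesh (vertices in a consistent length unit)."""

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        f = np.asarray(self.faces, dtype=int).reshape(-1, 3)
        if len(f) and (f.min() < 0 or f.max() >= len(v)):
            raise ValueError("face indices out of range")
        self.vertices, self.faces = v, f

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def _edge_counts(self) -> np.ndarray:
        if not len(self.faces):
            return np.empty(0, dtype=int)
        edges = np.sort(
            self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return counts

    def boundary_edge_count(self) -> int:
        """Open (odd-face-count) edges; 0 for a closed surface."""
        counts = self._edge_counts()
        return int(np.sum(counts % 2 != 0))

    @property
    def is_closed(self) -> bool:
        """Every edge shared by an even number of faces (volume well defined;
        alpha-shape boundaries may be pinched at an edge between regions)."""
        return len(self.faces) > 0 and self.boundary_edge_count() == 0

    @property
    def is_watertight(self) -> bool:
        """Closed and manifold: every edge shared by exactly two faces."""
        counts = self._edge_counts()
        return len(self.faces) > 0 and bool(np.all(counts == 2))

    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(vertices=self.vertices, faces=self.faces,
                                process=False)

    @classmethod
    def from_trimesh(cls, mesh: _trimesh.Trimesh, name: str = "") -> "TriMesh":
        return cls(vertices=np.asarray(mesh.vertices, dtype=float),
                   faces=np.asarray(mesh.faces, dtype=int), name=name)

    def transformed(self, transform) -> "TriMesh":
        """Apply a rigid transform (endocast.kinematics.RigidTransform)."""
        return TriMesh(vertices=transform.apply(self.vertices),
                       faces=self.faces.copy(), name=self.name)


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is None:
        fmt = str(path).rsplit(".", 1)[-1].lower()
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise MeshFormatError(f"unsupported mesh format '{fmt}' "
                              f"(supported: {sorted(_FORMATS)})")
    return fmt


def read_mesh(path, fmt: str | None = None) -> TriMesh:
    """Read an OBJ/STL/PLY mesh; non-triangular faces are fan-triangulated."""
    fmt = _infer_format(path, fmt)
    try:
        mesh = _trimesh.load(str(path), file_type=fmt, force="mesh",
                             process=False)
    except Exception as exc:
        raise MeshFormatError(f"could not parse {path} as {fmt}: {exc}") from exc
    if not isinstance(mesh, _trimesh.Trimesh) or len(mesh.faces) == 0:
        raise MeshFormatError(f"{path}: no triangular faces found")
    return TriMesh.from_trimesh(mesh, name=str(path))


def write_mesh(mesh: TriMesh, path, fmt: str | None = None) -> None:
    """Write a mesh to OBJ (ascii), STL (binary) or PLY (ascii)."""
    fmt = _infer_format(path, fmt)
    if mesh.n_faces == 0:
        raise ValueError(f"refusing to write empty mesh to {path}")
    tm = mesh.to_trimesh()
    try:
        if fmt == "ply":
            data = tm.export(file_type="ply", encoding="ascii")
        else:
            data = tm.export(file_type=fmt)
        mode = "wb" if isinstance(data, bytes) else "w"
        with open(path, mode) as fh:
            fh.write(data)
    except OSError as exc:
        raise OSError(f"failed writing mesh to {path}: {exc}") from exc


def closed_mesh_volume(mesh: TriMesh) -> float:
    """Divergence-theorem volume of a watertight mesh.

    Computes the signed sum of tetrahedra (origin, v1, v2, v3) over faces,
    sum v1 . (v2 x v3) / 6.  If the mesh is wound inward (negative signed
    volume) the absolute value is returned with a warning.

    Raises NotWatertightError when the mesh has open (odd-count) edges.
    """
    be = mesh.boundary_edge_count()
    if be or mesh.n_faces == 0:
        raise NotWatertightError(be, mesh.name)
    v1 = mesh.vertices[mesh.faces[:, 0]]
    v2 = mesh.vertices[mesh.faces[:, 1]]
    v3 = mesh.vertices[mesh.faces[:, 2]]
    signed = float(np.einsum("ij,ij->", v1, np.cross(v2, v3)) / 6.0)
    if signed < 0:
        warnings.warn(
            f"mesh '{mesh.name}' is oriented inward (signed volume "
            f"{signed:.6g}); returning |volume|", stacklevel=2)
        return -signed
    return signed


def cavity_volume_by_subtraction(surface: TriMesh, wrapped: TriMesh) -> float:
    """Gold-standard cavity volume: volume(wrapped) - volume(surface).

    ``wrapped`` must enclose the solid represented by ``surface`` plus the
    cavity; a negative difference means the inputs are swapped or invalid.
    """
    v_surface = closed_mesh_volume(surface)
    v_wrapped = closed_mesh_volume(wrapped)
    diff = v_wrapped - v_surface
    if diff < 0:
        raise ValueError(
            f"wrapped volume ({v_wrapped:.6g}) is smaller than surface volume "
            f"({v_surface:.6g}); inputs swapped or invalid")
    return diff


# ---------------------------------------------------------------------------
# CSV table formats
#
# markers:    bone,frame,marker,x,y,z
# locators:   locator,parent,x,y,z          (bone-local coordinates)
# RBTs:       bone,frame,m00..m33           (16 row-major matrix entries)
# framecloud: frame,locator,x,y,z           (world coordinates)
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"  # full round-trip precision, byte-stable


def _write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


def read_markers_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["bone", "frame", "marker", "x", "y", "z"], path)
    return df


def write_markers_csv(df: pd.DataFrame, path) -> None:
    _write_csv(df[["bone", "frame", "marker", "x", "y", "z"]], path)


def read_locators_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["locator", "parent", "x", "y", "z"], path)
    return df


def write_locators_csv(df: pd.DataFrame, path) -> None:
    _write_csv(df[["locator", "parent", "x", "y", "z"]], path)


_RBT_COLS = [f"m{i}{j}" for i in range(4) for j in range(4)]


def read_rbt_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["bone", "frame", *_RBT_COLS], path)
    return df


def write_rbt_csv(df: pd.DataFrame, path) -> None:
    _write_csv(df[["bone", "frame", *_RBT_COLS]], path)


def read_framecloud_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["frame", "locator", "x", "y", "z"], path)
    return df


def write_framecloud_csv(df: pd.DataFrame, path) -> None:
    _write_csv(df[["frame", "locator", "x", "y", "z"]], path)
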