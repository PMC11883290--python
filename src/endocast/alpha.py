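"""3D alpha complexes on Delaunay tetrahedralizations.

An alpha complex retains exactly those Delaunay tetrahedra whose
circumradius is at most the alpha value (the "alpha-radius" convention).
Alpha carries the same length unit as the input coordinates: with
coordinates in cm, volumes are in cm^3 = ml.  Small alpha gives a tight,
possibly fragmented wrap of the point cloud; as alpha grows the shape
monotonically approaches the convex hull.

All connected regions of the complex are kept and no holes are filled:
the volume is simply the sum of retained tetrahedron volumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay, QhullError

from .errors import DegenerateCloudError

__all__ = [
    "PointCloud3D",
    "TetraSet",
    "AlphaShapeResult",
    "tetrahedralize",
    "circumradius",
    "alpha_complex",
    "critical_alpha",
    "boundary_mesh",
]

#: tetrahedra with volume below this fraction of bbox_diagonal^3 are
#: treated as degenerate (circumradius +inf, never retained)
DEGENERATE_VOLUME_FACTOR = 1e-12

#: magnitude of the symbolic-perturbation jitter, as a fraction of the
#: bounding-box diagonal, applied only when the raw triangulation contains
#: degenerate simplices (e.g. co-spherical grid points)
JITTER_FACTOR = 1e-9

# fixed seed for the tie-break jitter: the perturbation is a deterministic
# part of the algorithm, not a source of randomness
_JITTER_SEED = 20407


@dataclass(frozen=True)
class PointCloud3D:
    """A labelled 3D point cloud (coordinates in one consistent length unit)."""

    points: np.ndarray
    ids: tuple[str, ...] | None = None

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (n, 3), got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("points contain non-finite coordinates")
        if self.ids is not None and len(self.ids) != len(pts):
            raise ValueError("ids length does not match point count")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)


def _as_points(cloud) -> np.ndarray:
    if isinstance(cloud, PointCloud3D):
        return cloud.points
    pts = np.asarray(cloud, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"expected (n, 3) coordinates, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points contain non-finite coordinates")
    return pts


@dataclass
class TetraSet:
    """A tetrahedralization of a point cloud with per-tetra circumradii.

    ``points`` are the *effective* coordinates used by the triangulation;
    they differ from the input only if the degeneracy-breaking jitter was
    applied (``jittered`` is then True).
    """

    points: np.ndarray          # (n, 3)
    simplices: np.ndarray       # (m, 4) vertex indices
    circumradii: np.ndarray     # (m,), +inf for degenerate tetrahedra
    volumes: np.ndarray         # (m,), unsigned
    jittered: bool = False

    def __len__(self) -> int:
        return len(self.simplices)

    @property
    def total_volume(self) -> float:
        return float(self.volumes[np.isfinite(self.circumradii)].sum())


def _tet_signed_volumes(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    a, b, c, d = (points[simplices[:, i]] for i in range(4))
    return np.einsum("ij,ij->i", b - a, np.cross(c - a, d - a)) / 6.0


def _degeneracy_tolerance(points: np.ndarray) -> float:
    diag = float(np.linalg.norm(points.max(axis=0) - points.min(axis=0)))
    return DEGENERATE_VOLUME_FACTOR * diag**3


def _circumradii(points: np.ndarray, simplices: np.ndarray,
                 volumes: np.ndarray, tol: float) -> np.ndarray:
    """Vectorized circumradius per tetrahedron; +inf below the volume tolerance.

    The circumcenter x solves 2 (v_i - v_0) . x = |v_i|^2 - |v_0|^2 for
    i = 1..3 (equidistance from all four vertices).
    """
    a = points[simplices[:, 0]]
    rows = np.stack([points[simplices[:, i]] - a for i in (1, 2, 3)], axis=1)
    rhs = np.stack(
        [
            np.einsum("ij,ij->i", points[simplices[:, i]] - a,
                      points[simplices[:, i]] + a)
            for i in (1, 2, 3)
        ],
        axis=1,
    ) / 2.0
    radii = np.full(len(simplices), np.inf)
    ok = volumes > tol
    if ok.any():
        centers = np.linalg.solve(rows[ok], rhs[ok][..., None])[..., 0]
        radii[ok] = np.linalg.norm(centers - a[ok], axis=1)
    return radii


def circumradius(tet: np.ndarray, tol: float | None = None) -> float:
    """Circumradius of a single tetrahedron given as four xyz points.

    Returns ``+inf`` for (near-)degenerate tetrahedra whose volume falls
    below ``tol`` (default: the bounding-box based tolerance).
    """
    pts = np.asarray(tet, dtype=float)
    if pts.shape != (4, 3):
        raise ValueError(f"expected four xyz points, got shape {pts.shape}")
    simplices = np.array([[0, 1, 2, 3]])
    vol = np.abs(_tet_signed_volumes(pts, simplices))
    if tol is None:
        tol = _degeneracy_tolerance(pts)
    return float(_circumradii(pts, simplices, vol, tol)[0])


def tetrahedralize(cloud) -> TetraSet:
    """Delaunay-tetrahedralize a point cloud.

    The union of the returned tetrahedra is the convex hull of the points.
    If the raw triangulation contains degenerate simplices (co-spherical or
    gridded inputs), the points are jittered by ``JITTER_FACTOR`` x the
    bounding-box diagonal with a fixed internal seed and re-triangulated, so
    results are deterministic and the complex carries no zero-volume slivers.

    Raises
    ------
    DegenerateCloudError
        For fewer than 4 points or an entirely coplanar/collinear cloud.
    """
    pts = _as_points(cloud)
    if len(pts) < 4:
        raise DegenerateCloudError(len(pts))
    tol = _degeneracy_tolerance(pts)

    def _build(p):
        tri = Delaunay(p)
        vols = np.abs(_tet_signed_volumes(p, tri.simplices))
        return tri.simplices.copy(), vols

    try:
        simplices, vols = _build(pts)
    except QhullError as exc:
        raise DegenerateCloudError(len(pts)) from exc

    jittered = False
    if np.any(vols <= tol):
        diag = float(np.linalg.norm(pts.max(axis=0) - pts.min(axis=0)))
        rng = np.random.default_rng(_JITTER_SEED)
        jpts = pts + rng.normal(scale=JITTER_FACTOR * diag, size=pts.shape)
        try:
            simplices, vols = _build(jpts)
        except QhullError as exc:  # pragma: no cover - extremely unlikely
            raise DegenerateCloudError(len(pts)) from exc
        pts = jpts
        jittered = True

    radii = _circumradii(pts, simplices, vols, tol)
    return TetraSet(points=pts, simplices=simplices, circumradii=radii,
                    volumes=vols, jittered=jittered)


@dataclass
class AlphaShapeResult:
    """Alpha complex of one point cloud at one alpha value."""

    alpha: float
    tetra: TetraSet | None
    retained: np.ndarray            # indices into tetra.simplices
    volume: float
    n_regions: int
    degenerate: bool = False
    _boundary: object = field(default=None, repr=False)

    @property
    def boundary(self):
        """Boundary TriMesh (computed lazily)."""
        if self._boundary is None:
            self._boundary = boundary_mesh(self)
        return self._boundary


def _count_regions(tetra: TetraSet, retained: np.ndarray) -> int:
    """Connected components of retained tetrahedra under shared-face adjacency."""
    if len(retained) == 0:
        return 0
    simp = tetra.simplices[retained]
    face_of = {}
    rows, cols = [], []
    for local, tet in enumerate(simp):
        for omit in range(4):
            face = tuple(sorted(np.delete(tet, omit)))
            other = face_of.pop(face, None)
            if other is None:
                face_of[face] = local
            else:
                rows.append(other)
                cols.append(local)
    n = len(simp)
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, _ = connected_components(adj, directed=False)
    return int(n_comp)


def alpha_complex(cloud, alpha: float) -> AlphaShapeResult:
    """Alpha complex: Delaunay tetrahedra with circumradius <= alpha.

    Volume is the sum of retained tetra volumes; all connected regions are
    kept.  A degenerate cloud yields a zero-volume result with a warning
    rather than an error (so a pipeline over many frames can continue).
    """
    if not alpha > 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    try:
        tetra = cloud if isinstance(cloud, TetraSet) else tetrahedralize(cloud)
    except DegenerateCloudError as exc:
        warnings.warn(f"degenerate cloud, recording zero volume ({exc})",
                      stacklevel=2)
        return AlphaShapeResult(alpha=float(alpha), tetra=None,
                                retained=np.empty(0, dtype=int), volume=0.0,
                                n_regions=0, degenerate=True)
    retained = np.flatnonzero(tetra.circumradii <= alpha)
    volume = float(tetra.volumes[retained].sum())
    return AlphaShapeResult(alpha=float(alpha), tetra=tetra, retained=retained,
                            volume=volume,
                            n_regions=_count_regions(tetra, retained))


def critical_alpha(cloud) -> float:
    """Smallest alpha at which every input point lies on the alpha shape.

    Searches the sorted distinct circumradius values of the Delaunay
    tetrahedra for the smallest radius r such that every point is a vertex
    of some tetrahedron with circumradius <= r.
    """
    tetra = cloud if isinstance(cloud, TetraSet) else tetrahedralize(cloud)
    finite = np.isfinite(tetra.circumradii)
    radii = tetra.circumradii[finite]
    simp = tetra.simplices[finite]
    # coverage is judged against the vertices the triangulation references:
    # exact duplicates merged by the triangulator coincide with a kept twin
    n_pts = len(np.unique(tetra.simplices))
    candidates = np.unique(radii)

    def covers(r: float) -> bool:
        keep = radii <= r
        return len(np.unique(simp[keep])) == n_pts

    lo, hi = 0, len(candidates) - 1
    if not covers(candidates[hi]):
        raise DegenerateCloudError(n_pts, "no alpha covers every point")
    while lo < hi:
        mid = (lo + hi) // 2
        if covers(candidates[mid]):
            hi = mid
        else:
            lo = mid + 1
    return float(candidates[lo])


def boundary_mesh(result: AlphaShapeResult):
    """Outward-oriented triangle boundary of the retained complex.

    A face belongs to the boundary iff it appears in exactly one retained
    tetrahedron; it is wound so its normal points away from that
    tetrahedron's opposite vertex.  Closed per connected region.
    """
    from .meshvol import TriMesh  # local import to avoid a cycle

    if result.tetra is None or len(result.retained) == 0:
        return TriMesh(vertices=np.empty((0, 3)), faces=np.empty((0, 3), dtype=int),
                       name=f"alpha_shape_a{result.alpha:g}")
    pts = result.tetra.points
    simp = result.tetra.simplices[result.retained]
    seen: dict[tuple, tuple] = {}
    for tet in simp:
        for omit in range(4):
            tri = np.delete(tet, omit)
            key = tuple(sorted(tri))
            if key in seen:
                seen[key] = None  # interior: shared by two tetrahedra
            else:
                seen[key] = (tri, tet[omit])
    faces = []
    for entry in seen.values():
        if entry is None:
            continue
        (i, j, k), opp = entry
        a, b, c, d = pts[i], pts[j], pts[k], pts[opp]
        # outward: normal must point away from the opposite vertex
        if np.dot(np.cross(b - a, c - a), d - a) > 0:
            i, j = j, i
        faces.append((i, j, k))
    faces = np.asarray(faces, dtype=int).reshape(-1, 3)
    used = np.unique(faces)
    remap = np.full(len(pts), -1, dtype=int)
    remap[used] = np.arange(len(used))
    return TriMesh(vertices=pts[used], faces=remap[faces],
                   name=f"alpha_shape_a{result.alpha:g}")
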