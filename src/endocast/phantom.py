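"""Synthetic expanding-cavity phantom with analytic ground truth.

The phantom is a hinged wedge: plate A is fixed in the z = 0 plane, plate B
shares a hinge with it along the x-axis and rotates open by an angle theta.
The cavity ("envelope") bounded by the two plates and planar end caps is a
triangular prism of volume

    V_env(theta) = 1/2 * L * W^2 * sin(theta)

with L the hinge length and W the plate width (cm; volumes in ml).  The
phantom emulates a specimen CT-scanned in a pseudo time series of poses
from closed to fully expanded:

* rigid plates carry >= 3 implanted markers each, optionally observed with
  Gaussian noise, from which per-pose rigid body transforms are estimated;
* an incompressible "tissue" wedge of volume T is attached inside plate A —
  endocast locators sit on the bone surfaces, so the endocast encloses this
  tissue (it inflates absolute volume but not volume change);
* an analytic "pocket" term models air the endocast cannot see (the analog
  of the space under the branchiostegal rays): it grows with expansion as
  pocket(theta) = c * (V_env(theta) - V_env(theta_min)).

The true (gold-standard) air volume is A = V_env - T + pocket.  Because an
ideal endocast measures V_env, regressing endocast volume on A gives

    slope = 1 / (1 + c),   intercept = (T + c * V_env(theta_min)) / (1 + c)

which is the accuracy law the validation suite tests against.

A concave variant (``cap_depth > 0``) replaces the planar front cap with a
cylindrical surface bulging inward; soft-tissue locators ride that cap, and
a "cap bone" mesh occupies the bulge so that over-large alpha values make
the endocast bridge the concavity and interpenetrate it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import alpha as _alpha
from .errors import PhantomSpecError
from .kinematics import (FrameCloud, LocatorSet, RigidTransform,
                         animate_locators, attach_locators, estimate_rbt)
from .meshvol import TriMesh

__all__ = [
    "PhantomSpec",
    "PhantomFrame",
    "PhantomScene",
    "PhantomTruth",
    "build_phantom",
    "phantom_truth",
    "phantom_pose_series",
    "envelope_volume",
]

PLATE_A = "plate_a"
PLATE_B = "plate_b"


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for the synthetic phantom.

    Defaults emulate the validation experiment's scale: seven poses from
    closed to fully expanded, envelope volumes in the tens of ml, enclosed
    tissue of 29.4 ml, a pocket coefficient of 0.1173 (accuracy law slope
    1/(1+c) = 0.895), and sub-0.1 mm marker observation noise.
    """

    L: float = 10.0                 # hinge length, cm
    W: float = 5.5                  # plate width, cm
    theta_min: float = math.radians(17.0)
    theta_max: float = math.radians(57.5)
    n_frames: int = 7
    tissue_volume: float = 29.4     # ml
    pocket_coeff: float = 0.1173    # dimensionless, >= 0
    markers_per_plate: int = 4
    marker_noise_sd: float = 0.005  # cm, per coordinate
    seed: int = 0
    plate_thickness: float = 0.4    # cm
    tissue_width_frac: float = 0.95
    cap_depth: float = 0.0          # sagitta / chord; > 0 -> concave variant
    cap_arc_segments: int = 16
    grid_nx: int = 25               # locator candidate grid per plate
    grid_ny: int = 14

    def __post_init__(self):
        if not (0 < self.theta_min < self.theta_max < math.radians(150)):
            raise PhantomSpecError(
                "need 0 < theta_min < theta_max < 150 degrees")
        if self.L <= 0 or self.W <= 0:
            raise PhantomSpecError("plate dimensions must be positive")
        if self.pocket_coeff < 0:
            raise PhantomSpecError("pocket_coeff must be >= 0")
        if self.markers_per_plate < 3:
            raise PhantomSpecError("need >= 3 markers per plate")
        if self.n_frames < 2:
            raise PhantomSpecError("need >= 2 frames")
        if self.marker_noise_sd < 0:
            raise PhantomSpecError("marker_noise_sd must be >= 0")
        if not (0 <= self.cap_depth < 0.4):
            raise PhantomSpecError("cap_depth must be in [0, 0.4)")
        v_min = envelope_volume(self, self.theta_min)
        if not (0 <= self.tissue_volume < v_min):
            raise PhantomSpecError(
                f"tissue volume {self.tissue_volume} ml does not fit the "
                f"closed envelope ({v_min:.3f} ml at theta_min)")
        # tissue wedge feasibility (see _tissue_wedge)
        if self.tissue_volume > 0:
            w_t = self.tissue_width_frac * self.W
            if w_t > 0.99 * self.W * math.cos(self.theta_min / 2):
                raise PhantomSpecError(
                    "tissue wedge too wide for the closed pose")
            s = 2 * self.tissue_volume / (self.L * w_t**2)
            if s >= math.sin(0.97 * self.theta_min):
                raise PhantomSpecError(
                    "tissue volume infeasible: wedge would exit the cavity "
                    "at theta_min")

    @property
    def thetas(self) -> np.ndarray:
        return np.linspace(self.theta_min, self.theta_max, self.n_frames)


def _cap_polygon(spec: PhantomSpec, theta: float) -> np.ndarray:
    """Sampled inward-bulging arc from (W, 0) to W*(cos t, sin t), in (y, z)."""
    W, d = spec.W, spec.cap_depth
    a = np.array([W, 0.0])
    b = np.array([W * math.cos(theta), W * math.sin(theta)])
    chord = np.linalg.norm(b - a)
    s = d * chord
    mid = (a + b) / 2
    inward = -mid / np.linalg.norm(mid)
    # circle through a, b with sagitta s toward the hinge
    R = (chord**2 / 4 + s**2) / (2 * s)
    center = mid + inward * (s - R)
    phi_a = math.atan2(*(a - center)[::-1])
    phi_b = math.atan2(*(b - center)[::-1])
    # shorter arc from a to b
    dphi = (phi_b - phi_a + math.pi) % (2 * math.pi) - math.pi
    phis = phi_a + dphi * np.linspace(0, 1, spec.cap_arc_segments + 1)
    return center + R * np.stack([np.cos(phis), np.sin(phis)], axis=1)


def _envelope_polygon(spec: PhantomSpec, theta: float) -> np.ndarray:
    """CCW cavity cross-section in the (y, z) plane."""
    if spec.cap_depth > 0:
        arc = _cap_polygon(spec, theta)
        return np.vstack([[0.0, 0.0], arc])
    return np.array([
        [0.0, 0.0],
        [spec.W, 0.0],
        [spec.W * math.cos(theta), spec.W * math.sin(theta)],
    ])


def _polygon_area(poly: np.ndarray) -> float:
    y, z = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.dot(y, np.roll(z, -1)) - np.dot(z, np.roll(y, -1)))


def _prism_mesh(poly: np.ndarray, x0: float, x1: float, name: str) -> TriMesh:
    """Extrude a CCW simple polygon in the (y, z) plane along x. Watertight."""
    k = len(poly)
    verts = np.empty((2 * k, 3))
    verts[:k, 0] = x0
    verts[k:, 0] = x1
    verts[:k, 1:] = poly
    verts[k:, 1:] = poly
    faces = []
    for i in range(1, k - 1):          # caps (fans; polygon must be convex)
        faces.append((0, i + 1, i))            # x0 cap, normal -x
        faces.append((k, k + i, k + i + 1))    # x1 cap, normal +x
    for i in range(k):                  # sides
        j = (i + 1) % k
        faces.append((i, j, k + j))
        faces.append((i, k + j, k + i))
    mesh = TriMesh(vertices=verts, faces=np.asarray(faces, dtype=int),
                   name=name)
    return mesh


def envelope_volume(spec: PhantomSpec, theta: float) -> float:
    """Analytic cavity volume at opening angle theta (ml).

    Planar cap: exactly 1/2 * L * W^2 * sin(theta).  Concave variant:
    the prism volume minus the (polygonal) bulge segment, computed from the
    same sampled arc used to build the meshes, so truth and geometry agree
    exactly.
    """
    if spec.cap_depth > 0:
        return spec.L * _polygon_area(_envelope_polygon(spec, theta))
    return 0.5 * spec.L * spec.W**2 * math.sin(theta)


@dataclass(frozen=True)
class PhantomTruth:
    V_env: float    # envelope (endocast-visible) volume, ml
    A: float        # true air volume (gold standard), ml
    pocket: float   # uncovered pocket air, ml
    T: float        # enclosed tissue volume, ml


def phantom_truth(spec: PhantomSpec, theta: float) -> PhantomTruth:
    """Closed-form ground truth at one pose: A = V_env - T + pocket."""
    if not (spec.theta_min - 1e-12 <= theta <= spec.theta_max + 1e-12):
        raise ValueError(
            f"theta {theta:.4f} outside [{spec.theta_min:.4f}, "
            f"{spec.theta_max:.4f}]")
    v_env = envelope_volume(spec, theta)
    pocket = spec.pocket_coeff * (v_env - envelope_volume(spec, spec.theta_min))
    return PhantomTruth(V_env=v_env, A=v_env - spec.tissue_volume + pocket,
                        pocket=pocket, T=spec.tissue_volume)


def _tissue_wedge(spec: PhantomSpec) -> TriMesh | None:
    """Tissue body: a wedge prism sharing the hinge, attached to plate A.

    Volume 1/2 * L * W_t^2 * sin(theta_t) == tissue_volume exactly, with
    theta_t < theta_min so the body stays enclosed in every pose.
    """
    if spec.tissue_volume == 0:
        return None
    w_t = spec.tissue_width_frac * spec.W
    theta_t = math.asin(2 * spec.tissue_volume / (spec.L * w_t**2))
    poly = np.array([
        [0.0, 0.0],
        [w_t, 0.0],
        [w_t * math.cos(theta_t), w_t * math.sin(theta_t)],
    ])
    return _prism_mesh(poly, 0.0, spec.L, "tissue")


def _marker_layout(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Marker sites on a plate's inner face (local z = 0), non-collinear."""
    m = 0.08 * min(spec.L, spec.W)
    corners = np.array([
        [m, m, 0.0],
        [spec.L - m, m, 0.0],
        [spec.L - m, spec.W - m, 0.0],
        [m, spec.W - m, 0.0],
    ])
    n = spec.markers_per_plate
    if n <= 4:
        return corners[:n]
    extra = np.column_stack([
        rng.uniform(m, spec.L - m, n - 4),
        rng.uniform(m, spec.W - m, n - 4),
        np.zeros(n - 4),
    ])
    return np.vstack([corners, extra])


def _inner_face_mesh(spec: PhantomSpec, name: str,
                     rng: np.random.Generator) -> TriMesh:
    """Triangulated candidate sites on a plate's inner face (local z = 0).

    A jittered grid: interior nodes are perturbed in-plane, edge nodes only
    along their edge, and the four corners are pinned (so the plate's full
    extent stays reachable).  The perturbation emulates hand placement and
    avoids the co-circular degeneracies of an exact lattice; every site
    remains exactly on the plate surface.
    """
    xs = np.linspace(0.0, spec.L, spec.grid_nx)
    ys = np.linspace(0.0, spec.W, spec.grid_ny)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    jx = 0.25 * (xs[1] - xs[0]) * rng.uniform(-1, 1, xx.shape)
    jy = 0.25 * (ys[1] - ys[0]) * rng.uniform(-1, 1, yy.shape)
    jx[0, :] = jx[-1, :] = 0.0    # pin x on the x-extreme edges
    jy[:, 0] = jy[:, -1] = 0.0    # pin y on the y-extreme edges
    xx = xx + jx
    yy = yy + jy
    verts = np.column_stack([xx.ravel(), yy.ravel(),
                             np.zeros(xx.size)])
    faces = []
    ny = spec.grid_ny
    for i in range(spec.grid_nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            faces.append((a, a + ny, a + ny + 1))
            faces.append((a, a + ny + 1, a + 1))
    return TriMesh(vertices=verts, faces=np.asarray(faces, dtype=int),
                   name=name)


def _plate_transform(theta_rel: float) -> RigidTransform:
    """Rotation of plate B about the hinge (x-axis) by theta."""
    c, s = math.cos(theta_rel), math.sin(theta_rel)
    R = np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])
    return RigidTransform.from_rt(R, np.zeros(3))


@dataclass
class PhantomFrame:
    """One pose of the phantom (one pseudo-time step)."""

    index: int
    theta: float
    transforms: dict            # bone -> true RigidTransform
    markers: dict               # bone -> (m, 3) observed (noisy) world xyz
    V_env: float
    A: float
    pocket: float
    envelope_mesh: TriMesh


@dataclass
class PhantomScene:
    """Static phantom scene plus its pose series and pipeline helpers."""

    spec: PhantomSpec
    plates: dict                    # bone -> slab TriMesh, bone-local coords
    inner_faces: dict               # bone -> candidate-surface TriMesh
    marker_local: dict              # bone -> (m, 3) bone-local marker sites
    tissue: TriMesh | None
    frames: list = field(default_factory=list)

    # -- construction helpers -------------------------------------------------

    def locator_set(self, n: int, seed: int | None = None,
                    strategy: str = "farthest-point",
                    alpha: float | None = None,
                    n_candidates: int = 1) -> LocatorSet:
        """n locators split evenly across the two plate inner faces.

        Placement per count is an independent draw (sets for different n
        are not subsets of one another).  With ``n_candidates > 1`` and an
        ``alpha`` value given, placement is *strategic*: several
        independent candidate placements are drawn and the one with the
        best worst-frame endocast fit (per-pose volume relative to the
        best candidate at that pose) is kept — the automated analog of
        hand-placing locators and visually checking the endocast fit in
        every frame.
        """
        if n < 4:
            raise ValueError("need at least 4 locators for a 3D shape")
        seed = self.spec.seed if seed is None else seed
        if n_candidates > 1 and alpha is None:
            raise ValueError("strategic placement needs the alpha value "
                             "used to judge endocast fit")

        def draw(sub_seed: int) -> LocatorSet:
            n_b = n // 2
            n_a = n - n_b
            set_a = attach_locators(self.inner_faces[PLATE_A], n_a,
                                    strategy=strategy, seed=2 * sub_seed,
                                    parent=PLATE_A)
            set_b = attach_locators(self.inner_faces[PLATE_B], n_b,
                                    strategy=strategy, seed=2 * sub_seed + 1,
                                    parent=PLATE_B)
            return LocatorSet.concat([set_a, set_b])

        if n_candidates <= 1:
            return draw(seed)
        candidates = [draw(seed * 97 + j) for j in range(n_candidates)]
        per_pose = np.array([self.endocast_volumes(locs, alpha)
                             for locs in candidates])
        best_per_pose = per_pose.max(axis=0)
        best_per_pose[best_per_pose == 0] = np.inf
        worst_frame_fit = (per_pose / best_per_pose).min(axis=1)
        return candidates[int(np.argmax(worst_frame_fit))]

    def dense_locator_set(self) -> LocatorSet:
        """Every candidate-grid vertex on both plates (the plateau limit)."""
        sets = []
        for bone in (PLATE_A, PLATE_B):
            verts = self.inner_faces[bone].vertices
            ids = tuple(f"{bone}_dense{i:04d}" for i in range(len(verts)))
            sets.append(LocatorSet(ids=ids, parents=(bone,) * len(verts),
                                   local=verts))
        return LocatorSet.concat(sets)

    # -- kinematics ------------------------------------------------------------

    def estimated_transforms(self) -> dict:
        """Per-bone RBTs estimated from the (noisy) marker observations."""
        out = {}
        for bone in (PLATE_A, PLATE_B):
            ref = self.marker_local[bone]
            out[bone] = [estimate_rbt(ref, fr.markers[bone])
                         for fr in self.frames]
        return out

    def true_transforms(self) -> dict:
        return {bone: [fr.transforms[bone] for fr in self.frames]
                for bone in (PLATE_A, PLATE_B)}

    def frame_cloud(self, locators: LocatorSet,
                    use_estimated_rbt: bool = True) -> FrameCloud:
        transforms = (self.estimated_transforms() if use_estimated_rbt
                      else self.true_transforms())
        cloud = animate_locators(locators, transforms)
        if self.spec.cap_depth > 0:
            cloud = self._append_cap_locators(cloud)
        return cloud

    def _append_cap_locators(self, cloud: FrameCloud) -> FrameCloud:
        """Soft-tissue locators riding the deforming concave cap surface."""
        spec = self.spec
        xs = np.linspace(0.0, spec.L, max(spec.grid_nx // 2, 4))
        coords = []
        for fr in self.frames:
            arc = _cap_polygon(spec, fr.theta)
            pts = np.concatenate([
                np.column_stack([np.full(len(arc), x), arc]) for x in xs])
            coords.append(pts)
        coords = np.stack(coords)
        n_cap = coords.shape[1]
        ids = cloud.ids + tuple(f"cap_loc{i:03d}" for i in range(n_cap))
        return FrameCloud(frames=cloud.frames, times=cloud.times, ids=ids,
                          coords=np.concatenate([cloud.coords, coords],
                                                axis=1))

    # -- validation-facing interface ------------------------------------------

    def gold_volumes(self) -> np.ndarray:
        """True air volumes A per pose (the gold standard), ml."""
        return np.array([fr.A for fr in self.frames])

    def envelope_volumes(self) -> np.ndarray:
        return np.array([fr.V_env for fr in self.frames])

    def endocast_volumes(self, locators: LocatorSet, alpha_value: float,
                         use_estimated_rbt: bool = True) -> np.ndarray:
        """Per-pose alpha-shape volumes for one locator set, ml."""
        cloud = self.frame_cloud(locators, use_estimated_rbt=use_estimated_rbt)
        return np.array([
            _alpha.alpha_complex(cloud.coords[f], alpha_value).volume
            for f in range(cloud.n_frames)
        ])

    def critical_alpha(self, locators: LocatorSet,
                       use_estimated_rbt: bool = True) -> float:
        """Largest per-pose critical alpha over the series."""
        cloud = self.frame_cloud(locators, use_estimated_rbt=use_estimated_rbt)
        return max(_alpha.critical_alpha(cloud.coords[f])
                   for f in range(cloud.n_frames))

    def cap_bulge_mesh(self, theta: float) -> TriMesh:
        """The 'cap bone' occupying the concave bulge at a given pose."""
        if self.spec.cap_depth <= 0:
            raise ValueError("planar-cap phantom has no bulge region")
        # the arc polyline closed by its chord bounds the segment region
        poly = _cap_polygon(self.spec, theta)
        if _polygon_area(poly) < 0:
            poly = poly[::-1]
        return _prism_mesh(poly, 0.0, self.spec.L, "cap_bone")

    def gold_standard_meshes(self, frame: PhantomFrame):
        """(surface, wrapped) meshes whose subtraction gives the pocketless
        air volume V_env - T: surface = tissue solid, wrapped = envelope."""
        if self.tissue is None:
            raise ValueError("phantom has no tissue body")
        return self.tissue, frame.envelope_mesh


def build_phantom(spec: PhantomSpec) -> PhantomScene:
    """Construct the static scene: plate slabs, marker sites, candidate
    surfaces and the tissue body.  Deterministic given spec.seed."""
    rng = np.random.default_rng([int(spec.seed), 101])
    plate_a_poly = np.array([[0.0, -spec.plate_thickness],
                             [spec.W, -spec.plate_thickness],
                             [spec.W, 0.0], [0.0, 0.0]])
    plate_b_poly = np.array([[0.0, 0.0], [spec.W, 0.0],
                             [spec.W, spec.plate_thickness],
                             [0.0, spec.plate_thickness]])
    plates = {
        PLATE_A: _prism_mesh(plate_a_poly, 0.0, spec.L, PLATE_A),
        PLATE_B: _prism_mesh(plate_b_poly, 0.0, spec.L, PLATE_B),
    }
    marker_local = {
        PLATE_A: _marker_layout(spec, rng),
        PLATE_B: _marker_layout(spec, rng),
    }
    inner_faces = {
        PLATE_A: _inner_face_mesh(spec, f"{PLATE_A}_inner", rng),
        PLATE_B: _inner_face_mesh(spec, f"{PLATE_B}_inner", rng),
    }
    return PhantomScene(spec=spec, plates=plates, inner_faces=inner_faces,
                        marker_local=marker_local, tissue=_tissue_wedge(spec))


def phantom_pose_series(spec: PhantomSpec,
                        scene: PhantomScene | None = None) -> PhantomScene:
    """Build the pose series: equally spaced opening angles, noisy markers,
    watertight envelope meshes, analytic truth per pose."""
    if scene is None:
        scene = build_phantom(spec)
    rng = np.random.default_rng([int(spec.seed), 202])
    scene.frames = []
    for i, theta in enumerate(spec.thetas):
        transforms = {PLATE_A: RigidTransform.identity(),
                      PLATE_B: _plate_transform(theta)}
        markers = {}
        for bone in (PLATE_A, PLATE_B):
            world = transforms[bone].apply(scene.marker_local[bone])
            if spec.marker_noise_sd > 0:
                world = world + rng.normal(scale=spec.marker_noise_sd,
                                           size=world.shape)
            markers[bone] = world
        truth = phantom_truth(spec, theta)
        env_mesh = _prism_mesh(_envelope_polygon(spec, theta), 0.0, spec.L,
                               f"envelope_{i:03d}")
        scene.frames.append(PhantomFrame(
            index=i, theta=float(theta), transforms=transforms,
            markers=markers, V_env=truth.V_env, A=truth.A,
            pocket=truth.pocket, envelope_mesh=env_mesh))
    return scene
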