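"""Rigid-body kinematics: marker-based transform estimation and locator animation.

A rigid body transform (RBT) maps bone-local coordinates to world
coordinates, world = R @ local + t, with R a proper rotation (right-handed
coordinates, column-vector convention).  RBTs are estimated per frame from
>= 3 non-collinear bone markers by the least-squares (Kabsch/Umeyama,
rotation-only) fit, with the standard reflection correction.

Locators are virtual landmarks expressed in bone-local coordinates; they
inherit their parent bone's RBT when animated.  Locators parented to a
static reference (e.g. the midsagittal plane) use the identity transform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import UnderdeterminedError
from .meshvol import TriMesh, _RBT_COLS

__all__ = [
    "RigidTransform",
    "MarkerSet",
    "LocatorSet",
    "FrameCloud",
    "estimate_rbt",
    "apply_transform",
    "attach_locators",
    "plane_locators",
    "animate_locators",
]

STATIC_PARENT = "midsagittal-plane"
_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """4x4 homogeneous rigid transform (proper rotation + translation)."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"expected 4x4 matrix, got {m.shape}")
        if not np.allclose(m[3], [0, 0, 0, 1], atol=_ORTHO_TOL):
            raise ValueError("last row must be (0, 0, 0, 1)")
        R = m[:3, :3]
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation block is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation block is a reflection (det = -1)")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rt(cls, R: np.ndarray, t: np.ndarray) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = np.asarray(t, dtype=float)
        return cls(m)

    @property
    def R(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def t(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.R.T + self.t

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self @ other).apply(p) == self.apply(other.apply(p))."""
        return RigidTransform(self.matrix @ other.matrix)

    __matmul__ = compose

    def inverse(self) -> "RigidTransform":
        return RigidTransform.from_rt(self.R.T, -self.R.T @ self.t)


@dataclass
class MarkerSet:
    """Reference-pose and per-frame observed marker coordinates for one bone."""

    bone: str
    reference: np.ndarray       # (m, 3) bone-local / reference pose
    observed: np.ndarray        # (f, m, 3) per frame

    def __post_init__(self):
        self.reference = np.asarray(self.reference, dtype=float).reshape(-1, 3)
        obs = np.asarray(self.observed, dtype=float)
        if obs.ndim != 3 or obs.shape[1:] != self.reference.shape:
            raise ValueError("observed must be (n_frames, n_markers, 3) "
                             "matching the reference markers")
        _check_noncollinear(self.reference, self.bone)
        self.observed = obs

    @property
    def n_frames(self) -> int:
        return len(self.observed)

    def transforms(self) -> list[RigidTransform]:
        return [estimate_rbt(self.reference, obs) for obs in self.observed]


def _check_noncollinear(markers: np.ndarray, label: str = "") -> None:
    if len(markers) < 3:
        raise UnderdeterminedError(
            f"need >= 3 markers{' for ' + label if label else ''}, "
            f"got {len(markers)}")
    centered = markers - markers.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-10 *
                             max(1.0, np.abs(markers).max())) < 2:
        raise UnderdeterminedError(
            f"markers{' for ' + label if label else ''} are collinear")


def estimate_rbt(reference: np.ndarray, observed: np.ndarray) -> RigidTransform:
    """Least-squares rigid fit mapping reference markers onto observed ones.

    Centroid alignment plus SVD rotation solve; if the optimal orthogonal
    matrix is a reflection, the singular direction with the smallest
    singular value is flipped (standard proper-rotation correction).
    Minimizes the RMSD between transformed reference and observed markers.
    """
    ref = np.asarray(reference, dtype=float).reshape(-1, 3)
    obs = np.asarray(observed, dtype=float).reshape(-1, 3)
    if ref.shape != obs.shape:
        raise ValueError("reference/observed marker counts differ")
    _check_noncollinear(ref)
    ref_c, obs_c = ref.mean(axis=0), obs.mean(axis=0)
    H = (ref - ref_c).T @ (obs - obs_c)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = obs_c - R @ ref_c
    return RigidTransform.from_rt(R, t)


def apply_transform(T: RigidTransform, points: np.ndarray) -> np.ndarray:
    """world = R @ local + t for each point (pairwise distances preserved)."""
    return T.apply(points)


def rmsd(T: RigidTransform, reference: np.ndarray, observed: np.ndarray) -> float:
    diff = T.apply(reference) - np.asarray(observed, dtype=float)
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


@dataclass
class LocatorSet:
    """Locators in bone-local coordinates, each parented to a bone (or the
    static midsagittal plane)."""

    ids: tuple[str, ...]
    parents: tuple[str, ...]
    local: np.ndarray           # (n, 3)

    def __post_init__(self):
        self.local = np.asarray(self.local, dtype=float).reshape(-1, 3)
        if not (len(self.ids) == len(self.parents) == len(self.local)):
            raise ValueError("ids, parents and coordinates must align")
        if len(self.local) == 0:
            raise ValueError("empty locator set")
        if not np.all(np.isfinite(self.local)):
            raise ValueError("locator coordinates must be finite")

    def __len__(self) -> int:
        return len(self.local)

    @classmethod
    def concat(cls, sets: Sequence["LocatorSet"]) -> "LocatorSet":
        return cls(ids=tuple(i for s in sets for i in s.ids),
                   parents=tuple(p for s in sets for p in s.parents),
                   local=np.vstack([s.local for s in sets]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"locator": self.ids, "parent": self.parents,
                             "x": self.local[:, 0], "y": self.local[:, 1],
                             "z": self.local[:, 2]})


@dataclass
class FrameCloud:
    """World-space coordinates of every locator in every frame."""

    frames: np.ndarray          # (f,) frame indices
    times: np.ndarray           # (f,) seconds, or pseudo-time steps
    ids: tuple[str, ...]
    coords: np.ndarray          # (f, n, 3)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (n_frames, n_locators, 3)")
        if not (len(self.frames) == len(self.times) == len(self.coords)):
            raise ValueError("frame axis lengths disagree")
        if self.coords.shape[1] != len(self.ids):
            raise ValueError("locator axis does not match ids")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("missing/non-finite locator coordinates")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def to_frame(self) -> pd.DataFrame:
        f, n, _ = self.coords.shape
        return pd.DataFrame({
            "frame": np.repeat(self.frames, n),
            "locator": np.tile(np.asarray(self.ids, dtype=object), f),
            "x": self.coords[:, :, 0].ravel(),
            "y": self.coords[:, :, 1].ravel(),
            "z": self.coords[:, :, 2].ravel(),
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame, frame_rate: float | None = None):
        frames = np.sort(df["frame"].unique())
        ids = tuple(df.loc[df["frame"] == frames[0], "locator"])
        coords = np.empty((len(frames), len(ids), 3))
        for i, f in enumerate(frames):
            sub = df[df["frame"] == f].set_index("locator").loc[list(ids)]
            coords[i] = sub[["x", "y", "z"]].to_numpy()
        dt = 1.0 / frame_rate if frame_rate else 1.0
        return cls(frames=frames, times=frames * dt, ids=ids, coords=coords)


def attach_locators(mesh: TriMesh, n: int, strategy: str = "farthest-point",
                    seed: int = 0, parent: str = "bone") -> LocatorSet:
    """Place n locators on a bone mesh surface (bone-local coordinates).

    Strategies
    ----------
    ``vertex-subset``
        Uniform random sample of distinct mesh vertices.
    ``farthest-point``
        Greedy farthest-point sampling over the mesh vertices from a
        seeded random start — spreads locators evenly over the surface.

    Draws for different n are independent (sets for a smaller n are not
    subsets of those for a larger n), mirroring hand placement done
    separately per locator count.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    candidates = np.unique(np.asarray(mesh.vertices, dtype=float), axis=0)
    if len(candidates) == 0:
        raise ValueError("mesh has no vertices")
    rng = np.random.default_rng([int(seed), int(n)])
    if strategy == "vertex-subset":
        if n > len(candidates):
            raise ValueError(
                f"n={n} exceeds {len(candidates)} candidate vertices")
        idx = rng.choice(len(candidates), size=n, replace=False)
        chosen = candidates[np.sort(idx)]
    elif strategy == "farthest-point":
        if n > len(candidates):
            raise ValueError(
                f"n={n} exceeds {len(candidates)} candidate vertices")
        chosen_idx = [int(rng.integers(len(candidates)))]
        d = np.linalg.norm(candidates - candidates[chosen_idx[0]], axis=1)
        for _ in range(1, n):
            nxt = int(np.argmax(d))
            chosen_idx.append(nxt)
            d = np.minimum(d, np.linalg.norm(candidates - candidates[nxt],
                                             axis=1))
        chosen = candidates[chosen_idx]
    else:
        raise ValueError(f"unknown strategy '{strategy}'")
    ids = tuple(f"{parent}_loc{i:03d}" for i in range(n))
    return LocatorSet(ids=ids, parents=(parent,) * n, local=chosen)


def plane_locators(origin, normal, extent, grid, parent: str = STATIC_PARENT
                   ) -> LocatorSet:
    """Rectangular grid of locators on a plane (e.g. the midsagittal plane).

    ``extent`` is ((umin, umax), (vmin, vmax)) in the plane's in-plane axes,
    ``grid`` is (nu, nv).  The plane is static unless its parent name is a
    bone with transforms at animation time.
    """
    origin = np.asarray(origin, dtype=float)
    normal = np.asarray(normal, dtype=float)
    nn = np.linalg.norm(normal)
    if nn == 0:
        raise ValueError("plane normal must be non-zero")
    n_hat = normal / nn
    (umin, umax), (vmin, vmax) = extent
    nu, nv = grid
    if umax <= umin or vmax <= vmin:
        raise ValueError("zero-area plane extent")
    if nu < 1 or nv < 1:
        raise ValueError("grid counts must be >= 1")
    # build an orthonormal in-plane basis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(n_hat @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u_hat = np.cross(n_hat, helper)
    u_hat /= np.linalg.norm(u_hat)
    v_hat = np.cross(n_hat, u_hat)
    us = np.linspace(umin, umax, nu)
    vs = np.linspace(vmin, vmax, nv)
    uu, vv = np.meshgrid(us, vs, indexing="ij")
    pts = origin + uu.ravel()[:, None] * u_hat + vv.ravel()[:, None] * v_hat
    ids = tuple(f"{parent}_grid{i:03d}" for i in range(len(pts)))
    return LocatorSet(ids=ids, parents=(parent,) * len(pts), local=pts)


def animate_locators(locators: LocatorSet,
                     transforms: Mapping[str, Sequence[RigidTransform]],
                     times: np.ndarray | None = None) -> FrameCloud:
    """Animate locators through per-bone per-frame transforms.

    Parents absent from ``transforms`` are static (identity) — this is how
    midsagittal-plane locators stay put.  A parent present in the table but
    lacking a transform for some frame raises, naming bone and frame.
    """
    lengths = {len(seq) for seq in transforms.values()}
    if len(lengths) > 1:
        raise ValueError(f"bones have differing frame counts: {sorted(lengths)}")
    n_frames = lengths.pop() if lengths else 1
    for bone, seq in transforms.items():
        for f, T in enumerate(seq):
            if T is None:
                raise ValueError(f"missing transform for bone '{bone}' "
                                 f"at frame {f}")
    coords = np.empty((n_frames, len(locators), 3))
    parents = np.asarray(locators.parents, dtype=object)
    for parent in np.unique(parents):
        mask = parents == parent
        local = locators.local[mask]
        seq = transforms.get(parent)
        for f in range(n_frames):
            T = RigidTransform.identity() if seq is None else seq[f]
            coords[f, mask] = T.apply(local)
    frames = np.arange(n_frames)
    if times is None:
        times = frames.astype(float)
    return FrameCloud(frames=frames, times=times, ids=locators.ids,
                      coords=coords)


def transforms_to_frame(transforms: Mapping[str, Sequence[RigidTransform]]
                        ) -> pd.DataFrame:
    rows = []
    for bone, seq in transforms.items():
        for f, T in enumerate(seq):
            rows.append({"bone": bone, "frame": f,
                         **dict(zip(_RBT_COLS, T.matrix.ravel()))})
    return pd.DataFrame(rows)


def transforms_from_frame(df: pd.DataFrame
                          ) -> dict[str, list[RigidTransform]]:
    out: dict[str, list[RigidTransform]] = {}
    for bone, sub in df.groupby("bone", sort=False):
        sub = sub.sort_values("frame")
        expected = np.arange(len(sub))
        got = sub["frame"].to_numpy()
        if not np.array_equal(got, expected):
            missing = sorted(set(expected) - set(got))
            frame = missing[0] if missing else int(got[0])
            raise ValueError(f"missing transform for bone '{bone}' "
                             f"at frame {frame}")
        out[str(bone)] = [
            RigidTransform(np.asarray(row[_RBT_COLS], dtype=float).reshape(4, 4))
            for _, row in sub.iterrows()
        ]
    return out
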