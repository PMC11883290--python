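"""Endocast pipeline: frame clouds -> volume time series -> rate of change.

Per frame, the locator cloud is wrapped in an alpha shape at the configured
alpha value; the unilateral volume is doubled when the cavity is measured
on one side of a symmetry plane (bilateral doubling).  The volume series is
optionally low-pass filtered (zero-phase, forward-backward) before central
differencing, since differentiation amplifies noise.  Frames whose clouds
are degenerate are flagged and recorded as missing, never silently
interpolated.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .alpha import AlphaShapeResult, alpha_complex
from .errors import ConfigError, NotWatertightError
from .kinematics import FrameCloud
from .meshvol import TriMesh, write_mesh

__all__ = [
    "PipelineConfig",
    "VolumeSeries",
    "endocast_series",
    "filter_volume_series",
    "rate_of_volume_change",
    "interpenetration_report",
    "tissue_correction",
    "locator_plateau_curve",
    "PenetrationReport",
]

#: below this many frames a low-pass filter is unreliable; the series is
#: passed through with a warning (pseudo-time series of a few poses cannot
#: be filtered meaningfully)
MIN_FRAMES_FOR_FILTER = 15


@dataclass(frozen=True)
class FilterSpec:
    """Volume-series filter: 'none', zero-phase low-pass, or moving average."""

    kind: str = "none"              # none | low-pass | moving-average
    cutoff: float | None = None     # fraction of Nyquist, in (0, 1)
    order: int = 2
    window: int | None = None       # odd, >= 3

    def __post_init__(self):
        if self.kind not in ("none", "low-pass", "moving-average"):
            raise ConfigError(f"unknown filter kind '{self.kind}'")
        if self.kind == "low-pass":
            if self.cutoff is None or not (0 < self.cutoff < 1):
                raise ConfigError(
                    "low-pass filter needs cutoff in (0, 1) "
                    "(fraction of Nyquist); no default is assumed")
            if self.order < 1:
                raise ConfigError("filter order must be >= 1")
        if self.kind == "moving-average":
            if (self.window is None or self.window < 3
                    or self.window % 2 == 0):
                raise ConfigError("moving average needs an odd window >= 3")


@dataclass(frozen=True)
class PipelineConfig:
    """Endocast run configuration.

    ``alpha`` is in the same length unit as the locator coordinates.
    ``unit_scale`` converts input length units to cm so volumes report in
    ml (e.g. 0.1 for coordinates in mm).  ``frame_rate`` is Hz, or
    "pseudo" for a unit-step pseudo time series.
    """

    alpha: float
    bilateral: bool = True
    filter: FilterSpec = field(default_factory=FilterSpec)
    frame_rate: float | str = "pseudo"
    unit_scale: float = 1.0

    def __post_init__(self):
        if not self.alpha > 0:
            raise ConfigError("alpha must be positive")
        if self.unit_scale <= 0:
            raise ConfigError("unit_scale must be positive")
        if self.frame_rate != "pseudo" and not float(self.frame_rate) > 0:
            raise ConfigError("frame_rate must be positive or 'pseudo'")

    @property
    def dt(self) -> float:
        return 1.0 if self.frame_rate == "pseudo" else 1.0 / float(self.frame_rate)


@dataclass
class VolumeSeries:
    """Per-frame endocast volumes (ml) and their rate of change.

    ``v_filtered`` and ``dv_dt`` are None until the corresponding stage has
    run.  ``degenerate`` flags frames whose locator cloud could not be
    tetrahedralized (volumes there are NaN).
    """

    frames: np.ndarray
    times: np.ndarray
    v_uni: np.ndarray
    v_bi: np.ndarray | None = None
    v_filtered: np.ndarray | None = None
    dv_dt: np.ndarray | None = None
    degenerate: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.frames)
        for name in ("times", "v_uni", "v_bi", "v_filtered", "dv_dt",
                     "degenerate"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != n:
                raise ValueError(f"column '{name}' length {len(arr)} != {n}")
        if self.degenerate is None:
            self.degenerate = np.zeros(n, dtype=bool)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def measurement(self) -> np.ndarray:
        """The series differentiation acts on: filtered if present, else
        bilateral if present, else unilateral."""
        if self.v_filtered is not None:
            return self.v_filtered
        return self.v_bi if self.v_bi is not None else self.v_uni

    def to_frame(self) -> pd.DataFrame:
        def col(arr):
            return np.full(self.n_frames, np.nan) if arr is None else arr
        return pd.DataFrame({
            "frame": self.frames,
            "time": self.times,
            "V_uni_ml": self.v_uni,
            "V_bi_ml": col(self.v_bi),
            "V_filtered_ml": col(self.v_filtered),
            "dVdt": col(self.dv_dt),
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def endocast_series(cloud: FrameCloud, cfg: PipelineConfig,
                    export_dir: str | None = None
                    ) -> tuple[VolumeSeries, list[AlphaShapeResult]]:
    """Per-frame alpha shapes and their volume time series.

    V_uni is the alpha-shape volume rescaled to ml via unit_scale^3;
    V_bi = 2 * V_uni when bilateral doubling is enabled.  Degenerate frames
    are flagged (NaN volume) and the run continues.  With ``export_dir``
    set, each frame's endocast boundary is written as endocast_<frame>.obj.
    """
    n = cloud.n_frames
    v_uni = np.full(n, np.nan)
    degenerate = np.zeros(n, dtype=bool)
    results: list[AlphaShapeResult] = []
    for i in range(n):
        res = alpha_complex(cloud.coords[i], cfg.alpha)
        results.append(res)
        if res.degenerate:
            degenerate[i] = True
            warnings.warn(f"frame {cloud.frames[i]}: degenerate locator "
                          "cloud, volume recorded as missing", stacklevel=2)
            continue
        v_uni[i] = res.volume * cfg.unit_scale**3
        if export_dir is not None and len(res.retained):
            write_mesh(res.boundary,
                       os.path.join(export_dir,
                                    f"endocast_{cloud.frames[i]:04d}.obj"))
    series = VolumeSeries(
        frames=cloud.frames.copy(),
        times=cloud.times.copy() * (1.0 if cfg.frame_rate == "pseudo" else 1.0),
        v_uni=v_uni,
        v_bi=2.0 * v_uni if cfg.bilateral else None,
        degenerate=degenerate,
    )
    return series, results


def filter_volume_series(series: VolumeSeries, cfg: PipelineConfig
                         ) -> VolumeSeries:
    """Zero-phase low-pass (forward-backward Butterworth) or centered
    moving average on the measurement column; reflection padding at the
    ends.  Below MIN_FRAMES_FOR_FILTER frames the series passes through
    unchanged with a warning."""
    spec = cfg.filter
    x = series.v_bi if series.v_bi is not None else series.v_uni
    if spec.kind == "none":
        return replace(series, v_filtered=None)
    if np.any(series.degenerate):
        raise ConfigError("cannot filter a series with missing frames; "
                          "handle gaps explicitly first")
    if spec.kind == "low-pass":
        if series.n_frames < MIN_FRAMES_FOR_FILTER:
            warnings.warn(
                f"only {series.n_frames} frames (< {MIN_FRAMES_FOR_FILTER}): "
                "low-pass filter skipped, series passed through", stacklevel=2)
            return replace(series, v_filtered=x.copy())
        b, a = butter(spec.order, spec.cutoff)
        y = filtfilt(b, a, x, padtype="even")
    else:  # moving-average
        w = spec.window
        if series.n_frames < w:
            warnings.warn("window longer than series; passed through",
                          stacklevel=2)
            return replace(series, v_filtered=x.copy())
        padded = np.pad(x, w // 2, mode="reflect")
        y = np.convolve(padded, np.ones(w) / w, mode="valid")
    return replace(series, v_filtered=y)


def rate_of_volume_change(series: VolumeSeries,
                          cfg: PipelineConfig | None = None) -> VolumeSeries:
    """dV/dt by central differences (one-sided at the ends).

    Acts on the filtered series if present, else the (bilateral) volume;
    dt is 1/frame_rate, or 1 per step for pseudo-time series.
    """
    if series.n_frames < 2:
        raise ValueError("need >= 2 frames to differentiate")
    dt = cfg.dt if cfg is not None else float(np.mean(np.diff(series.times))) or 1.0
    dv = np.gradient(series.measurement, dt)
    return replace(series, dv_dt=dv)


@dataclass(frozen=True)
class PenetrationReport:
    """Monte-Carlo bone-interpenetration estimate for one endocast."""

    fraction: float
    se: float
    n_samples: int


def points_inside_mesh(mesh: TriMesh, points: np.ndarray,
                       chunk: int = 2048) -> np.ndarray:
    """Point-in-mesh test by the generalized winding number.

    Sums the signed solid angle each triangle subtends at the query point
    (Van Oosterom-Strackee); for a closed, consistently oriented mesh the
    total is ~4*pi inside and ~0 outside.  Robust to pinched edges.
    """
    tri = mesh.vertices[mesh.faces]           # (F, 3, 3)
    points = np.asarray(points, dtype=float)
    inside = np.empty(len(points), dtype=bool)
    for start in range(0, len(points), chunk):
        p = points[start:start + chunk]
        a = tri[None, :, 0] - p[:, None]      # (P, F, 3)
        b = tri[None, :, 1] - p[:, None]
        c = tri[None, :, 2] - p[:, None]
        la = np.linalg.norm(a, axis=-1)
        lb = np.linalg.norm(b, axis=-1)
        lc = np.linalg.norm(c, axis=-1)
        num = np.einsum("pfi,pfi->pf", a, np.cross(b, c))
        den = (la * lb * lc + np.einsum("pfi,pfi->pf", a, b) * lc
               + np.einsum("pfi,pfi->pf", b, c) * la
               + np.einsum("pfi,pfi->pf", a, c) * lb)
        omega = 2.0 * np.arctan2(num, den)
        winding = omega.sum(axis=1) / (4.0 * np.pi)
        inside[start:start + chunk] = np.abs(winding) > 0.5
    return inside


def _sample_inside(mesh: TriMesh, n: int, rng: np.random.Generator
                   ) -> np.ndarray:
    """Uniform interior samples by rejection from the bounding box."""
    lo = mesh.vertices.min(axis=0)
    hi = mesh.vertices.max(axis=0)
    out = []
    got = 0
    max_rounds = 200
    for _ in range(max_rounds):
        cand = rng.uniform(lo, hi, size=(max(2 * n, 1024), 3))
        pts = cand[points_inside_mesh(mesh, cand)]
        if len(pts):
            out.append(pts)
            got += len(pts)
        if got >= n:
            break
    if got < n:
        raise RuntimeError("could not sample points inside the endocast "
                           "(is the mesh degenerate?)")
    return np.vstack(out)[:n]


def interpenetration_report(endocast: TriMesh, bones: list[TriMesh],
                            n_samples: int = 10_000, seed: int = 0
                            ) -> PenetrationReport:
    """Fraction of the endocast interior lying inside any bone mesh.

    Monte-Carlo with uniform interior samples; deterministic given seed.
    Large fractions indicate the alpha value is too large (the shape
    bridges concavities and penetrates the bones).
    """
    for mesh in (endocast, *bones):
        be = mesh.boundary_edge_count()
        if be or mesh.n_faces == 0:
            raise NotWatertightError(be, mesh.name)
    rng = np.random.default_rng(seed)
    pts = _sample_inside(endocast, n_samples, rng)
    hit = np.zeros(len(pts), dtype=bool)
    for bone in bones:
        hit |= points_inside_mesh(bone, pts)
    p = float(hit.mean())
    se = math.sqrt(p * (1 - p) / n_samples)
    return PenetrationReport(fraction=p, se=se, n_samples=n_samples)


def tissue_correction(series: VolumeSeries, tissue_volume: float
                      ) -> VolumeSeries:
    """Subtract a constant enclosed-tissue volume from the absolute volumes.

    ``tissue_volume`` is on the scale of the series' measurement column:
    for a bilateral series it is the full enclosed-tissue volume (half of
    it is removed from the unilateral column).  dV/dt is untouched (the
    derivative of a constant offset is zero, which is why incompressible
    enclosed tissue does not bias volume change).  Corrections that would
    produce negative volumes are clamped to zero with a warning, never
    silently.
    """
    if tissue_volume < 0:
        raise ValueError("tissue_volume must be >= 0")

    def corrected(arr, offset):
        if arr is None:
            return None
        out = arr - offset
        neg = out < 0
        if np.any(neg & np.isfinite(out)):
            warnings.warn(
                f"tissue correction drove {int(np.sum(neg))} frame(s) "
                "negative; clamping to 0", stacklevel=3)
            out = np.where(neg, 0.0, out)
        return out

    uni_offset = tissue_volume / 2 if series.v_bi is not None else tissue_volume
    return replace(series, v_uni=corrected(series.v_uni, uni_offset),
                   v_bi=corrected(series.v_bi, tissue_volume),
                   v_filtered=corrected(series.v_filtered, tissue_volume))


def locator_plateau_curve(cloud_builder, counts, alpha: float
                          ) -> list[tuple[int, float]]:
    """Single-frame endocast volume as a function of locator count.

    ``cloud_builder(n)`` must return an (n, 3) cloud.  Used to find the
    count at which the volume plateaus (the recommended stopping rule for
    adding locators).  Duplicate counts are deduplicated with a warning.
    """
    counts = list(counts)
    if any(c < 4 for c in counts):
        raise ValueError("all locator counts must be >= 4")
    if sorted(counts) != counts:
        raise ValueError("counts must be ascending")
    uniq = sorted(set(counts))
    if len(uniq) != len(counts):
        warnings.warn("duplicate locator counts removed", stacklevel=2)
    out = []
    for n in uniq:
        res = alpha_complex(cloud_builder(n), alpha)
        out.append((n, res.volume))
    return out
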