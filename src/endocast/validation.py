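"""Precision/accuracy validation: regression against the gold standard.

The endocast volume (y) is regressed on the gold-standard air volume (x)
by ordinary least squares.  R^2 of the fit measures *precision*; the slope
measures *accuracy of volume change* (slope < 1 means the method
underestimates dV); the intercept estimates the enclosed hard/soft tissue
volume included in every endocast; residuals against the identity line
y = x quantify absolute-volume overestimation.

Sensitivity sweeps repeat the regression over locator counts and alpha
values, sharing the same pose series so differences are attributable to
the swept variable alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegressionReport",
    "SweepResult",
    "ols_regression",
    "residuals_vs_identity",
    "sweep_locators",
    "sweep_alpha",
]


@dataclass(frozen=True)
class RegressionReport:
    """OLS fit y = slope * x + intercept with 95% confidence intervals."""

    slope: float
    intercept: float
    r2: float
    ci_slope: tuple[float, float]
    ci_intercept: tuple[float, float]
    n: int
    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    residuals: np.ndarray = field(repr=False)   # y - fitted
    provenance: dict = field(default_factory=dict, repr=False)

    def identity_residuals(self, x=None) -> np.ndarray:
        """Fitted-line minus identity-line y-values: (slope - 1) x + intercept."""
        x = self.x if x is None else np.asarray(x, dtype=float)
        return (self.slope - 1.0) * x + self.intercept

    def to_dict(self) -> dict:
        return {
            "slope": self.slope, "intercept": self.intercept, "r2": self.r2,
            "ci_slope_lo": self.ci_slope[0], "ci_slope_hi": self.ci_slope[1],
            "ci_int_lo": self.ci_intercept[0],
            "ci_int_hi": self.ci_intercept[1], "n": self.n,
            **self.provenance,
        }


def ols_regression(x, y, ci_level: float = 0.95, method: str = "t",
                   n_boot: int = 10_000, seed: int = 0,
                   provenance: dict | None = None) -> RegressionReport:
    """Least-squares regression of endocast volume (y) on gold volume (x).

    CIs are classical t-intervals on n - 2 degrees of freedom by default;
    ``method='bootstrap'`` uses seeded case-resampling percentile
    intervals instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be equal-length 1D arrays "
                         f"(got {len(x)} and {len(y)})")
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 points, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance; regression undefined")
    fit = stats.linregress(x, y)
    slope, intercept = fit.slope, fit.intercept
    fitted = slope * x + intercept
    resid = y - fitted
    sst = float(np.sum((y - y.mean()) ** 2))
    ssr = float(np.sum(resid**2))
    r2 = 1.0 if sst == 0 else 1.0 - ssr / sst

    if method == "t":
        tval = stats.t.ppf(0.5 + ci_level / 2, n - 2)
        ci_slope = (slope - tval * fit.stderr, slope + tval * fit.stderr)
        ci_int = (intercept - tval * fit.intercept_stderr,
                  intercept + tval * fit.intercept_stderr)
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        slopes = np.empty(n_boot)
        ints = np.empty(n_boot)
        for b in range(n_boot):
            xb, yb = x[idx[b]], y[idx[b]]
            if np.ptp(xb) == 0:
                slopes[b], ints[b] = np.nan, np.nan
                continue
            m, c = np.polyfit(xb, yb, 1)
            slopes[b], ints[b] = m, c
        lo, hi = 50 * (1 - ci_level), 50 * (1 + ci_level)
        ci_slope = tuple(np.nanpercentile(slopes, [lo, hi]))
        ci_int = tuple(np.nanpercentile(ints, [lo, hi]))
    else:
        raise ValueError(f"unknown CI method '{method}'")
    return RegressionReport(
        slope=float(slope), intercept=float(intercept), r2=float(r2),
        ci_slope=(float(ci_slope[0]), float(ci_slope[1])),
        ci_intercept=(float(ci_int[0]), float(ci_int[1])), n=n,
        x=x.copy(), y=y.copy(), residuals=resid,
        provenance=dict(provenance or {}))


def residuals_vs_identity(report: RegressionReport, x) -> np.ndarray:
    """Overestimation diagnostic: fitted-line y minus identity-line y at x.

    Positive values flag absolute-volume overestimation relative to the
    gold standard.
    """
    return report.identity_residuals(x)


@dataclass
class SweepResult:
    """Per-value regression reports for one swept variable."""

    variable: str               # "locator_count" | "alpha"
    values: list
    reports: list               # RegressionReport or None for flagged values
    flagged: list               # swept values that produced all-empty shapes

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v, rep in zip(self.values, self.reports):
            row = {self.variable: v}
            if rep is None:
                row["flagged"] = True
            else:
                row.update(rep.to_dict())
                row["flagged"] = False
            rows.append(row)
        return pd.DataFrame(rows)


def _scene_regression(scene, locators, alpha_value, provenance,
                      use_estimated_rbt=True):
    y = scene.endocast_volumes(locators, alpha_value,
                               use_estimated_rbt=use_estimated_rbt)
    if np.allclose(y, 0):
        return None
    x = scene.gold_volumes()
    return ols_regression(x, y, provenance=provenance)


def sweep_locators(scene, counts, alpha_value: float, seed: int = 0,
                   use_estimated_rbt: bool = True,
                   placement_candidates: int = 8) -> SweepResult:
    """Regression per locator count at a fixed alpha value.

    Locator sets are placed independently per count (a smaller set is not
    a subset of a larger one); all counts share the same pose series.
    ``placement_candidates > 1`` selects the best of several candidate
    placements per count by worst-frame endocast fit (strategic
    placement, emulating hand placement with visual fit checks).
    """
    counts = list(counts)
    if counts != sorted(counts):
        raise ValueError("counts must be ascending")
    if any(c < 4 for c in counts):
        raise ValueError("every locator count must be >= 4")
    reports, flagged = [], []
    for n in counts:
        try:
            locs = scene.locator_set(n, seed=seed, alpha=alpha_value,
                                     n_candidates=placement_candidates)
        except Exception as exc:
            raise RuntimeError(f"locator placement failed at count {n}: "
                               f"{exc}") from exc
        rep = _scene_regression(
            scene, locs, alpha_value,
            {"locator_count": n, "alpha": alpha_value, "seed": seed},
            use_estimated_rbt)
        if rep is None:
            flagged.append(n)
        reports.append(rep)
    return SweepResult(variable="locator_count", values=counts,
                       reports=reports, flagged=flagged)


def sweep_alpha(scene, alphas, locators, seed: int = 0,
                use_estimated_rbt: bool = True) -> SweepResult:
    """Regression per alpha value for one fixed locator set.

    An alpha producing all-empty shapes is flagged and the sweep continues.
    """
    alphas = [float(a) for a in alphas]
    if alphas != sorted(alphas) or any(a <= 0 for a in alphas):
        raise ValueError("alphas must be positive and ascending")
    if isinstance(locators, int):
        locators = scene.locator_set(locators, seed=seed)
    reports, flagged = [], []
    for a in alphas:
        rep = _scene_regression(
            scene, locators, a,
            {"alpha": a, "locator_count": len(locators), "seed": seed},
            use_estimated_rbt)
        if rep is None:
            warnings.warn(f"alpha {a:g} produced empty shapes in every "
                          "frame; flagged", stacklevel=2)
            flagged.append(a)
        reports.append(rep)
    return SweepResult(variable="alpha", values=alphas, reports=reports,
                       flagged=flagged)
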