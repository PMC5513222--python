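"""Fit the simplified Gielis leaf model to an observed boundary.

Five parameters are estimated jointly by Nelder--Mead simplex minimization:
the model's scale ``l`` and shape ``n``, plus three rigid-pose nuisance
parameters — the polar-origin translation ``(x0, y0)`` and the tip-axis
rotation ``theta`` — that align a digitized leaf with the model frame.

The objective is the sum of squared *radial* residuals: each boundary
point is pose-normalized, converted to polar coordinates ``(phi_i, r_i)``
about the candidate origin, and compared with the model radius at the same
angle.  Goodness of fit is summarized by the coefficient of determination
on radii; because the model is bilaterally symmetric by construction, a
high R^2 is direct evidence that the blade itself is mirror-symmetric
about its tip--base axis, and one-sided departures from symmetry depress
R^2.

Positivity of ``l`` and ``n`` is enforced by optimizing their logarithms,
so the simplex never proposes an invalid model.  The tip/base orientation
ambiguity (``theta`` vs ``theta + pi``) is resolved by fitting from both
starts and keeping the better R^2.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .geometry import (
    BoundaryCurve,
    GielisParams,
    PoseParams,
    ShapeFunctionals,
    _radius_raw,
    functionals,
)

__all__ = [
    "PoseParams",
    "FitOptions",
    "FitResult",
    "apply_pose",
    "normalize_pose",
    "to_polar",
    "objective",
    "initialize",
    "fit",
    "r_squared",
    "read_boundary_csv",
    "write_boundary_csv",
]


@dataclass(frozen=True)
class FitOptions:
    """Optimizer controls.

    max_restarts
        Extra Nelder--Mead runs from jittered starting points, tried only
        when neither deterministic start (initial pose and its tip/base
        flip) converges to a credible optimum (best R^2 below
        ``restart_r2_threshold``).  Jitter is drawn from a generator
        seeded with ``seed``, so fits are reproducible.
    fatol_rel
        Absolute simplex function tolerance, as a fraction of the
        objective at the starting point.
    xatol
        Simplex parameter tolerance (log l, log n, x0, y0, theta space).
    """

    max_restarts: int = 4
    seed: int = 0
    fatol_rel: float = 1e-10
    xatol: float = 1e-8
    maxiter: int = 5000
    restart_r2_threshold: float = 0.9


@dataclass(frozen=True)
class FitResult:
    """Estimated model, pose, fit quality and derived leaf descriptors."""

    params: GielisParams
    pose: PoseParams
    r_squared: float
    rss: float
    n_points: int
    converged: bool
    n_restarts_used: int
    functionals: ShapeFunctionals

    def to_dict(self) -> dict:
        return {
            "l": self.params.l,
            "n": self.params.n,
            "x0": self.pose.x0,
            "y0": self.pose.y0,
            "theta": self.pose.theta,
            "r_squared": self.r_squared,
            "rss": self.rss,
            "n_points": self.n_points,
            "length": self.functionals.length,
            "width": self.functionals.width,
            "aspect_ratio": self.functionals.aspect_ratio,
            "area": self.functionals.area,
            "converged": self.converged,
            "n_restarts_used": self.n_restarts_used,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def apply_pose(curve: BoundaryCurve, pose: PoseParams) -> BoundaryCurve:
    """Rotate by theta then translate by (x0, y0): model frame -> data frame."""
    c, s = np.cos(pose.theta), np.sin(pose.theta)
    x = curve.x * c - curve.y * s + pose.x0
    y = curve.x * s + curve.y * c + pose.y0
    return BoundaryCurve(np.column_stack([x, y]), curve.units, curve.closed)


def normalize_pose(curve: BoundaryCurve, pose: PoseParams) -> BoundaryCurve:
    """Inverse of :func:`apply_pose`: bring the polar origin to (0, 0) and
    the tip axis onto +x.

    ``x' = (x - x0) cos(theta) + (y - y0) sin(theta)``,
    ``y' = -(x - x0) sin(theta) + (y - y0) cos(theta)``.
    """
    pts = _normalize_points(curve.points, pose.x0, pose.y0, pose.theta)
    return BoundaryCurve(pts, curve.units, curve.closed)


def _normalize_points(pts, x0, y0, theta):
    c, s = np.cos(theta), np.sin(theta)
    dx = pts[:, 0] - x0
    dy = pts[:, 1] - y0
    return np.column_stack([dx * c + dy * s, -dx * s + dy * c])


def to_polar(curve: BoundaryCurve) -> tuple[np.ndarray, np.ndarray]:
    """Polar coordinates of an (already pose-normalized) boundary.

    Returns ``(phi, r)`` with ``phi = atan2(y, x)`` in (-pi, pi] and
    ``r = hypot(x, y)``, preserving the original point order.
    """
    r = np.hypot(curve.x, curve.y)
    if np.any(r == 0.0):
        raise ValueError(
            "boundary point coincides with the polar origin; geometry is "
            "degenerate for a polar model"
        )
    return np.arctan2(curve.y, curve.x), r


def r_squared(r_obs, r_pred) -> float:
    """Coefficient of determination on radii.

    ``1 - RSS/TSS`` with ``TSS`` the variance of the observed radii about
    their mean.  Equals 1 iff the fitted curve passes through every
    observed point.
    """
    r_obs = np.asarray(r_obs, dtype=float)
    r_pred = np.asarray(r_pred, dtype=float)
    if r_obs.shape != r_pred.shape or r_obs.size < 2:
        raise ValueError("r_obs and r_pred must be matched sequences of length >= 2")
    tss = float(np.sum((r_obs - r_obs.mean()) ** 2))
    if tss == 0.0:
        raise ZeroDivisionError("observed radii are constant; R^2 undefined")
    return 1.0 - float(np.sum((r_obs - r_pred) ** 2)) / tss


def _residual_rss(pts, l, n, x0, y0, theta) -> float:
    norm = _normalize_points(pts, x0, y0, theta)
    phi = np.arctan2(norm[:, 1], norm[:, 0])
    r_obs = np.hypot(norm[:, 0], norm[:, 1])
    return float(np.sum((r_obs - _radius_raw(phi, l, n)) ** 2))


def objective(
    curve: BoundaryCurve, l: float, n: float, x0: float, y0: float, theta: float
) -> float:
    """Sum of squared radial residuals at the observed angles."""
    if not all(np.isfinite([l, n, x0, y0, theta])) or l <= 0 or n <= 0:
        raise ValueError("objective requires finite parameters with l, n > 0")
    return _residual_rss(curve.points, l, n, x0, y0, theta)


def initialize(curve: BoundaryCurve) -> tuple[float, float, float, float, float]:
    """Deterministic starting values ``(l, n, x0, y0, theta)``.

    The polar origin starts at the boundary centroid; the tip is taken as
    the point farthest from it (ties broken by lowest index, so the result
    is reproducible on degenerate inputs such as circles); theta points at
    the tip and l is the centroid-to-tip distance.  The shape parameter
    starts at 0.06, the midpoint of the lanceolate range.
    """
    pts = curve.points
    if len(pts) < 16:
        raise ValueError("need >= 16 boundary points to initialize a fit")
    centroid = pts.mean(axis=0)
    d2 = np.sum((pts - centroid) ** 2, axis=1)
    if np.max(d2) == 0.0:
        raise ValueError("all boundary points coincide; degenerate geometry")
    tip = pts[int(np.argmax(d2))]  # argmax returns the lowest maximizing index
    theta = float(np.arctan2(tip[1] - centroid[1], tip[0] - centroid[0]))
    l = float(np.sqrt(np.max(d2)))
    return l, 0.06, float(centroid[0]), float(centroid[1]), theta


def _check_angular_span(pts, x0, y0) -> float:
    phi = np.arctan2(pts[:, 1] - y0, pts[:, 0] - x0)
    # span of sorted angles: 2*pi minus the largest gap between neighbors
    s = np.sort(phi)
    gaps = np.diff(np.concatenate([s, [s[0] + 2 * np.pi]]))
    return 2 * np.pi - float(np.max(gaps))


def fit(curve: BoundaryCurve, options: FitOptions | None = None) -> FitResult:
    """Estimate ``(l, n, x0, y0, theta)`` by Nelder--Mead least squares.

    Runs from the deterministic initialization and from its tip/base flip
    (theta + pi), keeping the solution with lower residual; optional
    seeded jittered restarts are tried only if neither run converges to a
    credible optimum.  The returned result carries R^2 on radii, the
    residual sum of squares, and the derived leaf functionals.
    """
    opts = options or FitOptions()
    l0, n0, x00, y00, th0 = initialize(curve)
    if _check_angular_span(curve.points, x00, y00) < 1.5 * np.pi:
        raise ValueError(
            "boundary spans less than 3*pi/2 around the initial origin; "
            "not a closed leaf outline"
        )

    pts = curve.points

    def penalized(z):
        logl, logn, x0, y0, theta = z
        if abs(logl) > 50 or abs(logn) > 50:
            return np.inf
        return _residual_rss(pts, np.exp(logl), np.exp(logn), x0, y0, theta)

    def run(z0):
        f0 = max(penalized(z0), np.finfo(float).tiny)
        res = minimize(
            penalized,
            z0,
            method="Nelder-Mead",
            options={
                "fatol": opts.fatol_rel * f0,
                "xatol": opts.xatol,
                "maxiter": opts.maxiter,
                "maxfev": 2 * opts.maxiter,
            },
        )
        return res

    z_base = np.array([np.log(l0), np.log(n0), x00, y00, th0])
    starts = [z_base, z_base + np.array([0.0, 0.0, 0.0, 0.0, np.pi])]
    results = [run(z) for z in starts]
    best = min(results, key=lambda r: r.fun)

    n_restarts_used = 0
    rng = np.random.default_rng(opts.seed)
    while (
        n_restarts_used < opts.max_restarts
        and (not best.success or _r2_of(pts, best.x) < opts.restart_r2_threshold)
    ):
        jitter = rng.normal(0.0, [0.2, 0.4, 0.05 * l0, 0.05 * l0, 0.5])
        cand = run(z_base + jitter)
        n_restarts_used += 1
        if cand.fun < best.fun:
            best = cand

    logl, logn, x0, y0, theta = best.x
    params = _quiet_params(np.exp(logl), np.exp(logn))
    pose = PoseParams(float(x0), float(y0), PoseParams(0, 0, float(theta)).theta_wrapped)

    norm = _normalize_points(pts, pose.x0, pose.y0, pose.theta)
    phi = np.arctan2(norm[:, 1], norm[:, 0])
    r_obs = np.hypot(norm[:, 0], norm[:, 1])
    r_pred = _radius_raw(phi, params.l, params.n)
    r2 = r_squared(r_obs, r_pred)

    if not best.success:
        warnings.warn(
            f"Nelder-Mead did not converge after {n_restarts_used} restarts "
            f"({best.message}); returning best point found",
            stacklevel=2,
        )
    return FitResult(
        params=params,
        pose=pose,
        r_squared=r2,
        rss=float(best.fun),
        n_points=len(pts),
        converged=bool(best.success),
        n_restarts_used=n_restarts_used,
        functionals=functionals(params),
    )


def _r2_of(pts, z) -> float:
    logl, logn, x0, y0, theta = z
    norm = _normalize_points(pts, x0, y0, theta)
    r_obs = np.hypot(norm[:, 0], norm[:, 1])
    tss = np.sum((r_obs - r_obs.mean()) ** 2)
    if tss == 0:
        return -np.inf
    phi = np.arctan2(norm[:, 1], norm[:, 0])
    rss = np.sum((r_obs - _radius_raw(phi, np.exp(logl), np.exp(logn))) ** 2)
    return 1.0 - rss / tss


def _quiet_params(l: float, n: float) -> GielisParams:
    # an out-of-range n estimate is the fit's honest answer; no warning here
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return GielisParams(l, n)


def read_boundary_csv(path, units: str = "cm") -> BoundaryCurve:
    """Read a boundary from CSV with header columns ``x`` and ``y``."""
    df = pd.read_csv(path)
    missing = {"x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"boundary CSV {path} lacks columns: {sorted(missing)}")
    return BoundaryCurve(df[["x", "y"]].to_numpy(dtype=float), units=units)


def write_boundary_csv(curve: BoundaryCurve, path) -> None:
    pd.DataFrame({"x": curve.x, "y": curve.y}).to_csv(path, index=False)
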