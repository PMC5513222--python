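"""Forward model for bilaterally symmetric lanceolate leaf outlines.

The outline is a two-parameter special case of the Gielis superformula in
polar coordinates,

    r(phi) = l * (|cos(phi/4)| + |sin(phi/4)|)^(-1/n),

with the leaf tip at ``phi = 0`` (where ``r = l``) and the base at
``phi = +-pi``.  ``l`` sets absolute size (distance from the polar origin
to the tip, in cm) and the dimensionless shape parameter ``n`` sets the
width-to-length proportion: small ``n`` gives narrow, linear-lanceolate
blades, larger ``n`` broader ones.  The kernel has period ``2*pi`` and is
even in ``phi``, so the modeled blade is mirror-symmetric about the
tip--base axis by construction.

This module evaluates the curve, its six-parameter generalization, and the
derived functionals (length, width, aspect ratio, area).  Everything here
is deterministic pure computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

__all__ = [
    "GielisParams",
    "GeneralGielisParams",
    "PoseParams",
    "BoundaryCurve",
    "ShapeFunctionals",
    "radius",
    "general_radius",
    "boundary",
    "leaf_length",
    "leaf_width",
    "aspect_ratio",
    "area",
    "shoelace_area",
    "functionals",
]

TWO_PI = 2.0 * np.pi

#: Range of the shape parameter observed across lanceolate bamboo foliage
#: leaves; values outside it are legal but trigger a soft warning.
BIOLOGICAL_N_RANGE = (0.01, 0.2)


@dataclass(frozen=True)
class GielisParams:
    """Parameters of the simplified Gielis leaf model.

    Parameters
    ----------
    l : float
        Polar-radius scale (cm): the distance from the polar origin to the
        leaf tip, ``r(0) = l``.  Must be positive.
    n : float
        Dimensionless leaf-shape parameter.  Must be positive; lanceolate
        leaves typically fall in ``[0.01, 0.2]`` (a warning, not an error,
        outside this range).
    """

    l: float
    n: float

    def __post_init__(self) -> None:
        l, n = float(self.l), float(self.n)
        if not (np.isfinite(l) and l > 0):
            raise ValueError(f"l must be a positive finite real, got {self.l!r}")
        if not (np.isfinite(n) and n > 0):
            raise ValueError(f"n must be a positive finite real, got {self.n!r}")
        lo, hi = BIOLOGICAL_N_RANGE
        if not lo <= n <= hi:
            warnings.warn(
                f"shape parameter n={n:g} outside the typical lanceolate "
                f"range [{lo}, {hi}]",
                stacklevel=3,
            )
        object.__setattr__(self, "l", l)
        object.__setattr__(self, "n", n)


@dataclass(frozen=True)
class GeneralGielisParams:
    """Parameters of the general six-parameter Gielis superformula.

    ``r(phi) = [|cos(m*phi/4)/a|^n2 + |sin(m*phi/4)/b|^n3]^(-1/n1)``.
    Only the reduction to the simplified model (``m=1, a=b=1, n2=n3=1,
    n1=n``) is exercised elsewhere in the package.
    """

    m: float
    a: float
    b: float
    n1: float
    n2: float
    n3: float

    def __post_init__(self) -> None:
        for name in ("m", "a", "b"):
            v = float(getattr(self, name))
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive, got {v!r}")
        if self.n1 == 0 or not np.isfinite(self.n1):
            raise ValueError("n1 must be nonzero and finite")
        if not (np.isfinite(self.n2) and np.isfinite(self.n3)):
            raise ValueError("n2, n3 must be finite")


@dataclass(frozen=True)
class PoseParams:
    """Rigid-motion nuisance parameters aligning a digitized leaf with the
    model frame: polar-origin translation ``(x0, y0)`` in cm and rotation
    ``theta`` (radians) of the tip axis away from +x."""

    x0: float = 0.0
    y0: float = 0.0
    theta: float = 0.0

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.x0, self.y0, self.theta])):
            raise ValueError("pose parameters must be finite")

    @property
    def theta_wrapped(self) -> float:
        """theta reduced to the principal interval (-pi, pi]."""
        t = float(np.mod(self.theta + np.pi, TWO_PI) - np.pi)
        return np.pi if t == -np.pi else t


IDENTITY_POSE = PoseParams(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class BoundaryCurve:
    """Ordered closed planar point sequence — the exchange object between
    extraction, synthesis and fitting.

    ``points`` is an ``(N, 2)`` float array of (x, y) coordinates in
    ``units`` (``"cm"`` or ``"px"``).  If ``closed``, the first and last
    points are treated as adjacent (the closing vertex is NOT repeated).
    """

    points: np.ndarray
    units: str = "cm"
    closed: bool = True

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"points must be (N, 2), got shape {pts.shape}")
        if len(pts) < 3:
            raise ValueError(f"a boundary needs >= 3 points, got {len(pts)}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("boundary points must be finite")
        seg = np.diff(pts, axis=0)
        if np.any(np.all(seg == 0.0, axis=1)):
            raise ValueError("consecutive identical points in boundary")
        if self.closed and np.all(pts[0] == pts[-1]):
            raise ValueError(
                "closed curves must not repeat the closing vertex"
            )
        if self.units not in ("cm", "px"):
            raise ValueError(f"units must be 'cm' or 'px', got {self.units!r}")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]


@dataclass(frozen=True)
class ShapeFunctionals:
    """Derived scalar descriptors of a fitted leaf: length L and width W
    (cm), their ratio W/L, and blade area (cm^2)."""

    length: float
    width: float
    aspect_ratio: float
    area: float


def _reduce_angle(phi: np.ndarray) -> np.ndarray:
    # symmetric reduction to [-pi, pi]; round() is odd, so the reduction
    # commutes with phi -> -phi bit-exactly, preserving r(phi) == r(-phi)
    phi = np.asarray(phi, dtype=float)
    return phi - TWO_PI * np.round(phi / TWO_PI)


def _radius_raw(phi: np.ndarray, l: float, n: float) -> np.ndarray:
    """Kernel evaluation without parameter validation (optimizer path)."""
    q = _reduce_angle(phi) / 4.0
    kernel = np.abs(np.cos(q)) + np.abs(np.sin(q))
    return l * kernel ** (-1.0 / n)


def radius(phi, params: GielisParams):
    """Polar radius of the simplified Gielis curve at angle(s) ``phi``.

    ``r = l * (|cos(phi/4)| + |sin(phi/4)|)^(-1/n)``, evaluated modulo the
    curve's 2*pi period.  Even in phi (bilateral symmetry) and strictly
    positive.  Scalar in, scalar out; array in, array out.
    """
    phi_arr = np.asarray(phi, dtype=float)
    if not np.all(np.isfinite(phi_arr)):
        raise ValueError("phi must be finite")
    r = _radius_raw(phi_arr, params.l, params.n)
    return float(r) if np.isscalar(phi) or phi_arr.ndim == 0 else r


def general_radius(phi, params: GeneralGielisParams):
    """Polar radius of the general Gielis superformula.

    ``r = [|cos(m*phi/4)/a|^n2 + |sin(m*phi/4)/b|^n3]^(-1/n1)``.  Raises a
    domain error where both kernel terms vanish (possible only for
    pathological exponent combinations).
    """
    phi_arr = np.asarray(phi, dtype=float)
    if not np.all(np.isfinite(phi_arr)):
        raise ValueError("phi must be finite")
    q = params.m * phi_arr / 4.0
    with np.errstate(divide="ignore"):
        t1 = np.abs(np.cos(q) / params.a) ** params.n2
        t2 = np.abs(np.sin(q) / params.b) ** params.n3
    s = t1 + t2
    if np.any(s == 0.0) or not np.all(np.isfinite(s)):
        raise ZeroDivisionError(
            "general Gielis kernel vanished or diverged at some phi"
        )
    r = s ** (-1.0 / params.n1)
    return float(r) if np.isscalar(phi) or phi_arr.ndim == 0 else r


def _apply_pose(points: np.ndarray, pose: PoseParams) -> np.ndarray:
    """Rotate by theta, then translate by (x0, y0): model frame -> data frame."""
    c, s = np.cos(pose.theta), np.sin(pose.theta)
    x = points[:, 0] * c - points[:, 1] * s + pose.x0
    y = points[:, 0] * s + points[:, 1] * c + pose.y0
    return np.column_stack([x, y])


def boundary(
    params: GielisParams,
    num_points: int = 2000,
    pose: PoseParams | None = None,
) -> BoundaryCurve:
    """Sample the model outline as a closed boundary curve.

    phi is sampled uniformly on [-pi, pi); each (r, phi) maps to Cartesian
    (x, y) = (r cos phi, r sin phi); the optional pose (rotation theta then
    translation (x0, y0)) is applied last.  With the identity pose the
    returned curve is symmetric about the x-axis, tip on +x.
    """
    if num_points < 16:
        raise ValueError(f"num_points must be >= 16, got {num_points}")
    phi = -np.pi + TWO_PI * np.arange(num_points) / num_points
    r = _radius_raw(phi, params.l, params.n)
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
    if pose is not None:
        pts = _apply_pose(pts, pose)
    return BoundaryCurve(pts, units="cm", closed=True)


def leaf_length(params: GielisParams) -> float:
    """Tip-to-base blade length ``L = (1 + 2^(-1/(2n))) * l``.

    The closed form is the sum of the polar radii at the tip (phi = 0,
    where r = l) and at the base (phi = pi, where the kernel equals
    sqrt(2) so r = l * 2^(-1/(2n))).
    """
    return (1.0 + 2.0 ** (-1.0 / (2.0 * params.n))) * params.l


def _half_width_objective(phi: float, l: float, n: float) -> float:
    return -_radius_raw(phi, l, n) * np.sin(phi)


def leaf_width(params: GielisParams) -> float:
    """Maximal blade extent perpendicular to the tip--base axis.

    ``W = 2 * max_{phi in [0, pi]} r(phi) sin(phi)`` (the factor 2 uses
    bilateral symmetry).  The maximizer is found by bounded scalar
    optimization; r(phi) sin(phi) is smooth on the open interval (the
    kernel's only kink is at the tip, phi = 0, where the objective
    vanishes anyway).
    """
    res = minimize_scalar(
        _half_width_objective,
        bounds=(0.0, np.pi),
        args=(params.l, params.n),
        method="bounded",
        options={"xatol": 1e-12},
    )
    if not res.success:
        raise RuntimeError(f"width maximization failed: {res.message}")
    return -2.0 * res.fun


def aspect_ratio(n: float) -> float:
    """Width-to-length ratio W/L of the modeled blade.

    Depends only on the shape parameter n — both W and L scale linearly in
    l, so the ratio is size-free.  Increasing in n: low values give
    linear-lanceolate outlines, higher values broader blades.
    """
    p = GielisParams(l=1.0, n=n)
    return leaf_width(p) / leaf_length(p)


def area(params: GielisParams, rel_tol: float = 1e-10) -> float:
    """Blade area by the polar sector integral ``(1/2) int r(phi)^2 dphi``.

    Adaptive quadrature over [0, pi] doubled (the integrand is even in
    phi); integration never crosses the slope discontinuity at the tip.
    """
    val, err = quad(
        lambda p: _radius_raw(p, params.l, params.n) ** 2,
        0.0,
        np.pi,
        epsabs=0.0,
        epsrel=rel_tol,
        limit=200,
    )
    if not np.isfinite(val) or (val > 0 and err / val > 1e-6):
        raise RuntimeError(
            f"area quadrature did not converge (value {val}, error {err})"
        )
    return val  # 2 * (1/2) * integral over the half-range


def shoelace_area(points_or_curve) -> float:
    """Exact polygon area of an ordered closed vertex sequence."""
    pts = (
        points_or_curve.points
        if isinstance(points_or_curve, BoundaryCurve)
        else np.asarray(points_or_curve, dtype=float)
    )
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def functionals(params: GielisParams) -> ShapeFunctionals:
    """All derived scalar descriptors of a parameter pair at once."""
    L = leaf_length(params)
    W = leaf_width(params)
    return ShapeFunctionals(
        length=L, width=W, aspect_ratio=W / L, area=area(params)
    )
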