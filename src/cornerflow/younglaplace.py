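"""Axisymmetric Young-Laplace drop shapes and pendant-drop surface-tension fitting.

The equilibrium shape of an axisymmetric drop is governed, in arc length ``s``
measured from the apex, by the system

.. math::

    dx/ds   = \\cos\\varphi \\\\
    dz/ds   = \\sin\\varphi \\\\
    d\\varphi/ds = 2/b \\pm \\beta z / b^2 - \\sin\\varphi / x

where ``b`` is the radius of curvature at the apex, ``beta`` is the Bond
number :math:`\\beta = \\Delta\\rho\\, g\\, b^2 / \\gamma`, and the sign of the
gravitational term is ``+`` for a pendant drop (apex down, z measured upward
from the apex) and ``-`` for a sessile drop.  At the apex the singular term
has the analytic limit :math:`\\sin\\varphi/x \\to 1/b`.

Inverting this forward model against an observed silhouette recovers the
surface tension :math:`\\gamma = \\Delta\\rho\\, g\\, b^2 / \\beta`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .errors import InsufficientProfileError, InvalidParameterError

__all__ = [
    "DropProfile",
    "PendantFit",
    "FluidProperties",
    "integrate_drop_profile",
    "fit_pendant_profile",
]

#: Default gravitational acceleration [m/s^2].
DEFAULT_GRAVITY = 9.81


@dataclass
class DropProfile:
    """Ordered planar half-silhouette of a drop, anchored at the apex.

    Parameters
    ----------
    x : ndarray
        Horizontal distance from the symmetry axis [m]; ``x[0] == 0`` and all
        values are non-negative (right half-profile, symmetry assumed).
    z : ndarray
        Distance from the apex along the axis [m], non-decreasing away from
        the apex.
    orientation : {"pendant", "sessile"}
        Which way gravity acts relative to the apex.
    calibration : float, optional
        Length per pixel [m/px] when the profile came from an image.
    closed : bool
        True when forward integration terminated because the tangent angle
        reached pi (profile closes on itself) before the requested arc length.
    """

    x: np.ndarray
    z: np.ndarray
    orientation: str = "pendant"
    calibration: float | None = None
    closed: bool = False
    apex_px: tuple[float, float] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.x.shape != self.z.shape or self.x.ndim != 1:
            raise InvalidParameterError("x and z must be 1-D arrays of equal length")
        if self.x.size == 0:
            raise InvalidParameterError("profile must contain at least one point")
        if abs(self.x[0]) > 1e-12:
            raise InvalidParameterError("first profile point must be the apex (x = 0)")
        if np.any(self.x < -1e-12):
            raise InvalidParameterError("half-profile requires x >= 0")
        if self.orientation not in ("pendant", "sessile"):
            raise InvalidParameterError(f"unknown orientation {self.orientation!r}")

    def __len__(self) -> int:
        return self.x.size

    @property
    def points(self) -> np.ndarray:
        """(N, 2) array of (x, z) points."""
        return np.column_stack([self.x, self.z])

    def arc_length(self) -> float:
        """Total polyline arc length [m]."""
        return float(np.hypot(np.diff(self.x), np.diff(self.z)).sum())

    def scaled(self, k: float) -> "DropProfile":
        """Return a copy with all lengths multiplied by ``k``."""
        return DropProfile(self.x * k, self.z * k, self.orientation,
                           None if self.calibration is None else self.calibration * k,
                           self.closed)


@dataclass
class PendantFit:
    """Result of fitting a pendant profile.

    Attributes
    ----------
    surface_tension : float
        Recovered surface tension [N/m].
    apex_radius : float
        Radius of curvature at the apex [m].
    bond_number : float
        Dimensionless Bond number of the fitted shape.
    rmse : float
        Mean orthogonal distance between observed points and the fitted
        curve [m].
    converged : bool
        Optimizer reported success and ``rmse`` is below the configured
        tolerance.
    """

    surface_tension: float
    apex_radius: float
    bond_number: float
    rmse: float
    converged: bool

    def __post_init__(self) -> None:
        if self.surface_tension <= 0 or self.apex_radius <= 0:
            raise InvalidParameterError("surface tension and apex radius must be positive")
        if self.bond_number < 0 or self.rmse < 0:
            raise InvalidParameterError("bond number and rmse must be non-negative")

    def to_dict(self) -> dict:
        return {
            "surface_tension_N_per_m": self.surface_tension,
            "apex_radius_m": self.apex_radius,
            "bond_number": self.bond_number,
            "rmse_m": self.rmse,
            "converged": bool(self.converged),
        }


@dataclass
class FluidProperties:
    """Bulk fluid constants used by the corner-flow predictions."""

    density: float = 1000.0            # [kg/m^3]
    surface_tension: float = 0.072     # [N/m]
    contact_angle_deg: float = 0.0     # [deg]
    gravity: float = DEFAULT_GRAVITY   # [m/s^2]

    def __post_init__(self) -> None:
        if self.density <= 0 or self.surface_tension <= 0 or self.gravity <= 0:
            raise InvalidParameterError("density, surface tension and gravity must be positive")
        if not 0.0 <= self.contact_angle_deg <= 180.0:
            raise InvalidParameterError("contact angle must lie in [0, 180] degrees")


def _rhs(x: float, z: float, phi: float, b: float, bond: float, sign: float):
    """Right-hand side of the shape ODE, with the apex limit at x -> 0."""
    sin_phi = math.sin(phi)
    if x > 1e-14:
        curv = sin_phi / x
    else:
        curv = 1.0 / b
    dphi = 2.0 / b + sign * bond * z / (b * b) - curv
    return math.cos(phi), sin_phi, dphi


def integrate_drop_profile(
    bond: float,
    apex_radius: float,
    arc_length_max: float | None = None,
    step: float | None = None,
    orientation: str = "pendant",
) -> DropProfile:
    """Integrate the axisymmetric drop-shape system from the apex.

    Fixed-step classical 4th-order Runge-Kutta in arc length; the apex
    singularity is handled by the analytic limit ``sin(phi)/x -> 1/b``.

    Parameters
    ----------
    bond : float
        Bond number (>= 0).
    apex_radius : float
        Radius of curvature at the apex [m] (> 0).
    arc_length_max : float, optional
        Arc length at which to stop [m]; defaults to ``3 * apex_radius``.
    step : float, optional
        Integration step [m]; defaults to ``apex_radius / 200``.
    orientation : {"pendant", "sessile"}
        Sign of the gravitational term.

    Returns
    -------
    DropProfile
        Profile from the apex outward.  ``closed`` is set when the tangent
        angle reached pi before ``arc_length_max``.
    """
    b = float(apex_radius)
    if b <= 0:
        raise InvalidParameterError("apex_radius must be positive")
    if bond < 0:
        raise InvalidParameterError("bond number must be non-negative")
    if orientation not in ("pendant", "sessile"):
        raise InvalidParameterError(f"unknown orientation {orientation!r}")
    if step is None:
        step = b / 200.0
    if arc_length_max is None:
        arc_length_max = 3.0 * b
    if step <= 0:
        raise InvalidParameterError("step must be positive")
    if arc_length_max <= step:
        raise InvalidParameterError("arc_length_max must exceed step")

    # hydrostatics: in a hanging drop the Laplace pressure falls with height
    # above the apex (elongation); in a sitting drop it rises below the apex
    # (flattening)
    sign = -1.0 if orientation == "pendant" else +1.0
    n_steps = int(math.ceil(arc_length_max / step))
    h = arc_length_max / n_steps

    xs = [0.0]
    zs = [0.0]
    x, z, phi = 0.0, 0.0, 0.0
    closed = False
    for _ in range(n_steps):
        k1 = _rhs(x, z, phi, b, bond, sign)
        k2 = _rhs(x + 0.5 * h * k1[0], z + 0.5 * h * k1[1], phi + 0.5 * h * k1[2], b, bond, sign)
        k3 = _rhs(x + 0.5 * h * k2[0], z + 0.5 * h * k2[1], phi + 0.5 * h * k2[2], b, bond, sign)
        k4 = _rhs(x + h * k3[0], z + h * k3[1], phi + h * k3[2], b, bond, sign)
        x += h * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0]) / 6.0
        z += h * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1]) / 6.0
        phi += h * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2]) / 6.0
        if phi >= math.pi:
            closed = True
            break
        xs.append(x)
        zs.append(z)

    return DropProfile(np.array(xs), np.array(zs), orientation=orientation, closed=closed)


def _resample_polyline(pts: np.ndarray, n: int) -> np.ndarray:
    """Resample a polyline to ``n`` points uniformly spaced in arc length."""
    seg = np.hypot(np.diff(pts[:, 0]), np.diff(pts[:, 1]))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return np.repeat(pts[:1], n, axis=0)
    target = np.linspace(0.0, total, n)
    return np.column_stack([np.interp(target, s, pts[:, 0]),
                            np.interp(target, s, pts[:, 1])])


def _points_to_polyline_distance(points: np.ndarray, curve: np.ndarray) -> np.ndarray:
    """Orthogonal distance from each point to a polyline (segment projection)."""
    a = curve[:-1]                       # (M, 2)
    ab = curve[1:] - a                   # (M, 2)
    ab2 = np.einsum("ij,ij->i", ab, ab)
    ab2[ab2 == 0] = 1.0
    # (N, M, 2) broadcasting: points against every segment
    ap = points[:, None, :] - a[None, :, :]
    t = np.clip(np.einsum("nmj,mj->nm", ap, ab) / ab2[None, :], 0.0, 1.0)
    d = ap - t[:, :, None] * ab[None, :, :]
    dist = np.sqrt(np.einsum("nmj,nmj->nm", d, d))
    return dist.min(axis=1)


def _apex_circle_radius(profile: DropProfile, fraction: float = 0.2) -> float:
    """Estimate the apex radius from a circle fit to the near-apex points.

    A circle with its center constrained to the symmetry axis satisfies
    ``x^2 + z^2 = 2 c z`` with ``c`` the center height; linear least squares.
    """
    n = max(5, int(round(fraction * len(profile))))
    x = profile.x[:n]
    z = profile.z[:n]
    rhs = x * x + z * z
    a = np.column_stack([2.0 * z, np.ones_like(z)])
    (c, k), *_ = np.linalg.lstsq(a, rhs, rcond=None)
    r2 = k + c * c
    if r2 <= 0:
        raise InsufficientProfileError("apex circle fit failed (degenerate profile)")
    return float(math.sqrt(r2))


def profile_residual(profile: DropProfile, apex_radius: float, bond: float,
                     n_model: int = 200) -> float:
    """Mean orthogonal distance between a profile and the model shape.

    The model is integrated to the observed arc length plus a small margin
    and resampled to ``n_model`` points before segment-projection distance.
    """
    arc = 1.02 * profile.arc_length()
    model = integrate_drop_profile(bond, apex_radius, arc_length_max=arc,
                                   step=apex_radius / 200.0,
                                   orientation=profile.orientation)
    curve = _resample_polyline(model.points, n_model)
    return float(_points_to_polyline_distance(profile.points, curve).mean())


def fit_pendant_profile(
    profile: DropProfile,
    density_difference: float,
    gravity: float = DEFAULT_GRAVITY,
    init: PendantFit | None = None,
    rmse_tolerance: float = 1e-5,
    max_iter: int = 600,
) -> PendantFit:
    """Recover surface tension from a pendant-drop silhouette.

    Minimizes the mean orthogonal distance between the observed profile and
    the integrated Young-Laplace shape over ``(apex_radius, bond)`` with a
    bounded Nelder-Mead search, then converts the optimum to
    :math:`\\gamma = \\Delta\\rho\\, g\\, b^2 / \\beta`.

    Parameters
    ----------
    profile : DropProfile
        Observed half-silhouette with at least 20 points.
    density_difference : float
        Density difference between drop and surrounding phase [kg/m^3] (> 0).
    gravity : float
        Gravitational acceleration [m/s^2].
    init : PendantFit, optional
        Warm start; otherwise the apex radius is seeded from a circle fit to
        the 20% of points nearest the apex and the Bond number from 0.2.
    rmse_tolerance : float
        Residual [m] below which the fit is declared converged.
    max_iter : int
        Nelder-Mead iteration cap per start.

    Returns
    -------
    PendantFit
    """
    if len(profile) < 20:
        raise InsufficientProfileError(
            f"need at least 20 profile points, got {len(profile)}")
    if density_difference <= 0:
        raise InvalidParameterError("density_difference must be positive")
    if gravity <= 0:
        raise InvalidParameterError("gravity must be positive")
    # collinearity check via the smaller singular value of centered points
    pts = profile.points - profile.points.mean(axis=0)
    sv = np.linalg.svd(pts, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1e-300):
        raise InsufficientProfileError("profile points are collinear")

    if init is not None:
        b0, beta0 = init.apex_radius, init.bond_number
    else:
        b0 = _apex_circle_radius(profile)
        beta0 = 0.2

    bounds = [(0.2 * b0, 5.0 * b0), (1e-4, 3.0)]

    def objective(p):
        b, beta = p
        try:
            return profile_residual(profile, b, beta)
        except InvalidParameterError:
            return 1e6 * b0

    def solve(x0):
        return minimize(objective, x0, method="Nelder-Mead", bounds=bounds,
                        options={"xatol": 1e-6 * b0, "fatol": 1e-12 * b0,
                                 "maxiter": max_iter})

    res = solve([b0, max(min(beta0, bounds[1][1]), bounds[1][0])])
    # fallback restarts: the spec objective can be multimodal for strongly
    # necked drops when started far from the true Bond number
    if res.fun > max(rmse_tolerance, 1e-4 * b0):
        for beta_try in (0.05, 0.5, 1.0, 1.5):
            alt = solve([b0, beta_try])
            if alt.fun < res.fun:
                res = alt

    b_fit, beta_fit = map(float, res.x)
    gamma = density_difference * gravity * b_fit ** 2 / beta_fit
    rmse = float(res.fun)
    return PendantFit(
        surface_tension=gamma,
        apex_radius=b_fit,
        bond_number=beta_fit,
        rmse=rmse,
        converged=bool(res.success) and rmse <= rmse_tolerance,
    )


def bond_number(gamma: float, density_difference: float, apex_radius: float,
                gravity: float = DEFAULT_GRAVITY) -> float:
    """Bond number ``beta = drho * g * b^2 / gamma`` for given physicals."""
    if gamma <= 0 or density_difference <= 0 or apex_radius <= 0 or gravity <= 0:
        raise InvalidParameterError("all physical parameters must be positive")
    return density_difference * gravity * apex_radius ** 2 / gamma
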