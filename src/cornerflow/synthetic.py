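"""Seed-deterministic synthetic inputs with known ground truth.

Every downstream stage of the pipeline has a generator here whose truth it
must recover: rendered pendant silhouettes (surface tension), spherical-cap
sessile drops (contact angle), corner time-lapse stacks (tip trajectory),
and concentration series (wetting-threshold crossing).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InfeasibleDropError, InvalidInputError, InvalidParameterError
from .imaging import DropImage
from .corner import SurfactantSeries
from .tracking import ramp_plateau
from .younglaplace import DEFAULT_GRAVITY, bond_number, integrate_drop_profile

__all__ = [
    "SyntheticTruth",
    "gen_pendant_image",
    "gen_sessile_image",
    "gen_corner_timelapse",
    "gen_concentration_series",
    "theta_crossing_concentration",
]


@dataclass
class SyntheticTruth:
    """Generator parameters plus the ground-truth quantity the artifact encodes."""

    kind: str
    seed: int
    params: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(f"not JSON serializable: {type(o)}")
        return json.dumps(
            {"kind": self.kind, "seed": self.seed,
             "params": self.params, "truth": self.truth},
            sort_keys=True, default=_default)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(kind=d["kind"], seed=d["seed"],
                   params=d["params"], truth=d["truth"])


def _render_halfwidths(height_px: int, width_px: int, axis_col: float,
                       rows: np.ndarray, halfwidth_px: np.ndarray,
                       fg: float, bg: float) -> np.ndarray:
    """Rasterize a symmetric silhouette with area-coverage anti-aliasing.

    Pixel value interpolates linearly between background and foreground with
    the covered fraction, so a 0.5-threshold crossing interpolated between
    pixel centers lands on the true edge position.
    """
    img = np.full((height_px, width_px), bg, dtype=float)
    cols = np.arange(width_px, dtype=float)
    for r, w in zip(rows, halfwidth_px):
        if w <= 0:
            continue
        left, right = axis_col - w, axis_col + w
        cov = np.clip(np.minimum(cols + 0.5, right) - np.maximum(cols - 0.5, left),
                      0.0, 1.0)
        img[r] = bg + (fg - bg) * cov
    return img


def gen_pendant_image(
    gamma: float,
    density_difference: float = 1000.0,
    apex_radius: float = 1.5e-3,
    calibration: float = 5e-6,
    noise_sigma_px: float = 0.0,
    seed: int = 0,
    gravity: float = DEFAULT_GRAVITY,
    arc_factor: float = 2.0,
) -> tuple[DropImage, SyntheticTruth]:
    """Render a pendant-drop silhouette (dark on light) with known gamma.

    The silhouette is the Young-Laplace shape for the implied Bond number;
    seeded Gaussian jitter is added to the per-row half-width.  Drops whose
    Bond number reaches 1.5, or whose profile closes before the requested
    arc length, are rejected as infeasible (they would detach).
    """
    if gamma <= 0 or density_difference <= 0 or apex_radius <= 0 or calibration <= 0:
        raise InvalidParameterError("physical parameters must be positive")
    beta = bond_number(gamma, density_difference, apex_radius, gravity)
    if beta >= 1.5:
        raise InfeasibleDropError(f"Bond number {beta:.2f} >= 1.5: drop would detach")
    profile = integrate_drop_profile(beta, apex_radius,
                                     arc_length_max=arc_factor * apex_radius,
                                     orientation="pendant")
    if profile.closed:
        raise InfeasibleDropError("profile closes before the needle plane")

    rng = np.random.default_rng(seed)
    margin = 20
    z_max_px = int(math.ceil(profile.z.max() / calibration))
    x_max_px = int(math.ceil(profile.x.max() / calibration))
    height_px = z_max_px + 2 * margin
    width_px = 2 * x_max_px + 2 * margin
    axis_col = width_px / 2.0
    apex_row = height_px - margin  # apex at the bottom, needle side at the top

    rows = np.arange(apex_row - z_max_px, apex_row + 1)
    z_rows = (apex_row - rows) * calibration
    halfwidth_px = np.interp(z_rows, profile.z, profile.x) / calibration
    if noise_sigma_px > 0:
        halfwidth_px = halfwidth_px + rng.normal(0.0, noise_sigma_px,
                                                 size=halfwidth_px.size)
        halfwidth_px = np.clip(halfwidth_px, 0.0, None)

    pixels = _render_halfwidths(height_px, width_px, axis_col, rows,
                                halfwidth_px, fg=0.1, bg=1.0)
    truth = SyntheticTruth(
        kind="pendant",
        seed=seed,
        params={"gamma": gamma, "density_difference": density_difference,
                "apex_radius": apex_radius, "calibration": calibration,
                "noise_sigma_px": noise_sigma_px, "gravity": gravity},
        truth={"gamma": gamma, "bond_number": beta, "apex_row": int(apex_row),
               "axis_col": axis_col},
    )
    return DropImage(pixels, calibration), truth


def gen_sessile_image(
    theta_deg: float,
    cap_base_radius: float = 2.0e-3,
    calibration: float = 5e-6,
    noise_sigma_px: float = 0.0,
    seed: int = 0,
) -> tuple[DropImage, SyntheticTruth]:
    """Render a spherical-cap sessile drop above a substrate line.

    The cap meets the baseline at exactly ``theta_deg``; the substrate is a
    darker band below the baseline row so that baseline detection has a
    dominant horizontal edge to find.
    """
    if not 5.0 <= theta_deg <= 175.0:
        raise InvalidParameterError("theta must lie in [5, 175] degrees")
    if cap_base_radius <= 0 or calibration <= 0:
        raise InvalidParameterError("geometry parameters must be positive")
    theta = math.radians(theta_deg)
    sphere_radius = cap_base_radius / math.sin(theta)
    center_height = -sphere_radius * math.cos(theta)  # above baseline; <0 when theta<90
    apex_height = center_height + sphere_radius

    rng = np.random.default_rng(seed)
    margin = 20
    apex_px = int(math.ceil(apex_height / calibration))
    max_halfwidth = sphere_radius if theta_deg > 90.0 else cap_base_radius
    halfwidth_margin_px = int(math.ceil(max_halfwidth / calibration)) + margin

    baseline_row = margin + apex_px
    height_px = baseline_row + 2 * margin  # substrate band below
    width_px = 2 * halfwidth_margin_px
    axis_col = width_px / 2.0

    rows = np.arange(baseline_row)
    z_above = (baseline_row - rows) * calibration  # height above the baseline
    inside = z_above <= apex_height
    halfwidth = np.zeros(rows.size)
    dz = z_above[inside] - center_height
    halfwidth[inside] = np.sqrt(np.clip(sphere_radius ** 2 - dz ** 2, 0.0, None))
    halfwidth_px = halfwidth / calibration
    if noise_sigma_px > 0:
        jitter = rng.normal(0.0, noise_sigma_px, size=halfwidth_px.size)
        halfwidth_px = np.where(halfwidth_px > 0,
                                np.clip(halfwidth_px + jitter, 0.0, None), 0.0)

    pixels = _render_halfwidths(height_px, width_px, axis_col, rows,
                                halfwidth_px, fg=0.1, bg=1.0)
    pixels[baseline_row:] = 0.35  # substrate band

    truth = SyntheticTruth(
        kind="sessile",
        seed=seed,
        params={"theta_deg": theta_deg, "cap_base_radius": cap_base_radius,
                "calibration": calibration, "noise_sigma_px": noise_sigma_px},
        truth={"theta_deg": theta_deg, "baseline_row": int(baseline_row),
               "axis_col": axis_col},
    )
    return DropImage(pixels, calibration), truth


def gen_corner_timelapse(
    h_max: float,
    t_start_h: float,
    t_end_h: float,
    total_hours: float = 24.0,
    frame_interval_min: float = 10.0,
    corner_alpha_deg: float = 30.0,
    calibration: float = 50e-6,
    noise_sigma: float = 0.02,
    seed: int = 0,
    frame_height: int = 320,
    frame_width: int = 64,
) -> tuple[np.ndarray, SyntheticTruth]:
    """Generate a corner time-lapse stack with a ramp-plateau tip trajectory.

    The liquid pool fills every row below the baseline; the corner flow is a
    bright column segment inside the corner ROI whose top follows the truth
    trajectory (zero before ``t_start_h``, linear ramp, plateau at ``h_max``
    from ``t_end_h``).  ``h_max = 0`` emulates a surfactant-deficient
    control.  Seeded Gaussian intensity noise is added per pixel.
    """
    if not 0.0 < t_start_h < t_end_h <= total_hours:
        raise InvalidParameterError("need 0 < t_start < t_end <= total_hours")
    if h_max < 0:
        raise InvalidParameterError("h_max must be non-negative")
    if frame_interval_min <= 0 or calibration <= 0:
        raise InvalidParameterError("frame interval and calibration must be positive")
    if not 0.0 < corner_alpha_deg < 180.0:
        raise InvalidParameterError("corner angle must lie in (0, 180) degrees")

    rng = np.random.default_rng(seed)
    n_frames = int(math.floor(total_hours * 60.0 / frame_interval_min)) + 1
    times_h = np.arange(n_frames) * frame_interval_min / 60.0
    baseline_row = frame_height - 40
    if h_max / calibration > baseline_row - 10:
        raise InvalidParameterError("h_max does not fit in the frame")
    heights = (ramp_plateau(times_h, t_start_h, t_end_h, h_max)
               if h_max > 0 else np.zeros(n_frames))

    c_mid = frame_width // 2
    c0, c1 = c_mid - 4, c_mid + 4  # corner filament columns
    bg, fg = 0.1, 0.9
    stack = np.full((n_frames, frame_height, frame_width), bg, dtype=float)
    stack[:, baseline_row:, :] = fg  # liquid pool below the initial level
    for i, h in enumerate(heights):
        h_px = h / calibration
        tip = baseline_row - h_px
        full_top = int(math.ceil(tip))
        if full_top < baseline_row:
            stack[i, full_top:baseline_row, c0:c1] = fg
        frac = full_top - tip  # partial coverage of the tip pixel
        if frac > 0 and 0 <= full_top - 1:
            stack[i, full_top - 1, c0:c1] = bg + frac * (fg - bg)
    if noise_sigma > 0:
        stack = np.clip(stack + rng.normal(0.0, noise_sigma, stack.shape), 0.0, 1.0)

    truth = SyntheticTruth(
        kind="timelapse",
        seed=seed,
        params={"h_max": h_max, "t_start_h": t_start_h, "t_end_h": t_end_h,
                "total_hours": total_hours, "frame_interval_min": frame_interval_min,
                "corner_alpha_deg": corner_alpha_deg, "calibration": calibration,
                "noise_sigma": noise_sigma},
        truth={"times_h": times_h.tolist(), "heights_m": heights.tolist(),
               "baseline_row": int(baseline_row), "corner_roi": [int(c0), int(c1)],
               "mean_speed_m_per_h": (h_max / (t_end_h - t_start_h))},
    )
    return stack, truth


def _logistic_decrease(log_c: np.ndarray, high: float, low: float,
                       log_c_mid: float, slope: float) -> np.ndarray:
    """Monotone decrease from ``high`` to ``low`` with midpoint in log10 C."""
    return low + (high - low) / (1.0 + 10.0 ** (slope * (log_c - log_c_mid)))


def gen_concentration_series(
    concentrations: np.ndarray,
    theta_high_deg: float = 120.0,
    theta_low_deg: float = 60.0,
    gamma_high: float = 0.072,
    gamma_low: float = 0.028,
    log_c_mid: float = -4.0,
    slope: float = 1.5,
    noise: float = 0.0,
    seed: int = 0,
    label: str = "synthetic",
) -> tuple[SurfactantSeries, SyntheticTruth]:
    """Concentration series with logistic-in-log10 gamma(C) and theta(C).

    Both curves decrease from their high plateau to their low plateau around
    ``log_c_mid`` with the given per-decade steepness.  ``noise`` is a
    relative jitter (fraction of the plateau-to-plateau range) applied to
    both columns.  The truth records the analytic parameters, from which the
    crossing concentration of any contact-angle threshold follows.
    """
    concentrations = np.asarray(concentrations, dtype=float)
    if concentrations.size == 0:
        raise InvalidInputError("need at least one concentration")
    if np.any(concentrations <= 0):
        raise InvalidInputError("concentrations must be positive")
    if concentrations.size > 1 and not np.all(np.diff(concentrations) > 0):
        raise InvalidInputError("concentrations must be strictly increasing")
    if theta_high_deg <= theta_low_deg:
        raise InvalidParameterError("theta_high must exceed theta_low")
    if gamma_high <= gamma_low:
        raise InvalidParameterError("gamma_high must exceed gamma_low")
    if slope <= 0:
        raise InvalidParameterError("slope must be positive")

    rng = np.random.default_rng(seed)
    log_c = np.log10(concentrations)
    theta = _logistic_decrease(log_c, theta_high_deg, theta_low_deg, log_c_mid, slope)
    gamma = _logistic_decrease(log_c, gamma_high, gamma_low, log_c_mid, slope)
    if noise > 0:
        theta = theta + rng.normal(0.0, noise * (theta_high_deg - theta_low_deg),
                                   theta.size)
        gamma = gamma + rng.normal(0.0, noise * (gamma_high - gamma_low), gamma.size)
        theta = np.clip(theta, 0.0, 180.0)
        gamma = np.clip(gamma, 1e-4, None)

    series = SurfactantSeries(concentrations, gamma, theta, label=label)
    truth = SyntheticTruth(
        kind="concentration_series",
        seed=seed,
        params={"theta_high_deg": theta_high_deg, "theta_low_deg": theta_low_deg,
                "gamma_high": gamma_high, "gamma_low": gamma_low,
                "log_c_mid": log_c_mid, "slope": slope, "noise": noise},
        truth={"concentrations": concentrations.tolist()},
    )
    return series, truth


def theta_crossing_concentration(truth: SyntheticTruth, threshold_deg: float
                                 ) -> float | None:
    """Analytic concentration where the noiseless theta(C) crosses a threshold.

    Returns None when the threshold lies outside the open plateau interval.
    """
    p = truth.params
    high, low = p["theta_high_deg"], p["theta_low_deg"]
    if not low < threshold_deg < high:
        return None
    frac = (threshold_deg - low) / (high - low)
    log_c = p["log_c_mid"] + math.log10((1.0 - frac) / frac) / p["slope"]
    return 10.0 ** log_c
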