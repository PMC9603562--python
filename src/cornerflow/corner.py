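"""Corner-flow predictions: wetting criterion, critical angle, rise height.

A liquid spreads spontaneously along an interior corner of opening angle
``alpha`` when ``alpha/2 + theta_c < 90 deg`` (Concus-Finn).  In a rounded
corner the rise is capped by the minimum gap ``d`` at the tip: balancing the
capillary force between effectively parallel walls against the weight of the
risen liquid gives ``h = 2 * gamma * cos(theta_c) / (rho * g * d)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import InvalidInputError, InvalidParameterError
from .younglaplace import FluidProperties

__all__ = [
    "CornerSpec",
    "FlowPrediction",
    "SurfactantSeries",
    "ConcentrationBracket",
    "concus_finn_flow",
    "critical_corner_angle",
    "max_rise_height",
    "critical_concentration",
]

#: Default half-width [deg] of the "marginal" band around the wetting boundary.
DEFAULT_MARGINAL_TOLERANCE_DEG = 1.0


@dataclass
class CornerSpec:
    """Interior corner geometry: opening angle and minimum gap at the tip."""

    alpha_deg: float
    min_gap: float  # [m]

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_deg < 180.0:
            raise InvalidParameterError("corner angle must lie in (0, 180) degrees")
        if self.min_gap <= 0:
            raise InvalidParameterError("minimum gap must be positive")


@dataclass
class FlowPrediction:
    """Outcome of the corner-wetting criterion.

    ``margin_deg`` is ``90 - (alpha/2 + theta_c)`` in degrees: positive means
    the corner admits flow.  ``h_max`` is filled in by callers that also know
    the rounded-tip gap.
    """

    flows: str  # yes | no | marginal
    margin_deg: float
    h_max: float | None = None

    def to_dict(self) -> dict:
        d = {"flows": self.flows, "margin_deg": self.margin_deg}
        if self.h_max is not None:
            d["h_max_m"] = self.h_max
        return d


class ConcentrationBracket(NamedTuple):
    """Bracketing interval around the onset of corner flow.

    ``c_low`` is None when even the lowest tested concentration flows
    (onset below the measured range).
    """

    c_low: float | None
    c_high: float


@dataclass
class SurfactantSeries:
    """Per-concentration surface tension and contact angle measurements."""

    concentrations: np.ndarray  # [mol/L], strictly increasing
    surface_tensions: np.ndarray  # [N/m]
    contact_angles_deg: np.ndarray  # [deg]
    label: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.surface_tensions = np.asarray(self.surface_tensions, dtype=float)
        self.contact_angles_deg = np.asarray(self.contact_angles_deg, dtype=float)
        n = self.concentrations.size
        if n == 0:
            raise InvalidInputError("series must contain at least one row")
        if self.surface_tensions.size != n or self.contact_angles_deg.size != n:
            raise InvalidInputError("series columns must have equal length")
        if n > 1 and not np.all(np.diff(self.concentrations) > 0):
            raise InvalidInputError("concentrations must be strictly increasing")
        if np.any(self.surface_tensions <= 0):
            raise InvalidInputError("surface tensions must be positive")
        if np.any((self.contact_angles_deg < 0) | (self.contact_angles_deg > 180)):
            raise InvalidInputError("contact angles must lie in [0, 180] degrees")

    def __len__(self) -> int:
        return self.concentrations.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "concentration_M": self.concentrations,
            "gamma_N_per_m": self.surface_tensions,
            "theta_deg": self.contact_angles_deg,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, label: str = "") -> "SurfactantSeries":
        df = pd.read_csv(path)
        required = {"concentration_M", "gamma_N_per_m", "theta_deg"}
        missing = required - set(df.columns)
        if missing:
            raise InvalidInputError(f"series CSV missing columns: {sorted(missing)}")
        return cls(df["concentration_M"].to_numpy(),
                   df["gamma_N_per_m"].to_numpy(),
                   df["theta_deg"].to_numpy(), label=label)


def _check_angles(alpha_deg: float, theta_deg: float) -> None:
    if not 0.0 < alpha_deg < 180.0:
        raise InvalidParameterError("corner angle must lie in (0, 180) degrees")
    if not 0.0 <= theta_deg <= 180.0:
        raise InvalidParameterError("contact angle must lie in [0, 180] degrees")


def concus_finn_flow(
    alpha_deg: float,
    theta_deg: float,
    tolerance_deg: float = DEFAULT_MARGINAL_TOLERANCE_DEG,
) -> FlowPrediction:
    """Apply the corner-wetting criterion ``alpha/2 + theta_c < 90 deg``.

    ``flows`` is "yes" when the margin exceeds ``tolerance_deg``, "marginal"
    within the band, "no" otherwise.  A nonzero default band is kept because
    observed onsets sit exactly on the boundary at desk precision.
    """
    _check_angles(alpha_deg, theta_deg)
    if tolerance_deg < 0:
        raise InvalidParameterError("tolerance must be non-negative")
    margin = 90.0 - (alpha_deg / 2.0 + theta_deg)
    if margin > tolerance_deg:
        flows = "yes"
    elif abs(margin) <= tolerance_deg:
        flows = "marginal"
    else:
        flows = "no"
    return FlowPrediction(flows=flows, margin_deg=margin)


def critical_corner_angle(theta_min_deg: float) -> float:
    """Largest corner opening that still admits flow: ``2 * (90 - theta_min)``.

    Clamped at 0 for non-wetting liquids (no corner admits flow).
    """
    if not 0.0 <= theta_min_deg <= 180.0:
        raise InvalidParameterError("contact angle must lie in [0, 180] degrees")
    return max(0.0, 2.0 * (90.0 - theta_min_deg))


def max_rise_height(fluid: FluidProperties, corner: CornerSpec) -> float:
    """Maximum capillary rise height in a rounded corner [m].

    ``h = 2 * gamma * cos(theta_c) / (rho * g * d)`` for a wetting liquid
    (theta_c < 90 deg); 0 otherwise.  Independent of the opening angle under
    the parallel-plate (step-structure) approximation of the rounded tip.
    """
    theta = fluid.contact_angle_deg
    if theta >= 90.0:
        return 0.0
    return (2.0 * fluid.surface_tension * math.cos(math.radians(theta))
            / (fluid.density * fluid.gravity * corner.min_gap))


def critical_concentration(
    series: SurfactantSeries,
    alpha_deg: float,
    tolerance_deg: float = 0.0,
) -> ConcentrationBracket | None:
    """Bracket the lowest concentration at which the corner admits flow.

    Scans the series in increasing concentration as-is (no smoothing; the
    first crossing wins) and returns ``(largest C without flow, smallest C
    with flow)``.  Returns None when no concentration flows and
    ``(None, C[0])`` when the lowest concentration already flows.
    """
    if len(series) == 0:
        raise InvalidInputError("empty series")
    flows = [concus_finn_flow(alpha_deg, float(t), tolerance_deg).flows == "yes"
             for t in series.contact_angles_deg]
    first_yes = next((i for i, f in enumerate(flows) if f), None)
    if first_yes is None:
        return None
    c = series.concentrations
    if first_yes == 0:
        return ConcentrationBracket(None, float(c[0]))
    return ConcentrationBracket(float(c[first_yes - 1]), float(c[first_yes]))
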