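"""Drop silhouette extraction and contact-angle goniometry.

Image convention: row 0 is the top of the frame.  Physical heights are
converted so that z increases away from the drop apex before any geometry is
computed; the substrate baseline is either detected as the dominant
horizontal intensity edge in the lower half of the frame or supplied by the
caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import (
    BaselineNotFoundError,
    InvalidParameterError,
    NoContactError,
    SegmentationError,
)
from .younglaplace import DropProfile

__all__ = [
    "DropImage",
    "ContactAngleMeasurement",
    "extract_drop_edge",
    "detect_baseline",
    "measure_contact_angle",
    "contact_angle_from_image",
]

#: Minimum connected silhouette area [px] accepted by segmentation.
MIN_SILHOUETTE_PX = 400

#: Default number of edge points in the tangent fit near the contact line.
DEFAULT_TANGENT_WINDOW = 15


@dataclass
class DropImage:
    """A grayscale goniometry/tensiometry frame with its calibration.

    ``baseline_row`` marks the substrate surface (row index); pixels at or
    below it are ignored during edge extraction (mirror-reflection crop).
    """

    pixels: np.ndarray
    calibration: float
    baseline_row: int | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise InvalidParameterError("pixels must be a 2-D grayscale array")
        if self.calibration <= 0:
            raise InvalidParameterError("calibration must be positive")
        if self.baseline_row is not None and not (
                0 <= self.baseline_row < self.pixels.shape[0]):
            raise InvalidParameterError("baseline_row outside image bounds")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ContactAngleMeasurement:
    """Advancing contact angle against the substrate baseline.

    ``uncertainty`` is the half-spread between the left- and right-side
    measurements (0 when only one side was measured).
    """

    theta_deg: float
    side: str  # left | right | mean
    tangent_window: int
    uncertainty_deg: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta_deg <= 180.0:
            raise InvalidParameterError("contact angle must lie in [0, 180] degrees")
        if self.tangent_window < 5:
            raise InvalidParameterError("tangent_window must be >= 5")

    def to_dict(self) -> dict:
        return {
            "theta_deg": self.theta_deg,
            "side": self.side,
            "tangent_window": self.tangent_window,
            "uncertainty_deg": self.uncertainty_deg,
        }


def detect_baseline(image: DropImage, min_response: float = 0.05,
                    override: int | None = None) -> int:
    """Locate the substrate surface as the strongest horizontal edge.

    The response of a row boundary is the mean absolute vertical intensity
    difference across that boundary; the search is restricted to the lower
    half of the frame.  A config-supplied ``override`` is returned verbatim.
    """
    if override is not None:
        return int(override)
    img = image.pixels
    dyn = img.max() - img.min()
    if dyn <= 0:
        raise BaselineNotFoundError("uniform image: no baseline edge")
    response = np.abs(np.diff(img, axis=0)).mean(axis=1) / dyn
    lo = img.shape[0] // 2
    idx = int(np.argmax(response[lo:])) + lo
    if response[idx] < min_response:
        raise BaselineNotFoundError(
            f"horizontal edge response {response[idx]:.3f} below {min_response}")
    # diff[idx] sits between rows idx and idx+1; the substrate starts at idx+1
    return idx + 1


def _subpixel_crossing(row: np.ndarray, j_inside: int, direction: int,
                       thresh: float) -> float:
    """Linear interpolation of the threshold crossing next to a mask column.

    ``j_inside`` is the outermost in-mask column; ``direction`` is +1 when
    the background lies at larger column index (right edge), -1 for left.
    """
    j_out = j_inside + direction
    if not 0 <= j_out < row.size:
        return float(j_inside)
    inside, outside = row[j_inside], row[j_out]
    if outside == inside:
        return float(j_inside)
    frac = (thresh - inside) / (outside - inside)
    frac = min(max(frac, 0.0), 1.0)
    return j_inside + direction * frac


def extract_drop_edge(
    image: DropImage,
    threshold: float = 0.5,
    side: str = "right",
    orientation: str = "sessile",
    polarity: str = "dark",
    min_area_px: int = MIN_SILHOUETTE_PX,
) -> DropProfile:
    """Extract a sub-pixel drop silhouette as an apex-anchored half-profile.

    Per image row the threshold crossing is linearly interpolated between the
    outermost silhouette pixel and its background neighbour; the symmetry
    axis is the median of the row midpoints.  The result is in physical
    units, ordered from the apex outward.

    Raises
    ------
    SegmentationError
        If no (or more than one) connected silhouette of at least
        ``min_area_px`` pixels is present above the baseline.
    """
    if side not in ("left", "right"):
        raise InvalidParameterError("side must be 'left' or 'right'")
    if orientation not in ("pendant", "sessile"):
        raise InvalidParameterError("orientation must be 'pendant' or 'sessile'")
    img = image.pixels
    if image.baseline_row is not None:
        img = img[: image.baseline_row]
    if img.size == 0:
        raise SegmentationError("empty image region above baseline")

    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        raise SegmentationError("image has no intensity contrast")
    if polarity == "dark":
        thresh = hi - threshold * (hi - lo)
        mask = img < thresh
    else:
        thresh = lo + threshold * (hi - lo)
        mask = img > thresh

    labels, n = ndimage.label(mask)
    if n == 0:
        raise SegmentationError("no silhouette found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    big = np.nonzero(sizes >= min_area_px)[0]
    if big.size == 0:
        raise SegmentationError(f"no silhouette of at least {min_area_px} px")
    if big.size > 1:
        raise SegmentationError(f"{big.size} silhouettes above size cutoff")
    mask = labels == big[0] + 1

    rows = np.nonzero(mask.any(axis=1))[0]
    apex_row = rows[0] if orientation == "sessile" else rows[-1]

    left_edges, right_edges, row_idx = [], [], []
    for r in rows:
        cols = np.nonzero(mask[r])[0]
        row = img[r]
        left_edges.append(_subpixel_crossing(row, cols[0], -1, thresh))
        right_edges.append(_subpixel_crossing(row, cols[-1], +1, thresh))
        row_idx.append(r)
    left_edges = np.array(left_edges)
    right_edges = np.array(right_edges)
    row_idx = np.array(row_idx)

    axis_col = float(np.median((left_edges + right_edges) / 2.0))
    if side == "right":
        half_width = right_edges - axis_col
    else:
        half_width = axis_col - left_edges
    half_width = np.clip(half_width, 0.0, None)

    z_px = np.abs(row_idx - apex_row).astype(float)
    order = np.argsort(z_px)
    cal = image.calibration
    x = half_width[order] * cal
    z = z_px[order] * cal

    # sub-pixel apex: near the tip the silhouette is parabolic,
    # z ~ z_apex + x^2 / (2 b); the vertex offset corrects the one-pixel
    # quantization of the apex row
    apex_row_refined = float(apex_row)
    n_fit = min(10, x.size)
    if n_fit >= 3 and np.ptp(x[:n_fit]) > 0:
        a = np.column_stack([np.ones(n_fit), x[:n_fit] ** 2])
        (z_apex, curv), *_ = np.linalg.lstsq(a, z[:n_fit], rcond=None)
        if curv > 0 and abs(z_apex) < 2.0 * cal:
            z = np.clip(z - z_apex, 0.0, None)
            drow = z_apex / cal
            apex_row_refined += drow if orientation == "sessile" else -drow

    # anchor exactly at the apex
    if x[0] > 0:
        x = np.concatenate([[0.0], x])
        z = np.concatenate([[0.0], z])
    else:
        x[0] = 0.0
    return DropProfile(x, z, orientation=orientation, calibration=cal,
                       apex_px=(apex_row_refined, axis_col))


def _tangent_angle_deg(window: np.ndarray) -> float:
    """Interior contact angle from a straight-line (total least squares) fit.

    ``window`` holds (x, z) edge points with z increasing toward the
    baseline; the tangent direction is oriented up into the liquid and the
    angle is measured from the substrate direction pointing toward the drop
    axis, through the liquid.
    """
    centered = window - window.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    v = vt[0]
    if v[1] > 0:  # points toward the baseline; flip to point up into the liquid
        v = -v
    # physical up-coordinates: t = (vx, -vz); angle from (-1, 0)
    t = np.array([v[0], -v[1]])
    t /= np.linalg.norm(t)
    return math.degrees(math.acos(np.clip(-t[0], -1.0, 1.0)))


def measure_contact_angle(
    edge: DropProfile,
    baseline_z: float,
    tangent_window: int = DEFAULT_TANGENT_WINDOW,
    side: str = "right",
) -> ContactAngleMeasurement:
    """Measure the contact angle of one drop side against the baseline.

    Fits a straight line to the ``tangent_window`` edge points nearest the
    contact point and returns the interior angle between that line and the
    baseline, measured through the liquid.

    Parameters
    ----------
    edge : DropProfile
        Apex-anchored half-profile (z increasing from the apex toward the
        substrate).
    baseline_z : float
        Substrate position in the profile's z coordinate [m].
    tangent_window : int
        Number of edge points in the tangent fit (>= 5).
    side : {"left", "right"}
        Label recorded on the measurement.
    """
    if tangent_window < 5:
        raise InvalidParameterError("tangent_window must be >= 5")
    z = edge.z
    # tolerance: the crop at the baseline row leaves the last sample ~1 px short
    tol = 2.0 * (edge.calibration if edge.calibration else
                 max(float(np.median(np.diff(z))) if z.size > 1 else 0.0, 1e-12))
    if z.max() < baseline_z - tol:
        raise NoContactError(
            f"edge ends {baseline_z - z.max():.2e} m above the baseline")
    near = np.nonzero(z <= baseline_z + tol)[0]
    if near.size < tangent_window:
        raise NoContactError("not enough edge points near the contact line")
    sel = near[-tangent_window:]
    window = np.column_stack([edge.x[sel], z[sel]])
    theta = _tangent_angle_deg(window)
    return ContactAngleMeasurement(theta_deg=theta, side=side,
                                   tangent_window=tangent_window)


def contact_angle_from_image(
    image: DropImage,
    threshold: float = 0.5,
    tangent_window: int = DEFAULT_TANGENT_WINDOW,
    baseline_row: int | None = None,
) -> ContactAngleMeasurement:
    """Full goniometry pipeline: baseline, both edges, mean contact angle."""
    if baseline_row is None:
        baseline_row = (image.baseline_row if image.baseline_row is not None
                        else detect_baseline(image))
    cropped = DropImage(image.pixels, image.calibration, baseline_row=baseline_row)
    sides = {}
    for side in ("left", "right"):
        edge = extract_drop_edge(cropped, threshold=threshold, side=side,
                                 orientation="sessile")
        apex_row = edge.apex_px[0]
        baseline_z = (baseline_row - apex_row) * image.calibration
        sides[side] = measure_contact_angle(edge, baseline_z,
                                            tangent_window=tangent_window,
                                            side=side).theta_deg
    mean = 0.5 * (sides["left"] + sides["right"])
    spread = 0.5 * abs(sides["left"] - sides["right"])
    return ContactAngleMeasurement(theta_deg=mean, side="mean",
                                   tangent_window=tangent_window,
                                   uncertainty_deg=spread)
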