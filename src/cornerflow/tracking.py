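"""Corner-flow tip tracking from time-lapse stacks and onset/plateau kinetics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import medfilt

from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "TipTrajectory",
    "FlowKinetics",
    "track_tip_heights",
    "flow_onset_end",
    "ramp_plateau",
]

#: Default frame spacing [min] when no timestamps are supplied.
DEFAULT_FRAME_INTERVAL_MIN = 2.0

#: Default height [m] above which the tip counts as moving.
DEFAULT_MOVEMENT_THRESHOLD = 0.2e-3


@dataclass
class TipTrajectory:
    """Tip height of a corner flow above the initial liquid level over time.

    Negative raw detections are clipped to 0 and flagged in ``clipped``.
    """

    times_h: np.ndarray
    heights_m: np.ndarray
    frame_interval_min: float = DEFAULT_FRAME_INTERVAL_MIN
    corner_label: str = ""
    clipped: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        heights = np.asarray(self.heights_m, dtype=float)
        if self.times_h.size == 0:
            raise InvalidInputError("trajectory must contain at least one frame")
        if self.times_h.size != heights.size:
            raise InvalidInputError("times and heights must have equal length")
        if self.times_h.size > 1 and not np.all(np.diff(self.times_h) > 0):
            raise InvalidInputError("times must be strictly increasing")
        if self.clipped is None:
            self.clipped = heights < 0
        self.heights_m = np.clip(heights, 0.0, None)

    def __len__(self) -> int:
        return self.times_h.size

    def smoothed_heights(self) -> np.ndarray:
        """3-frame temporal median filter (flicker suppression)."""
        if len(self) < 3:
            return self.heights_m.copy()
        return medfilt(self.heights_m, kernel_size=3)


@dataclass
class FlowKinetics:
    """Onset time, plateau-attainment time, plateau height, mean speed."""

    t_start_h: float
    t_end_h: float
    h_max_m: float
    mean_speed_m_per_h: float
    flow_detected: bool = True

    def __post_init__(self) -> None:
        if self.flow_detected and self.t_start_h > self.t_end_h:
            raise InvalidParameterError("t_start must not exceed t_end")
        if self.mean_speed_m_per_h < 0:
            raise InvalidParameterError("mean speed must be non-negative")

    def to_dict(self) -> dict:
        return {
            "t_start_h": self.t_start_h,
            "t_end_h": self.t_end_h,
            "h_max_m": self.h_max_m,
            "mean_speed_m_per_h": self.mean_speed_m_per_h,
            "flow_detected": bool(self.flow_detected),
        }


def track_tip_heights(
    stack: np.ndarray,
    corner_roi: tuple[int, int],
    baseline_row: int,
    calibration: float,
    intensity_threshold: float = 0.5,
    frame_interval_min: float = DEFAULT_FRAME_INTERVAL_MIN,
    times_h: np.ndarray | None = None,
    corner_label: str = "",
) -> TipTrajectory:
    """Locate the corner-flow tip in every frame of a time-lapse stack.

    Per frame the tip is the topmost row inside the ``corner_roi`` column
    range whose maximum intensity exceeds ``intensity_threshold`` times the
    frame's dynamic range; its height above the initial liquid level
    (``baseline_row``) is converted to meters and clipped at 0.

    Parameters
    ----------
    stack : ndarray
        (T, H, W) image stack (any numeric dtype).
    corner_roi : (int, int)
        Half-open column range [c0, c1) containing the corner.
    baseline_row : int
        Row of the initial liquid surface.
    calibration : float
        Length per pixel [m/px].
    intensity_threshold : float
        Fraction of the per-frame dynamic range separating signal from
        background.
    frame_interval_min : float
        Frame spacing [min], used when ``times_h`` is absent.
    times_h : ndarray, optional
        Explicit frame timestamps [h].
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise InvalidInputError("stack must be a non-empty (T, H, W) array")
    c0, c1 = corner_roi
    t_frames, height, width = stack.shape
    if not (0 <= c0 < c1 <= width):
        raise InvalidInputError(f"corner_roi {corner_roi} invalid for width {width}")
    if not 0 <= baseline_row < height:
        raise InvalidInputError("baseline_row outside frame bounds")
    if calibration <= 0:
        raise InvalidParameterError("calibration must be positive")
    if frame_interval_min <= 0:
        raise InvalidParameterError("frame interval must be positive")

    heights = np.empty(t_frames)
    for i in range(t_frames):
        frame = stack[i]
        lo, hi = float(frame.min()), float(frame.max())
        if hi <= lo:  # blank frame: nothing above the pool
            heights[i] = 0.0
            continue
        thresh = lo + intensity_threshold * (hi - lo)
        row_max = frame[:, c0:c1].max(axis=1)
        above = np.nonzero(row_max > thresh)[0]
        tip_row = int(above[0]) if above.size else baseline_row
        heights[i] = (baseline_row - tip_row) * calibration

    if times_h is None:
        times_h = np.arange(t_frames) * frame_interval_min / 60.0
    return TipTrajectory(times_h, heights, frame_interval_min=frame_interval_min,
                         corner_label=corner_label)


def flow_onset_end(
    traj: TipTrajectory,
    movement_threshold: float = DEFAULT_MOVEMENT_THRESHOLD,
    plateau_fraction: float = 0.95,
    smooth: bool = True,
) -> FlowKinetics:
    """Onset, plateau attainment, and mean climbing speed of a trajectory.

    ``t_start`` is the first time the (median-filtered) height exceeds
    ``movement_threshold``; ``t_end`` the first time it reaches
    ``plateau_fraction`` of the maximum height; the mean speed is the height
    gained between those times divided by the elapsed time.  A trajectory
    that never exceeds the threshold is flagged no-flow with zero speed.
    """
    if len(traj) == 0:
        raise InvalidInputError("empty trajectory")
    h = traj.smoothed_heights() if smooth else traj.heights_m
    t = traj.times_h
    h_max = float(h.max())
    moving = np.nonzero(h > movement_threshold)[0]
    if moving.size == 0:
        return FlowKinetics(t_start_h=float(t[-1]), t_end_h=float(t[-1]),
                            h_max_m=h_max, mean_speed_m_per_h=0.0,
                            flow_detected=False)
    i_start = int(moving[0])
    reached = np.nonzero(h >= plateau_fraction * h_max)[0]
    i_end = max(int(reached[0]), i_start)
    dt = float(t[i_end] - t[i_start])
    speed = float((h[i_end] - h[i_start]) / dt) if dt > 0 else 0.0
    return FlowKinetics(t_start_h=float(t[i_start]), t_end_h=float(t[i_end]),
                        h_max_m=h_max, mean_speed_m_per_h=max(speed, 0.0))


def ramp_plateau(times_h: np.ndarray, t_start_h: float, t_end_h: float,
                 h_max: float) -> np.ndarray:
    """Piecewise-linear tip trajectory: 0, then a linear ramp, then a plateau."""
    if t_end_h <= t_start_h:
        raise InvalidParameterError("t_end must exceed t_start")
    if h_max < 0:
        raise InvalidParameterError("h_max must be non-negative")
    times_h = np.asarray(times_h, dtype=float)
    return np.interp(times_h, [t_start_h, t_end_h], [0.0, h_max])
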