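"""Gait-event detection and cycle normalization.

Heel strikes and toe offs are located from the foot-dorsum angular
velocity: each swing phase produces one dominant positive peak; the toe
off is the nearest pronounced local minimum preceding that peak and the
heel strike the nearest pronounced minimum following it. Joint-angle
trajectories are then cut at heel strikes and each cycle linearly
resampled to a fixed 256-point grid on cycle fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .synthetic import CHANNEL_ORDER, JointTrajectory, ValidationError

logger = logging.getLogger(__name__)

N_POINTS = 256
N_CHANNELS = len(CHANNEL_ORDER)


class NoGaitDetectedError(RuntimeError):
    """No swing-phase peaks found in the angular-velocity trace."""


@dataclass
class GaitEvents:
    heel_strikes: np.ndarray  # seconds, strictly increasing
    toe_offs: np.ndarray  # seconds, one per complete cycle
    sampling_rate: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.heel_strikes) <= 0):
            raise ValidationError("heel strikes must be strictly increasing")

    @property
    def n_cycles(self) -> int:
        return max(0, len(self.heel_strikes) - 1)

    def stance_fractions(self) -> np.ndarray:
        hs = self.heel_strikes
        return (self.toe_offs - hs[:-1]) / (hs[1:] - hs[:-1])


@dataclass
class GaitCycle:
    """One heel-strike-to-heel-strike segment on the fixed 256-point grid."""

    angles: np.ndarray  # (256, 6) in CHANNEL_ORDER, degrees
    stance_boundary: int  # index into [0, 256)
    subject_id: str
    side: str
    cycle_index: int
    duration_s: float

    def __post_init__(self) -> None:
        if self.angles.shape != (N_POINTS, N_CHANNELS):
            raise ValidationError(
                f"cycle matrix must be {(N_POINTS, N_CHANNELS)}, got {self.angles.shape}"
            )

    @property
    def stance_fraction(self) -> float:
        return self.stance_boundary / N_POINTS


def detect_events(
    foot_angvel: np.ndarray,
    sampling_rate: float,
    min_prominence: float = 50.0,
    min_peak_distance_s: float = 0.4,
    min_dip_prominence: float = 30.0,
    smooth_sigma: float = 2.0,
    relative_height: float = 0.4,
) -> GaitEvents:
    """Detect heel strikes and toe offs from foot angular velocity.

    Swing peaks must exceed ``min_prominence`` (deg/s) and be at least
    ``min_peak_distance_s`` apart. Toe off / heel strike are the nearest
    local minima (prominence >= ``min_dip_prominence``) before / after
    each peak. Toe offs are only retained when they fall between two
    detected heel strikes, so there is exactly one per complete cycle.
    """
    x = np.asarray(foot_angvel, dtype=float)
    if x.ndim != 1:
        raise ValidationError("foot_angvel must be 1-D")
    if not np.all(np.isfinite(x)):
        raise ValidationError("foot_angvel contains NaN/inf")
    if len(x) < sampling_rate:
        raise ValidationError("need at least 1 s of data")

    xs = gaussian_filter1d(x, smooth_sigma) if smooth_sigma > 0 else x
    distance = max(1, int(round(min_peak_distance_s * sampling_rate)))
    peaks, _ = find_peaks(xs, prominence=min_prominence, distance=distance)
    if len(peaks) == 0:
        raise NoGaitDetectedError("no swing-phase peaks found")
    # deep toe-off/heel-strike valleys lend small stance-phase humps large
    # prominence; keep only peaks comparable to the dominant swing peak
    peaks = peaks[xs[peaks] >= relative_height * xs[peaks].max()]
    minima, _ = find_peaks(-xs, prominence=min_dip_prominence)
    if len(minima) == 0:
        raise NoGaitDetectedError("no event minima found")

    heel: list[int] = []
    toe: list[int] = []
    for p in peaks:
        after = minima[minima > p]
        before = minima[minima < p]
        if len(after):
            heel.append(int(after[0]))
        if len(before):
            toe.append(int(before[-1]))
    heel_idx = np.unique(heel)
    if len(heel_idx) == 0:
        raise NoGaitDetectedError("no heel strikes recoverable")
    # one toe off per complete HS->HS cycle
    toe_idx = []
    for a, b in zip(heel_idx[:-1], heel_idx[1:]):
        inside = [t for t in toe if a < t < b]
        toe_idx.append(int(inside[0]) if inside else int(round((a + b) / 2)))
    return GaitEvents(
        heel_strikes=heel_idx / sampling_rate,
        toe_offs=np.asarray(toe_idx, dtype=float) / sampling_rate,
        sampling_rate=sampling_rate,
    )


def segment_and_normalize(
    traj: JointTrajectory,
    events: GaitEvents,
    subject_id: str = "",
    side: str = "L",
    stance_bounds: tuple[float, float] = (0.2, 0.8),
) -> list[GaitCycle]:
    """Cut a trajectory at heel strikes and resample each cycle to 256 points.

    Resampling is linear interpolation on uniform cycle fraction with both
    endpoints (the bounding heel strikes) preserved. Cycles whose stance
    fraction falls outside ``stance_bounds`` are dropped and logged.
    Returns an empty list (with a warning) when no complete cycle exists.
    """
    if events.n_cycles == 0:
        logger.warning("no complete gait cycles for subject %s", subject_id)
        return []
    fs = traj.sampling_rate
    t = traj.time_s
    chans = []
    for name in CHANNEL_ORDER:
        key = f"{name}_{side}"
        if key not in traj.channels:
            raise ValidationError(f"trajectory missing channel {key!r}")
        chans.append(np.asarray(traj.channels[key], dtype=float))

    cycles: list[GaitCycle] = []
    sfracs = events.stance_fractions()
    lo, hi = stance_bounds
    u_grid = np.linspace(0.0, 1.0, N_POINTS)
    for k in range(events.n_cycles):
        sf = sfracs[k]
        if not lo < sf < hi:
            logger.info(
                "dropping cycle %d of %s/%s: stance fraction %.2f outside (%.2f, %.2f)",
                k, subject_id, side, sf, lo, hi,
            )
            continue
        t0, t1 = events.heel_strikes[k], events.heel_strikes[k + 1]
        i0 = int(np.searchsorted(t, t0 - 0.5 / fs))
        i1 = int(np.searchsorted(t, t1 - 0.5 / fs))
        if i1 >= len(t):
            continue
        seg_t = t[i0:i1 + 1]
        u_raw = (seg_t - t0) / (t1 - t0)
        mat = np.empty((N_POINTS, N_CHANNELS))
        for c, y in enumerate(chans):
            mat[:, c] = np.interp(u_grid, u_raw, y[i0:i1 + 1])
        cycles.append(
            GaitCycle(
                angles=mat,
                stance_boundary=int(round(sf * N_POINTS)),
                subject_id=subject_id,
                side=side,
                cycle_index=k,
                duration_s=float(t1 - t0),
            )
        )
    return cycles
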