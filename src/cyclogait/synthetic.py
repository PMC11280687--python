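"""Seeded synthetic two-group gait cohorts.

Generates multi-cycle periodic joint-angle trajectories (hip/knee x
sagittal/transverse/coronal x side) plus a foot-dorsum angular-velocity
trace with known heel-strike / toe-off times, and clinical covariates with
configurable group-specific distributions. The progression group differs
from the non-progression group only by an additive amplitude bump confined
to a configurable window of the gait cycle (default: the swing phase), so
downstream classifiers and saliency maps can be validated against ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

PLANES = ("sagittal", "transverse", "coronal")
JOINTS = ("hip", "knee")
SIDES = ("L", "R")

#: Canonical channel order used by the fixed-length cycle matrix.
CHANNEL_ORDER = (
    "hip_sagittal",
    "knee_sagittal",
    "hip_transverse",
    "knee_transverse",
    "hip_coronal",
    "knee_coronal",
)

STANCE_FRACTION = 0.60


class ValidationError(ValueError):
    """Raised when a configuration or input fails validation."""


@dataclass(frozen=True)
class GaitTemplate:
    """Periodic joint-angle waveform as a truncated Fourier series.

    ``harmonics`` holds (amplitude_deg, phase_rad) pairs for harmonics
    1..n of the gait cycle, so the waveform is periodic by construction:
    evaluate(0) == evaluate(1).
    """

    joint: str
    plane: str
    harmonics: tuple[tuple[float, float], ...]
    offset: float = 0.0

    def evaluate(self, cycle_fraction: np.ndarray) -> np.ndarray:
        u = np.asarray(cycle_fraction, dtype=float)
        y = np.full_like(u, self.offset)
        for k, (amp, phase) in enumerate(self.harmonics, start=1):
            y = y + amp * np.cos(2.0 * np.pi * k * u + phase)
        return y


# Plausibility-driven defaults: hip ~30 deg flexion at heel strike falling
# to ~-10 deg extension; knee double-bump with ~60 deg peak swing flexion;
# transverse/coronal amplitudes an order of magnitude smaller.
DEFAULT_TEMPLATES: dict[tuple[str, str], GaitTemplate] = {
    ("hip", "sagittal"): GaitTemplate(
        "hip", "sagittal",
        ((19.084, -0.017), (2.585, 1.435), (0.79, -2.027), (0.263, 1.623), (0.201, -2.404)),
        offset=10.55,
    ),
    ("knee", "sagittal"): GaitTemplate(
        "knee", "sagittal",
        ((18.446, 1.543), (14.654, -2.838), (4.586, -1.868), (0.559, -2.382), (0.336, 2.407)),
        offset=22.525,
    ),
    ("hip", "transverse"): GaitTemplate(
        "hip", "transverse", ((3.625, 0.464), (0.0, -2.222), (0.403, -0.464)), offset=0.0
    ),
    ("knee", "transverse"): GaitTemplate(
        "knee", "transverse", ((2.893, 1.117), (0.13, -0.132), (0.288, -2.417)), offset=0.65
    ),
    ("hip", "coronal"): GaitTemplate(
        "hip", "coronal", ((5.395, -1.336), (1.096, -0.316), (0.111, -2.172)), offset=0.45
    ),
    ("knee", "coronal"): GaitTemplate(
        "knee", "coronal", ((2.822, -1.575), (0.425, 0.482), (0.48, 2.64)), offset=1.05
    ),
}

#: Group-specific clinical covariate (mean, sd): age yr, height cm,
#: weight kg, first Cobb angle deg.
DEFAULT_CLINICAL_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "P": {
        "age": (12.9, 2.5),
        "height": (155.1, 8.8),
        "weight": (49.9, 10.5),
        "cobb1": (13.0, 6.9),
    },
    "NP": {
        "age": (11.9, 2.5),
        "height": (147.9, 11.8),
        "weight": (44.2, 11.0),
        "cobb1": (11.6, 4.4),
    },
}

CLINICAL_FIELDS = ("age", "weight", "height", "cobb1")

# Lower truncation bounds (physical plausibility).
_CLINICAL_LOWER = {"age": 5.0, "height": 100.0, "weight": 20.0, "cobb1": 0.0}


@dataclass(frozen=True)
class CohortConfig:
    n_progression: int = 14
    n_nonprogression: int = 24
    cycles_per_subject: int = 20
    sampling_rate: float = 100.0
    effect_size: float = 8.0
    effect_window: tuple[float, float] = (0.60, 1.00)
    subject_sd: float = 2.0
    cycle_sd: float = 1.0
    stance_fraction: float = STANCE_FRACTION
    mean_cycle_duration: float = 1.1
    subject_duration_sd: float = 0.05
    cycle_duration_sd: float = 0.02
    angvel_noise_sd: float = 10.0
    clinical_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_CLINICAL_PARAMS.items()}
    )
    sides: tuple[str, ...] = SIDES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_progression < 1 or self.n_nonprogression < 1:
            raise ValidationError("group counts must be >= 1")
        if self.cycles_per_subject < 1:
            raise ValidationError("cycles_per_subject must be >= 1")
        w0, w1 = self.effect_window
        if not (0.0 <= w0 < w1 <= 1.0):
            raise ValidationError(f"malformed effect_window {self.effect_window}")
        for name in ("subject_sd", "cycle_sd", "angvel_noise_sd",
                     "subject_duration_sd", "cycle_duration_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0.2 < self.stance_fraction < 0.8:
            raise ValidationError("stance_fraction must be in (0.2, 0.8)")
        for group in ("P", "NP"):
            if group not in self.clinical_params:
                raise ValidationError(f"clinical_params missing group {group!r}")


@dataclass
class JointTrajectory:
    """Multi-channel angle time series at a fixed sampling rate.

    ``channels`` maps e.g. ``hip_sagittal_L`` or ``foot_angvel_sagittal_L``
    to a 1-D array aligned with ``time_s``.
    """

    time_s: np.ndarray
    channels: dict[str, np.ndarray]
    sampling_rate: float

    def __post_init__(self) -> None:
        n = len(self.time_s)
        for name, arr in self.channels.items():
            if len(arr) != n:
                raise ValidationError(f"channel {name!r} length mismatch")


@dataclass
class SubjectRecord:
    subject_id: str
    group: str  # "P" or "NP"
    trajectory: JointTrajectory
    clinical: dict[str, float]
    heel_strikes: dict[str, np.ndarray]  # per side, seconds
    toe_offs: dict[str, np.ndarray]  # per side, seconds

    def __post_init__(self) -> None:
        for side, hs in self.heel_strikes.items():
            if np.any(np.diff(hs) <= 0):
                raise ValidationError(f"heel strikes not increasing (side {side})")


def _effect_bump(u: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Smooth raised-cosine bump supported exactly on ``window``.

    Zero (with zero derivative) at both window edges, peaking at the
    window centre, so the group-mean difference vanishes identically
    outside the window.
    """
    w0, w1 = window
    inside = (u > w0) & (u < w1)
    out = np.zeros_like(u)
    s = (u[inside] - w0) / (w1 - w0)
    out[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * s))
    return out


def _raised_cosine(n: int) -> np.ndarray:
    """0.5*(1-cos) window over n+1 samples, zero at both ends."""
    j = np.arange(n + 1)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * j / n))


def synth_foot_angular_velocity(
    cycle_lengths: list[int],
    stance_fraction: float = STANCE_FRACTION,
    lead_in: int = 0,
    tail: int = 0,
    swing_amplitude: float = 300.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Synthesize a foot-dorsum angular-velocity trace (deg/s).

    Each cycle carries one dominant positive swing-phase peak plus sharp
    local minima exactly at its toe-off and terminal heel-strike samples,
    which is what the event detector keys on. Returns ``(signal,
    heel_strike_idx, toe_off_idx)``; indices are exact sample positions.

    ``lead_in`` samples of the tail of a notional preceding swing are
    prepended (so the first heel strike has a peak before it) and ``tail``
    quiet samples are appended after the final heel strike.
    """
    if not cycle_lengths:
        raise ValidationError("empty cycle list")
    if any(n <= 0 for n in cycle_lengths):
        raise ValidationError("non-positive cycle length")
    total = lead_in + sum(cycle_lengths) + tail
    sig = np.zeros(total)

    def add_cycle(start: int, n: int, partial_from: int = 0) -> tuple[int, int]:
        """Draw one cycle whose heel strike falls at start+n; returns (to, hs)."""
        m = int(round(stance_fraction * n))
        # stance bump: small positive hump mid-stance
        s0, s1 = int(round(0.10 * n)), int(round(0.50 * n))
        sw = _raised_cosine(s1 - s0) * 0.12 * swing_amplitude
        # swing bump: dominant peak between toe-off and heel strike
        sw2 = _raised_cosine(n - m) * swing_amplitude
        dip = -0.25 * swing_amplitude
        sigma = max(1.5, 0.02 * n)

        def paste(arr: np.ndarray, offset: int) -> None:
            for j, v in enumerate(arr):
                idx = start + offset + j - partial_from
                if 0 <= idx < total:
                    sig[idx] += v

        paste(sw, s0)
        paste(sw2, m)
        # sharp gaussian dips centred exactly on toe-off and heel strike
        half = int(np.ceil(4 * sigma))
        j = np.arange(-half, half + 1)
        g = dip * np.exp(-0.5 * (j / sigma) ** 2)
        paste(g, m - half)
        paste(g, n - half)
        return start + m - partial_from, start + n - partial_from

    events_hs: list[int] = []
    events_to: list[int] = []
    # notional preceding cycle whose heel strike falls exactly at index
    # lead_in; only its swing tail (peak + terminal dip) is inside the trace
    n0 = cycle_lengths[0]
    if lead_in > 0:
        add_cycle(lead_in, n0, partial_from=n0)
    pos = lead_in
    for n in cycle_lengths:
        to, hs = add_cycle(pos, n)
        events_to.append(to)
        events_hs.append(hs)
        pos += n
    hs_idx = np.array([lead_in] + events_hs)
    to_idx = np.array(events_to)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        sig = sig + rng.normal(0.0, noise_sd, size=total)
    return sig, hs_idx, to_idx


def _subject_trajectory(
    cfg: CohortConfig, group: str, rng: np.random.Generator
) -> tuple[JointTrajectory, dict[str, np.ndarray], dict[str, np.ndarray]]:
    fs = cfg.sampling_rate
    n_cyc = cfg.cycles_per_subject
    base_dur = cfg.mean_cycle_duration + rng.normal(0.0, cfg.subject_duration_sd)
    base_dur = max(0.8, base_dur)
    # per-channel subject-level random effects (amplitude scale + offset)
    offsets = {ch: rng.normal(0.0, cfg.subject_sd) for ch in CHANNEL_ORDER}
    # amplitude-scale sd kept small: larger values let a subject's overall
    # amplitude mimic a localized swing-phase effect at the knee peak
    scales = {ch: max(0.2, rng.normal(1.0, 0.02)) for ch in CHANNEL_ORDER}

    channels: dict[str, np.ndarray] = {}
    heel_strikes: dict[str, np.ndarray] = {}
    toe_offs: dict[str, np.ndarray] = {}
    time_s: np.ndarray | None = None
    for side in cfg.sides:
        durs = base_dur + rng.normal(0.0, cfg.cycle_duration_sd, size=n_cyc)
        lens = np.maximum(int(0.8 * fs), np.round(durs * fs).astype(int))
        lead_in = int(round(0.30 * lens[0]))
        tail = int(round(0.10 * lens[-1]))
        sig, hs_idx, to_idx = synth_foot_angular_velocity(
            list(lens),
            stance_fraction=cfg.stance_fraction,
            lead_in=lead_in,
            tail=tail,
            noise_sd=cfg.angvel_noise_sd,
            rng=rng,
        )
        total = lead_in + int(lens.sum()) + tail
        # cycle fraction at every sample (lead-in mapped to tail of a
        # notional previous cycle, tail to start of a notional next one)
        u = np.empty(total)
        u[:lead_in] = 1.0 - (lead_in - np.arange(lead_in)) / lens[0]
        pos = lead_in
        for n in lens:
            u[pos:pos + n] = np.arange(n) / n
            pos += n
        u[pos:] = np.arange(total - pos) / lens[-1]

        bump = _effect_bump(u, cfg.effect_window) if group == "P" else 0.0
        for joint in JOINTS:
            for plane in PLANES:
                ch = f"{joint}_{plane}"
                tmpl = DEFAULT_TEMPLATES[(joint, plane)]
                y = scales[ch] * tmpl.evaluate(u) + offsets[ch]
                if group == "P" and plane == "sagittal":
                    y = y + cfg.effect_size * bump
                y = y + rng.normal(0.0, cfg.cycle_sd, size=total)
                channels[f"{ch}_{side}"] = y
        channels[f"foot_angvel_sagittal_{side}"] = sig
        heel_strikes[side] = hs_idx / fs
        toe_offs[side] = to_idx / fs
        if time_s is None or total > len(time_s):
            time_s = np.arange(total) / fs

    # pad shorter sides to the common length (sides are independent traces)
    assert time_s is not None
    n_max = len(time_s)
    for name, arr in channels.items():
        if len(arr) < n_max:
            channels[name] = np.pad(arr, (0, n_max - len(arr)), mode="edge")
    traj = JointTrajectory(time_s=time_s, channels=channels, sampling_rate=fs)
    return traj, heel_strikes, toe_offs


def _draw_clinical(
    params: dict[str, tuple[float, float]], rng: np.random.Generator
) -> dict[str, float]:
    out = {}
    for name in CLINICAL_FIELDS:
        mu, sd = params[name]
        lo = _CLINICAL_LOWER[name]
        v = rng.normal(mu, sd)
        while v <= lo:  # truncate at plausibility bound
            v = rng.normal(mu, sd)
        out[name] = float(v)
    return out


def generate_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Generate a seeded synthetic cohort.

    Identical config (including seed) yields a bit-identical cohort. The
    P group differs from NP in expectation only inside
    ``config.effect_window`` (sagittal channels), by ``effect_size`` deg
    at the window centre.
    """
    ss = np.random.SeedSequence(config.seed)
    n_total = config.n_progression + config.n_nonprogression
    streams = [np.random.default_rng(s) for s in ss.spawn(n_total)]
    subjects = []
    groups = ["P"] * config.n_progression + ["NP"] * config.n_nonprogression
    for i, (group, rng) in enumerate(zip(groups, streams)):
        traj, hs, to = _subject_trajectory(config, group, rng)
        clinical = _draw_clinical(config.clinical_params[group], rng)
        subjects.append(
            SubjectRecord(
                subject_id=f"S{i:03d}",
                group=group,
                trajectory=traj,
                clinical=clinical,
                heel_strikes=hs,
                toe_offs=to,
            )
        )
    return subjects


def with_effect_size(config: CohortConfig, effect_size: float) -> CohortConfig:
    """Copy of ``config`` with a different group effect size."""
    return replace(config, effect_size=effect_size)
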