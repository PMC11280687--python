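"""Grad-CAM over the temporal axis of cyclogram inputs.

The class activation map is built from the network's final residual-block
feature maps: channel weights are the time-averaged gradients of the
target-class logit with respect to those maps, the map is the rectified
weighted sum, linearly upsampled to the 256-point cycle grid and min-max
normalized. Saliency mass above half of the map maximum is then
attributed to gait phases (stance, pre-swing, initial/mid/terminal
swing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dcnn import NormalizationStats, ResNet1D
from .events import N_POINTS
from .synthetic import ValidationError

#: Cycle-fraction cut points: stance | pre-swing | initial | mid | terminal swing.
DEFAULT_PHASE_BOUNDS = (0.50, 0.60, 0.73, 0.87)

PHASE_NAMES = ("stance", "pre_swing", "initial_swing", "mid_swing", "terminal_swing")


@dataclass
class SaliencyMap:
    values: np.ndarray  # 256 values in [0, 1]
    target_class: int
    all_zero: bool = False
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.values) != N_POINTS:
            raise ValidationError(f"saliency map must have {N_POINTS} points")
        if self.values.min() < 0 or self.values.max() > 1 + 1e-9:
            raise ValidationError("saliency values must lie in [0, 1]")


@dataclass
class PhaseAttribution:
    """Fractions of above-threshold saliency mass per gait phase.

    The five fractions partition the cycle and sum to 1. ``stance_total``
    additionally reports mass up to the cycle's stance boundary (pre-swing
    is conventionally part of stance), with ``swing_total`` its
    complement.
    """

    stance: float
    pre_swing: float
    initial_swing: float
    mid_swing: float
    terminal_swing: float
    stance_total: float
    swing_total: float
    undefined: bool = False

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PHASE_NAMES}


def grad_cam(
    model: ResNet1D,
    cycle: np.ndarray,
    clinical: np.ndarray | None,
    stats: NormalizationStats,
    target_class: int = 1,
    source: str = "",
) -> SaliencyMap:
    """Saliency over the gait cycle for one input cycle.

    ``cycle`` is an un-normalized (256, 6) matrix; ``clinical`` the raw
    4-vector (ignored when the model has no clinical branch). An all-zero
    map (vanishing gradients) is returned flagged rather than raised.
    """
    cycle = np.asarray(cycle, dtype=float)
    if cycle.shape != (N_POINTS, model.config.input_channels):
        raise ValidationError(f"cycle must be ({N_POINTS}, {model.config.input_channels})")
    clin = clinical if clinical is not None else np.zeros(len(stats.clinical_mean))
    Xn, cn = stats.normalize(cycle[None], np.asarray(clin, dtype=float)[None])
    logits = model.forward(Xn, cn if model.config.use_clinical else None, training=False)
    if not 0 <= target_class < logits.shape[1]:
        raise ValidationError(f"target_class {target_class} out of range")
    dlogits = np.zeros_like(logits)
    dlogits[0, target_class] = 1.0
    model.backward(dlogits)
    A = model.last_feature[0]  # (T', C)
    dA = model.last_feature_grad[0]
    weights = dA.mean(axis=0)  # time-averaged gradients per channel
    cam = np.maximum(A @ weights, 0.0)
    # linear upsampling to the 256-point cycle grid
    t_src = (np.arange(len(cam)) + 0.5) / len(cam)
    t_dst = (np.arange(N_POINTS) + 0.5) / N_POINTS
    cam256 = np.interp(t_dst, t_src, cam)
    peak = cam256.max()
    if peak <= 0:
        return SaliencyMap(values=np.zeros(N_POINTS), target_class=target_class,
                           all_zero=True, source=source)
    return SaliencyMap(values=cam256 / peak, target_class=target_class, source=source)


def attribute_phases(
    sal: SaliencyMap,
    stance_boundary: int,
    phase_bounds: tuple[float, float, float, float] = DEFAULT_PHASE_BOUNDS,
    threshold_frac: float = 0.5,
) -> PhaseAttribution:
    """Distribute above-threshold saliency mass over the gait phases.

    The threshold is ``threshold_frac`` times the map maximum; mass is the
    sum of saliency values at points meeting it. All-zero maps yield an
    attribution flagged ``undefined`` with zero fractions.
    """
    if not 0 <= stance_boundary < N_POINTS:
        raise ValidationError("stance_boundary out of range")
    v = sal.values
    if sal.all_zero or v.max() <= 0:
        return PhaseAttribution(0, 0, 0, 0, 0, 0, 0, undefined=True)
    mask = v >= threshold_frac * v.max()
    mass = np.where(mask, v, 0.0)
    total = mass.sum()
    u = np.arange(N_POINTS) / N_POINTS
    edges = (0.0, *phase_bounds, 1.0 + 1e-12)
    fracs = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        fracs.append(float(mass[(u >= lo) & (u < hi)].sum() / total))
    stance_total = float(mass[: stance_boundary].sum() / total)
    return PhaseAttribution(
        *fracs, stance_total=stance_total, swing_total=1.0 - stance_total
    )


def saliency_mass_in_window(sal: SaliencyMap, window: tuple[float, float],
                            threshold_frac: float = 0.5) -> float:
    """Fraction of above-threshold saliency mass inside a cycle-fraction window."""
    v = sal.values
    if v.max() <= 0:
        return 0.0
    mask = v >= threshold_frac * v.max()
    mass = np.where(mask, v, 0.0)
    u = np.arange(N_POINTS) / N_POINTS
    inside = (u >= window[0]) & (u <= window[1])
    return float(mass[inside].sum() / mass.sum())


def cohort_mean_map(maps: list[SaliencyMap]) -> np.ndarray:
    """Pointwise mean of a collection of saliency maps (0..1 scale)."""
    if not maps:
        raise ValidationError("no saliency maps supplied")
    return np.mean([m.values for m in maps], axis=0)


def plot_saliency(sal: SaliencyMap, cycle: np.ndarray, path) -> None:
    """Diagnostic figure: saliency over the cycle and over the sagittal loop."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    u = np.arange(N_POINTS) / N_POINTS
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    ax1.plot(u, cycle[:, 0], label="hip sagittal")
    ax1.plot(u, cycle[:, 1], label="knee sagittal")
    ax1t = ax1.twinx()
    ax1t.fill_between(u, sal.values, alpha=0.3, color="red")
    ax1.set_xlabel("cycle fraction")
    ax1.set_ylabel("angle (deg)")
    ax1.legend(loc="upper left")
    sc = ax2.scatter(cycle[:, 0], cycle[:, 1], c=sal.values, cmap="hot_r", s=8)
    ax2.set_xlabel("hip angle (deg)")
    ax2.set_ylabel("knee angle (deg)")
    fig.colorbar(sc, ax=ax2, label="saliency")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
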