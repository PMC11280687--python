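import numpy as np
import pandas as pd
import pytest

from cyclogait import events as ev
from cyclogait import synthetic as sg
from cyclogait.dcnn import CycleDataset, DCNNConfig


def build_cohort_cycles(cohort_cfg: sg.CohortConfig, sides=("L",)):
    """Generate a cohort and segment its cycles with detected events."""
    subjects = sg.generate_cohort(cohort_cfg)
    cycles = []
    for s in subjects:
        for side in sides:
            det = ev.detect_events(
                s.trajectory.channels[f"foot_angvel_sagittal_{side}"],
                cohort_cfg.sampling_rate,
            )
            cycles += ev.segment_and_normalize(s.trajectory, det, s.subject_id, side)
    return subjects, cycles


def cohort_metadata(subjects) -> pd.DataFrame:
    return pd.DataFrame(
        [{"subject_id": s.subject_id, "group": s.group, **s.clinical} for s in subjects]
    )


def cycle_dataset(subjects, cycles) -> CycleDataset:
    clin = {s.subject_id: s.clinical for s in subjects}
    lab = {s.subject_id: s.group for s in subjects}
    return CycleDataset.from_cycles(cycles, clin, lab)


#: Tiny network config for unit tests (trains in ~a second).
def micro_dcnn_config(**overrides) -> DCNNConfig:
    base = dict(
        n_residual_blocks=2,
        base_filters=8,
        epochs=5,
        batch_size=16,
        dropout=0.0,
        augment_offset_sd=0.0,
        block_plan=((8, 4), (16, 2)),
        seed=0,
    )
    base.update(overrides)
    return DCNNConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    """12 subjects x 8 cycles with a strong effect; shared across tests."""
    cfg = sg.CohortConfig(
        n_progression=6, n_nonprogression=6, cycles_per_subject=8,
        effect_size=8.0, seed=42,
    )
    subjects, cycles = build_cohort_cycles(cfg)
    return cfg, subjects, cycles


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    _, subjects, cycles = small_cohort
    return cycle_dataset(subjects, cycles)


def random_simple_polygon(rng: np.random.Generator, n: int = 12) -> np.ndarray:
    """Star-shaped (hence simple) polygon: random radii at sorted angles."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n))
    radii = rng.uniform(1.0, 10.0, n)
    centre = rng.uniform(-20, 20, 2)
    return np.column_stack(
        [centre[0] + radii * np.cos(angles), centre[1] + radii * np.sin(angles)]
    )
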