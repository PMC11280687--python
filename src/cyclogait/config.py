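"""Schema-validated pipeline configuration.

Unknown keys are rejected so config typos fail loudly before any stage
runs. Sections map one-to-one onto the pipeline commands.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CohortSection(_Strict):
    n_progression: int = 14
    n_nonprogression: int = 24
    cycles_per_subject: int = 20
    sampling_rate: float = 100.0
    effect_size: float = 8.0
    effect_window: tuple[float, float] = (0.60, 1.00)
    subject_sd: float = 2.0
    cycle_sd: float = 1.0
    sides: tuple[str, ...] = ("L", "R")


class EventsSection(_Strict):
    min_prominence: float = 50.0
    min_peak_distance_s: float = 0.4
    stance_bounds: tuple[float, float] = (0.2, 0.8)
    sides: tuple[str, ...] = ("L",)

    @field_validator("stance_bounds")
    @classmethod
    def _ordered(cls, v):
        if not 0 <= v[0] < v[1] <= 1:
            raise ValueError("stance_bounds must satisfy 0 <= lo < hi <= 1")
        return v


class FeaturesSection(_Strict):
    per_cycle: bool = True


class ClassicalSection(_Strict):
    svm_c: float = 1.0
    svm_kernel: str = "rbf"
    rf_n_estimators: int = 500
    use_clinical: bool = True


class DCNNSection(_Strict):
    preset: str = "reduced"  # "reduced" or "full"
    use_clinical: bool = True
    epochs: int | None = None
    batch_size: int | None = None
    dropout: float | None = None

    @field_validator("preset")
    @classmethod
    def _known(cls, v):
        if v not in ("reduced", "full"):
            raise ValueError("preset must be 'reduced' or 'full'")
        return v


class EvaluationSection(_Strict):
    k: int = 10
    stratified: bool = True


class ExplainSection(_Strict):
    target_class: int = 1
    threshold_frac: float = 0.5


class PipelineConfig(_Strict):
    seed: int = 0
    outdir: str = "out"
    cohort: CohortSection = Field(default_factory=CohortSection)
    events: EventsSection = Field(default_factory=EventsSection)
    features: FeaturesSection = Field(default_factory=FeaturesSection)
    classical: ClassicalSection = Field(default_factory=ClassicalSection)
    dcnn: DCNNSection = Field(default_factory=DCNNSection)
    evaluation: EvaluationSection = Field(default_factory=EvaluationSection)
    explain: ExplainSection = Field(default_factory=ExplainSection)


def load_config(path: str | Path | None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)
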