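"""Configuration objects for the synthetic cohort generator and the pipeline.

Every generator knob lives in :class:`CohortConfig`, which serializes to
YAML or JSON and validates on construction (positive SDs, probability
bounds, coupling inside (-1, 1), ...).  The defaults are calibrated to the
published cohort summaries of the 24-week multi-domain-intervention trial
the generator emulates: 130 participants aged 60-85 with mild cognitive
impairment, ~390 recorded task-level reaction-time/accuracy pairs each,
a mean RBANS change of 8.26 (SD 8.74), and an RTACC regression coefficient
of -11.90 on the week-24 RBANS outcome.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import yaml
from pydantic import BaseModel, Field, model_validator


class CovariateParams(BaseModel):
    """Baseline covariate distributions (truncated normals / Bernoullis)."""

    age_mean: float = 73.02
    age_sd: float = Field(5.53, gt=0)
    age_bounds: tuple[float, float] = (60.0, 85.0)  # trial eligibility window
    education_mean: float = 10.73
    education_sd: float = Field(4.54, gt=0)
    education_bounds: tuple[float, float] = (0.0, 22.0)
    p_female: float = Field(0.6385, ge=0, le=1)  # sex coded 1 = female
    p_apoe_e4: float = Field(0.3154, ge=0, le=1)
    rbans_baseline_mean: float = 90.10
    rbans_baseline_sd: float = Field(15.26, gt=0)

    @model_validator(mode="after")
    def _check_bounds(self) -> "CovariateParams":
        for lo, hi in (self.age_bounds, self.education_bounds):
            if not lo < hi:
                raise ValueError("truncation bounds must satisfy lo < hi")
        return self


class CouplingParams(BaseModel):
    """Population distribution of the per-participant latent RT-accuracy
    coupling rho_p, truncated to (-1, 1).

    The trial does not report the observed distribution of the correlation
    metric; mean -0.10 / SD 0.20 is a calibration choice that reproduces the
    printed effect size and standard error of the outcome regression.
    """

    mean: float = Field(-0.10, gt=-1, lt=1)
    sd: float = Field(0.20, gt=0)
    # task-level latents are clipped to +/- this many SDs: a 3-minute task
    # score is an average over ~10-30 trials, so gross single-task outliers
    # do not occur (matching streams that pass a k=3 MAD screen untouched)
    latent_bound: float = Field(2.0, gt=0)


class OutcomeParams(BaseModel):
    """Planted linear model for the week-24 RBANS outcome.

    rbans_week24 = rbans_baseline + b0 + b1*age + b2*sex + b3*education
                   + b4*apoe_e4 + b5*rbans_baseline + b6*rho_p + eps,
    eps ~ N(0, residual_sd^2).  Equivalently the RBANS *change* is the
    linear predictor; b5 < 0 encodes regression to the mean.
    """

    b0: float = 26.68
    b1_age: float = -0.15
    b2_sex: float = 1.0
    b3_education: float = 0.2
    b4_apoe: float = -2.0
    b5_baseline: float = -0.12
    b6_coupling: float = -11.90
    # 0 switches outcome noise off (useful for exact-recovery checks)
    residual_sd: float = Field(8.0, ge=0)


class BiomarkerPath(BaseModel):
    """Planted paths for one blood biomarker change.

    change = intercept + coupling_to_marker * rho_p + eps_m, and the marker
    feeds the outcome with weight marker_to_outcome (default 0: the trial's
    marker-to-outcome paths were all non-significant).
    """

    intercept: float = 0.0
    coupling_to_marker: float = 0.0
    marker_to_outcome: float = 0.0
    residual_sd: float = Field(1.0, ge=0)


def _default_biomarkers() -> dict[str, BiomarkerPath]:
    # Path coefficients from the published path table; residual SDs
    # back-solved so the per-path standard errors match at n = 130 with
    # coupling SD 0.20.
    return {
        "bdnf": BiomarkerPath(coupling_to_marker=-3.132, residual_sd=3.85),
        "ptau": BiomarkerPath(coupling_to_marker=2.832, residual_sd=9.9),
        "nfl": BiomarkerPath(coupling_to_marker=3.879, residual_sd=17.2),
        "gfap": BiomarkerPath(coupling_to_marker=-31.69, residual_sd=60.5),
    }


class ScheduleParams(BaseModel):
    """Weekly training schedule: sessions/week is uniform on
    [sessions_min, sessions_max], each session holds tasks_per_session
    3-minute tasks; trials per task is uniform on [trials_min, trials_max].

    Defaults give 24 * 4 * 4 = 384 expected pairs per participant,
    emulating the trial's ~390.
    """

    sessions_min: int = Field(3, ge=1)
    sessions_max: int = Field(5, ge=1)
    tasks_per_session: int = Field(4, ge=1)
    trials_min: int = Field(10, ge=1)
    trials_max: int = Field(30, ge=1)

    @model_validator(mode="after")
    def _ordered(self) -> "ScheduleParams":
        if self.sessions_max < self.sessions_min:
            raise ValueError("sessions_max < sessions_min")
        if self.trials_max < self.trials_min:
            raise ValueError("trials_max < trials_min")
        return self


class DifficultyParams(BaseModel):
    """Adaptive staircase: level goes up after a task with accuracy >=
    up_threshold, down below down_threshold, clamped to [level_min, level_max]."""

    up_threshold: float = Field(0.85, ge=0, le=1)
    down_threshold: float = Field(0.65, ge=0, le=1)
    level_min: int = 1
    level_max: int = 10
    level_start: int = 1

    @model_validator(mode="after")
    def _ordered(self) -> "DifficultyParams":
        if self.down_threshold > self.up_threshold:
            raise ValueError("down_threshold > up_threshold")
        if not self.level_min <= self.level_start <= self.level_max:
            raise ValueError("level_start outside [level_min, level_max]")
        return self


class RTParams(BaseModel):
    """Per-task mean-RT model: lognormal around location (seconds) with
    log-scale sigma, floored at rt_floor.  level_slope shifts the log
    location per difficulty level above the minimum (default 0: the
    staircase is designed to hold effective challenge constant, so the
    performance stream is stationary by default)."""

    location_s: float = Field(2.5, gt=0)
    sigma: float = Field(0.15, gt=0)
    floor_s: float = Field(0.2, gt=0)
    level_slope: float = 0.0


class AccuracyParams(BaseModel):
    """Per-task accuracy model: linear in the latent with clipping to [0,1]."""

    mean: float = Field(0.75, ge=0, le=1)
    sd: float = Field(0.08, gt=0)
    level_slope: float = 0.0


class CohortConfig(BaseModel):
    """Everything the synthetic cohort generator needs, plus the seed."""

    n_participants: int = Field(130, ge=0)
    n_weeks: int = Field(24, ge=1)
    schedule: ScheduleParams = Field(default_factory=ScheduleParams)
    covariates: CovariateParams = Field(default_factory=CovariateParams)
    coupling: CouplingParams = Field(default_factory=CouplingParams)
    outcome: OutcomeParams = Field(default_factory=OutcomeParams)
    biomarkers: dict[str, BiomarkerPath] = Field(default_factory=_default_biomarkers)
    difficulty: DifficultyParams = Field(default_factory=DifficultyParams)
    rt: RTParams = Field(default_factory=RTParams)
    accuracy: AccuracyParams = Field(default_factory=AccuracyParams)
    seed: int = 0

    def expected_pairs_per_participant(self) -> float:
        """Closed-form expected number of (RT, accuracy) pairs per participant."""
        s = self.schedule
        mean_sessions = (s.sessions_min + s.sessions_max) / 2.0
        return self.n_weeks * mean_sessions * s.tasks_per_session

    # --- serialization -------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return self.model_dump(mode="json")

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "CohortConfig":
        return cls.model_validate(d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in {".yaml", ".yml"}:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "CohortConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in {".yaml", ".yml"} else json.loads(text)
        return cls.from_dict(data)

    def config_hash(self) -> str:
        """Stable short hash of the full configuration (seed included)."""
        canon = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(canon).hexdigest()[:12]


class PreprocessConfig(BaseModel):
    """MAD-rule settings: flag |v - median| > k * scale * MAD."""

    k: float = Field(3.0, gt=0)
    scale: float = Field(1.4826, gt=0)  # normal-consistency constant
    pooled: bool = False  # pool across cohort instead of per participant
    min_records: int = Field(3, ge=1)


class MetricsConfig(BaseModel):
    windows: list[int] = Field(default_factory=lambda: [1, 2, 3, 6, 12, 24])
    min_pairs: int = Field(10, ge=3)
    correlation: str = "pearson"  # or "spearman"

    @model_validator(mode="after")
    def _check(self) -> "MetricsConfig":
        if self.correlation not in {"pearson", "spearman"}:
            raise ValueError("correlation must be 'pearson' or 'spearman'")
        if self.windows != sorted(self.windows) or len(set(self.windows)) != len(self.windows):
            raise ValueError("windows must be strictly ascending")
        if any(w < 1 for w in self.windows):
            raise ValueError("windows must be >= 1")
        return self


class ModelsConfig(BaseModel):
    adjust_covariates: bool = True
    alpha: float = Field(0.05, gt=0, le=1)
    bootstrap_reps: int = Field(2000, ge=1)
    huber_t: float = Field(1.345, gt=0)


class RunConfig(BaseModel):
    """Top-level pipeline configuration; the seed propagates everywhere."""

    cohort: CohortConfig = Field(default_factory=CohortConfig)
    participants_csv: str | None = None  # set both to ingest real-format data
    training_log_csv: str | None = None
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    metrics: MetricsConfig = Field(default_factory=MetricsConfig)
    models: ModelsConfig = Field(default_factory=ModelsConfig)
    output_dir: str = "runs/run1"
    seed: int = 0

    @model_validator(mode="after")
    def _propagate_seed(self) -> "RunConfig":
        # one seed for the whole run: the cohort generator inherits it
        object.__setattr__(self.cohort, "seed", self.seed)
        return self

    def to_dict(self) -> dict[str, Any]:
        return self.model_dump(mode="json")

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        return cls.model_validate(d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in {".yaml", ".yml"}:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in {".yaml", ".yml"} else json.loads(text)
        return cls.from_dict(data)

    def config_hash(self) -> str:
        """Hash of the scientific configuration: the output path is excluded
        so identical analyses in different directories share a hash."""
        d = self.to_dict()
        d.pop("output_dir", None)
        canon = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(canon).hexdigest()[:12]
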