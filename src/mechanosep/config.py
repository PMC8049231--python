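"""Configuration surface for the whole pipeline.

Every tunable of the simulation and analysis lives in a small frozen-ish
dataclass here, with defaults calibrated to the published cohort-level
statistics (group means/SDs of the biophysical metrics, cohort compositions,
clinical severity summaries).  Configs round-trip through plain dicts / YAML;
unknown keys are rejected so that typos fail loudly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

CELL_TYPES = ("lymphocyte", "neutrophil", "monocyte")
DISEASE_STATES = ("healthy", "sirs_nonseptic", "septic")

#: Latent immune-activation factor mean per adjudicated state.  The factor has
#: unit SD within every state; the septic-vs-SIRS gap of 1.9 caps the optimal
#: classifier AUC at Phi(1.9/sqrt(2)) ~ 0.91.
FACTOR_MEANS = {"healthy": 0.0, "sirs_nonseptic": 1.0, "septic": 2.9}

def _check_unknown(cls, data: Mapping[str, Any]) -> None:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")


class ConfigError(ValueError):
    """Raised for invalid or inconsistent configuration values."""


@dataclass
class PopulationParams:
    """Between/within-subject distribution of one cell type in one state.

    Means and between-subject SDs are on the natural scales (size and VEIR in
    um, AR dimensionless, intensity in log a.u.).  ``within_sd_factor`` scales
    the between-subject SD to the cell-level SD; ``between_feature_corr`` is
    the cell-level equicorrelation between size, AR and VEIR.
    """

    mean_size: float
    sd_size_between: float
    mean_ar: float
    sd_ar_between: float
    mean_veir: float
    sd_veir_between: float
    mean_log_intensity: float
    sd_log_intensity: float
    within_sd_factor: float = 2.0
    between_feature_corr: float = 0.8

    def __post_init__(self) -> None:
        for name in ("sd_size_between", "sd_ar_between", "sd_veir_between",
                     "sd_log_intensity"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.mean_ar < 1:
            raise ConfigError("mean_ar must be >= 1")
        if self.mean_veir < 0:
            raise ConfigError("mean_veir must be >= 0")
        rho = self.between_feature_corr
        # 3x3 equicorrelation PSD requires rho >= -1/2
        if not (-0.5 <= rho <= 1.0):
            raise ConfigError("between_feature_corr outside PSD range [-0.5, 1]")

    def mean(self, metric: str) -> float:
        return {"size": self.mean_size, "ar": self.mean_ar,
                "veir": self.mean_veir,
                "log_intensity": self.mean_log_intensity}[metric]

    def sd_between(self, metric: str) -> float:
        return {"size": self.sd_size_between, "ar": self.sd_ar_between,
                "veir": self.sd_veir_between,
                "log_intensity": self.sd_log_intensity}[metric]


def _pp(size, ar, veir, log_int) -> PopulationParams:
    return PopulationParams(
        mean_size=size[0], sd_size_between=size[1],
        mean_ar=ar[0], sd_ar_between=ar[1],
        mean_veir=veir[0], sd_veir_between=veir[1],
        mean_log_intensity=log_int[0], sd_log_intensity=log_int[1],
    )


def default_population_params() -> dict[tuple[str, str], PopulationParams]:
    """Published healthy/septic group statistics, SIRS in between.

    Neutrophil and monocyte AR/VEIR healthy and septic entries are the printed
    group means +/- SDs; SIRS SDs interpolate.  SIRS means are implied by the
    single-factor model (healthy mean + loading x 1.0) so that the three
    states sit on one proportional-shift axis.  Lymphocyte trends are weak and
    unprinted; sizes and intensities are gating-driven choices.
    """
    p: dict[tuple[str, str], PopulationParams] = {}
    # (mean, between-subject SD) per metric
    p[("healthy", "lymphocyte")] = _pp((7.0, 0.40), (2.00, 0.20), (5.00, 0.50), (2.4, 0.06))
    p[("healthy", "neutrophil")] = _pp((8.5, 0.40), (2.55, 0.24), (6.73, 0.60), (4.1, 0.06))
    p[("healthy", "monocyte")] = _pp((9.5, 0.40), (3.24, 0.37), (8.26, 0.79), (3.1, 0.06))

    p[("sirs_nonseptic", "lymphocyte")] = _pp((7.0, 0.40), (2.03, 0.22), (5.10, 0.55), (2.4, 0.06))
    p[("sirs_nonseptic", "neutrophil")] = _pp((8.6, 0.40), (2.75, 0.28), (7.23, 0.75), (4.1, 0.06))
    p[("sirs_nonseptic", "monocyte")] = _pp((9.6, 0.40), (3.30, 0.45), (9.00, 0.95), (3.1, 0.06))

    p[("septic", "lymphocyte")] = _pp((7.0, 0.40), (2.10, 0.25), (5.30, 0.60), (2.4, 0.06))
    p[("septic", "neutrophil")] = _pp((8.8, 0.40), (3.13, 0.32), (8.19, 0.87), (4.1, 0.06))
    p[("septic", "monocyte")] = _pp((9.8, 0.40), (3.42, 0.60), (10.41, 0.90), (3.1, 0.06))
    return p


#: Expected leukocyte type fractions at the state's mean factor value.
DEFAULT_TYPE_FRACTIONS = {
    "healthy": {"lymphocyte": 0.30, "neutrophil": 0.60, "monocyte": 0.10},
    "sirs_nonseptic": {"lymphocyte": 0.235, "neutrophil": 0.660, "monocyte": 0.105},
    "septic": {"lymphocyte": 0.14, "neutrophil": 0.75, "monocyte": 0.11},
}


@dataclass
class WbcDist:
    """Lognormal WBC-count distribution, parameterized by median and IQR
    (units 10^3 cells/uL), as printed in the cohort tables."""

    median: float
    q1: float
    q3: float

    def __post_init__(self) -> None:
        if not (0 < self.q1 <= self.median <= self.q3):
            raise ConfigError("WBC quartiles must satisfy 0 < q1 <= median <= q3")

    @property
    def mu(self) -> float:
        return float(np.log(self.median))

    @property
    def sigma(self) -> float:
        # IQR of a lognormal: exp(mu +/- 0.6745 sigma)
        return float(np.log(self.q3 / self.q1) / (2 * 0.674489750196082))


@dataclass
class Demographics:
    age_median: float
    age_q1: float
    age_q3: float
    female_fraction: float
    race_fractions: dict[str, float] = field(
        default_factory=lambda: {"white": 0.53, "african_american": 0.40, "other": 0.07})

    def __post_init__(self) -> None:
        tot = sum(self.race_fractions.values())
        if abs(tot - 1.0) > 1e-6:
            self.race_fractions = {k: v / tot for k, v in self.race_fractions.items()}


@dataclass
class ClinicalLinks:
    """Monotone links from the latent severity factor to clinical outcomes.

    Constants were calibrated once by simulation against the printed
    high/low-acuity medians and rates (SOFA 4 vs 2, APACHE-II 15 vs 11,
    LOS 4 vs 2, ICU 26.4% vs 11.7%, mortality 10.1% vs 3.2%) and frozen.
    """

    sofa_intercept: float = 0.75
    sofa_slope: float = 2.0
    sofa_noise_sd: float = 1.15
    apache_intercept: float = 10.0
    apache_slope: float = 3.5
    apache_noise_sd: float = 3.0
    los_log_intercept: float = 0.7
    los_log_slope: float = 0.4
    los_log_noise_sd: float = 0.5
    icu_intercept: float = -2.775
    icu_slope: float = 1.0
    death_intercept: float = -4.369
    death_slope: float = 1.05
    death_time_scale: float = 9.0
    followup_days: float = 30.0


@dataclass
class CohortSpec:
    """Composition and generative parameters of one simulated cohort."""

    cohort_name: str
    n_subjects: int
    n_septic: int
    n_cells_per_subject: int = 2000
    population_params: dict[tuple[str, str], PopulationParams] = field(
        default_factory=default_population_params)
    wbc_dist: WbcDist = field(default_factory=lambda: WbcDist(6.0, 4.9, 7.0))
    type_fractions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {s: dict(DEFAULT_TYPE_FRACTIONS[s]) for s in DISEASE_STATES})
    type_fraction_logit_sd: float = 0.4
    #: added to the factor for clinical outcomes only (site acuity), never for
    #: the cellular metrics
    clinical_offset: float = 0.0
    demographics: Demographics = field(
        default_factory=lambda: Demographics(62.2, 50.4, 73.6, 0.502))
    clinical_links: ClinicalLinks = field(default_factory=ClinicalLinks)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 0 or self.n_septic < 0 or self.n_cells_per_subject < 0:
            raise ConfigError("counts must be non-negative")
        if self.n_septic > self.n_subjects:
            raise ConfigError("n_septic cannot exceed n_subjects")
        if self.cohort_name not in ("high_acuity", "low_acuity", "healthy"):
            raise ConfigError(f"unknown cohort_name {self.cohort_name!r}")
        for state, fr in self.type_fractions.items():
            if abs(sum(fr.values()) - 1.0) > 1e-9:
                raise ConfigError(f"type fractions for {state} must sum to 1")


def high_acuity_spec(n_cells_per_subject: int = 2000, seed: int = 0) -> CohortSpec:
    """ED cohort with SIRS 2+ plus organ-dysfunction signs: 307 subjects,
    72 adjudicated septic (23.5%)."""
    return CohortSpec(
        cohort_name="high_acuity", n_subjects=307, n_septic=72,
        n_cells_per_subject=n_cells_per_subject,
        wbc_dist=WbcDist(13.8, 10.1, 17.5),
        demographics=Demographics(62.2, 50.4, 73.6, 0.502,
                                  {"white": 0.531, "african_american": 0.401, "other": 0.068}),
        clinical_offset=0.0, seed=seed)


def low_acuity_spec(n_cells_per_subject: int = 2000, seed: int = 1) -> CohortSpec:
    """ED cohort with SIRS 2+ only: 94 subjects, 6 septic (6.4%)."""
    return CohortSpec(
        cohort_name="low_acuity", n_subjects=94, n_septic=6,
        n_cells_per_subject=n_cells_per_subject,
        wbc_dist=WbcDist(10.3, 7.5, 13.0),
        demographics=Demographics(55.3, 42.3, 70.6, 0.468,
                                  {"white": 0.50, "african_american": 0.468, "other": 0.032}),
        clinical_offset=-0.8, seed=seed)


def healthy_spec(n_cells_per_subject: int = 2000, seed: int = 2) -> CohortSpec:
    """Healthy blood-donor cohort: 72 subjects, no clinical outcomes."""
    return CohortSpec(
        cohort_name="healthy", n_subjects=72, n_septic=0,
        n_cells_per_subject=n_cells_per_subject,
        wbc_dist=WbcDist(6.0, 4.9, 7.0),
        demographics=Demographics(52.5, 38.0, 68.0, 0.556,
                                  {"white": 0.875, "african_american": 0.056, "other": 0.069}),
        clinical_offset=0.0, seed=seed)


BEAD_DIAMETER_UM = 8.86  # carboxylated polystyrene control beads


@dataclass
class AcquisitionParams:
    """Virtual-instrument acquisition settings for trace synthesis."""

    frame_interval_us: float = 2.0
    min_frames: int = 10
    max_frames: int = 15
    junction_position_um: float = 60.0
    nominal_speed_um_per_frame: float = 12.0
    channel_half_width_um: float = 30.0
    descriptor_noise_sd_um: float = 0.1
    image_size_px: int = 128
    um_per_pixel: float = 0.5

    def __post_init__(self) -> None:
        if self.min_frames < 5:
            raise ConfigError("frames_per_event must be >= 5")
        if self.max_frames < self.min_frames:
            raise ConfigError("max_frames < min_frames")
        if self.descriptor_noise_sd_um < 0:
            raise ConfigError("noise SD must be >= 0")


@dataclass
class QcThresholds:
    trajectory_pass_min: float = 0.95
    speed_tolerance: float = 0.10
    transverse_limit_um: float = 1.0
    min_beads: int = 10


@dataclass
class GatingConfig:
    bead_size_tolerance_um: float = 0.30
    uncertain_posterior: float = 0.5
    min_events: int = 300
    min_component_weight: float = 0.01
    seed: int = 0


@dataclass
class FeatureConfig:
    min_events: int = 500
    min_events_per_type: int = 10


@dataclass
class ValidationPlan:
    """Sequester split plus nested cross-validation layout."""

    sequester_fraction: float = 69 / 307
    k_outer: int = 5
    k_inner: int = 5
    lambda_grid: tuple[float, ...] = tuple(np.logspace(-3, 1, 13))
    n_repeats: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.sequester_fraction < 1):
            raise ConfigError("sequester_fraction must be in (0, 1)")
        if min(self.lambda_grid) < 0:
            raise ConfigError("lambda values must be >= 0")


@dataclass
class BandDefinition:
    """ISI interpretation bands on the 0.1-granular score in [0.1, 10.0]."""

    green_max: float = 5.4
    yellow_max: float = 6.7
    score_min: float = 0.1
    score_max: float = 10.0
    granularity: float = 0.1

    def __post_init__(self) -> None:
        if not (self.score_min < self.green_max < self.yellow_max < self.score_max):
            raise ConfigError("band thresholds must be increasing inside the score range")


@dataclass
class ScoreAnchors:
    """Affine score-map anchoring: mapped training scores reproduce the
    printed high-acuity score median and IQR."""

    median: float = 4.8
    q1: float = 3.7
    q3: float = 6.1


@dataclass
class PipelineConfig:
    """Everything needed for an end-to-end run."""

    cohorts: dict[str, CohortSpec] = field(default_factory=lambda: {
        "high_acuity": high_acuity_spec(),
        "low_acuity": low_acuity_spec(),
        "healthy": healthy_spec(),
    })
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    qc: QcThresholds = field(default_factory=QcThresholds)
    gating: GatingConfig = field(default_factory=GatingConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    validation: ValidationPlan = field(default_factory=ValidationPlan)
    bands: BandDefinition = field(default_factory=BandDefinition)
    anchors: ScoreAnchors = field(default_factory=ScoreAnchors)
    n_beads_per_run: int = 50
    #: subject ids whose virtual test run suffers a microfluidic clog (their
    #: bead run fails QC and the subject is excluded)
    clogged_subjects: tuple[str, ...] = ()
    write_traces: bool = True
    seed: int = 0
    output_dir: str = "mechanosep_out"


# ---------------------------------------------------------------------------
# dict / YAML round-trip


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {(k if isinstance(k, str) else "|".join(k)): _to_plain(v)
                for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def config_to_dict(cfg: PipelineConfig) -> dict[str, Any]:
    return _to_plain(cfg)


def _build(cls, data: Mapping[str, Any]):
    _check_unknown(cls, data)
    return cls(**data)


def _cohort_from_dict(data: Mapping[str, Any]) -> CohortSpec:
    _check_unknown(CohortSpec, data)
    data = dict(data)
    if "population_params" in data:
        data["population_params"] = {
            tuple(k.split("|")): _build(PopulationParams, v)
            for k, v in data["population_params"].items()}
    if "wbc_dist" in data:
        data["wbc_dist"] = _build(WbcDist, data["wbc_dist"])
    if "demographics" in data:
        data["demographics"] = _build(Demographics, data["demographics"])
    if "clinical_links" in data:
        data["clinical_links"] = _build(ClinicalLinks, data["clinical_links"])
    return CohortSpec(**data)


def config_from_dict(data: Mapping[str, Any]) -> PipelineConfig:
    _check_unknown(PipelineConfig, data)
    data = dict(data)
    if "cohorts" in data:
        data["cohorts"] = {k: _cohort_from_dict(v) for k, v in data["cohorts"].items()}
    if "validation" in data and isinstance(data["validation"], Mapping):
        v = dict(data["validation"])
        if "lambda_grid" in v:
            v["lambda_grid"] = tuple(v["lambda_grid"])
        data["validation"] = v
    for key, cls in (("acquisition", AcquisitionParams), ("qc", QcThresholds),
                     ("gating", GatingConfig), ("features", FeatureConfig),
                     ("validation", ValidationPlan), ("bands", BandDefinition),
                     ("anchors", ScoreAnchors)):
        if key in data:
            data[key] = _build(cls, data[key])
    return PipelineConfig(**data)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return config_from_dict(raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
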