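"""Configuration objects for the simulator and the end-to-end pipeline.

All constants that govern an analysis run (thresholds, closure depths,
bootstrap sizes) live here so they can be serialized alongside results
for provenance.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "SNVSpec",
    "DiseaseSpec",
    "HbA1cModel",
    "SimConfig",
    "RunConfig",
]


@dataclass(frozen=True)
class SNVSpec:
    """A simulated biallelic variant with an additive effect on phase.

    Parameters
    ----------
    snv_id : str
        Variant identifier (e.g. an rsID).
    alt_af : float
        Alternate (effect) allele frequency, in [0, 1].
    phase_effect_min : float
        Additive shift in heart-rate phase per alternate allele, in
        minutes (negative = earlier phase, i.e. a morningness allele).
    ref_allele, alt_allele : str
        Allele letters used when genotypes are written out.
    """

    snv_id: str
    alt_af: float
    phase_effect_min: float
    ref_allele: str = "C"
    alt_allele: str = "T"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alt_af <= 1.0:
            raise ValueError(f"alt_af must be in [0,1], got {self.alt_af}")


@dataclass(frozen=True)
class DiseaseSpec:
    """Logistic risk model for one simulated condition.

    The linear predictor is
    ``intercept + log_or_per_hour*(phase - phase_mean)
    + log_or_per_10k_steps*(steps - steps_mean) + log_or_per_year*(age - age_mean)
    + log_or_y*y_chromosome + confounding_strength*U``
    with covariates centred at their generative means, so with all
    effects zero the prevalence is ``expit(intercept)``.
    """

    concept_id: int
    intercept: float
    log_or_per_hour: float = 0.0
    log_or_per_10k_steps: float = 0.0
    log_or_per_year: float = 0.0
    log_or_y: float = 0.0


@dataclass(frozen=True)
class HbA1cModel:
    """Gaussian HbA1c (%) linked linearly to phase (hours)."""

    mean: float = 5.6
    sd: float = 0.8
    slope_per_hour: float = 0.05


def _default_snvs() -> list[SNVSpec]:
    # rs1144566-like morningness variant: rare T allele, earlier phase.
    return [
        SNVSpec("rs1144566", alt_af=0.025, phase_effect_min=-30.0),
        SNVSpec("rs684383", alt_af=0.30, phase_effect_min=-6.0, ref_allele="G", alt_allele="A"),
        SNVSpec("rs_null_1", alt_af=0.20, phase_effect_min=0.0, ref_allele="A", alt_allele="G"),
    ]


def _default_diseases() -> list[DiseaseSpec]:
    import math

    # Concept ids refer to nodes of the default toy ontology (depth 3,
    # branching 3, root 1; see synthetic.build_toy_ontology).
    return [
        # T2DM-like condition: later phase raises risk (OR 1.09/h).
        DiseaseSpec(concept_id=2, intercept=-1.9, log_or_per_hour=math.log(1.09),
                    log_or_per_10k_steps=-0.10, log_or_per_year=0.04, log_or_y=0.20),
        # Null condition for negative controls.
        DiseaseSpec(concept_id=3, intercept=-2.2),
    ]


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Defaults encode the assumed statistical structure of the study
    population: weekly heart rate following a 24 h sinusoid with
    participant-specific amplitude, baseline and phase; additive SNV
    effects on phase; logistic condition risk driven by phase, steps,
    age and sex; and censored diagnosis ages.
    """

    n_participants: int = 200
    seed: int = 0
    # heart-rate sinusoid, bpm
    hr_amplitude_mean: float = 10.0
    hr_amplitude_sd: float = 3.0
    hr_baseline_mean: float = 72.0
    hr_baseline_sd: float = 8.0
    hr_noise_sd: float = 5.0
    # phase distribution, hours
    phase_mean: float = 9.48
    phase_sd: float = 1.57
    snv_specs: list[SNVSpec] = field(default_factory=_default_snvs)
    disease_specs: list[DiseaseSpec] = field(default_factory=_default_diseases)
    confounding_strength: float = 0.0
    missingness_rate: float = 0.2
    n_days: int = 60
    hba1c_model: HbA1cModel = field(default_factory=HbA1cModel)
    # covariate distributions
    age_mean: float = 55.0
    age_sd: float = 12.0
    steps_mean_10k: float = 5.5  # weekly steps in units of 10,000
    steps_sd_10k: float = 2.0
    y_chromosome_rate: float = 0.32
    # monitoring / follow-up
    hr_sample_minutes: int = 5
    monitoring_start: str = "2022-01-02"  # a Sunday
    onset_age: float = 20.0  # earliest possible diagnosis age
    diagnosis_base_rate: float = 1.0 / 30.0  # events/year at null predictor
    # lab table
    hba1c_fraction: float = 0.40
    hba1c_outlier_rate: float = 0.02
    # genotype noise
    third_allele_rate: float = 0.002
    generate_hr: bool = True

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if not 0.0 <= self.missingness_rate <= 1.0:
            raise ValueError("missingness_rate must be in [0,1]")
        if self.phase_sd <= 0:
            raise ValueError("phase_sd must be > 0")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        self.snv_specs = [s if isinstance(s, SNVSpec) else SNVSpec(**s) for s in self.snv_specs]
        self.disease_specs = [
            d if isinstance(d, DiseaseSpec) else DiseaseSpec(**d) for d in self.disease_specs
        ]
        if not isinstance(self.hba1c_model, HbA1cModel):
            self.hba1c_model = HbA1cModel(**self.hba1c_model)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass
class RunConfig:
    """Analysis-stage constants, serialized with every run manifest."""

    r2_grid_step: float = 0.1
    min_days: int = 30           # participants need MORE than this many days
    phase_sd_limit: float = 3.0  # |phase - mean| >= limit*SD excluded
    min_alt_af: float = 0.01
    phewas_max_depth: int = 2
    t2dm_max_depth: int | None = None  # unlimited closure
    min_cases: int = 100               # strictly more than this retained
    hba1c_bounds: tuple[float, float] = (1.0, 30.0)
    hba1c_elevated_threshold: float = 5.6
    robust_cov: str = "HC1"
    mr_resamples: int = 100_000
    seed: int = 0
    t2dm_concept_id: int = 2

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hba1c_bounds"] = list(self.hba1c_bounds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "hba1c_bounds" in d:
            d["hba1c_bounds"] = tuple(d["hba1c_bounds"])
        return cls(**d)
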