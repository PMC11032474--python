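"""Configuration objects for the synthetic cohort and brain-map generator.

The generator emulates a UK-Biobank-like cohort in which childhood
maltreatment (CM) predicts adult trauma (AT), body-mass index (BMI) and
C-reactive protein (CRP) through a recursive linear structural model on
the standardized log scale, and in which those three adult variables have
small direct effects on parcellated measures of brain structure.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml

#: phenotype names, in the causal (topological) order of the structural model
PHENOTYPES = ("cm", "bmi", "at", "crp")

#: structural edges of the four-variable model and its brain extension
STRUCT_EDGE_MAP = {
    "a1": ("bmi", "cm"),
    "a2": ("crp", "cm"),
    "a3": ("at", "cm"),
    "b1": ("crp", "bmi"),
    "b2": ("crp", "at"),
}

#: covariate names available to the generator
COVARIATES = ("age", "sex", "age_sex", "ses", "site")

#: the seven bilaterally averaged subcortical structures
SUBCORTICAL_NAMES = (
    "thalamus",
    "caudate",
    "putamen",
    "pallidum",
    "hippocampus",
    "amygdala",
    "accumbens",
)


class ConfigError(ValueError):
    """Raised when a generator configuration is internally inconsistent."""


@dataclass
class RegionalEffects:
    """Population standardized effects of BMI/CRP/AT on regional structure.

    Cortical effect maps are smooth fields on the sphere: BMI (``c1``) and
    CRP (``c2``) maps are two noisy copies of one shared smooth map (mixing
    weight ``shared_weight``), which reproduces the empirically observed
    regime of highly correlated immuno-metabolic maps.  The AT map (``c3``)
    is weak cortically and mixed with the negated shared map.  Subcortical
    effects are constants: positive for BMI, negative for CRP and AT.
    """

    amp_bmi: float = 0.04
    amp_crp: float = 0.04
    amp_at: float = 0.01
    shared_weight: float = 0.9
    at_shared_weight: float = 0.4
    sub_bmi: float = 0.02
    sub_crp: float = -0.03
    sub_at: float = -0.04


def _default_struct_coeffs() -> dict:
    # standardized direct effects of the four-variable model (MRI sample)
    return {"a1": 0.072, "a2": 0.008, "a3": 0.315, "b1": 0.434, "b2": 0.019}


def _default_marginals() -> dict:
    # raw-scale mean/SD of each phenotype (MRI subsample)
    return {
        "bmi": (26.5, 4.2),
        "crp": (2.03, 3.53),
        "cm": (1.70, 2.31),
        "at": (1.93, 2.37),
    }


def _default_covariate_effects() -> dict:
    # standardized contributions of nuisance covariates on the log/latent
    # scale of each phenotype; CM covariate dependence defaults to zero
    # (exposed but not asserted as a property of the real cohort)
    return {
        "cm": {},
        "at": {"age": -0.05, "sex": 0.05, "ses": 0.15},
        "bmi": {"age": 0.10, "sex": 0.10, "age_sex": 0.02, "ses": 0.08, "site": 0.02},
        "crp": {"age": 0.12, "sex": 0.15, "age_sex": 0.02, "ses": 0.10, "site": 0.02},
        "brain": {"age": -0.20, "sex": 0.10, "ses": 0.02, "site": 0.05},
    }


@dataclass
class GeneratorConfig:
    """All population parameters of the synthetic cohort and brain maps."""

    n_participants: int = 21_738
    struct_coeffs: dict = field(default_factory=_default_struct_coeffs)
    regional_effects: RegionalEffects = field(default_factory=RegionalEffects)
    residual_sds: Optional[dict] = None  # None -> unit-variance completion
    marginal_calibration: dict = field(default_factory=_default_marginals)
    covariate_effects: dict = field(default_factory=_default_covariate_effects)
    spatial_kernel_length: float = 0.3
    n_cortical: int = 180
    n_subcortical: int = 7
    max_count: int = 25  # questionnaire sum scores live in [0, max_count]
    missing_rate: float = 0.0  # completely-at-random missingness of brain cells
    seed: int = 0

    # demographic marginals (age in years, Townsend-like SES index)
    age_mean: float = 55.0
    age_sd: float = 7.0
    female_fraction: float = 0.54
    ses_mean: float = -1.94
    ses_sd: float = 2.69
    site_probs: tuple = (0.5, 0.3, 0.2)

    def validate(self) -> "GeneratorConfig":
        if self.n_participants < 10:
            raise ConfigError("n_participants must be at least 10")
        unknown = set(self.struct_coeffs) - set(STRUCT_EDGE_MAP)
        if unknown:
            raise ConfigError(f"unknown structural edges: {sorted(unknown)}")
        missing = set(STRUCT_EDGE_MAP) - set(self.struct_coeffs)
        if missing:
            raise ConfigError(f"missing structural edges: {sorted(missing)}")
        if self.residual_sds is not None:
            bad = {k: v for k, v in self.residual_sds.items() if v < 0}
            if bad:
                raise ConfigError(f"residual SDs must be >= 0: {bad}")
        for name, (m, s) in self.marginal_calibration.items():
            if s <= 0:
                raise ConfigError(f"marginal SD for {name!r} must be > 0 (got {s})")
            if m <= 0:
                raise ConfigError(f"marginal mean for {name!r} must be > 0 (got {m})")
        if self.spatial_kernel_length < 0:
            raise ConfigError("spatial_kernel_length must be >= 0")
        if self.n_cortical < 2:
            raise ConfigError("n_cortical must be >= 2")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must be in [0, 1)")
        return self

    @property
    def n_regions(self) -> int:
        return self.n_cortical + self.n_subcortical


def mri_sample_config(**overrides) -> GeneratorConfig:
    """Defaults calibrated to the MRI subsample (n = 21,738)."""
    return GeneratorConfig(**overrides).validate()


def replication_config(**overrides) -> GeneratorConfig:
    """Replication-variant configuration for the larger non-imaging cohort.

    The direct CM->CRP effect is set to its replication-sample value and the
    raw-scale marginals follow the full-cohort column of the demographics
    table (n = 116,887).
    """
    cfg = GeneratorConfig(
        n_participants=116_887,
        struct_coeffs={"a1": 0.072, "a2": 0.0095, "a3": 0.315, "b1": 0.434, "b2": 0.019},
        marginal_calibration={
            "bmi": (26.8, 4.6),
            "crp": (2.29, 4.02),
            "cm": (1.76, 2.41),
            "at": (2.09, 2.51),
        },
        age_mean=56.0,
        age_sd=8.0,
        female_fraction=0.56,
        ses_mean=-1.68,
        ses_sd=2.85,
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg.validate()


def config_to_dict(config: GeneratorConfig) -> dict:
    return asdict(config)


def config_from_dict(data: dict) -> GeneratorConfig:
    data = dict(data)
    if "regional_effects" in data and isinstance(data["regional_effects"], dict):
        data["regional_effects"] = RegionalEffects(**data["regional_effects"])
    for key in ("marginal_calibration",):
        if key in data:
            data[key] = {k: tuple(v) for k, v in data[key].items()}
    if "site_probs" in data:
        data["site_probs"] = tuple(data["site_probs"])
    return GeneratorConfig(**data).validate()


def save_config(config: GeneratorConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(config_to_dict(config)), fh, sort_keys=True)


def load_config(path) -> GeneratorConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def _plain(obj):
    """Recursively convert tuples to lists so YAML round-trips cleanly."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def config_hash(config: GeneratorConfig) -> str:
    """Stable short hash identifying a generator configuration."""
    payload = yaml.safe_dump(_plain(config_to_dict(config)), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
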