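"""Synthetic cohort and parcellated brain-map generator.

Generates (i) a phenotype table whose four key variables - childhood
maltreatment (CM), adult trauma (AT), body-mass index (BMI) and
C-reactive protein (CRP) - satisfy a configurable recursive structural
model on the standardized log scale while matching published raw-scale
marginals, (ii) a quasi-uniform spherical parcel geometry standing in for
a symmetrized cortical atlas, and (iii) a participants x regions matrix
of thickness/volume-like measures carrying smooth regional effect maps of
the three adult variables plus spatially autocorrelated noise.

The structural contract is expressed on the scale the downstream analysis
actually sees: z-scored, covariate-residualized log (or log1p) values.
For the continuous phenotypes (BMI, CRP) the log transform is exactly
linear in the latent, so configured coefficients are recovered exactly;
for the count phenotype AT the latent path coefficient is pre-corrected
for discretization attenuation by exact quadrature (see
:mod:`cmpaths.counts`), so the observed-scale coefficient equals the
configured one up to Monte-Carlo error.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .config import (
    SUBCORTICAL_NAMES,
    ConfigError,
    GeneratorConfig,
    config_hash,
)
from .counts import calibrate_count_map, latent_slope_for

__all__ = [
    "generate_cohort",
    "generate_geometry",
    "generate_brain",
    "inject_outliers",
    "adult_covariance",
]


def _lognormal_params(mean: float, sd: float):
    """(meanlog, sdlog) of a lognormal with the given raw mean and SD."""
    sdlog2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sdlog2 / 2.0, np.sqrt(sdlog2)


def _zscore(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def _covariate_columns(age, sex, ses, site_codes, site_probs):
    """Standardized covariate columns used for effect injection."""
    z_age = _zscore(age)
    z_sex = _zscore(sex.astype(float))
    z_ses = _zscore(ses)
    inter = _zscore(z_age * z_sex)
    # fixed per-site offsets, centred and scaled to unit variance under the
    # configured site probabilities
    base = np.array([-1.0, 0.5, 1.25])[: len(site_probs)]
    p = np.asarray(site_probs)
    base = base - (base * p).sum()
    base = base / np.sqrt((base**2 * p).sum())
    z_site = base[site_codes]
    return {"age": z_age, "sex": z_sex, "age_sex": inter, "ses": z_ses, "site": z_site}


def _covariate_part(effects: dict, columns: dict) -> np.ndarray:
    n = len(next(iter(columns.values())))
    out = np.zeros(n)
    for name, coef in effects.items():
        if name not in columns:
            raise ConfigError(f"unknown covariate {name!r} in covariate_effects")
        out += coef * columns[name]
    return out


def _mix(struct: np.ndarray, cov_part: np.ndarray) -> np.ndarray:
    """Combine a unit-variance structural score with covariate effects.

    The combination keeps total variance at one so that raw-scale marginal
    calibration is unaffected by the covariate effects.
    """
    rho2 = cov_part.var()
    if rho2 >= 0.9:
        raise ConfigError("covariate effects explain >= 90% of a phenotype")
    return np.sqrt(1.0 - rho2) * struct + cov_part


def _residualize_on(v: np.ndarray, columns: dict) -> np.ndarray:
    X = np.column_stack([np.ones_like(v)] + [columns[c] for c in columns])
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def generate_cohort(config: GeneratorConfig, return_struct: bool = False):
    """Generate one synthetic phenotype table.

    Returns a DataFrame with one row per participant; the standardized
    structural scores and the covariate columns used are attached in
    ``df.attrs`` so the brain generator can reuse the exact same lineage.
    """
    config.validate()
    coeffs = config.struct_coeffs
    n = config.n_participants
    rng = np.random.default_rng([config.seed, 1])

    # --- covariates -------------------------------------------------------
    age = config.age_mean + config.age_sd * rng.standard_normal(n)
    sex = (rng.random(n) < config.female_fraction).astype(int)  # 1 = female
    ses = config.ses_mean + config.ses_sd * rng.standard_normal(n)
    site_codes = rng.choice(len(config.site_probs), size=n, p=config.site_probs)
    columns = _covariate_columns(age, sex, ses, site_codes, config.site_probs)
    cov = {
        v: _covariate_part(config.covariate_effects.get(v, {}), columns)
        for v in ("cm", "at", "bmi", "crp")
    }

    # --- CM: exogenous count phenotype -----------------------------------
    cmap_cm = calibrate_count_map(*config.marginal_calibration["cm"], config.max_count)
    cm_latent = _mix(rng.standard_normal(n), cov["cm"])
    cm_count = cmap_cm.latent_to_count(cm_latent)
    # the structural driver is what the analysis recovers: the z-scored
    # covariate-residualized log1p score
    cm = _zscore(_residualize_on(np.log1p(cm_count), columns))

    def resid_sd(name, explained_var):
        if config.residual_sds is not None and name in config.residual_sds:
            return float(config.residual_sds[name])
        if explained_var >= 1.0:
            raise ConfigError(f"structural paths into {name!r} explain variance >= 1")
        return float(np.sqrt(1.0 - explained_var))

    # --- BMI: lognormal, log-linear in the latent -------------------------
    a1 = coeffs["a1"]
    bmi = a1 * cm + resid_sd("bmi", a1**2) * rng.standard_normal(n)

    # --- AT: endogenous count phenotype, attenuation-corrected ------------
    a3 = coeffs["a3"]
    cmap_at = calibrate_count_map(*config.marginal_calibration["at"], config.max_count)
    a3_lat = latent_slope_for(cmap_at, a3, cmap_cm.log1p_atoms())
    at_struct = a3_lat * cm + resid_sd("at", a3_lat**2) * rng.standard_normal(n)
    at_count = cmap_at.latent_to_count(_mix(at_struct, cov["at"]))
    at = _zscore(_residualize_on(np.log1p(at_count), columns))

    # --- CRP: partial regression on CM, BMI and observed AT ---------------
    a2, b1, b2 = coeffs["a2"], coeffs["b1"], coeffs["b2"]
    pred = a2 * cm + b1 * bmi + b2 * at
    # population variance of the linear predictor under the implied
    # covariances cov(cm,bmi)=a1, cov(cm,at)=a3, cov(bmi,at)=a1*a3
    explained = (
        a2**2 + b1**2 + b2**2
        + 2 * (a2 * b1 * a1 + a2 * b2 * a3 + b1 * b2 * a1 * a3)
    )
    crp = pred + resid_sd("crp", explained) * rng.standard_normal(n)

    # --- raw-scale marginals ----------------------------------------------
    mu_b, sd_b = _lognormal_params(*config.marginal_calibration["bmi"])
    mu_c, sd_c = _lognormal_params(*config.marginal_calibration["crp"])
    bmi_raw = np.exp(mu_b + sd_b * _mix(bmi, cov["bmi"]))
    crp_raw = np.exp(mu_c + sd_c * _mix(crp, cov["crp"]))

    df = pd.DataFrame(
        {
            "participant_id": np.arange(n),
            "cm_score": cm_count.astype(int),
            "at_score": at_count.astype(int),
            "bmi": bmi_raw,
            "crp": crp_raw,
            "age": age,
            "sex": sex,
            "ses": ses,
            "site": pd.Categorical.from_codes(
                site_codes, categories=[f"site_{c}" for c in "abcdefg"[: len(config.site_probs)]]
            ),
        }
    )
    struct = pd.DataFrame({"cm": cm, "bmi": bmi, "at": at, "crp": crp})
    df.attrs["seed"] = config.seed
    df.attrs["config_hash"] = config_hash(config)
    df.attrs["struct"] = struct
    df.attrs["covariate_columns"] = pd.DataFrame(columns)
    if return_struct:
        return df, struct
    return df


def generate_geometry(config: GeneratorConfig) -> pd.DataFrame:
    """Quasi-uniform parcel centroids on the unit sphere (Fibonacci lattice).

    Cortical parcels carry unit-norm centroids; subcortical structures have
    no centroid and are exempt from spin tests.
    """
    config.validate()
    n = config.n_cortical
    i = np.arange(n)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z**2)
    theta = 2.0 * np.pi * i / golden
    xyz = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    xyz /= np.linalg.norm(xyz, axis=1, keepdims=True)

    n_sub = config.n_subcortical
    sub_names = list(SUBCORTICAL_NAMES[:n_sub]) + [
        f"sub_{k}" for k in range(len(SUBCORTICAL_NAMES), n_sub)
    ]
    geo = pd.DataFrame(
        {
            "region_id": [f"ctx_{k:03d}" for k in range(n)] + sub_names,
            "structure_class": ["cortical"] * n + ["subcortical"] * n_sub,
            "hemisphere_merged": True,
            "x": np.concatenate([xyz[:, 0], np.full(n_sub, np.nan)]),
            "y": np.concatenate([xyz[:, 1], np.full(n_sub, np.nan)]),
            "z": np.concatenate([xyz[:, 2], np.full(n_sub, np.nan)]),
        }
    )
    geo.attrs["config_hash"] = config_hash(config)
    return geo


def adult_covariance(coeffs: dict) -> np.ndarray:
    """Model-implied covariance of the standardized (BMI, CRP, AT) triplet."""
    a1, a2, a3 = coeffs["a1"], coeffs["a2"], coeffs["a3"]
    b1, b2 = coeffs["b1"], coeffs["b2"]
    c_bmi_at = a1 * a3
    c_bmi_crp = a2 * a1 + b1 + b2 * c_bmi_at
    c_at_crp = a2 * a3 + b1 * c_bmi_at + b2
    return np.array(
        [
            [1.0, c_bmi_crp, c_bmi_at],
            [c_bmi_crp, 1.0, c_at_crp],
            [c_bmi_at, c_at_crp, 1.0],
        ]
    )


def _sq_exp_chol(xyz: np.ndarray, length: float, jitter: float = 1e-8) -> np.ndarray:
    """Cholesky factor of a squared-exponential kernel in chordal distance."""
    n = len(xyz)
    if length == 0.0:
        return np.eye(n)
    d2 = ((xyz[:, None, :] - xyz[None, :, :]) ** 2).sum(-1)
    K = np.exp(-d2 / (2.0 * length**2)) + jitter * np.eye(n)
    return np.linalg.cholesky(K)


def _smooth_field(L: np.ndarray, rng) -> np.ndarray:
    g = L @ rng.standard_normal(L.shape[0])
    return g / g.std()


def generate_brain(
    phenotypes: pd.DataFrame, geometry: pd.DataFrame, config: GeneratorConfig
) -> pd.DataFrame:
    """Participants x regions matrix with planted regional effects.

    Each region's standardized value is ``c1*BMI + c2*CRP + c3*AT`` plus
    spatially correlated Gaussian noise over the cortical sphere; the
    cortical effect maps themselves are smooth fields, with BMI and CRP
    maps sharing a common component.  Subcortical regions get constant
    effects and independent noise.
    """
    config.validate()
    chash = config_hash(config)
    if phenotypes.attrs.get("config_hash") != chash:
        raise ConfigError("phenotypes were not generated from this config")
    if geometry.attrs.get("config_hash") != chash:
        raise ConfigError("geometry was not generated from this config")
    struct = phenotypes.attrs["struct"]
    if len(struct) != len(phenotypes):
        raise ValueError("phenotype/struct shape mismatch")

    rng = np.random.default_rng([config.seed, 3])
    eff = config.regional_effects
    n = len(phenotypes)
    nc, ns = config.n_cortical, config.n_subcortical

    cortical = geometry[geometry["structure_class"] == "cortical"]
    xyz = cortical[["x", "y", "z"]].to_numpy()
    L = _sq_exp_chol(xyz, config.spatial_kernel_length)

    # smooth effect maps: BMI and CRP share one component; AT mixes with the
    # negated shared map so its map is anticorrelated with the BMI map
    g0, g1, g2, g3 = (_smooth_field(L, rng) for _ in range(4))
    w, w_at = eff.shared_weight, eff.at_shared_weight
    c1 = eff.amp_bmi * (w * g0 + np.sqrt(1 - w**2) * g1)
    c2 = eff.amp_crp * (w * g0 + np.sqrt(1 - w**2) * g2)
    c3 = eff.amp_at * (w_at * (-g0) + np.sqrt(1 - w_at**2) * g3)
    c1 = np.concatenate([c1, np.full(ns, eff.sub_bmi)])
    c2 = np.concatenate([c2, np.full(ns, eff.sub_crp)])
    c3 = np.concatenate([c3, np.full(ns, eff.sub_at)])

    C = np.column_stack([c1, c2, c3])  # regions x (bmi, crp, at)
    sigma3 = adult_covariance(config.struct_coeffs)
    signal_var = np.einsum("rj,jk,rk->r", C, sigma3, C)
    if np.any(signal_var >= 0.95):
        raise ConfigError("regional effects leave < 5% residual variance")
    noise_sd = np.sqrt(1.0 - signal_var)

    adult = struct[["bmi", "crp", "at"]].to_numpy()
    signal = adult @ C.T

    noise = np.empty((n, nc + ns))
    noise[:, :nc] = rng.standard_normal((n, nc)) @ L.T
    noise[:, nc:] = rng.standard_normal((n, ns))
    region_std = signal + noise * noise_sd

    # covariate effects shared across regions, injected before raw scaling
    columns = {
        k: v.to_numpy() for k, v in phenotypes.attrs["covariate_columns"].items()
    }
    cov_brain = _covariate_part(config.covariate_effects.get("brain", {}), columns)
    rho2 = cov_brain.var()
    if rho2 >= 0.9:
        raise ConfigError("brain covariate effects explain >= 90% of variance")
    latent = np.sqrt(1.0 - rho2) * region_std + cov_brain[:, None]

    # thickness-like cortical values (mm), volume-like subcortical (mm^3)
    sub_means = np.array([7500.0, 3700.0, 5000.0, 1800.0, 4000.0, 1700.0, 550.0])
    sub_means = np.resize(sub_means, ns)
    scale = np.concatenate([np.full(nc, 0.15), 0.10 * sub_means])
    offset = np.concatenate([np.full(nc, 2.60), sub_means])
    values = offset + scale * latent

    if config.missing_rate > 0.0:
        mask = rng.random(values.shape) < config.missing_rate
        values = np.where(mask, np.nan, values)

    brain = pd.DataFrame(
        values, index=phenotypes["participant_id"].to_numpy(), columns=geometry["region_id"]
    )
    brain.attrs["seed"] = config.seed
    brain.attrs["config_hash"] = chash
    brain.attrs["effect_maps"] = pd.DataFrame(
        {"region_id": geometry["region_id"], "c1": c1, "c2": c2, "c3": c3}
    )
    return brain


def inject_outliers(
    matrix: pd.DataFrame, rate: float, magnitude: float, seed: int
):
    """Displace random cells to ``median +/- magnitude * MAD`` of their region.

    ``magnitude`` must exceed the 5-MAD exclusion threshold, otherwise the
    planted outliers would be undetectable by design.  Returns the modified
    matrix and the list of planted ``(row_position, region_id)`` indices.
    """
    if not 0.0 <= rate <= 1.0:
        raise ConfigError("outlier rate must be in [0, 1]")
    if magnitude <= 5.0:
        raise ConfigError("outlier magnitude must exceed 5 MAD")
    out = matrix.copy()
    n_cells = out.size
    n_plant = int(round(rate * n_cells))
    if n_plant == 0:
        return out, []
    rng = np.random.default_rng(seed)
    flat = rng.choice(n_cells, size=n_plant, replace=False)
    rows, cols = np.unravel_index(flat, out.shape)
    values = out.to_numpy()
    med = np.nanmedian(values, axis=0)
    mad = np.nanmedian(np.abs(values - med), axis=0)
    signs = rng.choice([-1.0, 1.0], size=n_plant)
    values[rows, cols] = med[cols] + signs * magnitude * mad[cols]
    out.iloc[:, :] = values
    planted = [(int(r), out.columns[c]) for r, c in zip(rows, cols)]
    return out, planted
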