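"""Transform raw phenotypes and regional measures into analysis variables.

The analysis operates on nuisance-corrected, log-transformed, z-scored
variables: skewed phenotypes are log-transformed (log1p for questionnaire
sum scores that contain zeros, plain log for the strictly positive BMI and
CRP), regional measures are screened with a 5-MAD outlier filter, and all
measures are residualized against age, sex, their interaction and a
socioeconomic index (plus batch covariates such as acquisition site for
the imaging data).  Variables are z-scored after residualization so that
downstream path coefficients are directly standardized.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as _linalg

__all__ = [
    "log_transform",
    "build_design",
    "residualize",
    "mad_filter",
    "symmetrize",
    "preprocess_phenotypes",
    "preprocess_brain",
    "ResidualizedData",
]

#: default log conventions per phenotype
LOG_CONVENTIONS = {"cm": "log1p", "at": "log1p", "bmi": "log", "crp": "log"}

#: raw column names in the cohort table for each model variable
RAW_COLUMNS = {"cm": "cm_score", "at": "at_score", "bmi": "bmi", "crp": "crp"}


def log_transform(values, convention: str = "log") -> np.ndarray:
    """Natural-log transform with an explicit zero-handling convention."""
    v = np.asarray(values, dtype=float)
    if convention == "log":
        bad = np.where(~(v > 0))[0]
        if bad.size:
            raise ValueError(
                f"non-positive values under 'log' convention at rows {bad[:5].tolist()}"
            )
        return np.log(v)
    if convention == "log1p":
        bad = np.where(v < 0)[0]
        if bad.size:
            raise ValueError(
                f"negative values under 'log1p' convention at rows {bad[:5].tolist()}"
            )
        return np.log1p(v)
    raise ValueError(f"unknown log convention {convention!r}")


def build_design(
    covariates: pd.DataFrame,
    terms: Sequence[str] = ("age", "sex", "age_sex", "ses"),
) -> pd.DataFrame:
    """Covariate design matrix with intercept.

    ``age_sex`` expands to the product of (centred) age and sex; categorical
    columns expand to indicator contrasts dropping the first level.  Raises
    if the resulting design is rank deficient, naming the collinear columns.
    """
    cols: dict = {"intercept": np.ones(len(covariates))}
    for term in terms:
        if term == "age_sex":
            age = covariates["age"].to_numpy(dtype=float)
            sex = covariates["sex"].to_numpy(dtype=float)
            cols["age_sex"] = (age - age.mean()) * (sex - sex.mean())
        else:
            col = covariates[term]
            if isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == object:
                dummies = pd.get_dummies(col, prefix=term, drop_first=True, dtype=float)
                for c in dummies:
                    cols[c] = dummies[c].to_numpy()
            else:
                cols[term] = col.to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=covariates.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify offending columns via pivoted QR
        _, R, piv = _linalg.qr(X.to_numpy(), pivoting=True)
        bad = [X.columns[j] for j in piv[rank:]]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    return X


def residualize(response, design: pd.DataFrame) -> np.ndarray:
    """Least-squares residuals of ``response`` on the design.

    Rows with missing response are fitted around and stay missing in the
    output (excluded, not zeroed).
    """
    y = np.asarray(response, dtype=float)
    X = design.to_numpy(dtype=float)
    out = np.full_like(y, np.nan)
    ok = np.isfinite(y)
    beta, *_ = np.linalg.lstsq(X[ok], y[ok], rcond=None)
    out[ok] = y[ok] - X[ok] @ beta
    return out


def mad_filter(values, n_mad: float = 5.0, consistency: float = 1.0) -> np.ndarray:
    """Inclusion mask excluding values beyond ``n_mad`` raw MADs of the median.

    The MAD is the raw median absolute deviation - no normal-consistency
    constant by default (``consistency`` exposes one).  If the MAD is zero
    nothing is excluded.  Missing values stay excluded from the mask but do
    not count as outliers.
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if finite.sum() < 3:
        raise ValueError("mad_filter needs at least 3 finite values")
    med = np.median(v[finite])
    mad = np.median(np.abs(v[finite] - med)) * consistency
    if mad == 0:
        return finite
    return finite & (np.abs(v - med) <= n_mad * mad)


def symmetrize(matrix: pd.DataFrame, pairs: pd.DataFrame) -> pd.DataFrame:
    """Average bilaterally homologous columns into one column per region.

    ``pairs`` has columns (region_id, left, right).  If one side of a pair
    is missing for a participant (e.g. excluded by the MAD filter), the
    other side's value is used alone.
    """
    missing = (set(pairs["left"]) | set(pairs["right"])) - set(matrix.columns)
    if missing:
        raise ValueError(f"unpaired region labels not in matrix: {sorted(missing)[:5]}")
    out = {}
    for _, row in pairs.iterrows():
        left = matrix[row["left"]].to_numpy(dtype=float)
        right = matrix[row["right"]].to_numpy(dtype=float)
        both = np.column_stack([left, right])
        with np.errstate(invalid="ignore"):
            out[row["region_id"]] = np.nanmean(both, axis=1)
    return pd.DataFrame(out, index=matrix.index)


def _zscore_nan(v: np.ndarray) -> np.ndarray:
    m = np.nanmean(v)
    s = np.nanstd(v)
    return (v - m) / s


@dataclass
class ResidualizedData:
    """Analysis-ready residualized, z-scored variables."""

    phenotypes: pd.DataFrame  # columns cm, bmi, at, crp (z-scored residuals)
    brain: Optional[pd.DataFrame] = None  # regions as columns; NaN = excluded
    design_columns: tuple = ()
    brain_design_columns: tuple = ()
    exclusions: Optional[pd.DataFrame] = None
    log_conventions: dict = field(default_factory=lambda: dict(LOG_CONVENTIONS))


def preprocess_phenotypes(
    cohort: pd.DataFrame,
    terms: Sequence[str] = ("age", "sex", "age_sex", "ses"),
    conventions: Optional[dict] = None,
) -> ResidualizedData:
    """Log-transform, residualize and z-score the four model phenotypes."""
    conventions = {**LOG_CONVENTIONS, **(conventions or {})}
    design = build_design(cohort, terms)
    out = {}
    for var, raw_col in RAW_COLUMNS.items():
        logged = log_transform(cohort[raw_col], conventions[var])
        out[var] = _zscore_nan(residualize(logged, design))
    phen = pd.DataFrame(out, index=cohort.index)
    return ResidualizedData(
        phenotypes=phen,
        design_columns=tuple(design.columns),
        log_conventions=conventions,
    )


def preprocess_brain(
    brain: pd.DataFrame,
    cohort: pd.DataFrame,
    terms: Sequence[str] = ("age", "sex", "age_sex", "ses", "site"),
    n_mad: float = 5.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """MAD-screen, residualize and z-score each regional measure.

    Returns the residualized matrix (NaN where excluded or missing) and an
    exclusions audit table (participant, region, value, threshold).
    """
    design = build_design(cohort, terms)
    values = brain.to_numpy(dtype=float)
    resid = np.full_like(values, np.nan)
    audit = []
    for j, region in enumerate(brain.columns):
        col = values[:, j]
        keep = mad_filter(col, n_mad=n_mad)
        excluded = np.isfinite(col) & ~keep
        if excluded.any():
            finite = np.isfinite(col)
            med = np.median(col[finite])
            mad = np.median(np.abs(col[finite] - med))
            for i in np.where(excluded)[0]:
                audit.append(
                    {
                        "participant": brain.index[i],
                        "region_id": region,
                        "value": col[i],
                        "threshold": n_mad * mad,
                    }
                )
        masked = np.where(keep, col, np.nan)
        resid[:, j] = _zscore_nan(residualize(masked, design))
    out = pd.DataFrame(resid, index=brain.index, columns=brain.columns)
    out.attrs = dict(brain.attrs)
    audit_df = pd.DataFrame(audit, columns=["participant", "region_id", "value", "threshold"])
    return out, audit_df
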