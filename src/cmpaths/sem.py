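"""Estimation and inference for recursive observed-variable path models.

Maximum-likelihood fitting of the model-implied covariance
``Sigma(theta) = (I - B)^-1 Psi (I - B)^-T`` to an observed covariance
matrix ``S``, with naive (normal-theory) and robust (Huber-White sandwich)
standard errors, a mean-scaled (Satorra-Bentler) test statistic, fit
indices (CFI, RMSEA with confidence interval, SRMR, robust variants),
product-of-coefficients indirect effects with delta-method inference, and
scaled likelihood-ratio comparison of nested models.

For this model class (recursive graph, diagonal residual covariance,
saturated exogenous block) the ML estimates coincide with per-equation
least squares, which is used as the warm start; a quasi-Newton polish
verifies first-order optimality.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .models import PathModel

logger = logging.getLogger(__name__)

__all__ = [
    "SampleMoments",
    "PathFit",
    "FitIndices",
    "IndirectEstimate",
    "ModelComparison",
    "implied_covariance",
    "fit_path_model",
    "robust_errors",
    "fit_indices",
    "indirect_effects",
    "lr_compare",
    "count_parameters",
]


class FitError(RuntimeError):
    """Raised when estimation fails (non-PD input or non-convergence)."""


# ---------------------------------------------------------------------------
# moments


@dataclass
class SampleMoments:
    """Observed covariance matrix, sample size and (optional) raw data."""

    cov: np.ndarray
    n: int
    variables: tuple
    means: Optional[np.ndarray] = None
    _gamma: Optional[np.ndarray] = None  # cached fourth-moment matrix

    @classmethod
    def from_data(cls, data: pd.DataFrame, ddof: int = 0) -> "SampleMoments":
        values = data.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValueError("SampleMoments.from_data requires complete cases")
        n = len(values)
        centred = values - values.mean(axis=0)
        cov = centred.T @ centred / (n - ddof)
        return cls(cov=cov, n=n, variables=tuple(data.columns), means=values.mean(axis=0))

    def check_pd(self) -> None:
        try:
            np.linalg.cholesky(self.cov)
        except np.linalg.LinAlgError as err:
            raise FitError("sample covariance matrix is not positive definite") from err


def empirical_gamma(data: pd.DataFrame) -> np.ndarray:
    """Asymptotic covariance of vech(S) estimated from per-row products."""
    values = data.to_numpy(dtype=float)
    z = values - values.mean(axis=0)
    p = z.shape[1]
    rows, cols = np.tril_indices(p)
    w = z[:, rows] * z[:, cols]
    w -= w.mean(axis=0)
    return w.T @ w / len(z)


# ---------------------------------------------------------------------------
# parameterization


def _param_index(model: PathModel):
    """Free-parameter bookkeeping: names, kinds and matrix positions."""
    idx = {v: k for k, v in enumerate(model.variables)}
    entries = []
    for e in model.edges:
        name = e.label or f"{e.child}<-{e.parent}"
        entries.append((name, "path", (idx[e.child], idx[e.parent])))
    for v in model.endogenous:
        entries.append((f"psi_{v}", "residual_variance", (idx[v], idx[v])))
    exo = model.exogenous
    for v in exo:
        entries.append((f"var_{v}", "exogenous_variance", (idx[v], idx[v])))
    if model.exogenous_covariances:
        for i, v in enumerate(exo):
            for u in exo[i + 1:]:
                entries.append((f"cov_{v}_{u}", "exogenous_covariance", (idx[v], idx[u])))
    return entries


def count_parameters(model: PathModel) -> int:
    """Number of free directed-path coefficients (variances excluded)."""
    return len(model.edges)


def n_free_parameters(model: PathModel) -> int:
    return len(_param_index(model))


def model_df(model: PathModel) -> int:
    p = len(model.variables)
    return p * (p + 1) // 2 - n_free_parameters(model)


def _build_matrices(model: PathModel, theta: np.ndarray):
    p = len(model.variables)
    B = np.zeros((p, p))
    Psi = np.zeros((p, p))
    for value, (name, kind, (i, j)) in zip(theta, _param_index(model)):
        if kind == "path":
            B[i, j] = value
        elif kind in ("residual_variance", "exogenous_variance"):
            Psi[i, i] = value
        else:
            Psi[i, j] = Psi[j, i] = value
    return B, Psi


def implied_covariance(model: PathModel, theta: np.ndarray) -> np.ndarray:
    """Sigma(theta) = (I - B)^-1 Psi (I - B)^-T."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (n_free_parameters(model),):
        raise ValueError(
            f"theta has length {theta.size}, model has {n_free_parameters(model)} free parameters"
        )
    B, Psi = _build_matrices(model, theta)
    p = len(model.variables)
    A = np.linalg.inv(np.eye(p) - B)  # acyclic B -> always invertible
    sigma = A @ Psi @ A.T
    return (sigma + sigma.T) / 2.0


def _warm_start(model: PathModel, S: np.ndarray) -> np.ndarray:
    """Per-equation least squares - exact ML for this model class."""
    idx = {v: k for k, v in enumerate(model.variables)}
    coef = {}
    psi = {}
    for v in model.endogenous:
        pa = [idx[u] for u in model.parents(v)]
        i = idx[v]
        beta = np.linalg.solve(S[np.ix_(pa, pa)], S[pa, i])
        for u, b in zip(model.parents(v), beta):
            coef[(v, u)] = b
        psi[v] = S[i, i] - S[pa, i] @ beta
    theta = []
    for name, kind, (i, j) in _param_index(model):
        if kind == "path":
            v = model.variables[i]
            u = model.variables[j]
            theta.append(coef[(v, u)])
        elif kind == "residual_variance":
            theta.append(psi[model.variables[i]])
        elif kind == "exogenous_variance":
            theta.append(S[i, i])
        else:
            theta.append(S[i, j])
    return np.array(theta)


def _fml_and_grad(model: PathModel, theta: np.ndarray, S: np.ndarray, logdet_S: float):
    p = len(model.variables)
    B, Psi = _build_matrices(model, theta)
    A = np.linalg.inv(np.eye(p) - B)
    sigma = A @ Psi @ A.T
    try:
        L = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return np.inf, np.zeros_like(theta)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    sigma_inv = np.linalg.inv(sigma)
    fml = logdet + float(np.trace(S @ sigma_inv)) - logdet_S - p
    M = sigma_inv @ (sigma - S) @ sigma_inv
    G_B = 2.0 * A.T @ M @ sigma  # gradient wrt B entries
    G_P = A.T @ M @ A  # gradient wrt Psi entries
    grad = np.empty_like(theta)
    for k, (name, kind, (i, j)) in enumerate(_param_index(model)):
        if kind == "path":
            grad[k] = G_B[i, j]
        elif kind in ("residual_variance", "exogenous_variance"):
            grad[k] = G_P[i, i]
        else:
            grad[k] = 2.0 * G_P[i, j]
    return fml, grad


# ---------------------------------------------------------------------------
# fit result


@dataclass
class PathFit:
    """One fitted path model: estimates, uncertainty and test statistics."""

    model: PathModel
    moments: SampleMoments
    theta: np.ndarray
    param_names: tuple
    param_kinds: tuple
    sigma: np.ndarray
    fml: float
    t_ml: float
    df: int
    converged: bool
    n_iter: int
    grad_norm: float
    vcov_naive: np.ndarray
    se_naive: np.ndarray
    vcov_robust: Optional[np.ndarray] = None
    se_robust: Optional[np.ndarray] = None
    t_sb: Optional[float] = None
    scaling_factor: Optional[float] = None

    @property
    def vcov(self) -> np.ndarray:
        return self.vcov_naive if self.vcov_robust is None else self.vcov_robust

    @property
    def se(self) -> np.ndarray:
        return self.se_naive if self.se_robust is None else self.se_robust

    @property
    def wald_z(self) -> np.ndarray:
        """Estimate / SE, using robust SEs when available."""
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.theta / self.se
        return np.where(self.theta == 0.0, 0.0, z)

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.wald_z))

    def estimate(self, label: str) -> float:
        return float(self.theta[self.param_names.index(label)])

    def params_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.param_names,
                "kind": self.param_kinds,
                "estimate": self.theta,
                "se_naive": self.se_naive,
                "se_robust": self.se_robust if self.se_robust is not None else np.nan,
                "z": self.wald_z,
                "p": self.pvalues,
            }
        )


def _vech(m: np.ndarray) -> np.ndarray:
    rows, cols = np.tril_indices(m.shape[0])
    return m[rows, cols]


def _duplication(p: int) -> np.ndarray:
    """Duplication matrix: vec(M) = D @ vech(M) for symmetric M."""
    rows, cols = np.tril_indices(p)
    D = np.zeros((p * p, len(rows)))
    for k, (i, j) in enumerate(zip(rows, cols)):
        D[i * p + j, k] = 1.0
        D[j * p + i, k] = 1.0
    return D


def _delta_matrix(model: PathModel, theta: np.ndarray) -> np.ndarray:
    """d vech(Sigma) / d theta, column per free parameter."""
    p = len(model.variables)
    B, Psi = _build_matrices(model, theta)
    A = np.linalg.inv(np.eye(p) - B)
    sigma = A @ Psi @ A.T
    cols = []
    for name, kind, (i, j) in _param_index(model):
        if kind == "path":
            d = np.outer(A[:, i], sigma[j, :])
            d = d + d.T
        elif kind in ("residual_variance", "exogenous_variance"):
            d = np.outer(A[:, i], A[:, i])
        else:
            d = np.outer(A[:, i], A[:, j]) + np.outer(A[:, j], A[:, i])
        cols.append(_vech(d))
    return np.column_stack(cols)


def _normal_weight(sigma: np.ndarray) -> np.ndarray:
    """Normal-theory weight matrix 0.5 D' (Sigma^-1 kron Sigma^-1) D."""
    p = sigma.shape[0]
    D = _duplication(p)
    s_inv = np.linalg.inv(sigma)
    return 0.5 * D.T @ np.kron(s_inv, s_inv) @ D


def fit_path_model(
    model: PathModel,
    moments: SampleMoments,
    gtol: float = 1e-10,
    maxiter: int = 500,
) -> PathFit:
    """Maximum-likelihood fit of a recursive path model to sample moments."""
    if tuple(moments.variables) != tuple(model.variables):
        order = [list(moments.variables).index(v) for v in model.variables]
        S = moments.cov[np.ix_(order, order)]
        moments = SampleMoments(S, moments.n, tuple(model.variables),
                                None if moments.means is None else moments.means[order])
    moments.check_pd()
    S = moments.cov
    if moments.n <= len(model.variables):
        raise FitError("sample size must exceed the number of variables")
    sign, logdet_S = np.linalg.slogdet(S)
    theta = _warm_start(model, S)
    fml, grad = _fml_and_grad(model, theta, S, logdet_S)
    n_iter = 0
    if np.linalg.norm(grad) > gtol:
        res = optimize.minimize(
            lambda t: _fml_and_grad(model, t, S, logdet_S),
            theta,
            jac=True,
            method="BFGS",
            options={"gtol": gtol, "maxiter": maxiter},
        )
        theta, fml = res.x, res.fun
        _, grad = _fml_and_grad(model, theta, S, logdet_S)
        n_iter = res.nit
    grad_norm = float(np.linalg.norm(grad))
    if grad_norm > 1e-8 or not np.isfinite(fml):
        raise FitError(
            f"path-model fit did not converge: |grad|={grad_norm:.3e}, F={fml:.3e}, "
            f"iterations={n_iter}"
        )
    fml = max(float(fml), 0.0)
    sigma = implied_covariance(model, theta)
    df = model_df(model)
    entries = _param_index(model)
    delta = _delta_matrix(model, theta)
    W = _normal_weight(sigma)
    info = delta.T @ W @ delta
    vcov_naive = np.linalg.inv(info) / moments.n
    se_naive = np.sqrt(np.clip(np.diag(vcov_naive), 0.0, None))
    return PathFit(
        model=model,
        moments=moments,
        theta=theta,
        param_names=tuple(e[0] for e in entries),
        param_kinds=tuple(e[1] for e in entries),
        sigma=sigma,
        fml=fml,
        t_ml=moments.n * fml,
        df=df,
        converged=True,
        n_iter=n_iter,
        grad_norm=grad_norm,
        vcov_naive=vcov_naive,
        se_naive=se_naive,
    )


def robust_errors(fit: PathFit, data: pd.DataFrame) -> PathFit:
    """Sandwich standard errors and the mean-scaled test statistic.

    ``data`` must be the per-row observations behind ``fit.moments`` -
    moments alone do not determine the fourth-moment matrix.
    """
    data = data[list(fit.model.variables)]
    if len(data) != fit.moments.n:
        raise ValueError("row count does not match the fitted moments")
    gamma = fit.moments._gamma
    if gamma is None:
        gamma = empirical_gamma(data)
        fit.moments._gamma = gamma
    delta = _delta_matrix(fit.model, fit.theta)
    W = _normal_weight(fit.sigma)
    info = delta.T @ W @ delta
    info_inv = np.linalg.inv(info)
    bread = info_inv @ delta.T @ W
    vcov_robust = bread @ gamma @ bread.T / fit.moments.n
    se_robust = np.sqrt(np.clip(np.diag(vcov_robust), 0.0, None))
    if fit.df == 0:
        logger.warning("saturated model: scaling factor undefined, reported as 1")
        c, t_sb = 1.0, 0.0
    else:
        U = W - W @ delta @ info_inv @ delta.T @ W
        c = float(np.trace(U @ gamma)) / fit.df
        t_sb = fit.t_ml / c
    return replace(fit, vcov_robust=vcov_robust, se_robust=se_robust,
                   t_sb=t_sb, scaling_factor=c)


# ---------------------------------------------------------------------------
# fit indices


def _band(value: float, good, acceptable, larger_is_better: bool) -> str:
    lo, hi = acceptable
    if larger_is_better:
        if value > good:
            return "good"
        if lo <= value <= hi:
            return "acceptable"
    else:
        if value < good:
            return "good"
        if lo <= value <= hi:
            return "acceptable"
    return "poor"


@dataclass
class FitIndices:
    """CFI / RMSEA / SRMR with robust variants and qualitative bands."""

    cfi: float
    rmsea: float
    rmsea_ci: tuple
    srmr: float
    n: int
    cfi_robust: Optional[float] = None
    rmsea_robust: Optional[float] = None
    rmsea_ci_robust: Optional[tuple] = None

    @property
    def bands(self) -> dict:
        return {
            "cfi": _band(self.cfi, 0.97, (0.95, 0.97), True),
            "srmr": _band(self.srmr, 0.05, (0.05, 0.10), False),
            "rmsea": _band(self.rmsea, 0.05, (0.05, 0.08), False),
        }


def srmr(S: np.ndarray, sigma: np.ndarray) -> float:
    """RMS of the standardized residual moment matrix over unique elements."""
    ds = np.sqrt(np.diag(S))
    dsig = np.sqrt(np.diag(sigma))
    resid = S / np.outer(ds, ds) - sigma / np.outer(dsig, dsig)
    return float(np.sqrt((_vech(resid) ** 2).mean()))


def _cfi(t: float, df: int, t_b: float, df_b: int) -> float:
    # noncentrality estimates below numerical noise are treated as exact zero
    num = max(t - df, 0.0)
    if num < 1e-8:
        num = 0.0
    den = max(t_b - df_b, num, 0.0)
    if den == 0.0:
        return 1.0
    return float(np.clip(1.0 - num / den, 0.0, 1.0))


def _rmsea(t: float, df: int, n: int) -> float:
    if df == 0:
        return 0.0
    return float(np.sqrt(max(t - df, 0.0) / (df * n)))


def _rmsea_ci(t: float, df: int, n: int, level: float = 0.90) -> tuple:
    """Noncentral-chi-square confidence interval for RMSEA."""
    if df == 0:
        return (0.0, 0.0)
    a = (1.0 - level) / 2.0

    def solve(prob):
        # find lambda with ncx2.cdf(t, df, lambda) = prob
        f = lambda lam: stats.ncx2.cdf(t, df, lam) - prob
        if f(0.0) < 0:
            return 0.0
        hi = max(t, 1.0)
        while f(hi) > 0 and hi < 1e8:
            hi *= 2.0
        if f(hi) > 0:
            return hi
        return optimize.brentq(f, 0.0, hi, xtol=1e-8)

    lam_lo = solve(1.0 - a)
    lam_hi = solve(a)
    return (float(np.sqrt(lam_lo / (df * n))), float(np.sqrt(lam_hi / (df * n))))


def fit_indices(fit: PathFit, baseline: PathFit) -> FitIndices:
    """Incremental and absolute fit indices against an independence baseline."""
    if set(baseline.model.variables) != set(fit.model.variables):
        raise ValueError("baseline must be defined on the same variables")
    if baseline.model.edges:
        raise ValueError("baseline must be the independence model (no edges)")
    n = fit.moments.n
    out = FitIndices(
        cfi=_cfi(fit.t_ml, fit.df, baseline.t_ml, baseline.df),
        rmsea=_rmsea(fit.t_ml, fit.df, n),
        rmsea_ci=_rmsea_ci(fit.t_ml, fit.df, n),
        srmr=srmr(fit.moments.cov, fit.sigma),
        n=n,
    )
    if fit.t_sb is not None and baseline.t_sb is not None:
        out.cfi_robust = _cfi(fit.t_sb, fit.df, baseline.t_sb, baseline.df)
        out.rmsea_robust = _rmsea(fit.t_sb, fit.df, n)
        out.rmsea_ci_robust = _rmsea_ci(fit.t_sb, fit.df, n)
    return out


# ---------------------------------------------------------------------------
# indirect effects


@dataclass
class IndirectEstimate:
    """Product-of-coefficients indirect effect along one directed chain."""

    chain: tuple  # edge labels, causally ordered
    estimate: float
    se: float
    z: float
    p: float
    components: tuple


def indirect_effects(fit: PathFit, chains: Sequence[Sequence[str]]):
    """Delta-method inference for products of chained path coefficients."""
    results = []
    for chain in chains:
        edges = [fit.model.edge_by_label(lab) for lab in chain]
        for e1, e2 in zip(edges, edges[1:]):
            if e1.child != e2.parent:
                raise ValueError(
                    f"chain {tuple(chain)} is not a directed path: "
                    f"{e1.child} != {e2.parent}"
                )
        idx = [fit.param_names.index(lab) for lab in chain]
        comps = fit.theta[idx]
        estimate = float(np.prod(comps))
        grad = np.array([np.prod(np.delete(comps, k)) for k in range(len(comps))])
        V = fit.vcov[np.ix_(idx, idx)]
        se = float(np.sqrt(max(grad @ V @ grad, 0.0)))
        z = 0.0 if estimate == 0.0 else (estimate / se if se > 0 else np.inf)
        p = 2.0 * stats.norm.sf(abs(z))
        results.append(
            IndirectEstimate(tuple(chain), estimate, se, float(z), float(p),
                             tuple(float(c) for c in comps))
        )
    return results


# ---------------------------------------------------------------------------
# nested comparison


@dataclass
class ModelComparison:
    """Scaled likelihood-ratio comparison of two nested path models."""

    full: PathFit
    sparse: PathFit
    statistic: float
    k: int
    p_value: float
    scaled: bool
    correction_factor: Optional[float]


def lr_compare(full: PathFit, sparse: PathFit) -> ModelComparison:
    """Satorra-Bentler scaled difference test, sparse nested in full."""
    if set(full.model.variables) != set(sparse.model.variables):
        raise ValueError("models must share the same variables")
    if full.moments.n != sparse.moments.n:
        raise ValueError("models must be fit to the same data")
    full_edges = {(e.child, e.parent) for e in full.model.edges}
    sparse_edges = {(e.child, e.parent) for e in sparse.model.edges}
    if not sparse_edges < full_edges:
        raise ValueError("sparse model is not strictly nested in the full model")
    k = count_parameters(full.model) - count_parameters(sparse.model)
    if k <= 0:
        raise ValueError("nested comparison requires k > 0 extra parameters")
    diff = sparse.t_ml - full.t_ml
    scaled = False
    cd = None
    if full.scaling_factor is not None and sparse.scaling_factor is not None:
        cd = (sparse.df * sparse.scaling_factor - full.df * full.scaling_factor) / (
            sparse.df - full.df
        )
        if cd > 0:
            diff = diff / cd
            scaled = True
        else:
            logger.warning(
                "negative scaled-difference correction (cd=%.4f); "
                "falling back to the unscaled statistic", cd,
            )
    statistic = max(float(diff), 0.0)
    p = float(stats.chi2.sf(statistic, k))
    return ModelComparison(full, sparse, statistic, k, p, scaled, cd)
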