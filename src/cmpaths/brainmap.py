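"""Region-wise univariate regressions of brain structure on a predictor.

Each regional measure is regressed on one predictor at a time (the models
deliberately do not adjust for each other), producing a map of
standardized slopes and t-statistics across parcels, with multiplicity
control over the region family (step-up Benjamini-Hochberg FDR by
default, step-down Holm as the familywise alternative) and rank
correlation between maps.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["StatMap", "regionwise_regression", "adjust_pvalues", "map_correlation"]


@dataclass
class StatMap:
    """Per-region regression statistics for one predictor."""

    predictor: str
    table: pd.DataFrame  # index region_id; beta, se, t, p, p_adj, flag

    @property
    def m(self) -> int:
        return len(self.table)

    def tvalues(self) -> pd.Series:
        return self.table["t"]


def regionwise_regression(
    predictor: pd.Series,
    brain: pd.DataFrame,
    min_cases: int = 10,
    method: str = "fdr_bh",
    alpha: float = 0.05,
    label: str = "",
) -> StatMap:
    """Simple least-squares slope of each region on the predictor.

    Predictor and regional measures are assumed residualized and z-scored
    upstream, so slopes are standardized betas.  Regions with fewer than
    ``min_cases`` complete cases, or with degenerate variance, are
    reported as missing rather than zero.
    """
    x_all = predictor.to_numpy(dtype=float)
    Y = brain.to_numpy(dtype=float)
    mask = np.isfinite(Y) & np.isfinite(x_all)[:, None]
    n = mask.sum(axis=0).astype(float)

    X = np.where(mask, x_all[:, None], 0.0)
    Ym = np.where(mask, Y, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = X.sum(axis=0) / n
        my = Ym.sum(axis=0) / n
        Xc = np.where(mask, X - mx, 0.0)
        Yc = np.where(mask, Ym - my, 0.0)
        sxx = (Xc**2).sum(axis=0)
        syy = (Yc**2).sum(axis=0)
        sxy = (Xc * Yc).sum(axis=0)
        beta = sxy / sxx
        rss = syy - beta * sxy
        dof = n - 2
        se = np.sqrt(np.clip(rss, 0.0, None) / dof / sxx)
        t = beta / se
    # degenerate (numerically constant) regions are missing, not zero
    with np.errstate(invalid="ignore", divide="ignore"):
        nondegenerate = (syy / n > 1e-14 * (1.0 + my**2)) & (
            sxx / n > 1e-14 * (1.0 + mx**2)
        )
    valid = (n >= min_cases) & nondegenerate & (se > 0)
    p = np.full_like(beta, np.nan)
    p[valid] = 2.0 * stats.t.sf(np.abs(t[valid]), dof[valid])
    beta[~valid] = se[~valid] = t[~valid] = np.nan

    p_adj, flag = adjust_pvalues(p, method=method, alpha=alpha)
    table = pd.DataFrame(
        {"beta": beta, "se": se, "t": t, "p": p, "p_adj": p_adj,
         "flag": flag, "n": n.astype(int)},
        index=brain.columns,
    )
    return StatMap(predictor=label or getattr(predictor, "name", ""), table=table)


def adjust_pvalues(pvals, method: str = "fdr_bh", alpha: float = 0.05):
    """Adjusted p-values and significance flags (BH step-up or Holm step-down).

    Missing entries drop out of the family; the family size is the number
    of analysed (non-missing) regions.
    """
    p = np.asarray(pvals, dtype=float)
    finite = np.isfinite(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    method = {"bh": "fdr_bh", "fdr": "fdr_bh", "fdr_bh": "fdr_bh", "holm": "holm"}[
        method.lower()
    ]
    p_adj = np.full_like(p, np.nan)
    flag = np.zeros(p.shape, dtype=bool)
    if finite.any():
        rej, adj, *_ = multipletests(p[finite], alpha=alpha, method=method)
        p_adj[finite] = adj
        flag[finite] = rej
    return p_adj, flag


def map_correlation(map1: StatMap, map2: StatMap, statistic: str = "spearman") -> float:
    """Rank correlation between the t-value vectors of two stat maps."""
    if statistic != "spearman":
        raise ValueError("only Spearman correlation is supported")
    joined = pd.concat([map1.tvalues(), map2.tvalues()], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("map correlation needs at least 3 shared regions")
    rho, _ = stats.spearmanr(joined.iloc[:, 0], joined.iloc[:, 1])
    return float(rho)
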