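"""End-to-end orchestration of the three analysis stages.

* H1 - the four-variable path model (CM -> BMI/AT/CRP with BMI/AT -> CRP),
  with robust errors, fit indices, the two indirect effects of CM on CRP,
  and the single-predictor CRP-on-CM regression used to demonstrate the
  "disappearing direct effect".
* H2 - region-wise univariate regressions of brain structure on BMI, CRP
  and AT (and the CM null check), with FDR control and spin-corrected
  map correlations.
* H3 - per-region nested "full" vs "sparse" brain-inclusive path models
  compared by a scaled likelihood-ratio test, with chain-wise indirect
  effect maps estimated only where each model won the comparison.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import brainmap, sem
from .models import full_model, h1_model, independence_model, sparse_model
from .preprocess import ResidualizedData
from .spin import generate_spins, spin_pvalue

logger = logging.getLogger(__name__)

__all__ = ["H1Result", "H2Result", "H3Result", "run_h1", "run_h2", "run_h3"]

#: indirect-effect chains of the brain-inclusive models, per host model
FULL_CHAINS = {
    "cm_bmi_mri": ("a1", "c1"),
    "cm_at_mri": ("a3", "c3"),
    "cm_crp_mri": ("a2", "c2"),
    "cm_bmi_crp_mri": ("a1", "b1", "c2"),
    "cm_at_crp_mri": ("a3", "b2", "c2"),
}
SPARSE_CHAINS = {
    "cm_bmi_crp_mri": ("a1", "b1", "c2"),
    "cm_at_crp_mri": ("a3", "b2", "c2"),
}


def _phenotype_frame(data) -> pd.DataFrame:
    if isinstance(data, ResidualizedData):
        return data.phenotypes
    return data


@dataclass
class H1Result:
    """Outputs of the four-variable path analysis."""

    fit: sem.PathFit
    baseline: sem.PathFit
    indices: sem.FitIndices
    indirect: list
    simple_regression: dict
    spearman: pd.DataFrame

    def params_table(self) -> pd.DataFrame:
        return self.fit.params_table()


def run_h1(data, min_n: int = 100) -> H1Result:
    """Fit the four-variable model to residualized, z-scored phenotypes."""
    phen = _phenotype_frame(data)[["cm", "bmi", "at", "crp"]].dropna()
    if len(phen) < min_n:
        raise ValueError(
            f"n={len(phen)} is too small for asymptotic path-model inference; "
            f"need at least {min_n} participants"
        )
    moments = sem.SampleMoments.from_data(phen)
    model = h1_model()
    fit = sem.robust_errors(sem.fit_path_model(model, moments), phen)
    baseline = sem.robust_errors(
        sem.fit_path_model(independence_model(model.variables), moments), phen
    )
    indices = sem.fit_indices(fit, baseline)
    indirect = sem.indirect_effects(fit, [("a1", "b1"), ("a3", "b2")])

    # single-predictor check: CRP ~ CM by plain least squares
    x = phen["cm"].to_numpy()
    y = phen["crp"].to_numpy()
    xc = x - x.mean()
    beta = float(xc @ (y - y.mean()) / (xc @ xc))
    resid = (y - y.mean()) - beta * xc
    se = float(np.sqrt(resid @ resid / (len(y) - 2) / (xc @ xc)))
    t = beta / se
    simple = {
        "beta": beta,
        "se": se,
        "t": t,
        "p": float(2.0 * stats.t.sf(abs(t), len(y) - 2)),
        "n": len(y),
    }
    rho = stats.spearmanr(phen.to_numpy()).statistic
    spearman = pd.DataFrame(rho, index=phen.columns, columns=phen.columns)
    return H1Result(fit, baseline, indices, indirect, simple, spearman)


@dataclass
class H2Result:
    """Region-wise regression maps and their spin-corrected correlations."""

    maps: dict  # predictor -> StatMap over all regions
    correlations: pd.DataFrame  # pair, rho, p_spin, n_spins


def run_h2(
    data,
    brain: pd.DataFrame,
    geometry: pd.DataFrame,
    n_spins: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> H2Result:
    """Brain ~ BMI, Brain ~ CRP, Brain ~ AT (plus the CM null check)."""
    phen = _phenotype_frame(data)
    maps = {
        name: brainmap.regionwise_regression(phen[name], brain, alpha=alpha, label=name)
        for name in ("bmi", "crp", "at", "cm")
    }
    cortical_ids = geometry.loc[geometry["structure_class"] == "cortical", "region_id"]
    spins = generate_spins(geometry, n_spins=n_spins, seed=seed)
    records = []
    for m1, m2 in (("bmi", "crp"), ("bmi", "at"), ("crp", "at")):
        t1 = maps[m1].table.loc[cortical_ids, "t"].to_numpy()
        t2 = maps[m2].table.loc[cortical_ids, "t"].to_numpy()
        ok = np.isfinite(t1) & np.isfinite(t2)
        null = spin_pvalue(np.where(ok, t1, 0.0), np.where(ok, t2, 0.0), spins, seed=seed)
        records.append(
            {"map1": m1, "map2": m2, "rho": null.observed,
             "p_spin": null.p_spin, "n_spins": null.n_spins}
        )
    return H2Result(maps, pd.DataFrame(records))


@dataclass
class H3Result:
    """Per-region nested model comparison and indirect-effect maps."""

    regions: pd.DataFrame  # winner, LR statistic, p, adjusted p, evaluated
    indirect: dict  # (host, chain name) -> DataFrame indexed by region
    contrast_correction: str
    alpha: float
    fits: Optional[dict] = field(default=None, repr=False)


def _region_records(fit: sem.PathFit, chains: dict) -> dict:
    out = {}
    estimates = sem.indirect_effects(fit, list(chains.values()))
    for name, est in zip(chains, estimates):
        out[name] = {"beta": est.estimate, "se": est.se, "z": est.z, "p": est.p}
    return out


def run_h3(
    data,
    brain: pd.DataFrame,
    geometry: pd.DataFrame,
    contrast_correction: str = "fdr_bh",
    alpha: float = 0.05,
    min_n: int = 100,
    keep_fits: bool = False,
) -> H3Result:
    """Full-vs-sparse mediation models at every region.

    The full model adds direct BMI, CRP and AT effects on the region; the
    sparse model routes BMI and AT effects through CRP only.  The winner at
    each region is decided by the scaled LR test with the configured
    multiplicity correction (FDR following the region-selection analysis;
    Holm available as the familywise alternative), and each indirect chain
    is evaluated only within its host model's winning set.
    """
    logger.info("H3 model contrasts corrected with %s at alpha=%g",
                contrast_correction, alpha)
    phen = _phenotype_frame(data)
    fm, sm = full_model(), sparse_model()
    rows = []
    chain_rows: dict = {("full", k): {} for k in FULL_CHAINS}
    chain_rows.update({("sparse", k): {} for k in SPARSE_CHAINS})
    fits: dict = {}
    for region in brain.columns:
        rec = {"region_id": region, "evaluated": False, "winner": None,
               "lr_stat": np.nan, "lr_p": np.nan, "k": np.nan}
        df5 = pd.concat(
            [phen[["cm", "bmi", "at", "crp"]], brain[region].rename("mri")], axis=1
        ).dropna()
        if len(df5) >= min_n:
            try:
                moments = sem.SampleMoments.from_data(df5)
                fit_full = sem.robust_errors(sem.fit_path_model(fm, moments), df5)
                fit_sparse = sem.robust_errors(sem.fit_path_model(sm, moments), df5)
                comp = sem.lr_compare(fit_full, fit_sparse)
                rec.update(evaluated=True, lr_stat=comp.statistic, lr_p=comp.p_value,
                           k=comp.k)
                fits[region] = (fit_full, fit_sparse)
            except sem.FitError as err:
                logger.warning("region %s not evaluated: %s", region, err)
        rows.append(rec)
    regions = pd.DataFrame(rows).set_index("region_id")

    p_adj, flags = brainmap.adjust_pvalues(
        regions["lr_p"].to_numpy(), method=contrast_correction, alpha=alpha
    )
    regions["lr_p_adj"] = p_adj
    evaluated = regions["evaluated"].to_numpy()
    regions.loc[evaluated & flags, "winner"] = "full"
    regions.loc[evaluated & ~flags, "winner"] = "sparse"

    for region, (fit_full, fit_sparse) in fits.items():
        winner = regions.loc[region, "winner"]
        if winner == "full":
            for name, rec in _region_records(fit_full, FULL_CHAINS).items():
                chain_rows[("full", name)][region] = rec
        elif winner == "sparse":
            for name, rec in _region_records(fit_sparse, SPARSE_CHAINS).items():
                chain_rows[("sparse", name)][region] = rec

    indirect = {}
    for key, rows_d in chain_rows.items():
        tab = pd.DataFrame.from_dict(rows_d, orient="index")
        if len(tab):
            tab.index.name = "region_id"
            tab["p_adj"], tab["flag"] = brainmap.adjust_pvalues(
                tab["p"].to_numpy(), method="fdr_bh", alpha=alpha
            )
        indirect[key] = tab
    return H3Result(regions, indirect, contrast_correction, alpha,
                    fits=fits if keep_fits else None)
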