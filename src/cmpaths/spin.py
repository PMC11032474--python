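"""Spatial-autocorrelation-preserving permutation ("spin") tests.

Parcellated cortical maps are spatially smooth, which makes naive
parametric p-values for between-map correlations anticonservative.  The
spin test preserves the spatial covariance of one map under the null by
applying uniformly random 3D rotations to the spherical parcel centroids
and re-assigning each parcel the value of the nearest rotated parcel.
Assignments may be non-bijective (values duplicated or dropped), as is
standard for centroid-based spin tests on parcellated data.  Subcortical
structures have no spherical coordinates and are exempt.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from scipy.stats import special_ortho_group

__all__ = ["SpinNull", "generate_spins", "spin_pvalue"]


@dataclass
class SpinNull:
    """Null distribution and p-value of one spin test."""

    n_spins: int
    observed: float
    nulls: np.ndarray
    p_spin: float
    seed: int


def _cortical_xyz(geometry: pd.DataFrame) -> np.ndarray:
    cortical = geometry[geometry["structure_class"] == "cortical"]
    if len(cortical) == 0:
        raise ValueError("spin test undefined: geometry has no cortical centroids")
    xyz = cortical[["x", "y", "z"]].to_numpy(dtype=float)
    if not np.allclose(np.linalg.norm(xyz, axis=1), 1.0, atol=1e-6):
        raise ValueError("cortical centroids must lie on the unit sphere")
    return xyz


def random_rotations(n: int, seed) -> np.ndarray:
    """Uniform (Haar) random rotation matrices, shape (n, 3, 3)."""
    rng = np.random.default_rng(seed)
    R = special_ortho_group.rvs(dim=3, size=n, random_state=rng)
    return R.reshape(n, 3, 3)


def generate_spins(geometry: pd.DataFrame, n_spins: int = 10_000, seed: int = 0) -> np.ndarray:
    """Region re-assignments under random rotations of the parcel sphere.

    Returns an integer array of shape (n_spins, n_cortical): row ``s``
    maps target parcel ``j`` to the source parcel whose rotated centroid
    lies nearest to parcel ``j``'s original centroid (ties resolved to the
    lowest region index), so a null map is ``map[spins[s]]``.
    """
    if n_spins < 100:
        raise ValueError("use at least 100 spins")
    xyz = _cortical_xyz(geometry)
    rotations = random_rotations(n_spins, seed)
    perms = np.empty((n_spins, len(xyz)), dtype=np.intp)
    for s, R in enumerate(rotations):
        rotated = xyz @ R.T
        _, nearest = cKDTree(rotated).query(xyz, k=1)
        perms[s] = nearest
    return perms


def spin_pvalue(
    map1, map2, spins: np.ndarray, statistic: str = "spearman", seed: int = 0
) -> SpinNull:
    """Two-sided spin p-value for the correlation between two cortical maps.

    The observed statistic is computed on the original maps; each null
    value permutes ``map1`` by one spin and leaves ``map2`` fixed:
    ``p = (1 + #{|null| >= |observed|}) / (n_spins + 1)``.
    """
    x = np.asarray(map1, dtype=float)
    y = np.asarray(map2, dtype=float)
    if x.shape != y.shape:
        raise ValueError("maps must have identical length")
    if spins.shape[1] != x.size:
        raise ValueError("spin permutations do not match map length")
    if statistic != "spearman":
        raise ValueError("only Spearman correlation is supported")
    observed = float(stats.spearmanr(x, y).statistic)
    null_maps = x[spins]  # (S, n) rearrangements of map1 values
    rx = stats.rankdata(null_maps, axis=1)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean(axis=1, keepdims=True)
    ry_c = ry - ry.mean()
    with np.errstate(invalid="ignore"):
        nulls = (rx_c @ ry_c) / np.sqrt((rx_c**2).sum(axis=1) * (ry_c**2).sum())
    n_spins = len(spins)
    p = (1.0 + np.sum(np.abs(nulls) >= abs(observed))) / (n_spins + 1.0)
    return SpinNull(n_spins=n_spins, observed=observed, nulls=nulls,
                    p_spin=float(p), seed=seed)
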