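"""Calibrated latent-normal-to-count maps for questionnaire sum scores.

Questionnaire phenotypes (childhood maltreatment and adult trauma) are
integer sum scores with a large point mass at zero and a long right tail.
The generator produces them by pushing a latent standard normal variable
through a rounded-lognormal quantile map,

    count(x) = clip(round(expm1(mu + sigma * x)), 0, max_count),

whose two parameters are solved so the count distribution matches a target
raw-scale mean and SD exactly (the zero mass arises from rounding the
small-value tail of the lognormal down to zero).

Because the analysis observes ``log1p(count)`` rather than the latent
normal itself, a structural path into a count phenotype is attenuated by
the discretization.  The helpers here compute that attenuation exactly
from the known count distribution, so the generator can place structural
coefficients on the *observed* standardized log1p scale - the scale on
which the downstream model is actually fit.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import optimize, stats

from .config import ConfigError


@dataclass(frozen=True)
class CountMap:
    """Rounded-lognormal map from a standard-normal latent to counts."""

    meanlog: float
    sdlog: float
    max_count: int = 25

    def latent_to_count(self, x: np.ndarray) -> np.ndarray:
        raw = np.expm1(self.meanlog + self.sdlog * np.asarray(x))
        return np.clip(np.round(raw), 0, self.max_count)

    def _thresholds(self):
        ks = np.arange(0, self.max_count + 1)
        lo = np.where(ks == 0, -np.inf, np.log1p(ks - 0.5))
        hi = np.where(ks == self.max_count, np.inf, np.log1p(ks + 0.5))
        return ks, lo, hi

    def count_probs(self):
        """Exact pmf of the count under a standard-normal latent."""
        ks, lo, hi = self._thresholds()
        p = stats.norm.cdf((hi - self.meanlog) / self.sdlog) - stats.norm.cdf(
            (lo - self.meanlog) / self.sdlog
        )
        return ks, p

    def count_moments(self):
        ks, p = self.count_probs()
        m = float((ks * p).sum())
        sd = float(np.sqrt(((ks - m) ** 2 * p).sum()))
        return m, sd

    def log1p_atoms(self):
        """Standardized atoms of log1p(count): (values, probabilities)."""
        ks, p = self.count_probs()
        y = np.log1p(ks)
        m = (y * p).sum()
        sd = np.sqrt((y**2 * p).sum() - m**2)
        return (y - m) / sd, p


@lru_cache(maxsize=64)
def calibrate_count_map(target_mean: float, target_sd: float, max_count: int = 25) -> CountMap:
    """Solve (meanlog, sdlog) so count mean/SD hit the raw-scale targets."""
    if target_sd <= 0 or target_mean <= 0:
        raise ConfigError("count calibration needs positive target mean and SD")

    def objective(par):
        cm = CountMap(par[0], float(np.exp(par[1])), max_count)
        m, s = cm.count_moments()
        return [m - target_mean, s - target_sd]

    sol = optimize.root(objective, x0=[np.log1p(target_mean) - 0.3, 0.0], tol=1e-12)
    if not sol.success:
        raise ConfigError(
            f"count-map calibration failed for mean={target_mean}, sd={target_sd}"
        )
    cmap = CountMap(float(sol.x[0]), float(np.exp(sol.x[1])), max_count)
    m, s = cmap.count_moments()
    if abs(m - target_mean) > 1e-6 or abs(s - target_sd) > 1e-6:
        raise ConfigError("count-map calibration did not reach the targets")
    return cmap


def observed_slope(cmap: CountMap, latent_slope: float, parent_atoms) -> float:
    """Regression slope of standardized log1p(count) on a discrete parent.

    The parent is given by its standardized atom values and probabilities;
    the count latent is ``latent_slope * parent + N(0, 1 - latent_slope^2)``.
    Everything is computed by exact quadrature over the joint (parent atom,
    count) grid - no sampling involved.
    """
    v, p_parent = parent_atoms
    se = np.sqrt(1.0 - latent_slope**2)
    ks, lo, hi = cmap._thresholds()
    y = np.log1p(ks)
    mean_shift = cmap.meanlog + cmap.sdlog * latent_slope * v[:, None]
    scale = cmap.sdlog * se
    pk = stats.norm.cdf((hi[None, :] - mean_shift) / scale) - stats.norm.cdf(
        (lo[None, :] - mean_shift) / scale
    )
    joint = p_parent[:, None] * pk
    ey = float((joint * y[None, :]).sum())
    ey2 = float((joint * y[None, :] ** 2).sum())
    exy = float((joint * v[:, None] * y[None, :]).sum())
    return exy / np.sqrt(ey2 - ey**2)


def latent_slope_for(cmap: CountMap, target_slope: float, parent_atoms) -> float:
    """Latent coefficient whose observed log1p-scale coefficient is ``target``.

    Inverts :func:`observed_slope` by root finding.  Raises if the target
    is too large to realize through the discretized map.
    """
    if target_slope == 0.0:
        return 0.0
    sign = np.sign(target_slope)
    target = abs(target_slope)

    def gap(t):
        return observed_slope(cmap, t, parent_atoms) - target

    hi = 0.999
    if gap(hi) < 0:
        raise ConfigError(
            f"target slope {target_slope} not attainable through the count map"
        )
    return sign * float(optimize.brentq(gap, 0.0, hi, xtol=1e-12))
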