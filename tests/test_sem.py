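"""Path-model estimation and inference against independent oracles."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cmpaths as cp
from cmpaths import sem
from cmpaths.models import (
    Edge,
    PathModel,
    full_model,
    h1_model,
    independence_model,
    parse_model,
    model_to_text,
    sparse_model,
)

from conftest import random_pd_moments, random_recursive_model


# ---------------------------------------------------------------------------
# model definitions and syntax


def test_parameter_counts_of_canonical_models():
    assert cp.count_parameters(full_model()) == 8
    assert cp.count_parameters(sparse_model()) == 6
    assert cp.count_parameters(h1_model()) == 5


def test_model_text_syntax_round_trip():
    model = full_model()
    again = parse_model(model_to_text(model), label=model.label)
    assert again.edges == model.edges
    assert set(again.variables) == set(model.variables)


def test_cyclic_model_rejected():
    with pytest.raises(ValueError, match="cycle"):
        parse_model("a <- b\nb <- a")


def test_model_degrees_of_freedom():
    # 4 variables: 10 moments, 5 paths + 3 residual + 1 exogenous variance
    assert sem.model_df(h1_model()) == 1
    assert sem.model_df(full_model()) == 2
    assert sem.model_df(sparse_model()) == 4


# ---------------------------------------------------------------------------
# implied covariance


def test_implied_covariance_no_paths_is_diagonal():
    model = independence_model(("x", "y", "z"))
    sigma = cp.implied_covariance(model, np.array([1.0, 2.0, 3.0]))
    assert np.allclose(sigma, np.diag([1.0, 2.0, 3.0]))


def test_implied_covariance_single_edge_closed_form():
    model = parse_model("y <- x : a")
    a, psi, var_x = 0.7, 0.4, 1.0
    sigma = cp.implied_covariance(model, np.array([a, psi, var_x]))
    assert np.isclose(sigma[0, 1], a)  # cov(x, y) = a (x first in parse order? no)
    # variable order is (y, x) per parse order; check both entries explicitly
    iy = model.variables.index("y")
    ix = model.variables.index("x")
    assert np.isclose(sigma[ix, iy], a)
    assert np.isclose(sigma[iy, iy], a**2 + psi)
    assert np.isclose(sigma[ix, ix], var_x)


def test_implied_cm_crp_correlation_by_path_tracing():
    """Total CM-CRP correlation equals a2 + a1*b1 + a3*b2 (path tracing)."""
    a1, a2, a3, b1, b2 = 0.072, 0.008, 0.315, 0.434, 0.019
    model = h1_model()
    theta = []
    coeffs = {"a1": a1, "a2": a2, "a3": a3, "b1": b1, "b2": b2}
    for name, kind, _ in sem._param_index(model):
        if kind == "path":
            theta.append(coeffs[name])
        elif name == "psi_bmi":
            theta.append(1 - a1**2)
        elif name == "psi_at":
            theta.append(1 - a3**2)
        elif name == "psi_crp":
            sig3 = np.array([[1, a1 * a3], [a1 * a3, 1]])
            expl = (
                a2**2 + b1**2 + b2**2
                + 2 * (a2 * b1 * a1 + a2 * b2 * a3 + b1 * b2 * a1 * a3)
            )
            theta.append(1 - expl)
        else:  # var_cm
            theta.append(1.0)
    sigma = cp.implied_covariance(model, np.array(theta))
    i_cm = model.variables.index("cm")
    i_crp = model.variables.index("crp")
    expected = a2 + a1 * b1 + a3 * b2  # hand path-tracing oracle
    assert np.isclose(sigma[i_cm, i_crp], expected, atol=1e-12)
    assert np.isclose(expected, 0.045233, atol=5e-7)
    # unit variances everywhere -> covariances are correlations
    assert np.allclose(np.diag(sigma), 1.0, atol=1e-12)


def test_gradient_matches_finite_differences():
    rng = np.random.default_rng(5)
    model = random_recursive_model(rng, n_vars=4)
    moments = random_pd_moments(rng, model.variables)
    S = moments.cov
    _, logdet = np.linalg.slogdet(S)
    theta = sem._warm_start(model, S) + 0.05 * rng.standard_normal(
        sem.n_free_parameters(model)
    )
    f0, grad = sem._fml_and_grad(model, theta, S, logdet)
    eps = 1e-6
    for k in range(len(theta)):
        tp = theta.copy()
        tp[k] += eps
        fp, _ = sem._fml_and_grad(model, tp, S, logdet)
        tm = theta.copy()
        tm[k] -= eps
        fm, _ = sem._fml_and_grad(model, tm, S, logdet)
        assert np.isclose(grad[k], (fp - fm) / (2 * eps), rtol=1e-4, atol=1e-6)


# ---------------------------------------------------------------------------
# estimation: oracle equivalence with least squares


@pytest.mark.parametrize("seed", range(12))
def test_ml_equals_per_equation_least_squares(seed):
    """ML on random recursive models matches the OLS oracle to 1e-8."""
    rng = np.random.default_rng(seed)
    model = random_recursive_model(rng)
    moments = random_pd_moments(rng, model.variables)
    fit = cp.fit_path_model(model, moments)
    S = moments.cov
    idx = {v: k for k, v in enumerate(model.variables)}
    for e in model.edges:
        pa = [idx[u] for u in model.parents(e.child)]
        beta = np.linalg.solve(S[np.ix_(pa, pa)], S[pa, idx[e.child]])
        oracle = beta[model.parents(e.child).index(e.parent)]
        assert abs(fit.estimate(e.label) - oracle) < 1e-8


def test_saturated_model_reproduces_sample_moments():
    rng = np.random.default_rng(11)
    variables = ("x", "y", "z")
    # complete DAG over 3 variables -> df = 0
    model = parse_model("y <- x : a\nz <- x : b\nz <- y : c")
    moments = random_pd_moments(rng, model.variables)
    fit = cp.fit_path_model(model, moments)
    assert fit.df == 0
    assert fit.fml < 1e-12
    assert np.allclose(fit.sigma, moments.cov[
        np.ix_([list(moments.variables).index(v) for v in model.variables],
               [list(moments.variables).index(v) for v in model.variables])
    ] if moments.variables != model.variables else moments.cov, atol=1e-8)


def test_fml_never_increases_as_edges_grow():
    rng = np.random.default_rng(3)
    moments = random_pd_moments(rng, ("cm", "bmi", "at", "crp", "mri"))
    f_sparse = cp.fit_path_model(sparse_model(), moments).fml
    f_full = cp.fit_path_model(full_model(), moments).fml
    assert f_full <= f_sparse + 1e-12


def test_monte_carlo_consistency():
    """Estimates converge to generating values at large n."""
    rng = np.random.default_rng(0)
    model = h1_model()
    coeffs = {"a1": 0.1, "a2": 0.05, "a3": 0.3, "b1": 0.4, "b2": 0.1}
    n = 100_000
    cm = rng.standard_normal(n)
    bmi = coeffs["a1"] * cm + rng.standard_normal(n) * 0.9
    at = coeffs["a3"] * cm + rng.standard_normal(n) * 0.9
    crp = (coeffs["a2"] * cm + coeffs["b1"] * bmi + coeffs["b2"] * at
           + rng.standard_normal(n) * 0.8)
    data = pd.DataFrame({"cm": cm, "bmi": bmi, "at": at, "crp": crp})
    fit = cp.fit_path_model(model, cp.SampleMoments.from_data(data))
    for label, value in coeffs.items():
        assert abs(fit.estimate(label) - value) < 0.01


def test_non_pd_covariance_rejected():
    S = np.array([[1.0, 1.0], [1.0, 1.0]])
    moments = cp.SampleMoments(S, 100, ("y", "x"))
    with pytest.raises(sem.FitError, match="positive definite"):
        cp.fit_path_model(parse_model("y <- x"), moments)


# ---------------------------------------------------------------------------
# robust errors and the scaled statistic


def _simulate_h1_frame(rng, n, heavy=False):
    noise = (lambda m: rng.standard_t(3, m) / np.sqrt(3)) if heavy else rng.standard_normal
    cm = noise(n)
    bmi = 0.2 * cm + 0.95 * noise(n)
    at = 0.3 * cm + 0.95 * noise(n)
    crp = 0.1 * cm + 0.4 * bmi + 0.1 * at + 0.85 * noise(n)
    return pd.DataFrame({"cm": cm, "bmi": bmi, "at": at, "crp": crp})


def test_robust_equals_naive_under_normality():
    data = _simulate_h1_frame(np.random.default_rng(1), 100_000)
    fit = cp.robust_errors(cp.fit_path_model(h1_model(), cp.SampleMoments.from_data(data)), data)
    ratio = fit.se_robust / fit.se_naive
    assert np.all(ratio > 0.95) and np.all(ratio < 1.05)
    assert 0.95 < fit.scaling_factor < 1.05


def test_scaling_factor_exceeds_one_under_heavy_tails():
    """Jointly heavy-tailed (multivariate-t3) data inflates the scaling factor.

    Note the tails must be joint (a common scale mixture): with independent
    heavy-tailed residuals the constrained moment direction of this model is
    a product of independent residuals, which is fourth-moment free, and the
    scaling factor correctly stays near 1.
    """
    hits = 0
    n_seeds = 200
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        data = _simulate_h1_frame(rng, 5_000)
        mixer = np.sqrt(3.0 / rng.chisquare(3.0, len(data)))
        data = data.mul(mixer, axis=0)
        fit = cp.robust_errors(
            cp.fit_path_model(h1_model(), cp.SampleMoments.from_data(data)), data
        )
        hits += fit.scaling_factor > 1.0
    assert hits >= 0.95 * n_seeds


def test_saturated_model_scaled_statistic_zero():
    rng = np.random.default_rng(2)
    data = pd.DataFrame(rng.standard_normal((500, 3)), columns=["x", "y", "z"])
    model = parse_model("y <- x\nz <- x\nz <- y")
    fit = cp.robust_errors(cp.fit_path_model(model, cp.SampleMoments.from_data(data)), data)
    assert fit.t_ml < 1e-8
    assert fit.t_sb == 0.0
    assert fit.scaling_factor == 1.0


def test_wald_z_is_estimate_over_robust_se():
    data = _simulate_h1_frame(np.random.default_rng(4), 2_000)
    fit = cp.robust_errors(cp.fit_path_model(h1_model(), cp.SampleMoments.from_data(data)), data)
    assert np.array_equal(fit.wald_z, fit.theta / fit.se_robust)


# ---------------------------------------------------------------------------
# fit indices


def test_fit_indices_saturated_model():
    rng = np.random.default_rng(6)
    data = pd.DataFrame(rng.standard_normal((400, 3)), columns=["x", "y", "z"])
    moments = cp.SampleMoments.from_data(data)
    sat = cp.fit_path_model(parse_model("y <- x\nz <- x\nz <- y"), moments)
    base = cp.fit_path_model(independence_model(("y", "x", "z")), moments)
    fi = cp.fit_indices(sat, base)
    assert fi.cfi == 1.0
    assert fi.rmsea == 0.0
    assert fi.srmr < 1e-8


def test_baseline_scored_against_itself_has_cfi_zero():
    rng = np.random.default_rng(8)
    data = pd.DataFrame(rng.standard_normal((400, 3)) @ np.array(
        [[1, 0.5, 0.2], [0, 1, 0.4], [0, 0, 1]]), columns=["x", "y", "z"])
    moments = cp.SampleMoments.from_data(data)
    base = cp.fit_path_model(independence_model(("x", "y", "z")), moments)
    fi = cp.fit_indices(base, base)
    assert fi.cfi == 0.0


def test_fit_indices_require_same_variable_baseline():
    rng = np.random.default_rng(9)
    m1 = random_pd_moments(rng, ("x", "y"))
    m2 = random_pd_moments(rng, ("x", "y", "z"))
    fit = cp.fit_path_model(parse_model("y <- x"), m1)
    base = cp.fit_path_model(independence_model(("x", "y", "z")), m2)
    with pytest.raises(ValueError, match="same variables"):
        cp.fit_indices(fit, base)


def test_rmsea_ci_brackets_point_estimate():
    data = _simulate_h1_frame(np.random.default_rng(10), 3_000)
    moments = cp.SampleMoments.from_data(data)
    fit = cp.fit_path_model(h1_model(), moments)
    base = cp.fit_path_model(independence_model(h1_model().variables), moments)
    fi = cp.fit_indices(fit, base)
    lo, hi = fi.rmsea_ci
    assert lo <= fi.rmsea <= hi or (fi.rmsea == 0.0 and lo == 0.0)


# ---------------------------------------------------------------------------
# indirect effects


def _handmade_fit(theta_map, vcov_diag):
    """A minimal PathFit carrying given path estimates and a diagonal vcov."""
    model = h1_model()
    entries = sem._param_index(model)
    names = tuple(e[0] for e in entries)
    theta = np.array([theta_map.get(n, 1.0) for n in names])
    se = np.array([vcov_diag.get(n, 0.0) for n in names])
    vcov = np.diag(se**2)
    return sem.PathFit(
        model=model, moments=cp.SampleMoments(np.eye(4), 100, model.variables),
        theta=theta, param_names=names, param_kinds=tuple(e[1] for e in entries),
        sigma=np.eye(4), fml=0.0, t_ml=0.0, df=1, converged=True, n_iter=0,
        grad_norm=0.0, vcov_naive=vcov, se_naive=se,
    )


def test_indirect_products_match_reported_arithmetic():
    """Products of printed direct effects reproduce the indirect effects."""
    fit = _handmade_fit(
        {"a1": 0.072, "b1": 0.434, "a3": 0.315, "b2": 0.019},
        {"a1": 0.007, "b1": 0.006, "a3": 0.0064, "b2": 0.0063},
    )
    bmi_chain, at_chain = cp.indirect_effects(fit, [("a1", "b1"), ("a3", "b2")])
    assert round(bmi_chain.estimate, 3) == 0.031
    assert round(at_chain.estimate, 3) == 0.006


def test_sobel_identity_for_two_chains():
    """Delta-method SE equals the explicit Sobel formula under diagonal vcov."""
    a, b, se_a, se_b = 0.25, 0.4, 0.01, 0.02
    fit = _handmade_fit({"a1": a, "b1": b}, {"a1": se_a, "b1": se_b})
    (est,) = cp.indirect_effects(fit, [("a1", "b1")])
    sobel = np.sqrt(b**2 * se_a**2 + a**2 * se_b**2)
    assert abs(est.se - sobel) < 1e-12


def test_zero_coefficient_chain_gives_zero_estimate_and_z():
    fit = _handmade_fit({"a1": 0.0, "b1": 0.4}, {"a1": 0.01, "b1": 0.01})
    (est,) = cp.indirect_effects(fit, [("a1", "b1")])
    assert est.estimate == 0.0
    assert est.z == 0.0


def test_indirect_rejects_broken_chain():
    fit = _handmade_fit({}, {})
    with pytest.raises(ValueError, match="not a directed path"):
        cp.indirect_effects(fit, [("b1", "a3")])  # crp<-bmi then at<-cm


# ---------------------------------------------------------------------------
# nested comparison


def _fit_pair(seed=0, n=2_000):
    rng = np.random.default_rng(seed)
    frame = _simulate_h1_frame(rng, n)
    frame["mri"] = 0.1 * frame["crp"] + rng.standard_normal(n)
    moments = cp.SampleMoments.from_data(frame)
    ff = cp.robust_errors(cp.fit_path_model(full_model(), moments), frame)
    fs = cp.robust_errors(cp.fit_path_model(sparse_model(), moments), frame)
    return ff, fs


def test_lr_compare_full_vs_sparse_df():
    ff, fs = _fit_pair()
    comp = cp.lr_compare(ff, fs)
    assert comp.k == 2
    assert comp.scaled
    assert 0.0 <= comp.p_value <= 1.0


def test_lr_compare_identical_models_rejected():
    ff, _ = _fit_pair()
    with pytest.raises(ValueError):
        cp.lr_compare(ff, ff)


def test_lr_compare_requires_nesting():
    ff, fs = _fit_pair()
    with pytest.raises(ValueError, match="nested"):
        cp.lr_compare(fs, ff)
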