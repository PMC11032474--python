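import numpy as np
import pandas as pd
import pytest

import cmpaths as cp


@pytest.fixture(scope="session")
def small_cfg():
    """A desk-scale configuration used by most pipeline tests."""
    return cp.mri_sample_config(
        n_participants=600, n_cortical=24, n_subcortical=3, seed=7
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return cp.generate_cohort(small_cfg)


@pytest.fixture(scope="session")
def small_geometry(small_cfg):
    return cp.generate_geometry(small_cfg)


@pytest.fixture(scope="session")
def small_brain(small_cfg, small_cohort, small_geometry):
    return cp.generate_brain(small_cohort, small_geometry, small_cfg)


@pytest.fixture(scope="session")
def small_resid(small_cohort):
    return cp.preprocess_phenotypes(small_cohort)


@pytest.fixture(scope="session")
def small_brain_resid(small_brain, small_cohort):
    resid, _ = cp.preprocess_brain(small_brain, small_cohort)
    return resid


def random_recursive_model(rng, n_vars=None):
    """A random acyclic path model with random edge density."""
    from cmpaths.models import Edge, PathModel

    n_vars = n_vars or rng.integers(3, 6)
    names = [f"v{k}" for k in range(n_vars)]
    edges = []
    for j in range(n_vars):
        for i in range(j + 1, n_vars):  # only downward edges -> acyclic
            if rng.random() < 0.5:
                edges.append(Edge(names[i], names[j], f"e{i}{j}"))
    return PathModel(tuple(names), tuple(edges))


def random_pd_moments(rng, variables, n=500):
    """Random positive-definite sample moments over the given variables."""
    p = len(variables)
    A = rng.standard_normal((p, p + 3))
    S = A @ A.T / (p + 3)
    return cp.SampleMoments(cov=S, n=n, variables=tuple(variables))
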