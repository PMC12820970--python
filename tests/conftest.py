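"""Shared fixtures: small synthetic cohorts and toy discrimination matrices."""

import numpy as np
import pytest

import nmrmet as nm


def make_separable(n1=12, n2=11, p=10, gap=6.0, noise=0.3, seed=0):
    """Two-class matrix with one variable carrying a large class offset."""
    rng = np.random.default_rng(seed)
    y = np.array([0.0] * n1 + [1.0] * n2)
    X = rng.normal(size=(n1 + n2, p))
    X[:, 0] = y * gap + rng.normal(scale=noise, size=n1 + n2)
    return X, y


def make_null(n1=12, n2=11, p=10, seed=0):
    """Two-class matrix with no association between X and the labels."""
    rng = np.random.default_rng(seed)
    y = np.array([0.0] * n1 + [1.0] * n2)
    return rng.normal(size=(n1 + n2, p)), y


@pytest.fixture(scope="session")
def aqueous_library():
    return nm.build_default_library("aqueous")


@pytest.fixture(scope="session")
def lipophilic_library():
    return nm.build_default_library("lipophilic")


@pytest.fixture(scope="session")
def small_design():
    """Fast aqueous design: reduced axis, default noise and jitter."""
    return nm.CohortDesign(phase="aqueous", n_SC=6, n_HF=6, n_points=4096, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_design, aqueous_library):
    return nm.simulate_cohort(small_design, aqueous_library, seed=11)


@pytest.fixture(scope="session")
def normalized_matrix(small_cohort):
    spectra, _ = small_cohort
    refd = [nm.reference_axis(s) for s in spectra]
    m = nm.build_matrix(refd)
    m = nm.exclude_regions(m, nm.default_exclusions("aqueous"))
    m = nm.align_rspa(m)
    return nm.normalize_total_area(m)


@pytest.fixture(scope="session")
def uv_matrix(normalized_matrix):
    return nm.scale_columns(normalized_matrix, "uv")
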