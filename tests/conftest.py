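"""Shared fixtures: a tiny cohort for unit tests and two desk-scale
cohorts (confounder-free and confounded) reused by the statistical
property tests."""

from __future__ import annotations

import pytest

from vertexlmm import (
    GeneratorConfig,
    build_atlas,
    compute_brm,
    generate_cohort,
    generate_replication,
    standardize_columns,
)

TINY_DIMS = {"ct": (6, 5), "ca": (6, 5), "st": (3, 4), "sa": (3, 4)}  # p = 168


@pytest.fixture(scope="session")
def tiny_config():
    return GeneratorConfig(N=120, grid_dims=dict(TINY_DIMS), seed=7)

@pytest.fixture(scope="session")
def tiny_atlas(tiny_config):
    return build_atlas(tiny_config)


@pytest.fixture(scope="session")
def tiny_raw(tiny_config):
    data, latent = generate_cohort(tiny_config)
    return data, latent


@pytest.fixture(scope="session")
def tiny_cohort(tiny_raw):
    data, _ = tiny_raw
    return standardize_columns(data)


@pytest.fixture(scope="session")
def cohort_free():
    """Confounder-free desk cohort (N=1000, p=5000) with its global BRM."""
    cfg = GeneratorConfig.desk(N=1000, p=5000, confounder_share=0.0, seed=5)
    raw, _ = generate_cohort(cfg)
    atlas = build_atlas(cfg)
    data = standardize_columns(raw)
    brm = compute_brm(data)
    brm.eigendecomposition()
    return data, atlas, brm


@pytest.fixture(scope="session")
def cohort_conf():
    """Confounded desk cohort (share 0.3) plus a raw replication cohort."""
    cfg = GeneratorConfig.desk(N=1000, p=5000, confounder_share=0.3, seed=9)
    raw, latent = generate_cohort(cfg)
    atlas = build_atlas(cfg)
    data = standardize_columns(raw)
    repl = generate_replication(cfg, latent, seed=1009, N=500)
    return data, atlas, repl
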