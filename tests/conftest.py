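"""Shared fixtures: the default synthetic atlas and its processed matrices."""
from __future__ import annotations

import warnings

import pytest
from hypothesis import HealthCheck, settings

import abcatlas as abc

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

ATLAS_SEED = 11


@pytest.fixture(scope="session")
def default_atlas() -> abc.SyntheticAtlas:
    """The default-design synthetic atlas (32 types x 50 cells, 3000 genes)."""
    return abc.simulate_atlas(seed=ATLAS_SEED)


@pytest.fixture(scope="session")
def processed(default_atlas):
    """QC-filtered and normalized matrices of the default atlas."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        qc = abc.qc_filter(default_atlas.counts, min_coding=600, min_lnc=150)
        norm_coding = abc.normalize_log2tpm10(qc.coding)
        norm_lnc = abc.normalize_log2tpm10(qc.lncrna)
    return qc, norm_coding, norm_lnc


@pytest.fixture(scope="session")
def default_signatures(processed):
    """Called signatures for both biotypes on the default atlas."""
    _, norm_coding, norm_lnc = processed
    return abc.find_signatures(norm_coding), abc.find_signatures(norm_lnc)


@pytest.fixture(scope="session")
def small_atlas() -> abc.SyntheticAtlas:
    """A reduced atlas (8 types, 900 genes) for cheaper end-to-end checks."""
    return abc.simulate_atlas(abc.AtlasConfig.small(), seed=ATLAS_SEED)
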