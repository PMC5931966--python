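"""Shared fixtures: small, fast phantom geometries reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from debloomct import (
    PhantomSpec,
    ScannerConfig,
    apply_blooming,
    build_psf,
    make_vessel_phantom,
)
from debloomct.pipeline import slice_ranges

SMALL_GRID = (96, 96, 24)


@pytest.fixture(scope="session")
def spec50():
    return PhantomSpec(stenosis_pct=50.0, grid_shape=SMALL_GRID)


@pytest.fixture(scope="session")
def truth50(spec50):
    vol, record = make_vessel_phantom(spec50)
    return vol, record


@pytest.fixture(scope="session")
def ranges50(spec50):
    reference, lesion = slice_ranges(spec50)
    return reference, lesion


@pytest.fixture(scope="session")
def stnd_quiet():
    """STND scanner with noise and rim disabled (deterministic blur only)."""
    return ScannerConfig.for_kernel("STND", noise_sd=0.0, rim_strength=0.0, seed=0)


@pytest.fixture(scope="session")
def bloomed50_quiet(truth50, stnd_quiet):
    vol, _ = truth50
    return apply_blooming(vol, stnd_quiet)


@pytest.fixture(scope="session")
def psf_stnd(stnd_quiet, spec50):
    return build_psf(stnd_quiet, spec50.spacing)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
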