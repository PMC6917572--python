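"""Shared fixtures.

The expensive artifacts (a full default-size cohort and one rendered
default core) are session-scoped and seeded so every test sees identical
data; everything else is cheap and constructed per test.
"""

from __future__ import annotations

import numpy as np
import pytest

from plexdia.pipeline import run_cohort
from plexdia.synthdata import (
    CohortConfig,
    DetectionModel,
    build_core,
    default_spectral_library,
    render_chromogenic,
    render_fluorescence,
    simulate_cohort_table,
)

FULL_COHORT_SEED = 7


@pytest.fixture(scope="session")
def library():
    return default_spectral_library()


@pytest.fixture(scope="session")
def model():
    return DetectionModel()


@pytest.fixture(scope="session")
def default_core(library, model):
    """One rendered core at default settings with its ground truth."""
    cfg = CohortConfig(seed=11, n_cases=4)
    cases = simulate_cohort_table(cfg)
    case = cases.iloc[0]
    truth = build_core(case, cfg)
    fluor = render_fluorescence(truth, library, model, cfg)
    chrom = render_chromogenic(truth, model, cfg, marker="CDX2")
    return {"config": cfg, "case": case, "truth": truth, "fluor": fluor, "chrom": chrom}


@pytest.fixture(scope="session")
def noiseless_core(library):
    """A noiseless render of the same core for exact-recovery tests."""
    cfg = CohortConfig(seed=11, n_cases=4)
    model = DetectionModel(noise_sd=0.0, chrom_noise_sd=0.0)
    cases = simulate_cohort_table(cfg)
    truth = build_core(cases.iloc[0], cfg)
    fluor = render_fluorescence(truth, library, model, cfg, noise=False)
    return {"config": cfg, "truth": truth, "fluor": fluor, "model": model}


@pytest.fixture(scope="session")
def full_cohort():
    """The end-to-end default cohort shared by the acceptance criteria.

    600 cases, 256x256 px, ~300 cells per core, default noise; the single
    most expensive fixture in the suite (several minutes), computed once.
    """
    cfg = CohortConfig(seed=FULL_COHORT_SEED, n_cases=600)
    return run_cohort(cfg, keep_cells=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
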