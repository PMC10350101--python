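"""Shared fixtures: phantom simulations and one full pipeline run.

Session scope keeps the expensive simulations to a single evaluation; all
randomness is seeded so every fixture is reproducible.
"""

import time

import numpy as np
import pytest

import qsmkit as qk


@pytest.fixture(scope="session")
def meta32():
    return qk.default_meta(grid_shape=(32, 32, 32))


@pytest.fixture(scope="session")
def noiseless32(meta32):
    """Effectively noiseless 32^3 phantom (SNR 1e9), with ground truth."""
    spec = qk.default_phantom_spec(grid_shape=(32, 32, 32), snr=1e9, seed=3)
    data, truth = qk.simulate_multiecho(spec, meta32)
    return spec, data, truth


@pytest.fixture(scope="session")
def meta64():
    return qk.default_meta()


@pytest.fixture(scope="session")
def noiseless64(meta64):
    """Noiseless default-scene phantom at the full 64^3 study grid."""
    spec = qk.default_phantom_spec(snr=1e9, seed=3)
    data, truth = qk.simulate_multiecho(spec, meta64)
    return spec, data, truth


@pytest.fixture(scope="session")
def pipeline_run():
    """One full default-chain run on the 64^3 phantom at SNR 50, timed."""
    t0 = time.perf_counter()
    result = qk.run_pipeline(qk.PipelineConfig(seed=1),
                             phantom_preset="default")
    elapsed = time.perf_counter() - t0
    return result, elapsed


@pytest.fixture(scope="session")
def pipeline_rerun():
    """Second run with identical configuration, for determinism checks."""
    return qk.run_pipeline(qk.PipelineConfig(seed=1),
                           phantom_preset="default")


def inner_sphere_errors(result, erode=2):
    """Relative ROI-mean errors of the two phantom inclusions."""
    from scipy import ndimage

    truth, chi = result.truth, result.chi_map
    vm = chi.valid_mask
    ref_true = truth.chi_volume[vm].mean()
    errs = []
    for label, chi_true in ((2, 0.1), (3, -0.1)):
        roi = ndimage.binary_erosion(truth.labels == label,
                                     iterations=erode) & vm
        est = chi.chi[roi].mean()
        errs.append(abs(est - (chi_true - ref_true)) / abs(chi_true - ref_true))
    return errs
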