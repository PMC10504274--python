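"""Shared fixtures: small phantoms and RF frame pairs used across modules."""

import numpy as np
import pytest

import cordelast as ce


@pytest.fixture(scope="session")
def small_spec():
    """Compact phantom (15 x 12 mm) that keeps RF synthesis fast."""
    return ce.PhantomSpec(depth_mm=15.0, width_mm=12.0, window_x_mm=(1.0, 11.0),
                          cord_center_mm=(7.5, 6.0))


@pytest.fixture(scope="session")
def rf_quiet():
    """Default probe, electronic noise off."""
    return ce.RFConfig()


@pytest.fixture(scope="session")
def speckle_frame(small_spec, rf_quiet):
    """One noiseless fully-developed-speckle frame of the small phantom."""
    scat = ce.generate_scatterers(
        small_spec, density=10.0,
        cell_area_mm2=ce.resolution_cell_area_mm2(rf_quiet), seed=3)
    return ce.synthesize_frame(scat, rf_quiet, seed=0)


@pytest.fixture(scope="session")
def dense_speckle_frame(small_spec, rf_quiet):
    """Denser scatterer field (20/cell) for first-order speckle statistics:
    at ~10 per cell the envelope is still mildly K-distributed, while by
    20 per cell its SNR has converged to the Rayleigh value."""
    scat = ce.generate_scatterers(
        small_spec, density=20.0,
        cell_area_mm2=ce.resolution_cell_area_mm2(rf_quiet), seed=13)
    return ce.synthesize_frame(scat, rf_quiet, seed=0)


@pytest.fixture(scope="session")
def homogeneous_pipeline():
    """Full pipeline run on a homogeneous 1%-compression speckle phantom.

    No stiffness contrast: the estimated strain should be uniform at the
    applied compression.  Shared by strain-accuracy and kernel tests.
    """
    spec = ce.PhantomSpec(depth_mm=15.0, width_mm=12.0, window_x_mm=(1.0, 11.0),
                          cord_center_mm=(7.5, 6.0), e_cord_kpa=25.0)
    rf = ce.RFConfig(noise_snr_db=30.0)
    mmap = ce.build_modulus_map(spec)
    truth = ce.solve_compression(mmap)
    scat = ce.generate_scatterers(spec, density=10.0,
                                  cell_area_mm2=ce.resolution_cell_area_mm2(rf), seed=11)
    pre = ce.synthesize_frame(scat, rf, seed=21)
    post = ce.deform_and_synthesize(scat, truth, rf, seed=22)
    return spec, rf, truth, pre, post


def resample_shift(samples: np.ndarray, shift_samples: float) -> np.ndarray:
    """Band-limited axial delay of a frame by cubic-spline resampling."""
    from scipy.interpolate import CubicSpline

    n = samples.shape[0]
    idx = np.arange(n)
    out = np.empty_like(samples)
    for li in range(samples.shape[1]):
        cs = CubicSpline(idx, samples[:, li])
        out[:, li] = cs(np.clip(idx - shift_samples, 0, n - 1))
    return out
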