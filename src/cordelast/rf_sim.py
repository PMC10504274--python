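"""Point-spread-function convolution model for RF ultrasound frames.

Each sub-resolution scatterer contributes a Gaussian-enveloped cosine pulse
at its two-way echo depth on every scan line within its lateral beam
footprint, weighted by a Gaussian lateral beam profile.  This separable-PSF
speckle model reproduces the first- and second-order statistics needed to
validate displacement tracking (fully developed Rayleigh speckle, correct
center frequency and bandwidth, exact axial shift behavior); it does not
model beamforming, attenuation, or phase aberration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.random import SeedSequence, default_rng
from scipy.interpolate import RegularGridInterpolator
from scipy.signal import hilbert

from .phantom import GroundTruthField, ScattererField, stable_seed

_SQRT_2LN2 = np.sqrt(2.0 * np.log(2.0))


class NyquistError(ValueError):
    """Sampling frequency too low for the pulse bandwidth."""


@dataclass
class RFConfig:
    """Probe and acquisition parameters.

    Defaults emulate a 38-mm linear array with 6.6 MHz center frequency,
    5–14 MHz (−6 dB) bandwidth and 1 mm lateral beamwidth in the focal
    plane.  The fractional bandwidth default 9/6.6 ≈ 1.36 encodes the 9-MHz
    −6 dB width of that band; the exact transmit pulse shape of the scanner
    is not known, so a Gaussian envelope with this width is assumed.
    """

    f0_mhz: float = 6.6
    fractional_bandwidth: float = 9.0 / 6.6
    fs_mhz: float = 40.0
    c_m_s: float = 1540.0
    lateral_beamwidth_mm: float = 1.0
    line_pitch_mm: float = 0.3
    noise_snr_db: float | None = None   # None = noise off

    def __post_init__(self) -> None:
        if min(self.f0_mhz, self.fractional_bandwidth, self.fs_mhz,
               self.c_m_s, self.lateral_beamwidth_mm, self.line_pitch_mm) <= 0:
            raise ValueError("all RF configuration values must be positive")
        if self.fs_mhz <= 2.0 * self.f0_mhz * (1.0 + self.fractional_bandwidth / 2.0):
            raise NyquistError(
                f"fs={self.fs_mhz} MHz violates Nyquist for f0={self.f0_mhz} MHz "
                f"with fractional bandwidth {self.fractional_bandwidth:.3f}"
            )

    @property
    def sample_dz_mm(self) -> float:
        """Axial depth spacing per RF sample, c/(2 fs)."""
        return self.c_m_s / (2.0 * self.fs_mhz * 1e6) * 1e3

    @property
    def axial_sigma_mm(self) -> float:
        """Gaussian envelope σ in depth from the −6 dB pulse bandwidth."""
        w6_mhz = self.fractional_bandwidth * self.f0_mhz      # −6 dB full width
        sigma_f = w6_mhz / (2.0 * _SQRT_2LN2)                 # spectral σ (MHz)
        sigma_t_us = 1.0 / (2.0 * np.pi * sigma_f)            # µs
        return sigma_t_us * 1e-6 * self.c_m_s / 2.0 * 1e3     # two-way, mm

    @property
    def lateral_sigma_mm(self) -> float:
        """Gaussian beam σ from the −6 dB beamwidth."""
        return self.lateral_beamwidth_mm / (2.0 * _SQRT_2LN2)

    @property
    def carrier_cycles_per_mm(self) -> float:
        """Spatial frequency of the RF carrier in depth (two-way)."""
        return 2.0 * self.f0_mhz * 1e6 / self.c_m_s * 1e-3


def resolution_cell_area_mm2(config: RFConfig) -> float:
    """−6 dB resolution-cell area: axial envelope FWHM × lateral beamwidth."""
    axial_fwhm = 2.0 * _SQRT_2LN2 * config.axial_sigma_mm
    return axial_fwhm * config.lateral_beamwidth_mm


@dataclass
class RFFrame:
    """One RF acquisition: samples (axial) × scan lines (lateral)."""

    samples: np.ndarray        # (n_samples, n_lines)
    config: RFConfig
    x_mm: np.ndarray           # lateral position of each scan line
    frame_role: str = "pre"    # "pre" | "post"
    provenance: dict = None

    def __post_init__(self) -> None:
        if self.provenance is None:
            self.provenance = {}

    @property
    def z_mm(self) -> np.ndarray:
        return np.arange(self.samples.shape[0]) * self.config.sample_dz_mm

    def envelope(self) -> np.ndarray:
        """Hilbert envelope per line (used for B-mode display and checks)."""
        return np.abs(hilbert(self.samples, axis=0))


def _deposit(
    z_mm: np.ndarray, x_mm: np.ndarray, amplitudes: np.ndarray,
    config: RFConfig, n_samples: int, line_x: np.ndarray,
) -> np.ndarray:
    """Accumulate the PSF of every scatterer into an RF frame."""
    dz = config.sample_dz_mm
    sig_z = config.axial_sigma_mm
    sig_x = config.lateral_sigma_mm
    k_mm = config.carrier_cycles_per_mm
    half = int(np.ceil(4.0 * sig_z / dz))
    offsets = np.arange(-half, half + 1)

    out = np.zeros((n_samples, line_x.size))
    order = np.argsort(x_mm, kind="stable")
    zs, xs, amps = z_mm[order], x_mm[order], amplitudes[order]
    reach = 3.5 * sig_x
    for li, xl in enumerate(line_x):
        lo = np.searchsorted(xs, xl - reach)
        hi = np.searchsorted(xs, xl + reach)
        if hi <= lo:
            continue
        z = zs[lo:hi]
        w = amps[lo:hi] * np.exp(-0.5 * ((xs[lo:hi] - xl) / sig_x) ** 2)
        mu = z / dz                                   # fractional sample index
        base = np.round(mu).astype(np.int64)
        idx = base[:, None] + offsets[None, :]        # (n_s, K)
        t = (idx - mu[:, None]) * dz                  # depth offset from scatterer (mm)
        pulse = w[:, None] * np.exp(-0.5 * (t / sig_z) ** 2) * np.cos(2.0 * np.pi * k_mm * t)
        ok = (idx >= 0) & (idx < n_samples)
        out[:, li] = np.bincount(idx[ok].ravel(), weights=pulse[ok].ravel(), minlength=n_samples)
    return out


def _frame_geometry(scatterers: ScattererField, config: RFConfig):
    n_samples = int(round(scatterers.depth_mm / config.sample_dz_mm)) + 1
    n_lines = int(np.floor(scatterers.width_mm / config.line_pitch_mm)) + 1
    line_x = np.arange(n_lines) * config.line_pitch_mm
    return n_samples, line_x


def _add_noise(samples: np.ndarray, config: RFConfig, seed: int) -> np.ndarray:
    if config.noise_snr_db is None or not np.isfinite(config.noise_snr_db):
        return samples
    rms = np.sqrt(np.mean(samples ** 2))
    if rms == 0:
        return samples
    sigma = rms * 10.0 ** (-config.noise_snr_db / 20.0)
    rng = default_rng(SeedSequence([int(seed) & 0x7FFFFFFF, stable_seed("rf-noise")]))
    return samples + rng.normal(0.0, sigma, size=samples.shape)


def synthesize_frame(
    scatterers: ScattererField, config: RFConfig, seed: int = 0,
) -> RFFrame:
    """Pre-compression RF frame of a scatterer field.

    Additive white electronic noise at ``config.noise_snr_db`` (relative to
    the frame RMS) is drawn from a stream seeded by ``seed``; an empty
    scatterer field with noise off yields an all-zero frame.
    """
    n_samples, line_x = _frame_geometry(scatterers, config)
    if len(scatterers) == 0:
        samples = np.zeros((n_samples, line_x.size))
    else:
        samples = _deposit(scatterers.z_mm, scatterers.x_mm, scatterers.amplitudes,
                           config, n_samples, line_x)
    samples = _add_noise(samples, config, seed)
    return RFFrame(samples=samples, config=config, x_mm=line_x, frame_role="pre",
                   provenance={"seed": int(seed), "n_scatterers": len(scatterers)})


def deform_and_synthesize(
    scatterers: ScattererField,
    truth: GroundTruthField,
    config: RFConfig,
    seed: int = 1,
) -> RFFrame:
    """Post-compression RF frame.

    Scatterer depths are moved toward the transducer by bilinear
    interpolation of the ground-truth echo-shift field (the transducer frame
    sees echoes arrive earlier as the tissue between them compresses).
    Amplitudes are unchanged — echogenicity is preserved under small strain.
    The noise stream is independent of the pre-frame stream via ``seed``.
    """
    n_samples, line_x = _frame_geometry(scatterers, config)
    if len(scatterers) == 0:
        samples = np.zeros((n_samples, line_x.size))
        clipped = 0
    else:
        shift = truth.shift_toward_transducer()
        interp = RegularGridInterpolator(
            (truth.z_mm, truth.x_mm), shift, method="linear",
            bounds_error=False, fill_value=None,
        )
        zq = np.clip(scatterers.z_mm, truth.z_mm[0], truth.z_mm[-1])
        xq = np.clip(scatterers.x_mm, truth.x_mm[0], truth.x_mm[-1])
        z_new = scatterers.z_mm - interp(np.column_stack([zq, xq]))
        inside = (z_new >= 0.0) & (z_new <= scatterers.depth_mm)
        clipped = int((~inside).sum())
        z_new = np.clip(z_new, 0.0, scatterers.depth_mm)
        samples = _deposit(z_new, scatterers.x_mm, scatterers.amplitudes,
                           config, n_samples, line_x)
    samples = _add_noise(samples, config, seed)
    return RFFrame(samples=samples, config=config, x_mm=line_x, frame_role="post",
                   provenance={"seed": int(seed), "n_scatterers": len(scatterers),
                               "clipped_scatterers": clipped})
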