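"""Strain-ratio quantification and mechanical-testing analysis.

The imaging biomarker is the spinal-cord/soft-tissue strain ratio
SR = mean(strain over the cord ROI) / mean(strain over a surrounding
soft-tissue reference), aggregated arithmetically at every level:
repeated acquisitions → neighborhood (imaging plane) → animal → group.

The mechanical-testing side converts force–displacement records of cord
samples into engineering stress–strain curves, fits the Young's modulus as
the OLS slope over the 10–20% strain range, and fits the one-parameter
hyperbola E = c / SR that expresses the expected inverse proportionality
between strain ratio and modulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .elasto import Elastogram, TrackingParams, support_half_width_mm
from .phantom import PhantomSpec, REFERENCE_BAND_MM

MIN_ROI_PIXELS = 25

MODULUS_FIT_RANGE = (0.10, 0.20)
_EDGE_TOL = 1e-9            # inclusive fit-range endpoints, compared with tolerance


class ROIError(ValueError):
    """An ROI has too few quality-masked-in pixels."""


class UndefinedRatioError(ValueError):
    """The reference-region mean strain is not positive."""


@dataclass
class ROIMasks:
    """Cord and soft-tissue reference masks on an elastogram grid."""

    cord_mask: np.ndarray
    reference_mask: np.ndarray
    provenance: str = "drawn-from-truth"   # or "supplied"

    def __post_init__(self) -> None:
        if np.any(self.cord_mask & self.reference_mask):
            raise ValueError("cord and reference masks must be disjoint")


#: Default lateral erosion of the cord ROI (mm): two Gaussian beam sigmas of
#: the default 1-mm (−6 dB) beamwidth, beyond which lateral PSF leakage of
#: soft-tissue motion into cord columns is negligible.
DEFAULT_CORD_LATERAL_MARGIN_MM = 0.85


def roi_masks_from_spec(
    spec: PhantomSpec,
    grid_z_mm: np.ndarray,
    grid_x_mm: np.ndarray,
    margin_mm: float = 0.0,
    cord_lateral_margin_mm: float = 0.0,
    band_mm: float = REFERENCE_BAND_MM,
    window_edge_margin_mm: float = 1.0,
) -> ROIMasks:
    """Ground-truth-derived ROI masks on a (window-center) grid.

    The cord mask keeps pixels at least ``margin_mm`` axially and
    ``cord_lateral_margin_mm`` laterally inside the cord boundary; the
    reference mask keeps soft-tissue pixels in the laminectomy window within
    ±(radius + band) of the cord depth that stand off the cord by the same
    margins and off the window's lateral edges by ``window_edge_margin_mm``.
    Passing the strain estimator's axial support half-width and the beam
    footprint as the margins ensures every retained pixel is estimated from
    a single tissue type; zero margins reproduce the raw geometry.
    """
    zc, xc = spec.cord_center_mm
    r = spec.cord_radius_mm
    x_lo, x_hi = spec.window_x_mm
    zz = np.asarray(grid_z_mm)[:, None] - zc
    xx = np.asarray(grid_x_mm)[None, :] - xc

    half_chord = np.sqrt(np.clip(r * r - xx * xx, 0.0, None))      # axial half-extent per column
    half_width = np.sqrt(np.clip(r * r - zz * zz, 0.0, None))      # lateral half-extent per row
    in_cord_col = np.abs(xx) < r
    cord = in_cord_col \
        & (np.abs(zz) <= half_chord - margin_mm) \
        & (np.abs(xx) <= half_width - cord_lateral_margin_mm)

    in_window = (np.asarray(grid_x_mm) >= x_lo + window_edge_margin_mm) & \
                (np.asarray(grid_x_mm) <= x_hi - window_edge_margin_mm)
    band = np.abs(zz) <= r + band_mm
    dilate = r + max(margin_mm, cord_lateral_margin_mm)
    near_cord = zz * zz + xx * xx <= dilate * dilate
    reference = in_window[None, :] & band & ~near_cord
    return ROIMasks(cord_mask=cord, reference_mask=reference)


def roi_masks_for_tracking(
    spec: PhantomSpec,
    elast: Elastogram,
    params: TrackingParams | None = None,
    rf_config=None,
) -> ROIMasks:
    """Default pipeline masks: geometry eroded by the estimator support.

    The axial margin is the strain estimator's support half-width; the
    lateral margin is two beam sigmas (taken from ``rf_config`` when given,
    otherwise for the default 1-mm beamwidth).
    """
    params = params or elast.params
    lateral = (2.0 * rf_config.lateral_sigma_mm if rf_config is not None
               else DEFAULT_CORD_LATERAL_MARGIN_MM)
    return roi_masks_from_spec(
        spec, elast.grid_z_mm, elast.grid_x_mm,
        margin_mm=support_half_width_mm(params),
        cord_lateral_margin_mm=lateral,
    )


def compute_strain_ratio(elast: Elastogram, masks: ROIMasks,
                         min_pixels: int = MIN_ROI_PIXELS) -> float:
    """SR = mean cord strain / mean reference strain over quality pixels."""
    q = elast.quality_mask
    cord = masks.cord_mask & q
    ref = masks.reference_mask & q
    if cord.sum() < min_pixels:
        raise ROIError(f"cord mask has {int(cord.sum())} valid pixels (< {min_pixels})")
    if ref.sum() < min_pixels:
        raise ROIError(f"reference mask has {int(ref.sum())} valid pixels (< {min_pixels})")
    ref_mean = float(elast.strain[ref].mean())
    if ref_mean <= 0:
        raise UndefinedRatioError("reference-region mean strain is not positive")
    return float(elast.strain[cord].mean() / ref_mean)


@dataclass
class StrainRatioRecord:
    """Per-animal aggregation of strain ratios.

    ``per_acquisition`` is nested as [neighborhood][repeat]; repeated
    measures average to a neighborhood value, neighborhoods average to the
    per-animal value (arithmetic means at every level).
    """

    animal_id: str
    group: str
    per_acquisition: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for nb in self.per_acquisition:
            for v in nb:
                if v <= 0:
                    raise ValueError("strain ratios must be positive")

    @property
    def per_neighborhood(self) -> np.ndarray:
        return np.array([float(np.mean(nb)) for nb in self.per_acquisition])

    @property
    def per_animal(self) -> float:
        return float(self.per_neighborhood.mean())


@dataclass
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float


def aggregate_cohort(records: list[StrainRatioRecord]) -> list[GroupSummary]:
    """Per-group mean and sample SD (n−1) of the per-animal strain ratios."""
    if not records:
        raise ValueError("no records to aggregate")
    groups: dict[str, list[float]] = {}
    for rec in records:
        groups.setdefault(rec.group, []).append(rec.per_animal)
    out = []
    for label, values in groups.items():
        v = np.asarray(values)
        sd = float(v.std(ddof=1)) if v.size > 1 else float("nan")
        out.append(GroupSummary(label=label, n=v.size, mean=float(v.mean()), sd=sd))
    return out


@dataclass
class StressStrainCurve:
    """Engineering stress–strain data from one compression test."""

    stress_kpa: np.ndarray
    strain: np.ndarray
    force_n: np.ndarray
    displacement_mm: np.ndarray
    area0_mm2: float
    length0_mm: float


@dataclass
class ModulusEstimate:
    e_kpa: float
    fit_range: tuple[float, float]
    r2: float
    n_points: int


@dataclass
class HyperbolaFit:
    c_kpa: float
    residual_ss: float


def engineering_curve(force_n, displacement_mm, area0_mm2: float,
                      length0_mm: float) -> StressStrainCurve:
    """Engineering stress σ = F/A₀ (kPa) and strain ε = d/L₀.

    Strain must be non-decreasing (a monotone loading ramp); reordering is
    never silent.
    """
    force_n = np.asarray(force_n, float)
    displacement_mm = np.asarray(displacement_mm, float)
    if area0_mm2 <= 0 or length0_mm <= 0:
        raise ValueError("initial area and length must be positive")
    if force_n.shape != displacement_mm.shape:
        raise ValueError("force and displacement must have the same length")
    strain = displacement_mm / length0_mm
    if np.any(np.diff(strain) < -1e-12):
        raise ValueError("engineering strain must be non-decreasing")
    if np.any(force_n < 0):
        raise ValueError("compressive force must be non-negative")
    stress_kpa = force_n / area0_mm2 * 1000.0    # N/mm² = MPa → kPa
    return StressStrainCurve(stress_kpa=stress_kpa, strain=strain,
                             force_n=force_n, displacement_mm=displacement_mm,
                             area0_mm2=area0_mm2, length0_mm=length0_mm)


def fit_modulus(curve: StressStrainCurve,
                fit_range: tuple[float, float] = MODULUS_FIT_RANGE) -> ModulusEstimate:
    """Young's modulus as the OLS slope of stress on strain over the fit range.

    The 10–20% range (inclusive endpoints) is the standard choice for the
    near-linear toe-to-linear transition of cord tissue in transverse
    compression; at least 3 points are required.
    """
    lo, hi = fit_range
    sel = (curve.strain >= lo - _EDGE_TOL) & (curve.strain <= hi + _EDGE_TOL)
    n = int(sel.sum())
    if n < 3:
        raise ValueError(f"only {n} samples with strain in [{lo}, {hi}] (need >= 3)")
    x = curve.strain[sel]
    y = curve.stress_kpa[sel]
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - float((resid ** 2).sum()) / ss_tot
    return ModulusEstimate(e_kpa=float(slope), fit_range=(lo, hi), r2=r2, n_points=n)


def fit_hyperbola(strain_ratios, moduli_kpa) -> HyperbolaFit:
    """Least-squares fit of the one-parameter hyperbola E = c / SR.

    Minimizing Σ (E_i − c/SR_i)² has the closed form
    c = Σ(E_i/SR_i) / Σ(1/SR_i²).
    """
    sr = np.asarray(strain_ratios, float)
    e = np.asarray(moduli_kpa, float)
    if sr.size < 2:
        raise ValueError("need at least 2 points")
    if np.any(sr <= 0):
        raise ValueError("strain ratios must be positive")
    inv = 1.0 / sr
    c = float((e * inv).sum() / (inv * inv).sum())
    resid = e - c * inv
    return HyperbolaFit(c_kpa=c, residual_ss=float((resid ** 2).sum()))
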