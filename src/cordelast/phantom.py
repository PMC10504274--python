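"""Virtual tissue phantoms for spinal-cord strain elastography.

A phantom is a 2-D Young's-modulus map of a transverse section through a
laminectomy site: a circular spinal-cord cross-section embedded in softer
paraspinal soft tissue, acoustically accessible only through the laminectomy
window (regions lateral to the window are rigid bone and carry no
scatterers).  A small uniaxial compression applied at the transducer face
produces a ground-truth axial strain field under a uniform-stress
approximation, from which cohorts of "non-paralyzed" (stiff, homogeneous
cord) and "paralyzed" (softer, heterogeneous cord) animals are synthesized
with prescribed cord/soft-tissue strain-ratio distributions.

Coordinates: ``z`` is axial depth in mm, increasing away from the transducer
face at z=0; ``x`` is lateral position in mm.  Grids hold pixel centers.
Compressive strain is stored positive.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from numpy.random import SeedSequence, default_rng
from scipy.stats import truncnorm

# region labels on the modulus map
SOFT = 0
CORD = 1
VOID = 2

#: Depth band (mm) beyond the cord radius that defines the soft-tissue
#: reference region ("surrounding soft tissue at the cord's depth").
REFERENCE_BAND_MM = 5.0


class GeometryError(ValueError):
    """Raised when the cord does not fit inside the imaging window."""


@dataclass
class PhantomSpec:
    """Geometry and material parameters of one virtual acquisition plane.

    Parameters
    ----------
    depth_mm, width_mm : float
        Axial and lateral extent of the simulated field of view. The width
        default matches a 38-mm linear-array transducer.
    grid_dz_mm, grid_dx_mm : float
        Mechanical grid spacing.
    e_soft_kpa : float
        Young's modulus of the background soft tissue (kPa).
    cord_center_mm : (float, float)
        (z, x) center of the circular cord cross-section.
    cord_radius_mm : float
        Cord radius.
    window_x_mm : (float, float)
        Lateral span of the laminectomy window; tissue outside it is
        labeled rigid/void (bone) and is acoustically inaccessible.
    e_cord_kpa : float
        Modulus of normal cord tissue. The in vivo cord/muscle contrast is
        not known a priori; this default is a configurable placeholder.
    e_lesion_kpa : float or None
        Modulus assigned to lesion pixels inside the cord. ``None`` means
        0.2 * e_soft_kpa (malacic tissue softer than the background).
    lesion_fraction : float
        Fraction of cord pixels replaced by lesion tissue (heterogeneous
        injury); 0 gives a homogeneous cord.
    applied_strain : float
        Frame-average axial compression (dimensionless, e.g. 0.01).
    seed : int
        Seed for the lesion-pixel placement and scatterer generation.
    """

    depth_mm: float = 30.0
    width_mm: float = 38.0
    grid_dz_mm: float = 0.1
    grid_dx_mm: float = 0.1
    e_soft_kpa: float = 25.0
    cord_center_mm: tuple[float, float] = (10.0, 19.0)
    cord_radius_mm: float = 2.5
    window_x_mm: tuple[float, float] = (9.0, 29.0)
    e_cord_kpa: float = 150.0
    e_lesion_kpa: float | None = None
    lesion_fraction: float = 0.0
    applied_strain: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.depth_mm, self.width_mm, self.grid_dz_mm, self.grid_dx_mm) <= 0:
            raise ValueError("geometry extents and grid spacings must be positive")
        if self.e_soft_kpa <= 0 or self.e_cord_kpa <= 0:
            raise ValueError("Young's moduli must be positive")
        if self.e_lesion_kpa is not None and self.e_lesion_kpa <= 0:
            raise ValueError("Young's moduli must be positive")
        if not 0.0 <= self.lesion_fraction <= 1.0:
            raise ValueError("lesion_fraction must lie in [0, 1]")
        if not 0.0 < self.applied_strain <= 0.05:
            raise ValueError("applied_strain must lie in (0, 0.05]")
        if self.cord_radius_mm <= 0:
            raise ValueError("cord radius must be positive")

    @property
    def lesion_modulus_kpa(self) -> float:
        return 0.2 * self.e_soft_kpa if self.e_lesion_kpa is None else self.e_lesion_kpa


@dataclass
class ModulusMap:
    """Labeled Young's-modulus field on the mechanical grid."""

    e_kpa: np.ndarray          # (nz, nx)
    labels: np.ndarray         # (nz, nx) int8, SOFT/CORD/VOID
    z_mm: np.ndarray           # (nz,) pixel centers
    x_mm: np.ndarray           # (nx,)
    spec: PhantomSpec

    @property
    def window_mask(self) -> np.ndarray:
        return self.labels != VOID

    @property
    def cord_mask(self) -> np.ndarray:
        return self.labels == CORD

    def reference_mask(self, band_mm: float = REFERENCE_BAND_MM) -> np.ndarray:
        """Soft tissue inside the window within ±(radius+band) of the cord depth."""
        zc = self.spec.cord_center_mm[0]
        half = self.spec.cord_radius_mm + band_mm
        band = np.abs(self.z_mm - zc) <= half
        return (self.labels == SOFT) & band[:, None]


@dataclass
class GroundTruthField:
    """Exact strain/displacement fields for one compressed phantom.

    ``strain`` is the axial normal strain (compression positive).
    ``displacement`` is the cumulative axial displacement (mm) of each pixel
    measured from the fixed deep boundary, i.e. u = ∫_z^depth ε dz'; it is
    zero at the deep boundary and largest at the surface.
    """

    strain: np.ndarray         # (nz, nx)
    displacement: np.ndarray   # (nz, nx) mm
    true_strain_ratio: float
    z_mm: np.ndarray
    x_mm: np.ndarray
    applied_strain: float
    sigma0_kpa: float

    def shift_toward_transducer(self) -> np.ndarray:
        """Echo shift s(z,x) = ∫_0^z ε dz' seen in the transducer frame.

        Under compression a scatterer at depth z appears at depth z - s(z,x)
        in the post-compression frame (the plate/transducer moves with the
        surface, so echoes shift toward the transducer).
        """
        dz = self.z_mm[1] - self.z_mm[0] if self.z_mm.size > 1 else 2.0 * self.z_mm[0]
        # total column integral from surface (z=0) to deep boundary; shift =
        # total - u(z) = integral from the surface down to z.
        total = self.displacement[0, :] + 0.5 * dz * self.strain[0, :]
        return total[None, :] - self.displacement


@dataclass
class ScattererField:
    """Sub-resolution point scatterers emulating tissue echogenicity."""

    z_mm: np.ndarray           # continuous depths
    x_mm: np.ndarray           # continuous lateral positions
    amplitudes: np.ndarray
    depth_mm: float            # frame axial extent
    width_mm: float            # frame lateral extent
    window_x_mm: tuple[float, float]
    density_per_cell: float

    def __len__(self) -> int:
        return self.z_mm.size


@dataclass
class CohortConfig:
    """Target strain-ratio distribution for one synthetic animal group."""

    label: str
    n_animals: int
    sr_mean: float
    sr_sd: float
    sr_truncation: float = 0.02
    acquisitions_per_animal: int = 2
    neighborhoods_per_animal: int = 2
    heterogeneity: float = 0.0   # lesion_fraction used for this group
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if self.sr_truncation < 0.01:
            raise ValueError("sr_truncation must be >= 0.01")
        if self.sr_mean <= self.sr_truncation:
            raise ValueError("sr_mean must exceed sr_truncation")
        if self.sr_sd < 0:
            raise ValueError("sr_sd must be >= 0")


@dataclass
class AnimalPhantom:
    """One synthesized animal: spec, modulus map and ground truth."""

    animal_id: str
    group: str
    target_sr: float
    spec: PhantomSpec
    modulus_map: ModulusMap
    truth: GroundTruthField


def stable_seed(*parts) -> int:
    """Deterministic 31-bit seed component from arbitrary labels.

    Uses CRC32 of the string representation so that per-animal substreams do
    not depend on Python's salted ``hash`` and adding an animal does not
    reshuffle the others.
    """
    text = ":".join(str(p) for p in parts)
    return zlib.crc32(text.encode("utf-8")) & 0x7FFFFFFF


def build_modulus_map(spec: PhantomSpec) -> ModulusMap:
    """Rasterize a phantom spec into a labeled modulus map.

    Cord pixels carry ``e_cord_kpa``; ``lesion_fraction`` of them (rounded)
    are replaced by the lesion modulus, chosen by seeded uniform sampling
    without replacement.  Deterministic given ``spec.seed``.
    """
    zc, xc = spec.cord_center_mm
    r = spec.cord_radius_mm
    x_lo, x_hi = spec.window_x_mm
    if xc - r < x_lo or xc + r > x_hi:
        raise GeometryError("cord cross-section extends laterally outside the laminectomy window")
    if zc - r < 0 or zc + r > spec.depth_mm:
        raise GeometryError("cord cross-section extends axially outside the imaging depth")

    nz = int(round(spec.depth_mm / spec.grid_dz_mm))
    nx = int(round(spec.width_mm / spec.grid_dx_mm))
    z = (np.arange(nz) + 0.5) * spec.grid_dz_mm
    x = (np.arange(nx) + 0.5) * spec.grid_dx_mm

    labels = np.full((nz, nx), SOFT, dtype=np.int8)
    outside = (x < x_lo) | (x > x_hi)
    labels[:, outside] = VOID
    zz = z[:, None] - zc
    xx = x[None, :] - xc
    cord = zz * zz + xx * xx <= r * r
    labels[cord] = CORD

    e = np.full((nz, nx), spec.e_soft_kpa, dtype=float)
    e[cord] = spec.e_cord_kpa
    n_cord = int(cord.sum())
    n_lesion = int(round(spec.lesion_fraction * n_cord))
    if n_lesion > 0:
        rng = default_rng(SeedSequence([int(spec.seed), stable_seed("lesion")]))
        flat = np.flatnonzero(cord)
        chosen = rng.choice(flat, size=n_lesion, replace=False)
        e.flat[chosen] = spec.lesion_modulus_kpa
    return ModulusMap(e_kpa=e, labels=labels, z_mm=z, x_mm=x, spec=spec)


def solve_compression(mmap: ModulusMap, applied_strain: float | None = None) -> GroundTruthField:
    """Uniform-stress compression of a modulus map.

    A single global axial stress σ0 is chosen so that the window-average
    strain equals ``applied_strain``; then ε(z,x) = σ0 / E(z,x) inside the
    window and 0 in the rigid void.  Displacement is the cumulative integral
    of ε along depth from the fixed deep boundary toward the transducer.
    This is a 1-D mechanical approximation (no shear coupling between
    columns), adequate because the applied compression field is uniform.
    """
    spec = mmap.spec
    alpha = spec.applied_strain if applied_strain is None else float(applied_strain)
    if alpha <= 0:
        raise ValueError("applied_strain must be positive")
    if np.any(mmap.e_kpa <= 0):
        raise ValueError("all moduli must be positive")

    window = mmap.window_mask
    compliance = 1.0 / mmap.e_kpa
    sigma0 = alpha / compliance[window].mean()
    strain = sigma0 * compliance
    strain[~window] = 0.0

    dz = spec.grid_dz_mm
    # u(z_k) = integral of strain from the pixel center down to the deep
    # boundary: full-pixel contributions below + half of the own pixel.
    csum = np.cumsum(strain, axis=0) * dz
    u = (csum[-1:, :] - csum) + 0.5 * strain * dz

    cord = mmap.cord_mask
    ref = mmap.reference_mask()
    tsr = float(strain[cord].mean() / strain[ref].mean())
    return GroundTruthField(
        strain=strain, displacement=u, true_strain_ratio=tsr,
        z_mm=mmap.z_mm, x_mm=mmap.x_mm, applied_strain=alpha, sigma0_kpa=float(sigma0),
    )


#: Default −6 dB resolution-cell area (mm²): axial pulse FWHM × 1 mm lateral
#: beamwidth for the default probe (see rf_sim.resolution_cell_area_mm2).
DEFAULT_CELL_AREA_MM2 = 0.075


def generate_scatterers(
    spec: PhantomSpec,
    density: float = 10.0,
    cell_area_mm2: float = DEFAULT_CELL_AREA_MM2,
    seed: int | None = None,
) -> ScattererField:
    """Uniform random scatterers over the acoustically accessible window.

    ``density`` is scatterers per resolution cell; >= 10 gives fully
    developed speckle (Rayleigh envelope). Amplitudes are i.i.d. standard
    normal. The rigid bone outside the window carries no scatterers.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    x_lo, x_hi = spec.window_x_mm
    area = spec.depth_mm * (x_hi - x_lo)
    n = int(round(density * area / cell_area_mm2))
    rng = default_rng(SeedSequence([int(spec.seed if seed is None else seed), stable_seed("scatterers")]))
    z = rng.uniform(0.0, spec.depth_mm, size=n)
    x = rng.uniform(x_lo, x_hi, size=n)
    a = rng.standard_normal(n)
    return ScattererField(
        z_mm=z, x_mm=x, amplitudes=a,
        depth_mm=spec.depth_mm, width_mm=spec.width_mm,
        window_x_mm=spec.window_x_mm, density_per_cell=density,
    )


def truncated_normal(mean: float, sd: float, lower: float):
    """Frozen scipy truncated normal on [lower, inf)."""
    a = (lower - mean) / sd
    return truncnorm(a, np.inf, loc=mean, scale=sd)


def draw_target_ratios(config: CohortConfig, master_seed: int | None = None) -> np.ndarray:
    """Per-animal target strain ratios from the truncated normal.

    Draws are stratified: animal i receives the truncated-normal quantile of
    a uniform draw from the i-th of n equal-probability strata (stratum
    order shuffled).  The marginal distribution of each draw is the
    truncated normal; stratification keeps the realized cohort mean close to
    the distribution mean even at n = 5–6, which is what a cohort built to
    emulate a printed group mean should do.
    """
    seed = config.seed if master_seed is None else master_seed
    rng = default_rng(SeedSequence([int(seed), stable_seed("cohort", config.label)]))
    n = config.n_animals
    if config.sr_sd == 0:
        return np.full(n, config.sr_mean)
    u = (rng.permutation(n) + rng.uniform(size=n)) / n
    dist = truncated_normal(config.sr_mean, config.sr_sd, config.sr_truncation)
    return np.asarray(dist.ppf(u))


def build_calibrated_phantom(
    target_sr: float,
    lesion_fraction: float = 0.0,
    seed: int = 0,
    **spec_overrides,
) -> AnimalPhantom:
    """Build a phantom whose true strain ratio equals ``target_sr`` exactly.

    The cord base modulus starts at E_soft / SR (the uniform-stress closed
    form for a homogeneous cord); with a heterogeneous cord all cord-pixel
    moduli (normal and lesion) are then rescaled by one factor so that the
    realized harmonic-mean compliance ratio hits the target — the relative
    softness of the lesion is preserved while the mean cord strain matches
    the draw.
    """
    if target_sr <= 0:
        raise ValueError("target strain ratio must be positive")
    overrides = dict(spec_overrides)
    e_soft = overrides.get("e_soft_kpa", PhantomSpec.e_soft_kpa)
    spec = PhantomSpec(
        e_cord_kpa=e_soft / target_sr,
        lesion_fraction=lesion_fraction,
        seed=seed,
        **overrides,
    )
    mmap = build_modulus_map(spec)
    cord = mmap.cord_mask
    # realized ratio under uniform stress: E_soft * mean cord compliance
    realized = e_soft * (1.0 / mmap.e_kpa[cord]).mean()
    mmap.e_kpa[cord] *= realized / target_sr
    truth = solve_compression(mmap)
    return AnimalPhantom(
        animal_id="", group="", target_sr=float(target_sr),
        spec=spec, modulus_map=mmap, truth=truth,
    )


def sample_cohort(config: CohortConfig, master_seed: int | None = None, **spec_overrides) -> list[AnimalPhantom]:
    """Synthesize one animal group with prescribed strain-ratio targets.

    Returns one phantom per animal, each calibrated so its ground-truth
    strain ratio equals its truncated-normal draw. Reproducible given the
    seed; per-animal substreams are derived by stable hashing of
    (group label, animal index) so adding an animal does not reshuffle the
    others.
    """
    seed = config.seed if master_seed is None else master_seed
    targets = draw_target_ratios(config, seed)
    animals = []
    for i, sr in enumerate(targets):
        sub = SeedSequence([int(seed), stable_seed("animal", config.label, i)])
        animal_seed = int(sub.generate_state(1)[0] & 0x7FFFFFFF)
        ph = build_calibrated_phantom(
            float(sr), lesion_fraction=config.heterogeneity,
            seed=animal_seed, **spec_overrides,
        )
        ph.animal_id = f"{config.label}_{i:02d}"
        ph.group = config.label
        animals.append(ph)
    return animals


def generate_compression_record(
    e_kpa: float,
    length0_mm: float = 3.0,
    area0_mm2: float = 7.0,
    max_strain: float = 0.70,
    n_points: int = 200,
    curvature_kpa: float | None = None,
    noise_kpa: float = 0.0,
    seed: int = 0,
):
    """Synthetic force–displacement record of a transverse cord compression.

    Emulates unconfined compression of a ~3 mm spinal-cord sample driven to
    70% engineering strain.  The stress model is the strain-stiffening
    quadratic σ(ε) = (E − 0.3 b) ε + b ε², whose OLS slope over the 10–20%
    strain range converges to ``e_kpa`` under dense symmetric sampling
    (slope of ε² regressed on ε over [0.1, 0.2] is 0.3).  ``curvature_kpa``
    defaults to 2·E, giving the concave-up curves typical of neural tissue.

    Returns (force_N, displacement_mm, area0_mm2, length0_mm).
    """
    if e_kpa <= 0 or length0_mm <= 0 or area0_mm2 <= 0:
        raise ValueError("modulus, length and area must be positive")
    b = 2.0 * e_kpa if curvature_kpa is None else curvature_kpa
    a = e_kpa - 0.3 * b
    eps = np.linspace(0.0, max_strain, n_points)
    stress_kpa = a * eps + b * eps * eps
    if noise_kpa > 0:
        rng = default_rng(SeedSequence([int(seed), stable_seed("mech")]))
        stress_kpa = stress_kpa + rng.normal(0.0, noise_kpa, size=eps.size)
    stress_kpa = np.clip(stress_kpa, 0.0, None)
    force_n = stress_kpa * area0_mm2 / 1000.0   # kPa·mm² = 1e-3 N
    displacement_mm = eps * length0_mm
    return force_n, displacement_mm, area0_mm2, length0_mm
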