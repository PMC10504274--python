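# Methods

This note documents the models, defaults and numerical choices behind
`cordelast`, and what the synthetic test bed does and does not establish
about real data.

## Phantom and mechanics

A phantom is a 2-D transverse plane: background soft tissue (default
E_soft = 25 kPa), a circular cord cross-section (radius 2.5 mm, default
center 10 mm deep) and a laminectomy window (default lateral span
9–29 mm of a 38-mm aperture, matching a 38-mm linear array). Tissue
lateral to the window is labeled rigid/void — bone is modeled only as an
acoustically inaccessible, non-deforming region; no bone acoustics.

Compression is solved under a **uniform-stress approximation**: one global
axial stress σ₀ is chosen so the window-average strain equals the applied
compression α (default 0.01), and ε = σ₀/E pixelwise. Each column deforms
independently (no shear coupling); displacement is the cumulative integral
of ε from the fixed deep boundary, and the echo shift seen by the
transducer is the integral of ε from the surface down. Consequences worth
knowing:

- the window-average strain equals α to machine precision by construction;
- strain and the true strain ratio are invariant to a global rescaling of
  the modulus map (σ₀ renormalizes);
- for a homogeneous cord, true SR = E_soft/E_cord exactly. This closed form
  is what makes the phantom a usable oracle for the whole pipeline.

This is not finite elements: real inclusions concentrate stress at their
boundaries and deform their surroundings. The approximation is adequate
here because the compression plate makes the far-field deformation uniform
and the quantity under test is a ratio of region means, not a full strain
image.

**Injured (heterogeneous) cords.** A lesion fraction f of cord pixels
(chosen by seeded sampling without replacement) is set to a soft lesion
modulus (default 0.2·E_soft). To make the mean cord strain hit a prescribed
target ratio, all cord-pixel moduli are rescaled by a single factor so that
the harmonic-mean compliance matches the target exactly; the lesion/normal
contrast is preserved. The resulting picture — a mostly stiff cord with
soft, high-strain lesion pockets — mirrors the heterogeneous elastograms
seen in paralyzed animals.

**Cohorts.** Each animal's target SR is drawn from a truncated normal
(lower bound 0.02; ratios near zero would need unbounded stiffness).
Draws are **stratified**: animal i takes the quantile of a uniform draw
from the i-th of n equal-probability strata, in shuffled order. The
marginal law of each draw is unchanged, but the realized cohort mean
concentrates around the distribution mean even at n = 5–6 — the right
behavior for cohorts whose purpose is to emulate a published group mean.
The canonical study emulation uses 6 "non_paralyzed" animals from
truncN(0.16, 0.06²) with homogeneous cords and 5 "paralyzed" animals from
truncN(0.34, 0.17²) with f = 0.3, two repeated acquisitions in each of two
imaging neighborhoods per animal. The in vivo modulus contrast between cord
and muscle is not established; the default E_cord = 150 kPa (6× background)
is a placeholder and fully configurable.

## RF synthesis

Frames are built by a separable point-spread-function convolution model:
each scatterer deposits a Gaussian-enveloped cosine at its two-way depth on
all lines within its lateral beam footprint, weighted by a Gaussian beam
profile. Probe defaults: 6.6 MHz center frequency, −6 dB bandwidth 9 MHz
(fractional 1.36, encoding a 5–14 MHz band; the true transmit pulse shape
of the emulated scanner is unknown, so the Gaussian envelope is an
assumption), 1 mm −6 dB lateral beamwidth, 40 MHz sampling, 1540 m/s,
0.3 mm line pitch. Scatterer density defaults to 10 per resolution cell
(~0.075 mm²), the usual threshold for fully developed speckle; positions
are uniform over the window, amplitudes standard normal, and amplitudes are
identical in the pre and post frames (echogenicity preserved under small
strain). Electronic noise is white Gaussian at a configurable SNR relative
to the frame RMS (off for unit tests, 30 dB for cohort runs), with
independent streams for pre and post frames.

The post frame moves each scatterer toward the transducer by the
bilinearly interpolated echo-shift field. Scatterers displaced outside the
frame are clipped and counted in the frame provenance. There is no
beamforming, attenuation/TGC, phase aberration or 3-D beam; those effects
degrade real tracking in ways this simulator cannot certify.

Two properties anchor the simulator's correctness: the frame is linear in
the scatterer set, and a constant integer-sample displacement reproduces
the pre frame shifted exactly — which in turn lets the tracker be tested
against an exact oracle. At ~10 scatterers per cell the envelope SNR is
mildly sub-Rayleigh (K-distributed speckle); it converges to
√(π/(4−π)) ≈ 1.91 by ~20 per cell.

## Displacement tracking and strain

Per line, windowed zero-normalized cross-correlation over a bounded axial
search, shallow to deep. Defaults: 1.0 mm windows, 80% overlap (0.2 mm
step), ±0.5 mm initial search. With guided search (default), each window's
search is re-centered on its shallower neighbor's integer lag within
±0.2 mm, falling back to the full range around zero when the guided peak's
quality drops below threshold — this prevents peak-hopping at 1% strain
where the true shift reaches ~16 samples.

**Subsample refinement** defaults to the *phase* method: the integer peak
is located on the real ZNCC, then the offset is the phase zero-crossing of
the analytic-signal cross-correlation at that lag, δ = −∠R_a/ω (clamped to
±0.5 samples). The textbook 3-point parabolic vertex is available but is
not the default: its bias is periodic in the true subsample offset and
averages out only where displacement sweeps many carrier cycles. Inside a
stiff cord the displacement spans less than one sample across the whole
ROI, the bias does not cancel, and ratio errors up to +0.05 result; the
phase method removed this (SR sweep error within ±0.03 across SR 0.1–0.5).
An envelope (log-Gaussian parabola) variant exists for broadband
experimentation. Exact integer matches (peak ≈ 1) shortcut to δ = 0, so
integer-sample shifts are recovered *exactly*, not approximately;
non-concave triplets and search-edge peaks also fall back to δ = 0.

**Quality.** The per-window quality is the normalized magnitude of the
analytic cross-correlation at the matched lag ("envelope coherence",
in [0, 1]), thresholded at 0.75. The raw real-NCC peak is unsuitable as a
quality metric: it dips to cos(ω/2) at half-sample offsets (≈0.67 at
25 MHz sampling) even with zero decorrelation, which would erase entire
regions whose shift happens to sit mid-sample. Coherence measures actual
speckle decorrelation and equals 1 for identical frames. All-zero windows
get quality 0 and are invalid.

**Strain** is the least-squares strain estimator: per line, the negated
slope of a sliding OLS fit of û versus depth over `lsq_kernel = 7` window
centers (compression positive, matching magnitude displays). A strain
pixel is masked unless every window in its kernel is valid and above
threshold. An optional 3×3 median filter is off by default. The tracking
defaults are this package's own resolution/variance compromise (the
emulated study does not publish its estimator settings): the axial support
of one strain estimate — (kernel−1)·step + window = ±1.1 mm — must stay
well under the 2.5 mm cord radius or no cord pixel is estimated from cord
tissue alone. Tracking is 1-D axial only, a deliberate simplification: the
simulator applies purely axial motion and only axial normal strain is
quantified.

## ROI masks and the strain ratio

Default masks derive from the ground-truth geometry. The cord ROI is
eroded axially by the strain-estimator support half-width (1.1 mm at
default settings) and laterally by two beam sigmas (0.85 mm at a 1 mm
beamwidth), so every retained pixel's estimate is supported by cord tissue
only — without this the estimator's axial smoothing and the beam's lateral
mixing bias SR upward by up to +0.1 at SR ≈ 0.16. The soft-tissue
reference keeps window pixels within ±(radius + 5 mm) of the cord depth,
standing off the cord by the same margin and off the window edges by 1 mm.
Zero-margin masks reproduce the raw geometry for supplied-mask workflows.
Both ROIs must keep ≥ 25 quality pixels; the ratio is
mean(ε̂ cord)/mean(ε̂ reference), with errors raised for nonpositive
reference means. Aggregation is arithmetic at every level: repeats →
neighborhood → animal → group (mean and n−1 SD). Display normalization and
the SR statistic are treated as one and the same definition.

## Mechanical testing and fits

Engineering stress σ = F/A₀ (kPa) and strain ε = d/L₀ from
force–displacement records; strain must be non-decreasing (reordering is
never silent). Young's modulus is the OLS slope of σ on ε restricted to
ε ∈ [0.10, 0.20], endpoints inclusive with 1e-9 tolerance, ≥ 3 points
required. The synthetic record generator uses σ(ε) = (E−0.3b)ε + bε²
(b = 2E by default), whose restricted OLS slope converges to E under dense
sampling, driven to 70% strain on 3 mm samples. The strain-ratio/modulus
relation is fitted as the one-parameter hyperbola E = c/SR with the closed
form c = Σ(Eᵢ/SRᵢ)/Σ(1/SRᵢ²); an offset hyperbola was considered and left
out — inverse proportionality is the stated model, and one parameter keeps
the fit identifiable from a handful of animals.

## Statistics

The group comparison is the two-tailed Wilcoxon rank-sum test with
midranks for ties, exact by full enumeration of all C(n₁+n₂, n₁)
assignments for pooled sizes ≤ 14 (the study's 5-vs-6 is always exact;
C(14,7) = 3432 is trivial), otherwise the tie-corrected normal
approximation with continuity correction. The two-sided p doubles the
smaller tail and caps at 1 — the convention matters in tie-heavy exact
tests and is fixed here for reproducibility. A caution established while
validating the driver: under the emulated group distributions
(truncN(0.16, 0.06²) vs truncN(0.34, 0.17²), n = 6 vs 5) the exact test's
Monte-Carlo power is only ≈ 0.4–0.5 even with error-free measurement,
because the distributions overlap substantially at these sample sizes; a
single synthetic experiment therefore rejects at α = 0.05 roughly half the
time when cohorts are redrawn. The experiment driver pins the canonical
cohort draws (`cohort_seed`) separately from measurement randomness so
that repeated runs estimate the same cohort's parameters.

Histology-score analysis is an OLS regression of strain ratio on ordinal
myelomalacia score (0–4, dorsal/ventral per plane), exercised on synthetic
score tables generated with a positive slope — softer, structurally
disrupted tissue strains more.

## Reproducibility and problem sizes

Every random stream descends from `numpy` `SeedSequence`s combined with
CRC32 hashes of stable labels (group, animal index, stage), so per-animal
substreams never depend on Python's salted `hash` and adding an animal does
not reshuffle the others. Reports and CSVs are byte-identical across runs
with the same seeds.

The full-resolution study emulation (11 animals × 4 acquisitions, 30 ×
38 mm frames, 40 MHz) runs in about a minute on one CPU. Replicate/power
studies use a reduced preset — 18 × 16 mm field of view, 25 MHz sampling,
5 scatterers per cell, one acquisition in one neighborhood per animal —
chosen as the smallest configuration whose cord ROI still clears the
25-pixel floor.

## What passing tests do and do not show

The generator emulates speckle-tracking physics faithfully enough to
validate the estimator chain: PSF-limited resolution, fully developed
speckle, strain-induced decorrelation, electronic noise, quality masking
and ROI effects. It does not emulate attenuation, reverberation, off-axis
clutter, lateral/elevational motion, probe pressure variation, anatomical
segmentation error, or physiologic motion — so passing tests certify the
*estimators and statistics*, not clinical performance. The mechanics is a
uniform-stress ratio model, exact only in that approximation; absolute
strain images near inclusion boundaries are not certified. Histologic
scores are synthetic ordinals; only the regression machinery, not any
biological association, is tested.
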