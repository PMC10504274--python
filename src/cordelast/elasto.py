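"""Axial displacement tracking and least-squares strain estimation.

The estimator is the classical quasi-static strain-elastography chain:

1. per scan line, 1-D windowed normalized cross-correlation (NCC) between
   the pre- and post-compression RF frames over a bounded axial search,
   optionally *guided* — each window's search is centered on the estimate of
   the adjacent shallower window, which prevents peak-hopping at ~1% strain;
2. subsample refinement of the NCC peak (3-point parabolic by default);
3. axial normal strain as the negated slope of a sliding ordinary
   least-squares fit of displacement versus depth (the least-squares strain
   estimator), so that compressive strain is reported positive.

Displacement is stored in mm, positive when tissue moves away from the
transducer; under compression in the transducer frame displacements are
negative and grow in magnitude with depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import correlate1d, median_filter
from scipy.signal import hilbert

from .rf_sim import RFFrame

_EXACT_PEAK = 1.0 - 1e-9   # NCC above this is treated as an exact match


@dataclass
class TrackingParams:
    """Speckle-tracking and strain-estimator parameters.

    The source study does not publish its estimator settings; these defaults
    are this package's own resolution/variance compromise, sized so that the
    strain-estimation support (correlation window plus least-squares kernel,
    half-width ``(window_len_mm + (lsq_kernel-1)*step)/2``) stays well below
    the 2.5-mm cord radius. See docs/methods.md.
    """

    window_len_mm: float = 1.0
    window_overlap: float = 0.8
    search_mm: float = 0.5
    guided_search_mm: float = 0.2
    subsample: str = "phase"           # "parabolic" | "envelope" | "phase" | "none"
    guided: bool = True
    ncc_threshold: float = 0.75
    lsq_kernel: int = 7
    median_filter: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.window_overlap < 1.0:
            raise ValueError("window_overlap must lie in [0, 1)")
        if self.window_len_mm <= 0 or self.search_mm <= 0 or self.guided_search_mm <= 0:
            raise ValueError("window length and search ranges must be positive")
        if self.subsample not in ("parabolic", "envelope", "phase", "none"):
            raise ValueError("subsample must be 'parabolic', 'envelope', 'phase' or 'none'")
        if self.lsq_kernel < 3 or self.lsq_kernel % 2 == 0:
            raise ValueError("lsq_kernel must be an odd integer >= 3")

    @property
    def step_mm(self) -> float:
        return self.window_len_mm * (1.0 - self.window_overlap)


def support_half_width_mm(params: TrackingParams) -> float:
    """Axial half-width of the support of one strain estimate.

    A strain pixel is influenced by RF samples within half the correlation
    window beyond the outermost displacement windows of its least-squares
    kernel.  ROI masks erode by this margin so that each retained pixel's
    estimate is supported by a single tissue type.
    """
    return ((params.lsq_kernel - 1) * params.step_mm + params.window_len_mm) / 2.0


@dataclass
class DisplacementField:
    """Estimated axial displacement on the window-center grid.

    ``ncc`` stores the normalized magnitude of the analytic-signal
    cross-correlation at the matched lag (in [0, 1]).  Unlike the raw real
    NCC peak — which dips to cos(omega/2) whenever the true shift falls
    halfway between samples — this envelope coherence measures actual
    speckle decorrelation and is the quantity thresholded for quality.
    """

    u_hat_mm: np.ndarray       # (n_windows, n_lines)
    ncc: np.ndarray            # envelope correlation coefficient per window
    valid: np.ndarray          # boolean: finite estimate with usable peak
    grid_z_mm: np.ndarray      # window centers (strictly increasing)
    grid_x_mm: np.ndarray      # line positions
    sample_dz_mm: float
    params: TrackingParams


@dataclass
class Elastogram:
    """Axial normal strain on the window grid with a quality mask."""

    strain: np.ndarray         # compression positive
    quality_mask: np.ndarray   # boolean; masked-out pixels excluded downstream
    ncc: np.ndarray
    grid_z_mm: np.ndarray
    grid_x_mm: np.ndarray
    params: TrackingParams
    provenance: dict = None

    def __post_init__(self) -> None:
        if self.provenance is None:
            self.provenance = {}


def _parabolic_vertex(y_m: np.ndarray, y_0: np.ndarray, y_p: np.ndarray) -> np.ndarray:
    """Vertex offset of the parabola through three equidistant ordinates."""
    denom = y_m - 2.0 * y_0 + y_p
    with np.errstate(invalid="ignore", divide="ignore"):
        delta = 0.5 * (y_m - y_p) / denom
    return np.where((denom < -1e-12) & np.isfinite(delta), delta, 0.0)


def _subsample_offset(y_m, y_0, y_p, c_m, c_0, c_p, omega: float, mode: str) -> np.ndarray:
    """Subsample peak offset in [-0.5, 0.5] samples.

    ``y_*`` are real NCC ordinates at the integer peak and its neighbors,
    ``c_*`` the corresponding complex (analytic-signal) correlations and
    ``omega`` the carrier frequency in rad/sample.  Modes:

    - ``parabolic``: vertex of the parabola through the real NCC triplet —
      the textbook estimator; carries a periodic bias toward integer lags
      because the NCC peak is carrier-modulated.
    - ``envelope``: parabola on the log magnitude of the complex
      correlation. The correlation envelope of a Gaussian pulse is Gaussian,
      so the log-parabola vertex is exact for the noiseless PSF and free of
      carrier bias.
    - ``phase``: zero crossing of the complex correlation phase at the
      integer peak, offset = angle / omega; nearly carrier-exact, slightly
      envelope-biased for very broadband pulses.

    Exact integer matches (peak NCC ≈ 1) return 0 so pure integer-sample
    shifts are recovered exactly.
    """
    if mode == "none":
        return np.zeros_like(y_0)
    if mode == "envelope":
        with np.errstate(invalid="ignore", divide="ignore"):
            lm = np.log(np.abs(c_m))
            l0 = np.log(np.abs(c_0))
            lp = np.log(np.abs(c_p))
        ok = np.isfinite(lm) & np.isfinite(l0) & np.isfinite(lp)
        delta = np.where(ok, _parabolic_vertex(np.where(ok, lm, 0.0),
                                               np.where(ok, l0, 0.0),
                                               np.where(ok, lp, 0.0)), 0.0)
    elif mode == "phase":
        with np.errstate(invalid="ignore"):
            delta = -np.angle(c_0) / omega
        delta = np.where(np.isfinite(delta), delta, 0.0)
    else:
        delta = _parabolic_vertex(y_m, y_0, y_p)
    delta = np.where(y_0 >= _EXACT_PEAK, 0.0, delta)
    return np.clip(delta, -0.5, 0.5)


def estimate_displacement(pre: RFFrame, post: RFFrame,
                          params: TrackingParams | None = None) -> DisplacementField:
    """Track axial motion between an RF frame pair.

    Windows advance from the transducer into depth; when ``params.guided``
    the search for each window is centered (within ±guided_search_mm) on the
    integer lag of the shallower neighbor, falling back to the full
    ±search_mm range around zero for lines whose guided peak drops below the
    NCC threshold.  Returns displacement in mm, peak NCC, and a validity
    mask (all-zero windows get ncc = 0 and are invalid).
    """
    params = params or TrackingParams()
    if pre.samples.shape != post.samples.shape:
        raise ValueError("pre and post frames must have the same shape")
    if pre.config.fs_mhz != post.config.fs_mhz or pre.config.c_m_s != post.config.c_m_s:
        raise ValueError("pre and post frames must share acquisition parameters")
    a_s, b_s = np.asarray(pre.samples, float), np.asarray(post.samples, float)
    n_samp, n_lines = a_s.shape
    dz = pre.config.sample_dz_mm

    w = max(4, int(round(params.window_len_mm / dz)))
    if w > n_samp:
        raise ValueError("correlation window is longer than the frame")
    step = max(1, int(round(w * (1.0 - params.window_overlap))))
    l_full = max(1, int(round(params.search_mm / dz)))
    l_guided = max(1, int(round(params.guided_search_mm / dz)))

    starts = np.arange(0, n_samp - w + 1, step)
    n_win = starts.size
    centers_z = (starts + (w - 1) / 2.0) * dz

    pos_max = n_samp - w            # last valid post-window start
    post_sw = sliding_window_view(b_s, w, axis=0)       # (pos_max+1, n_lines, w)
    zero = np.zeros((1, n_lines))
    b_cs = np.vstack([zero, np.cumsum(b_s, axis=0)])
    b2_cs = np.vstack([zero, np.cumsum(b_s * b_s, axis=0)])
    lines = np.arange(n_lines)
    # analytic frames for the complex correlation (envelope/phase subsample);
    # both sides analytic so the conjugate-image ripple cancels and the
    # correlation magnitude is the smooth pulse envelope.
    a_hil = np.conj(hilbert(a_s, axis=0))
    b_hil = hilbert(b_s, axis=0)
    post_sw_a = sliding_window_view(b_hil, w, axis=0)
    ba_cs = np.vstack([zero, np.cumsum(np.abs(b_hil) ** 2, axis=0)])
    omega = 2.0 * np.pi * pre.config.f0_mhz / pre.config.fs_mhz   # rad/sample

    u_hat = np.zeros((n_win, n_lines))
    ncc_out = np.zeros((n_win, n_lines))
    valid = np.zeros((n_win, n_lines), bool)
    centers = np.zeros(n_lines, dtype=np.int64)     # guided lag per line

    def _ncc_rows(j: int, ctr: np.ndarray, half: int, row_sel: np.ndarray):
        """ZNCC (and complex correlation) of pre window j at ctr±half lags."""
        i0 = starts[j]
        a = a_s[i0:i0 + w, row_sel].T                  # (n_sel, w)
        ah = a_hil[i0:i0 + w, row_sel].T
        asum = a.sum(axis=1)
        var_a = (a * a).sum(axis=1) - asum * asum / w
        lags = np.arange(-half, half + 1)
        pos = i0 + ctr[row_sel, None] + lags[None, :]
        ok = (pos >= 0) & (pos <= pos_max)
        posc = np.clip(pos, 0, pos_max)
        wins = post_sw[posc, row_sel[:, None], :]      # (n_sel, n_lags, w)
        dot = np.einsum("lkw,lw->lk", wins, a)
        wins_a = post_sw_a[posc, row_sel[:, None], :]
        dotc = np.einsum("lkw,lw->lk", wins_a, ah)
        bsum = b_cs[posc + w, row_sel[:, None]] - b_cs[posc, row_sel[:, None]]
        var_b = (b2_cs[posc + w, row_sel[:, None]] - b2_cs[posc, row_sel[:, None]]
                 - bsum * bsum / w)
        cov = dot - asum[:, None] * bsum / w
        denom = np.sqrt(np.clip(var_a, 0.0, None)[:, None] * np.clip(var_b, 0.0, None))
        with np.errstate(invalid="ignore", divide="ignore"):
            ncc = np.where(denom > 1e-12 * w, cov / denom, 0.0)
        ncc = np.clip(ncc, -1.0, 1.0)
        ncc[~ok] = -2.0
        dotc = np.where(ok, dotc, 0.0)
        # normalized magnitude of the analytic correlation ("coherence"):
        # insensitive to the subsample offset, used as the quality metric
        na = np.sqrt((np.abs(ah) ** 2).sum(axis=1))
        nb = np.sqrt(np.clip(ba_cs[posc + w, row_sel[:, None]]
                             - ba_cs[posc, row_sel[:, None]], 0.0, None))
        with np.errstate(invalid="ignore", divide="ignore"):
            coh = np.where(na[:, None] * nb > 1e-12 * w,
                           np.abs(dotc) / (na[:, None] * nb), 0.0)
        coh = np.where(ok, np.clip(coh, 0.0, 1.0), 0.0)
        return ncc, lags, dotc, coh

    def _peak_info(ncc: np.ndarray, lags: np.ndarray, dotc: np.ndarray,
                   coh: np.ndarray, ctr_sel: np.ndarray):
        """Per-row peak, its quality (coherence), lag and refinement neighbors."""
        rows = np.arange(ncc.shape[0])
        best = np.argmax(ncc, axis=1)
        peak = ncc[rows, best]
        quality = coh[rows, best]
        lag_int = ctr_sel + lags[best]
        idx_m = np.clip(best - 1, 0, ncc.shape[1] - 1)
        idx_p = np.clip(best + 1, 0, ncc.shape[1] - 1)
        y_m = ncc[rows, idx_m]
        y_p = ncc[rows, idx_p]
        c_m = dotc[rows, idx_m]
        c_0 = dotc[rows, best]
        c_p = dotc[rows, idx_p]
        interior = (best > 0) & (best < ncc.shape[1] - 1) & (y_m > -1.5) & (y_p > -1.5)
        return peak, quality, lag_int, (y_m, y_p, c_m, c_0, c_p), interior

    zeros_ctr = np.zeros(n_lines, dtype=np.int64)
    for j in range(n_win):
        use_guided = params.guided and j > 0
        half = l_guided if use_guided else l_full
        ctr = centers if use_guided else zeros_ctr
        ncc, lags, dotc, coh = _ncc_rows(j, ctr, half, lines)
        peak, quality, lag_int, nb, interior = _peak_info(ncc, lags, dotc, coh, ctr)
        y_m, y_p, c_m, c_0, c_p = nb

        if use_guided:
            # lines that lost the peak re-search the full range around zero
            lost = np.flatnonzero(quality < params.ncc_threshold)
            if lost.size:
                ncc_f, lags_f, dotc_f, coh_f = _ncc_rows(j, zeros_ctr, l_full, lost)
                pk_f, q_f, lag_f, nb_f, int_f = _peak_info(ncc_f, lags_f, dotc_f,
                                                           coh_f, zeros_ctr[lost])
                better = pk_f > peak[lost]
                sel = lost[better]
                peak[sel] = pk_f[better]
                quality[sel] = q_f[better]
                lag_int[sel] = lag_f[better]
                for dst, src in zip((y_m, y_p, c_m, c_0, c_p), nb_f):
                    dst[sel] = src[better]
                interior[sel] = int_f[better]

        delta = np.where(
            interior,
            _subsample_offset(y_m, peak, y_p, c_m, c_0, c_p, omega, params.subsample),
            0.0,
        )

        usable = peak > -1.5
        u_hat[j] = (lag_int + delta) * dz
        ncc_out[j] = np.where(usable, quality, 0.0)
        valid[j] = usable & (quality > 0.0)
        u_hat[j][~usable] = np.nan
        # guide the next (deeper) window where the peak is trustworthy
        upd = quality >= params.ncc_threshold
        centers[upd] = lag_int[upd]

    return DisplacementField(
        u_hat_mm=u_hat, ncc=ncc_out, valid=valid,
        grid_z_mm=centers_z, grid_x_mm=np.asarray(pre.x_mm, float),
        sample_dz_mm=dz, params=params,
    )


def estimate_strain(disp: DisplacementField,
                    params: TrackingParams | None = None) -> Elastogram:
    """Least-squares strain estimator on a displacement field.

    Per line, the axial normal strain at each window center is the negated
    slope of the OLS fit of displacement versus depth over ``lsq_kernel``
    consecutive window centers.  Pixels whose kernel includes any window
    below the NCC quality threshold (or outside the grid) are masked.
    """
    params = params or disp.params
    k = params.lsq_kernel
    if disp.u_hat_mm.shape[0] < k:
        raise ValueError("fewer displacement windows than the least-squares kernel")
    h = float(np.mean(np.diff(disp.grid_z_mm)))
    t = (np.arange(k) - (k - 1) / 2.0) * h
    weights = t / (t @ t)

    good = disp.valid & (disp.ncc >= params.ncc_threshold) & np.isfinite(disp.u_hat_mm)
    u = np.where(good, disp.u_hat_mm, 0.0)
    slope = correlate1d(u, weights, axis=0, mode="constant", cval=0.0)
    support = correlate1d(good.astype(float), np.ones(k), axis=0, mode="constant", cval=0.0)
    mask = support > k - 0.5                      # every kernel point valid
    strain = np.where(mask, -slope, 0.0)
    if params.median_filter:
        strain = median_filter(strain, size=3, mode="nearest")
    return Elastogram(
        strain=strain, quality_mask=mask, ncc=disp.ncc,
        grid_z_mm=disp.grid_z_mm, grid_x_mm=disp.grid_x_mm, params=params,
    )


def run_elastography(pre: RFFrame, post: RFFrame,
                     params: TrackingParams | None = None) -> Elastogram:
    """Frame pair → elastogram (displacement tracking + strain estimation)."""
    params = params or TrackingParams()
    disp = estimate_displacement(pre, post, params)
    elast = estimate_strain(disp, params)
    elast.provenance = {
        "pre": dict(pre.provenance), "post": dict(post.provenance),
        "n_windows": int(disp.u_hat_mm.shape[0]),
    }
    return elast
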