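"""Gait-cycle spectral analysis: epoching, PSDs, time-warped ERSPs,
spectral-PCA muscle correction, and aperiodic/periodic parameterization.

Conventions: power is expressed in dB as 10*log10(power) throughout; PSDs
use Welch's method with 2-s Hann windows and 50% overlap; the warped gait
grid has 200 points spanning one stride with anchor positions (RFS, LFO,
LFS, RFO, next RFS) fixed by the median event latencies; Morlet wavelet
cycle counts follow the [3, 0.8] expansion convention, i.e. cycles(f) =
3 * (f / f_min)^(1 - 0.8).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.optimize import curve_fit

from .core import DEFAULT_BANDS

logger = logging.getLogger(__name__)

__all__ = [
    "EpochSet", "epoch_walking", "reject_epoch_outliers", "compute_psd",
    "subject_normalize_psd", "morlet_tf", "timewarp_gait", "ersp_vs_rest",
    "SpcaModel", "fit_spca", "apply_spca", "SpectralFit",
    "fit_spectral_model", "band_power", "normalize_ersp",
    "peak_to_peak_fluctuation", "delta_ersp",
]

ANCHOR_NAMES = ("RFS", "LFO", "LFS", "RFO", "RFS_next")


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------

@dataclass
class EpochSet:
    """Fixed-length epochs anchored 1 s before each right foot strike.

    data is (n_epochs, n_components, n_samples); latencies holds each
    epoch's LFO, LFS, RFO and next-RFS times in seconds after the anchor
    RFS (which sits at ``pre_s`` from epoch start)."""

    data: np.ndarray
    fs: float
    pre_s: float
    latencies: np.ndarray  # (n_epochs, 4)
    condition: str = ""

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def window_s(self) -> float:
        return self.data.shape[2] / self.fs


def epoch_walking(activations: np.ndarray, fs: float, events,
                  mask: np.ndarray | None = None, pre_s: float = 1.0,
                  post_s: float = 4.25, condition: str = "") -> EpochSet:
    """One 5.25-s epoch per right foot strike (1 s before to 4.25 s after).

    Epochs whose window extends past the recording, or that overlap masked
    samples, are dropped; the per-epoch gait event latencies are recorded
    for time-warping and outlier rejection."""
    n = activations.shape[1]
    n_win = int(round((pre_s + post_s) * fs))
    datas, lats = [], []
    if len(events):
        rel = events.latencies_relative_to_rfs()
        for t0, lat in zip(events.column("t_RFS"), rel):
            i0 = int(round((t0 - pre_s) * fs))
            if i0 < 0 or i0 + n_win > n:
                continue
            if mask is not None and mask[i0:i0 + n_win].any():
                continue
            datas.append(activations[:, i0:i0 + n_win])
            lats.append(lat)
    if not datas:
        return EpochSet(np.empty((0, activations.shape[0], n_win)), fs,
                        pre_s, np.empty((0, 4)), condition)
    return EpochSet(np.stack(datas), fs, pre_s, np.asarray(lats), condition)


def reject_epoch_outliers(es: EpochSet, k_sd: float = 3.0) -> EpochSet:
    """Drop epochs with any gait-event latency > k_sd SDs from its mean."""
    if len(es) < 5:
        raise ValueError("need at least 5 epochs")
    lat = es.latencies
    sd = lat.std(axis=0, ddof=1)
    sd[sd == 0] = np.inf
    z = np.abs(lat - lat.mean(axis=0)) / sd
    keep = (z <= k_sd).all(axis=1)
    return EpochSet(es.data[keep], es.fs, es.pre_s, lat[keep], es.condition)


# ---------------------------------------------------------------------------
# PSD
# ---------------------------------------------------------------------------

def compute_psd(activations: np.ndarray, fs: float, window_s: float = 2.0):
    """Welch PSD per component, in dB (10*log10 of uV^2/Hz).

    Returns (freqs, psd_db) with psd_db shaped (n_components, n_freqs)."""
    nper = int(round(window_s * fs))
    if activations.shape[-1] < 5 * nper:
        logger.warning("short segment for PSD (%.1f s)",
                       activations.shape[-1] / fs)
    freqs, psd = signal.welch(activations, fs=fs, nperseg=nper, axis=-1)
    return freqs, 10 * np.log10(np.maximum(psd, 1e-30))


def subject_normalize_psd(psd_by_condition: dict) -> dict:
    """Subtract the across-condition mean log spectrum per component."""
    stack = np.stack(list(psd_by_condition.values()))
    mean = stack.mean(axis=0)
    return {c: p - mean for c, p in psd_by_condition.items()}


# ---------------------------------------------------------------------------
# time-frequency and warping
# ---------------------------------------------------------------------------

def morlet_cycles(freqs: np.ndarray, cycles=(3.0, 0.8)) -> np.ndarray:
    """Cycle counts under the [c0, factor] expansion convention.

    c0 cycles at the lowest analyzed frequency; the count grows as
    (f/f_min)^(1 - factor), so factor 1 keeps cycles constant and factor 0
    keeps the window length constant."""
    c0, fact = cycles
    freqs = np.asarray(freqs, dtype=float)
    return c0 * (freqs / freqs.min()) ** (1.0 - fact)


def morlet_tf(es: EpochSet, freqs: np.ndarray, cycles=(3.0, 0.8),
              decim: int = 4):
    """Per-epoch Morlet time-frequency power in dB.

    Returns (tf_db, times) with tf_db shaped (n_epochs, n_components,
    n_freqs, n_times); frequencies whose wavelet exceeds the epoch length
    are dropped with a warning.  Time axis is decimated by ``decim``."""
    from mne.time_frequency import tfr_array_morlet

    freqs = np.asarray(freqs, dtype=float)
    n_cycles = morlet_cycles(freqs, cycles)
    wav_len = n_cycles / freqs  # seconds (approximate support)
    ok = wav_len * 5 <= es.window_s  # mne uses ~5 sigma_t support
    if not ok.all():
        logger.warning("dropping %d frequencies with over-long wavelets",
                       (~ok).sum())
        freqs, n_cycles = freqs[ok], n_cycles[ok]
    power = tfr_array_morlet(es.data, sfreq=es.fs, freqs=freqs,
                             n_cycles=n_cycles, output="power",
                             decim=decim, zero_mean=True)
    times = np.arange(power.shape[-1]) * decim / es.fs
    return 10 * np.log10(np.maximum(power, 1e-30)), times, freqs


def timewarp_gait(tf_db: np.ndarray, times: np.ndarray, es: EpochSet,
                  n_grid: int = 200):
    """Warp each epoch's stride onto a common 0-100% gait grid.

    The template anchors are the median event latencies across epochs; a
    piecewise-linear time remapping sends each epoch's five anchors (RFS,
    LFO, LFS, RFO, next RFS) to the template's fixed grid positions and
    the time-frequency values are linearly interpolated at the remapped
    times.  Epochs with non-monotone latencies are dropped with a log
    entry.

    Returns (warped (n_kept, n_comp, n_freq, n_grid), grid_pct,
    anchor_pct dict)."""
    lat = es.latencies
    monotone = (np.diff(np.column_stack([np.zeros(len(lat)), lat]), axis=1)
                > 0).all(axis=1)
    if not monotone.all():
        logger.warning("dropping %d epochs with non-monotone latencies",
                       (~monotone).sum())
    lat = lat[monotone]
    tf_db = tf_db[monotone]
    template = np.concatenate([[0.0], np.median(lat, axis=0)])
    stride = template[-1]
    anchor_pct = {n: 100 * t / stride for n, t in zip(ANCHOR_NAMES, template)}
    grid_pct = np.linspace(0, 100, n_grid)
    template_pct = np.array([anchor_pct[n] for n in ANCHOR_NAMES])
    out = np.empty(tf_db.shape[:3] + (n_grid,))
    for e in range(tf_db.shape[0]):
        anchors_e = np.concatenate([[0.0], lat[e]])
        # map grid % -> epoch time (s after RFS), piecewise linear on anchors
        t_warp = np.interp(grid_pct, template_pct, anchors_e)
        # fractional sampling of the tf time axis (times are after epoch start)
        pos = np.interp(t_warp + es.pre_s, times, np.arange(len(times)))
        i0 = np.clip(np.floor(pos).astype(int), 0, len(times) - 2)
        w = pos - i0
        out[e] = tf_db[e][..., i0] * (1 - w) + tf_db[e][..., i0 + 1] * w
    return out, grid_pct, anchor_pct


def ersp_vs_rest(walk_db: np.ndarray, rest_spectrum_db: np.ndarray) -> np.ndarray:
    """dB difference of a walking map (freq on axis -2) from the rest mean."""
    return walk_db - np.asarray(rest_spectrum_db)[..., :, None]


# ---------------------------------------------------------------------------
# spectral PCA muscle correction
# ---------------------------------------------------------------------------

@dataclass
class SpcaModel:
    """PCA over component-by-frequency spectral observations.

    PC1 (the largest-eigenvalue direction) captures the broadband
    muscle-artifact profile (low below ~20 Hz, rising above) and is the
    default removal set.  The same model is applied to every condition of
    a subject."""

    mean: np.ndarray          # (n_features,)
    eigenvectors: np.ndarray  # (n_pc, n_features), orthonormal rows
    eigenvalues: np.ndarray
    removed: tuple = (1,)     # 1-based PC indices to remove

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(x) - self.mean) @ self.eigenvectors.T


def fit_spca(observations: np.ndarray, removed=(1,)) -> SpcaModel:
    """Fit the spectral PCA on condition-averaged observations.

    observations is (n_components, n_features) — e.g. PSD change vs rest
    per frequency, or flattened ERSP-change features.  Eigenvalues are
    sorted descending; fewer observations than features simply yields a
    reduced-rank basis."""
    x = np.atleast_2d(np.asarray(observations, dtype=float))
    mean = x.mean(axis=0)
    xc = x - mean
    if x.shape[0] < x.shape[1]:
        logger.info("sPCA fit on reduced rank (%d observations, %d features)",
                    x.shape[0], x.shape[1])
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    eigvals = s**2 / max(x.shape[0] - 1, 1)
    return SpcaModel(mean=mean, eigenvectors=vt, eigenvalues=eigvals,
                     removed=tuple(removed))


def apply_spca(model: SpcaModel, x: np.ndarray,
               rest_psd: np.ndarray | None = None) -> np.ndarray:
    """Project, zero the removed PCs, back-project.

    For PSD observations, pass the resting-condition PSD to add back so
    downstream aperiodic fitting sees absolute spectra.  An empty removal
    set is the identity transform."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != model.mean.shape[0]:
        raise ValueError("feature grid does not match the fitted model")
    scores = model.transform(x)
    for pc in model.removed:
        scores[:, pc - 1] = 0.0
    out = scores @ model.eigenvectors + model.mean
    if model.removed == ():
        # exact identity, including any component outside the eigenbasis span
        out = x.copy()
    if rest_psd is not None:
        out = out + np.atleast_2d(rest_psd)
    return out


# ---------------------------------------------------------------------------
# aperiodic / periodic parameterization
# ---------------------------------------------------------------------------

@dataclass
class SpectralFit:
    """Aperiodic 10^offset * f^-exponent model plus <= 2 Gaussian peaks.

    Peaks are Gaussians in log10-power over linear frequency:
    (center_hz, height_log10, width_hz) with width the Gaussian SD."""

    offset: float
    exponent: float
    peaks: list = field(default_factory=list)
    fit_range: tuple = (3.0, 40.0)
    r_squared: float = np.nan
    converged: bool = True

    def aperiodic_log10(self, freqs: np.ndarray) -> np.ndarray:
        return self.offset - self.exponent * np.log10(freqs)

    def model_log10(self, freqs: np.ndarray) -> np.ndarray:
        out = self.aperiodic_log10(freqs)
        for c, h, w in self.peaks:
            out = out + h * np.exp(-((freqs - c) ** 2) / (2 * w**2))
        return out


def _gauss(f, c, h, w):
    return h * np.exp(-((f - c) ** 2) / (2 * w**2))


def fit_spectral_model(
    freqs: np.ndarray,
    psd: np.ndarray,
    fit_range=(3.0, 40.0),
    peak_width_limits=(1.0, 8.0),
    min_peak_height: float = 0.05,
    max_n_peaks: int = 2,
):
    """Separate a PSD into an aperiodic 1/f component and Gaussian peaks.

    The aperiodic component is fit robustly in log-log space (refit on the
    points hugging the spectral floor so oscillatory peaks do not bias the
    slope); up to ``max_n_peaks`` Gaussian peaks are then extracted
    iteratively from the flattened spectrum, subject to the width limits
    and the minimum height (log10 units).  Returns
    ``(SpectralFit, flattened_db)`` where flattened_db is
    10*(log10 PSD - log10 aperiodic) over the full input grid.

    On peak-fit failure an aperiodic-only fit is returned with
    ``converged=False``.
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    sel = (freqs >= fit_range[0]) & (freqs <= fit_range[1])
    f = freqs[sel]
    if not (psd[sel] > 0).all():
        raise ValueError("PSD must be strictly positive over the fit range")
    logp = np.log10(psd[sel])

    def ap_fit(fv, lv):
        slope, icpt = np.polyfit(np.log10(fv), lv, 1)
        return icpt, -slope

    offset, exponent = ap_fit(f, logp)
    resid = logp - (offset - exponent * np.log10(f))
    floor = resid <= np.percentile(resid, 40)  # points hugging the 1/f floor
    if floor.sum() >= 3:
        offset, exponent = ap_fit(f[floor], logp[floor])

    flat = logp - (offset - exponent * np.log10(f))
    peaks = []
    work = flat.copy()
    converged = True
    lo_w, hi_w = peak_width_limits
    for _ in range(max_n_peaks):
        i = int(np.argmax(work))
        h0 = work[i]
        if h0 < max(min_peak_height, 1.0 * np.std(work)):
            break
        c0 = f[i]
        # half-height width guess
        above = work >= h0 / 2
        j0, j1 = i, i
        while j0 > 0 and above[j0 - 1]:
            j0 -= 1
        while j1 < len(f) - 1 and above[j1 + 1]:
            j1 += 1
        w0 = np.clip((f[j1] - f[j0]) / 2.355, lo_w, hi_w)
        try:
            popt, _ = curve_fit(
                _gauss, f, work, p0=[c0, h0, w0],
                bounds=([fit_range[0], 0.0, lo_w],
                        [fit_range[1], np.inf, hi_w]), maxfev=2000)
        except RuntimeError:
            converged = False
            break
        peaks.append(tuple(popt))
        work = work - _gauss(f, *popt)
    # joint refinement of all peaks against the flattened spectrum
    if peaks:
        def multi(fv, *params):
            out = np.zeros_like(fv)
            for k in range(len(params) // 3):
                out = out + _gauss(fv, *params[3 * k:3 * k + 3])
            return out

        p0 = np.concatenate(peaks)
        lb = [fit_range[0], 0.0, lo_w] * len(peaks)
        ub = [fit_range[1], np.inf, hi_w] * len(peaks)
        try:
            popt, _ = curve_fit(multi, f, flat, p0=p0, bounds=(lb, ub),
                                maxfev=4000)
            peaks = [tuple(popt[3 * k:3 * k + 3]) for k in range(len(peaks))]
        except RuntimeError:
            converged = False
        # final aperiodic refit with peaks removed
        peakless = logp - multi(f, *np.concatenate(peaks))
        offset, exponent = ap_fit(f, peakless)
        flat = logp - (offset - exponent * np.log10(f))
    peaks = [p for p in peaks if p[1] >= min_peak_height]
    peaks.sort(key=lambda p: -p[1])

    model = offset - exponent * np.log10(f)
    for c, h, w in peaks:
        model = model + _gauss(f, c, h, w)
    ss_res = float(np.sum((logp - model) ** 2))
    ss_tot = float(np.sum((logp - logp.mean()) ** 2))
    fit = SpectralFit(offset=offset, exponent=exponent, peaks=peaks,
                      fit_range=tuple(fit_range),
                      r_squared=1 - ss_res / max(ss_tot, 1e-30),
                      converged=converged)
    with np.errstate(divide="ignore"):
        full_ap = fit.aperiodic_log10(np.maximum(freqs, 1e-12))
    flattened_db = 10 * (np.log10(np.maximum(psd, 1e-30)) - full_ap)
    return fit, flattened_db


def band_power(flattened_db: np.ndarray, freqs: np.ndarray, band) -> float:
    """Mean flattened log-power (dB) over the band's frequency bins.

    Bands are half-open [lo, hi) so adjacent bands partition the axis."""
    lo, hi = band
    sel = (freqs >= lo) & (freqs < hi)
    if not sel.any():
        raise ValueError(f"no frequency bins inside band {band}")
    return float(np.mean(np.asarray(flattened_db)[..., sel], axis=-1))


# ---------------------------------------------------------------------------
# ERSP normalization and summary
# ---------------------------------------------------------------------------

def normalize_ersp(maps_by_condition: dict, mode: str = "within-condition"):
    """Normalize gait-warped maps (freq x gait%) to a baseline.

    within-condition: subtract each condition's own gait-cycle mean per
    frequency (isolates intra-stride fluctuations; gait-axis mean becomes
    0 dB at every frequency).  common-baseline: subtract the mean across
    all conditions (preserves between-condition power offsets)."""
    if mode == "within-condition":
        return {c: m - m.mean(axis=-1, keepdims=True)
                for c, m in maps_by_condition.items()}
    if mode == "common-baseline":
        base = np.mean([m.mean(axis=-1, keepdims=True)
                        for m in maps_by_condition.values()], axis=0)
        return {c: m - base for c, m in maps_by_condition.items()}
    raise ValueError(f"unknown normalization mode {mode!r}")


def peak_to_peak_fluctuation(ersp: np.ndarray, freqs: np.ndarray, band) -> float:
    """Peak-to-peak range of the band-average gait-cycle power curve (dB).

    The curve is the unsmoothed mean over the band's frequency rows at each
    gait percentage; the returned value is its max minus min."""
    lo, hi = band
    sel = (freqs >= lo) & (freqs < hi)
    curve = np.asarray(ersp)[..., sel, :].mean(axis=-2)
    return float(curve.max(axis=-1) - curve.min(axis=-1))


def delta_ersp(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Elementwise ERSP difference (uneven - Flat, or young - old deltas)."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("ERSP grids do not match")
    return a - b
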