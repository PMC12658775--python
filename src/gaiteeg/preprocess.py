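"""EEG cleaning chain, ICA decomposition, component selection, clustering.

The chain follows the fixed order: 1 Hz high-pass -> 20 Hz EMG high-pass
-> line-noise regression (60/120 Hz) -> bad-channel rejection -> per-role
average reference -> reference-guided cleaning against the noise layer
(R^2 = 0.65) and the EMG references (R^2 = 0.4) -> bad-window masking ->
re-reference -> ICA.  Component retention requires a brain-likeness score
>= 0.5, a negative 2-40 Hz spectral slope, dipole residual variance < 15%,
and a dipole inside the brain shell; retained components are clustered on
dipole location with robust k-means (k = 11 by default).

Every rejection decision (channel, window, component) is appended to a log
with the criterion value that triggered it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.cluster import KMeans
from sklearn.decomposition import FastICA
from sklearn.metrics import (calinski_harabasz_score, davies_bouldin_score,
                             silhouette_score)

from .config import PipelineConfig
from .core import Recording
from .forward import HeadModel, fit_dipole

logger = logging.getLogger(__name__)

__all__ = [
    "highpass", "emg_highpass", "remove_line_noise", "reject_bad_channels",
    "average_reference", "reference_guided_clean", "reject_bad_windows",
    "run_ica", "score_components", "cluster_components", "clean_recording",
    "ComponentSet", "ClusterModel", "cluster_count_report",
]


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def _fir_highpass_taps(fs: float, cutoff: float) -> np.ndarray:
    """Linear-phase Hamming-window FIR whose -6 dB point is cutoff/2.

    The transition band spans roughly (0, cutoff); a windowed-sinc design's
    -6 dB point sits at its nominal cutoff frequency, so the filter is
    designed at cutoff/2 with transition width = cutoff.
    """
    if cutoff >= fs / 2:
        raise ValueError("cutoff must be below Nyquist")
    trans = cutoff
    ntaps = int(np.ceil(3.3 * fs / trans)) | 1  # odd
    return signal.firwin(ntaps, cutoff / 2, fs=fs, pass_zero=False,
                         window="hamming")


def _apply_zero_phase(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Single-pass linear-phase FIR with group-delay compensation."""
    delay = (len(taps) - 1) // 2
    pad = len(taps)
    xp = np.pad(x, [(0, 0), (pad, pad)], mode="reflect")
    y = signal.fftconvolve(xp, taps[None, :], mode="same", axes=1)
    return y[:, pad:pad + x.shape[1]]


def highpass(rec: Recording, cutoff: float = 1.0,
             roles=("scalp", "noise", "emg")) -> Recording:
    """Zero-phase FIR high-pass (-6 dB at half the cutoff) on the given roles."""
    taps = _fir_highpass_taps(rec.fs, cutoff)
    out = rec.copy()
    mask = np.isin(rec.roles, roles)
    out.data[mask] = _apply_zero_phase(rec.data[mask], taps)
    return out


def emg_highpass(rec: Recording, cutoff: float = 20.0) -> Recording:
    """20 Hz high-pass restricted to EMG-role channels."""
    return highpass(rec, cutoff, roles=("emg",))


def remove_line_noise(rec: Recording, freqs=(60.0, 120.0),
                      window_s: float = 4.0) -> Recording:
    """Sliding-window sinusoidal regression of line components.

    Per 4-s Hann window (50% overlap), sine/cosine pairs at each line
    frequency are fit by least squares and subtracted; overlapping fitted
    segments are recombined by weighted overlap-add so broadband content is
    untouched.
    """
    for f0 in freqs:
        if f0 >= rec.fs / 2:
            raise ValueError("line frequency above Nyquist")
    out = rec.copy()
    n = rec.n_samples
    w = int(round(window_s * rec.fs))
    hop = w // 2
    win = np.hanning(w)
    fitted = np.zeros_like(rec.data)
    weight = np.zeros(n)
    starts = list(range(0, max(n - w, 0) + 1, hop))
    if not starts or starts[-1] + w < n:
        starts.append(max(n - w, 0))
    t_full = np.arange(n) / rec.fs
    for s in starts:
        t = t_full[s:s + w]
        cols = []
        for f0 in freqs:
            cols += [np.sin(2 * np.pi * f0 * t), np.cos(2 * np.pi * f0 * t)]
        d = np.stack(cols, axis=1)
        coef, *_ = np.linalg.lstsq(d, rec.data[:, s:s + w].T, rcond=None)
        seg = (d @ coef).T
        wl = win[: seg.shape[1]]
        fitted[:, s:s + w] += seg * wl
        weight[s:s + w] += wl
    weight[weight == 0] = 1.0
    out.data = rec.data - fitted / weight
    return out


# ---------------------------------------------------------------------------
# channel / reference handling
# ---------------------------------------------------------------------------

def reject_bad_channels(rec: Recording, k_sd: float = 3.0, log: list | None = None):
    """Drop channels whose robust amplitude deviates > k_sd SDs from the
    role mean.  The channel statistic is the median absolute deviation of
    the channel signal (a robust amplitude measure).  Raises if more than
    half of a role's channels would be dropped."""
    keep = np.ones(rec.n_channels, dtype=bool)
    rejected = []
    for role in ("scalp", "noise"):
        idx = np.flatnonzero(rec.pick(role))
        if len(idx) == 0:
            continue
        if len(idx) < 4:
            logger.warning("only %d %s channels; skipping %s bad-channel "
                           "screening", len(idx), role, role)
            continue
        mad = np.median(np.abs(rec.data[idx]
                               - np.median(rec.data[idx], axis=1, keepdims=True)),
                        axis=1)
        mu, sd = mad.mean(), mad.std(ddof=1)
        if sd == 0:
            continue
        z = (mad - mu) / sd
        bad = np.abs(z) > k_sd
        if bad.sum() > 0.5 * len(idx):
            raise RuntimeError(f"more than half of {role} channels bad")
        for i, zi in zip(idx[bad], z[bad]):
            rejected.append(rec.ch_names[i])
            keep[i] = False
            if log is not None:
                log.append({"stage": "bad_channel", "item": rec.ch_names[i],
                            "criterion": "amplitude_z", "value": float(zi)})
    out = Recording(
        data=rec.data[keep], fs=rec.fs, roles=rec.roles[keep],
        positions=rec.positions[keep],
        ch_names=[c for c, k in zip(rec.ch_names, keep) if k],
        subject=rec.subject, group=rec.group, condition=rec.condition,
        trial=rec.trial, speed=rec.speed)
    return out, rejected


def average_reference(rec: Recording) -> Recording:
    """Per-role average reference: the role mean is removed at each sample."""
    out = rec.copy()
    for role in ("scalp", "noise", "emg"):
        idx = rec.pick(role)
        if idx.sum() >= 2:
            out.data[idx] -= out.data[idx].mean(axis=0, keepdims=True)
    return out


def _cca(x: np.ndarray, y: np.ndarray, reg: float = 1e-9):
    """Canonical correlation via whitened SVD; returns (rhos, x_weights)."""
    x = x - x.mean(axis=1, keepdims=True)
    y = y - y.mean(axis=1, keepdims=True)
    n = x.shape[1]
    cxx = x @ x.T / n
    cyy = y @ y.T / n
    cxy = x @ y.T / n
    cxx += reg * np.trace(cxx) / len(cxx) * np.eye(len(cxx))
    cyy += reg * np.trace(cyy) / len(cyy) * np.eye(len(cyy))
    lx = np.linalg.cholesky(cxx)
    ly = np.linalg.cholesky(cyy)
    m = np.linalg.solve(lx, cxy) @ np.linalg.inv(ly).T
    u, s, _ = np.linalg.svd(m, full_matrices=False)
    ax = np.linalg.solve(lx.T, u)  # x-side canonical weights (columns)
    return np.clip(s, 0, 1), ax


def reference_guided_clean(rec: Recording, refs: str, r2: float,
                           window_s: float = 4.0, log: list | None = None) -> Recording:
    """Project out scalp subspaces highly correlated with reference channels.

    Per 4-s moving window (50% overlap, Hann overlap-add), the canonical
    correlations between the scalp channels and the reference-role channels
    are computed; canonical scalp components with squared correlation >= r2
    are regressed out of the scalp data within the window.
    """
    scalp_idx = np.flatnonzero(rec.pick("scalp"))
    ref_idx = np.flatnonzero(rec.pick(refs))
    if len(ref_idx) == 0:
        raise ValueError(f"no channels with role {refs!r}")
    out = rec.copy()
    n = rec.n_samples
    w = int(round(window_s * rec.fs))
    if w >= n:
        raise ValueError("window must be shorter than the recording")
    hop = w // 2
    win = np.hanning(w)
    acc = np.zeros((len(scalp_idx), n))
    weight = np.zeros(n)
    starts = list(range(0, n - w + 1, hop))
    if starts[-1] + w < n:
        starts.append(n - w)
    n_removed = 0
    for s in starts:
        xw = rec.data[scalp_idx, s:s + w]
        yw = rec.data[ref_idx, s:s + w]
        try:
            rho, ax = _cca(xw, yw)
        except np.linalg.LinAlgError:
            logger.warning("rank-deficient window at %.1f s skipped", s / rec.fs)
            cleaned = xw
        else:
            sel = rho**2 >= r2
            if sel.any():
                u = ax[:, sel].T @ (xw - xw.mean(axis=1, keepdims=True))
                coef, *_ = np.linalg.lstsq(u.T, xw.T, rcond=None)
                cleaned = xw - (u.T @ coef).T
                n_removed += int(sel.sum())
            else:
                cleaned = xw
        wl = win[: cleaned.shape[1]]
        acc[:, s:s + w] += cleaned * wl
        weight[s:s + w] += wl
    weight[weight == 0] = 1.0
    out.data[scalp_idx] = acc / weight
    if log is not None:
        log.append({"stage": f"reference_clean_{refs}", "item": "windows",
                    "criterion": "components_removed", "value": n_removed})
    return out


def reject_bad_windows(rec: Recording, chan_crit: float = 0.7,
                       win_crit: float = 0.4, amp_z_tol: float = 10.0,
                       window_s: float = 1.0, log: list | None = None):
    """Mask windows in which too many channels deviate from calibration.

    A channel is flagged within a window when its correlation with a
    cross-channel regression reconstruction falls below chan_crit, or when
    its window RMS exceeds a robust z of amp_z_tol (the upper amplitude
    tolerance; no lower bound is applied).  Windows with more than
    win_crit of channels flagged are excluded from downstream epoching.

    Returns (rec, bad_sample_mask).  Warns above 40% masked, fails above 70%.
    """
    scalp = rec.data[rec.pick("scalp")]
    nch, n = scalp.shape
    w = int(round(window_s * rec.fs))
    n_win = n // w
    # calibration: predict each channel from the others (ridge).  Windows
    # already failing the robust amplitude criterion are excluded from the
    # calibration covariance so that a short high-amplitude artifact cannot
    # corrupt the calibration it is meant to be judged against.
    segc = scalp[:, : n_win * w].reshape(nch, n_win, w)
    rms0 = np.sqrt((segc**2).mean(axis=2))
    med0 = np.median(rms0, axis=1, keepdims=True)
    mad0 = np.median(np.abs(rms0 - med0), axis=1, keepdims=True) * 1.4826 + 1e-30
    calib_ok = ~((rms0 - med0) / mad0 > amp_z_tol).any(axis=0)
    if not calib_ok.any():
        calib_ok = np.ones(n_win, dtype=bool)
    c = np.cov(segc[:, calib_ok].reshape(nch, -1))
    c += 1e-6 * np.trace(c) / nch * np.eye(nch)
    recon = np.empty_like(scalp)
    for i in range(nch):
        others = np.delete(np.arange(nch), i)
        wgt = np.linalg.solve(c[np.ix_(others, others)], c[others, i])
        recon[i] = wgt @ scalp[others]
    seg = scalp[:, : n_win * w].reshape(nch, n_win, w)
    rseg = recon[:, : n_win * w].reshape(nch, n_win, w)
    seg_c = seg - seg.mean(axis=2, keepdims=True)
    rseg_c = rseg - rseg.mean(axis=2, keepdims=True)
    num = (seg_c * rseg_c).sum(axis=2)
    den = np.sqrt((seg_c**2).sum(axis=2) * (rseg_c**2).sum(axis=2)) + 1e-30
    corr = num / den
    rms = np.sqrt((seg**2).mean(axis=2))
    med = np.median(rms, axis=1, keepdims=True)
    mad = np.median(np.abs(rms - med), axis=1, keepdims=True) * 1.4826 + 1e-30
    ampz = (rms - med) / mad
    bad_cw = (corr < chan_crit) | (ampz > amp_z_tol)
    bad_win = bad_cw.mean(axis=0) > win_crit
    mask = np.zeros(n, dtype=bool)
    for i in np.flatnonzero(bad_win):
        mask[i * w:(i + 1) * w] = True
        if log is not None:
            log.append({"stage": "bad_window", "item": f"win{i}",
                        "criterion": "bad_channel_fraction",
                        "value": float(bad_cw[:, i].mean())})
    frac = mask.mean()
    if frac > 0.7:
        raise RuntimeError(f"{frac:.0%} of data masked; recording unusable")
    if frac > 0.4:
        logger.warning("%.0f%% of data masked", 100 * frac)
    return rec, mask


def clean_recording(rec: Recording, cfg: PipelineConfig | None = None,
                    log: list | None = None):
    """Full cleaning chain in the fixed order; returns (rec, mask, rejected)."""
    cfg = cfg or PipelineConfig()
    log = log if log is not None else []
    rec = highpass(rec, cfg.highpass_hz)
    rec = emg_highpass(rec, cfg.emg_highpass_hz)
    rec = remove_line_noise(rec, cfg.line_freqs, cfg.clean_window_s)
    rec, rejected = reject_bad_channels(rec, cfg.bad_channel_k_sd, log)
    rec = average_reference(rec)
    rec = reference_guided_clean(rec, "noise", cfg.noise_r2, cfg.clean_window_s, log)
    rec = reference_guided_clean(rec, "emg", cfg.emg_r2, cfg.clean_window_s, log)
    rec, mask = reject_bad_windows(rec, cfg.chan_crit, cfg.win_crit,
                                   cfg.amp_z_tol, log=log)
    rec = average_reference(rec)  # re-reference after cleaning
    return rec, mask, rejected


# ---------------------------------------------------------------------------
# ICA and component selection
# ---------------------------------------------------------------------------

@dataclass
class ComponentSet:
    """ICA decomposition plus per-component selection metadata."""

    unmixing: np.ndarray          # (k, n_scalp)
    mixing: np.ndarray            # (n_scalp, k)
    activations: np.ndarray       # (k, n_samples) on the full recording
    ch_names: list
    positions: np.ndarray         # scalp electrode positions (mm)
    fs: float
    scores: pd.DataFrame | None = None
    subject: str = ""
    group: str = ""

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]

    def retained_indices(self) -> np.ndarray:
        if self.scores is None:
            return np.arange(self.n_components)
        return np.flatnonzero(self.scores["retained"].to_numpy())


def run_ica(rec: Recording, n_components: int | None = None,
            mask: np.ndarray | None = None, seed: int = 97,
            strict: bool = False) -> ComponentSet:
    """FastICA on the scalp channels (masked samples excluded from fitting).

    Deterministic given the seed.  Activations are computed on the full
    continuous data so downstream epoching can still exclude masked spans.
    Raises on non-convergence when strict, else logs the diagnostics.
    """
    scalp_idx = np.flatnonzero(rec.pick("scalp"))
    x = rec.data[scalp_idx]
    fit_x = x[:, ~mask] if mask is not None else x
    rank = np.linalg.matrix_rank(np.cov(fit_x))
    k = min(n_components or rank, rank)
    ica = FastICA(n_components=k, random_state=seed, max_iter=1000, tol=1e-4,
                  whiten="unit-variance")
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ica.fit(fit_x.T)
    if ica.n_iter_ >= 1000:
        msg = f"ICA did not converge ({ica.n_iter_} iterations, tol 1e-4)"
        if strict:
            raise RuntimeError(msg)
        logger.warning(msg)
    unmixing = ica.components_
    mixing = np.linalg.pinv(unmixing)
    acts = unmixing @ (x - ica.mean_[:, None])
    return ComponentSet(unmixing=unmixing, mixing=mixing, activations=acts,
                        ch_names=[rec.ch_names[i] for i in scalp_idx],
                        positions=rec.positions[scalp_idx], fs=rec.fs,
                        subject=rec.subject, group=rec.group)


def _psd_slope(freqs, psd, lo, hi):
    sel = (freqs >= lo) & (freqs <= hi) & (psd > 0)
    return float(np.polyfit(np.log10(freqs[sel]), 10 * np.log10(psd[sel]), 1)[0])


def score_components(cs: ComponentSet, cfg: PipelineConfig | None = None,
                     head: HeadModel | None = None,
                     log: list | None = None) -> ComponentSet:
    """Score and flag components for retention.

    brain_score averages three transparent subscores: dipolarity of the
    scalp map (1 - residual variance), steepness of the negative spectral
    slope, and the low fraction of 20-45 Hz power.  Retention requires all
    four criteria: score >= 0.5, negative 2-40 Hz slope, dipole residual
    variance < 15%, dipole inside the brain shell.
    """
    cfg = cfg or PipelineConfig()
    head = head or HeadModel()
    rows = []
    nper = int(min(4 * cs.fs, cs.activations.shape[1]))
    for i in range(cs.n_components):
        freqs, psd = signal.welch(cs.activations[i], fs=cs.fs, nperseg=nper)
        slope = _psd_slope(freqs, psd, *cfg.psd_slope_range)
        loc, mom, rv = fit_dipole(cs.mixing[:, i], cs.positions, head)
        radius = float(np.linalg.norm(loc))
        band = (freqs >= 2) & (freqs <= 45)
        hf = (freqs >= 20) & (freqs <= 45)
        hf_frac = float(psd[hf].sum() / max(psd[band].sum(), 1e-30))
        s_dip = float(np.clip(1 - rv, 0, 1))
        s_slope = float(np.clip(-slope / 20.0, 0, 1))
        s_hf = float(np.clip(1 - hf_frac, 0, 1))
        score = (s_dip + s_slope + s_hf) / 3
        retained = (score >= cfg.brain_score_min and slope < 0
                    and rv < cfg.dipole_rv_max and radius < head.brain_radius)
        rows.append({"component": i, "brain_score": score,
                     "psd_slope_2_40": slope, "dipole_x": loc[0],
                     "dipole_y": loc[1], "dipole_z": loc[2],
                     "dipole_rv": rv, "dipole_radius": radius,
                     "retained": retained})
        if log is not None and not retained:
            log.append({"stage": "component", "item": f"IC{i}",
                        "criterion": "retention", "value": score})
    cs.scores = pd.DataFrame(rows)
    return cs


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterModel:
    k: int
    centroids: np.ndarray
    assignments: pd.DataFrame  # component table + cluster, outlier, kept flags
    retained_clusters: list = field(default_factory=list)


def cluster_components(table: pd.DataFrame, k: int = 11, seed: int = 11,
                       outlier_sd: float = 3.0, n_init: int = 50,
                       min_group_fraction: float = 0.5) -> ClusterModel:
    """Cluster retained components across subjects by dipole location.

    k-means with many restarts; components farther than ``outlier_sd`` SDs
    (of the within-cluster centroid-distance distribution) from every
    centroid are flagged outliers; clusters containing fewer than half of
    each age group's subjects are dropped; within a (subject, cluster)
    pair only the component with the highest brain_score is kept.

    table needs columns: subject, group, brain_score, dipole_x/y/z.
    """
    locs = table[["dipole_x", "dipole_y", "dipole_z"]].to_numpy()
    if len(locs) < k:
        raise ValueError(f"need at least k={k} components, got {len(locs)}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(locs)
    out = table.copy().reset_index(drop=True)
    out["cluster"] = km.labels_
    dists = np.linalg.norm(locs - km.cluster_centers_[km.labels_], axis=1)
    sd = dists.std(ddof=1) if len(dists) > 1 else 0.0
    all_d = np.linalg.norm(locs[:, None, :] - km.cluster_centers_[None], axis=2)
    # "outlier_sd SDs away" is judged on the within-cluster centroid-distance
    # distribution: farther than its mean + outlier_sd * SD from every centroid
    thresh = dists.mean() + outlier_sd * sd
    out["outlier"] = (all_d.min(axis=1) > thresh) if sd > 0 else False

    # one component per (subject, cluster): keep max brain_score
    out["kept"] = ~out["outlier"]
    for (_, _), grp in out[out["kept"]].groupby(["subject", "cluster"]):
        if len(grp) > 1:
            losers = grp.index[grp["brain_score"] != grp["brain_score"].max()]
            # ties keep the first
            best = grp["brain_score"].idxmax()
            out.loc[[i for i in grp.index if i != best], "kept"] = False

    retained_clusters = []
    group_sizes = table.groupby("group")["subject"].nunique().to_dict()
    for c in range(k):
        members = out[(out["cluster"] == c) & out["kept"]]
        ok = True
        for g, size in group_sizes.items():
            n_g = members[members["group"] == g]["subject"].nunique()
            if n_g < np.ceil(min_group_fraction * size):
                ok = False
        if ok:
            retained_clusters.append(c)
    return ClusterModel(k=k, centroids=km.cluster_centers_, assignments=out,
                        retained_clusters=retained_clusters)


def cluster_count_report(locations: np.ndarray, k_range=range(9, 15),
                         seed: int = 11) -> pd.DataFrame:
    """Diagnostic comparison of cluster counts (silhouette / CH / DB)."""
    rows = []
    for k in k_range:
        if k >= len(locations):
            continue
        km = KMeans(n_clusters=k, n_init=20, random_state=seed).fit(locations)
        rows.append({
            "k": k,
            "silhouette": silhouette_score(locations, km.labels_),
            "calinski_harabasz": calinski_harabasz_score(locations, km.labels_),
            "davies_bouldin": davies_bouldin_score(locations, km.labels_),
        })
    return pd.DataFrame(rows)
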