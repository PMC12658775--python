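"""Epoching, Morlet/warping, sPCA, spectral parameterization, summaries."""

import numpy as np
import pytest

from gaiteeg.config import GaitSpec
from gaiteeg.spectral import (EpochSet, apply_spca, band_power, compute_psd,
                              epoch_walking, fit_spca, fit_spectral_model,
                              morlet_cycles, morlet_tf, normalize_ersp,
                              peak_to_peak_fluctuation,
                              reject_epoch_outliers, timewarp_gait)
from gaiteeg.synthgen import simulate_gait

FS = 500.0


def _events(duration=30.0, cv=0.04, seed=3):
    ev, _, _ = simulate_gait(GaitSpec(stride_cv=cv), duration, seed, fs=FS)
    return ev


def test_epoch_window_is_5_25_s():
    ev = _events()
    acts = np.random.default_rng(0).normal(size=(2, int(30 * FS)))
    es = epoch_walking(acts, FS, ev)
    assert es.window_s == pytest.approx(5.25)
    assert es.data.shape[2] == round(5.25 * FS)
    assert es.pre_s == 1.0
    assert len(es) > 0 and es.latencies.shape == (len(es), 4)


def test_epochs_skip_masked_and_edges():
    ev = _events()
    n = int(30 * FS)
    acts = np.zeros((1, n))
    mask = np.zeros(n, dtype=bool)
    es_all = epoch_walking(acts, FS, ev)
    t0 = ev.column("t_RFS")[2]
    mask[int(t0 * FS): int(t0 * FS) + 10] = True  # poison stride 2
    es = epoch_walking(acts, FS, ev, mask=mask)
    # every epoch whose full 5.25-s window touches the masked samples is
    # dropped: stride 2 itself and stride 1 (whose window extends 4.25 s
    # past its own strike, across stride 2's strike)
    assert len(es) == len(es_all) - 2


def test_epoch_latency_outlier_rejection():
    # enough epochs that a single wild value can exceed 3 SD of the sample
    # (with n epochs the largest attainable z is (n-1)/sqrt(n))
    data = np.zeros((30, 1, 10))
    lat = np.tile([0.12, 0.5, 0.62, 1.0], (30, 1)) * 1.2
    lat[3, 3] = 5.0  # wildly long stride
    es = EpochSet(data, FS, 1.0, lat)
    out = reject_epoch_outliers(es, 3.0)
    assert len(out) == 29
    with pytest.raises(ValueError):
        reject_epoch_outliers(EpochSet(data[:3], FS, 1.0, lat[:3]))


def test_morlet_cycles_convention():
    freqs = np.array([3.0, 12.0, 30.0])
    c = morlet_cycles(freqs, (3.0, 0.8))
    assert c[0] == pytest.approx(3.0)  # lowest frequency keeps 3 cycles
    assert np.all(np.diff(c) > 0)  # grows with frequency
    assert c[1] == pytest.approx(3.0 * (12.0 / 3.0) ** 0.2)


def test_morlet_detects_oscillation_band():
    rng = np.random.default_rng(1)
    n_win = round(5.25 * FS)
    t = np.arange(n_win) / FS
    data = (np.sin(2 * np.pi * 12.0 * t)[None, None, :]
            + 0.1 * rng.normal(size=(6, 1, n_win)))
    es = EpochSet(data, FS, 1.0, np.tile([0.12, 0.5, 0.62, 1.0], (6, 1)))
    tf, times, freqs = morlet_tf(es, np.arange(3.0, 41.0, 1.0))
    mean = tf.mean(axis=(0, 1, 3))
    assert freqs[np.argmax(mean)] == pytest.approx(12.0, abs=1.0)


def test_timewarp_aligns_jittered_modulation():
    """Stride-locked power modulation smeared by stride-duration jitter
    realigns on the warped grid: the warped band curve peaks where the
    modulation does, at every stride duration."""
    rng = np.random.default_rng(2)
    n_ep, n_f = 12, 5
    times = np.arange(0, 5.25, 1 / 50)  # decimated tf time axis
    lat = []
    maps = []
    for e in range(n_ep):
        stride = 1.2 * rng.uniform(0.85, 1.15)
        lat.append(np.array([0.12, 0.5, 0.62, 1.0]) * stride)
        phase = np.clip((times - 1.0) / stride, 0, 1)  # 0..1 over stride
        curve = np.cos(2 * np.pi * phase)  # max at 0% and 100%
        maps.append(np.tile(curve, (1, n_f, 1)))  # (comp, freq, time)
    es = EpochSet(np.zeros((n_ep, 1, 10)), FS, 1.0, np.array(lat))
    warped, grid, anchors = timewarp_gait(np.stack(maps), times, es,
                                          n_grid=100)
    assert warped.shape == (n_ep, 1, n_f, 100)
    curve = warped.mean(axis=(0, 1, 2))
    # cosine in gait phase: extremes at the stride endpoints, trough at 50%
    assert curve[0] > 0.9 and curve[-1] > 0.9
    assert curve[len(curve) // 2] < -0.9
    assert anchors["RFS"] == 0.0 and anchors["RFS_next"] == 100.0


def test_spca_identity_and_pc1_removal(rng):
    obs = rng.normal(size=(8, 50))
    ident = fit_spca(obs, removed=())
    assert np.allclose(apply_spca(ident, obs), obs)
    m = fit_spca(obs, removed=(1,))
    out = apply_spca(m, obs)
    # no variance left along PC1, other PCs untouched
    scores = m.transform(out)
    assert np.allclose(scores[:, 0], 0.0, atol=1e-10)
    assert np.allclose(m.transform(obs)[:, 1:], scores[:, 1:], atol=1e-10)
    # rest-PSD add-back is a plain addition
    rest = rng.normal(size=50)
    assert np.allclose(apply_spca(m, obs[0], rest_psd=rest),
                       apply_spca(m, obs[0]) + rest)
    with pytest.raises(ValueError):
        apply_spca(m, rng.normal(size=(2, 49)))


def test_spca_same_weights_across_conditions(rng):
    """One model fit once serves every condition (identical eigenbasis)."""
    obs = rng.normal(size=(6, 30))
    m = fit_spca(obs)
    a = apply_spca(m, obs + 1.0)
    b = apply_spca(m, obs + 1.0)
    assert np.array_equal(a, b)


def test_fit_spectral_model_construction_recovery():
    freqs = np.arange(0.5, 125.1, 0.5)
    true_log = 1.1 - 1.6 * np.log10(freqs) \
        + 0.7 * np.exp(-((freqs - 11.0) ** 2) / (2 * 1.8 ** 2)) \
        + 0.3 * np.exp(-((freqs - 22.0) ** 2) / (2 * 3.0 ** 2))
    fit, flat = fit_spectral_model(freqs, 10.0 ** true_log)
    assert abs(fit.exponent - 1.6) < 0.05
    assert abs(fit.offset - 1.1) < 0.1
    assert len(fit.peaks) == 2
    centers = sorted(p[0] for p in fit.peaks)
    assert abs(centers[0] - 11.0) < 0.3 and abs(centers[1] - 22.0) < 0.7
    # flattened spectrum reproduces the peak height in dB at 11 Hz
    i11 = np.argmin(np.abs(freqs - 11.0))
    assert abs(flat[i11] - 10 * 0.7) < 1.0


def test_fit_spectral_model_aperiodic_only():
    freqs = np.arange(1.0, 60.0, 0.5)
    fit, flat = fit_spectral_model(freqs, 10.0 ** (0.9 - 1.2 *
                                                   np.log10(freqs)))
    assert fit.peaks == []
    assert abs(fit.exponent - 1.2) < 0.02
    sel = (freqs >= 3) & (freqs <= 40)
    assert np.abs(flat[sel]).max() < 0.2
    with pytest.raises(ValueError):
        fit_spectral_model(freqs, np.zeros_like(freqs))


def test_band_power_half_open_edges():
    freqs = np.arange(0.0, 30.0, 1.0)
    flat = freqs.copy()  # value equals its frequency
    assert band_power(flat, freqs, (8.0, 13.0)) == pytest.approx(
        np.mean([8, 9, 10, 11, 12]))
    with pytest.raises(ValueError):
        band_power(flat, freqs, (40.0, 45.0))


def test_normalize_modes():
    maps = {"Flat": np.ones((3, 10)) * 2.0, "High": np.ones((3, 10)) * 6.0}
    within = normalize_ersp(maps, "within-condition")
    assert np.allclose(within["Flat"], 0.0) and np.allclose(within["High"],
                                                            0.0)
    common = normalize_ersp(maps, "common-baseline")
    assert np.allclose(common["Flat"], -2.0)
    assert np.allclose(common["High"], 2.0)
    with pytest.raises(ValueError):
        normalize_ersp(maps, "bogus")


def test_peak_to_peak_known_curve():
    freqs = np.arange(3.0, 41.0)
    g = np.linspace(0, 100, 200)
    ersp = np.zeros((len(freqs), len(g)))
    beta = (freqs >= 13) & (freqs < 30)
    ersp[beta] = 1.5 * np.cos(2 * np.pi * g / 100)[None, :]
    # tolerance covers the 200-point gait-grid discretization of the cosine
    assert peak_to_peak_fluctuation(ersp, freqs, (13.0, 30.0)) == \
        pytest.approx(3.0, abs=1e-3)
    assert peak_to_peak_fluctuation(ersp, freqs, (4.0, 8.0)) == 0.0


def test_compute_psd_parseval_scale():
    rng = np.random.default_rng(4)
    x = rng.normal(0, 2.0, size=(1, int(60 * FS)))
    freqs, psd_db = compute_psd(x, FS, 2.0)
    total = np.trapezoid(10 ** (psd_db[0] / 10), freqs)
    assert total == pytest.approx(4.0, rel=0.1)  # variance of the signal
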