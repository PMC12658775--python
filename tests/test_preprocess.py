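"""Cleaning-chain oracles: filters, line noise, CCA, ICA, clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal

from gaiteeg.core import Recording
from gaiteeg.forward import scalp_montage
from gaiteeg.preprocess import (_fir_highpass_taps, average_reference,
                                clean_recording, cluster_components,
                                emg_highpass, highpass,
                                reference_guided_clean, reject_bad_channels,
                                reject_bad_windows, remove_line_noise,
                                run_ica, score_components)

FS = 500.0


def _rec(data, roles=None):
    n_ch = data.shape[0]
    roles = roles if roles is not None else np.array(["scalp"] * n_ch)
    pos = np.full((n_ch, 3), np.nan)
    n_scalp = int((roles == "scalp").sum())
    pos[: n_scalp] = scalp_montage(n_scalp)
    return Recording(data=data, fs=FS, roles=roles, positions=pos,
                     ch_names=[f"c{i}" for i in range(n_ch)])


def test_highpass_response_oracle():
    """-6 dB at half the cutoff, near-unity in the passband (zero-phase)."""
    taps = _fir_highpass_taps(FS, 1.0)
    w, h = signal.freqz(taps, worN=16384, fs=FS)
    gain_db = 20 * np.log10(np.maximum(np.abs(h), 1e-12))
    at = lambda f: gain_db[np.argmin(np.abs(w - f))]
    assert abs(at(0.5) - (-6.0)) < 0.6
    assert abs(at(1.0)) < 0.2
    assert abs(at(10.0)) < 0.05
    assert at(0.05) < -30


def test_highpass_zero_phase_no_lag():
    t = np.arange(int(20 * FS)) / FS
    x = np.sin(2 * np.pi * 8.0 * t)
    rec = _rec(np.vstack([x, x]))
    out = highpass(rec, 1.0)
    mid = slice(int(5 * FS), int(15 * FS))
    lag = np.argmax(np.correlate(out.data[0][mid], x[mid], "full")) - (
        len(x[mid]) - 1)
    assert lag == 0
    assert np.allclose(out.data[0][mid], x[mid], atol=1e-2)


def test_emg_highpass_targets_emg_role_only():
    rng = np.random.default_rng(0)
    data = rng.normal(size=(3, int(10 * FS)))
    roles = np.array(["scalp", "scalp", "emg"])
    rec = _rec(data, roles)
    out = emg_highpass(rec, 20.0)
    assert np.array_equal(out.data[0], data[0])  # scalp untouched
    f, p = signal.welch(out.data[2], fs=FS, nperseg=2048)
    f0, p0 = signal.welch(data[2], fs=FS, nperseg=2048)
    # the design puts -6 dB at half the cutoff, so judge the stopband well
    # below the 10-20 Hz transition
    low = (f > 1.5) & (f < 4)
    assert p[low].mean() < 0.01 * p0[low].mean()
    high = (f > 40) & (f < 200)
    assert p[high].mean() > 0.9 * p0[high].mean()


def test_line_noise_removed_signal_kept():
    rng = np.random.default_rng(1)
    t = np.arange(int(30 * FS)) / FS
    brain = np.sin(2 * np.pi * 10 * t)
    x = brain + 5 * np.sin(2 * np.pi * 60 * t + 0.7) + rng.normal(
        0, 0.5, len(t))
    rec = _rec(x[None, :].repeat(2, axis=0))
    out = remove_line_noise(rec, (60.0,))

    def power_at(sig, f0):
        f, p = signal.welch(sig, fs=FS, nperseg=4096)
        return p[np.argmin(np.abs(f - f0))]

    assert power_at(out.data[0], 60.0) < 1e-3 * power_at(x, 60.0)
    assert power_at(out.data[0], 10.0) > 0.9 * power_at(x, 10.0)


def test_bad_channel_rejection():
    rng = np.random.default_rng(2)
    data = rng.normal(0, 10, size=(12, int(10 * FS)))
    data[3] *= 40.0  # huge-amplitude channel
    rec = _rec(data)
    log = []
    out, rejected = reject_bad_channels(rec, 3.0, log)
    assert "c3" in rejected
    assert out.n_channels == 11
    assert any(e["item"] == "c3" for e in log)


def test_average_reference_per_role():
    rng = np.random.default_rng(3)
    data = rng.normal(size=(4, 1000)) + 5.0
    roles = np.array(["scalp", "scalp", "scalp", "emg"])
    out = average_reference(_rec(data, roles))
    assert np.allclose(out.data[:3].mean(axis=0), 0.0, atol=1e-12)
    assert np.array_equal(out.data[3], data[3])  # emg not referenced


def test_reference_guided_clean_removes_shared_artifact():
    """An artifact present on scalp AND noise electrodes is removed; a
    cortical signal absent from the noise layer survives."""
    rng = np.random.default_rng(4)
    n = int(30 * FS)
    t = np.arange(n) / FS
    artifact = rng.normal(size=n)
    brain = np.sin(2 * np.pi * 9.0 * t)
    scalp = np.vstack([brain + artifact + 0.1 * rng.normal(size=n)
                       for _ in range(4)])
    noise = np.vstack([artifact + 0.1 * rng.normal(size=n)
                       for _ in range(4)])
    roles = np.array(["scalp"] * 4 + ["noise"] * 4)
    rec = _rec(np.vstack([scalp, noise]), roles)
    out = reference_guided_clean(rec, "noise", r2=0.65)
    cleaned = out.data[0]
    # artifact power drops strongly, 9 Hz cortical peak survives
    corr = np.corrcoef(cleaned, artifact)[0, 1]
    assert abs(corr) < 0.35
    f, p = signal.welch(cleaned, fs=FS, nperseg=4096)
    assert p[np.argmin(np.abs(f - 9.0))] > 10 * np.median(p)


def test_reject_bad_windows_flags_burst():
    rng = np.random.default_rng(5)
    n = int(30 * FS)
    common = rng.normal(size=n)
    data = np.vstack([common + 0.3 * rng.normal(size=n) for _ in range(8)])
    burst = slice(int(12 * FS), int(13 * FS))
    data[:, burst] += rng.normal(0, 40, size=(8, burst.stop - burst.start))
    rec = _rec(data)
    out, mask = reject_bad_windows(rec)
    assert mask[burst].mean() > 0.9
    assert mask.mean() < 0.2


def test_run_ica_deterministic_and_unmixes(rng):
    """FastICA recovers an invertible unmixing of independent sources
    (Amari-style permutation/scale-invariant check)."""
    n = 20000
    s = np.vstack([rng.laplace(size=n), rng.uniform(-1, 1, size=n),
                   np.sign(np.sin(2 * np.pi * np.arange(n) / 700))])
    a = rng.normal(size=(6, 3))
    x = a @ s
    rec = _rec(x + 1e-6 * rng.normal(size=x.shape))
    cs1 = run_ica(rec, n_components=3, seed=7)
    cs2 = run_ica(rec, n_components=3, seed=7)
    assert np.allclose(cs1.unmixing, cs2.unmixing)
    # performance matrix ~ permutation of scaled identity
    perf = cs1.unmixing @ a
    perf = np.abs(perf) / np.abs(perf).max(axis=1, keepdims=True)
    amari = (perf.sum(axis=1) - 1).mean() + (
        perf / np.abs(perf).max(axis=0)).sum(axis=0).mean() - 1
    assert amari < 0.2


def test_score_components_separates_brain_from_noise(rng):
    """A dipolar 1/f component is retained; a white-noise component with a
    random scalp map is rejected."""
    from gaiteeg.forward import HeadModel, dipole_potential
    from gaiteeg.synthgen import _shaped_noise_bands
    from gaiteeg.config import SourceSpec
    from gaiteeg.core import DEFAULT_BANDS
    from gaiteeg.preprocess import ComponentSet

    n = int(60 * FS)
    montage = scalp_montage(24)
    topo = dipole_potential((-30.0, -15.0, 45.0), (0.2, 1.0, 0.4), montage,
                            HeadModel())
    topo /= np.abs(topo).max()
    src = SourceSpec(name="s", peaks=((10.0, 0.8, 2.0),))
    parts = _shaped_noise_bands(rng, n, FS, src, DEFAULT_BANDS)
    brain = np.sum(list(parts.values()), axis=0)
    white = rng.normal(size=n) * brain.std()
    mixing = np.column_stack([topo, rng.normal(size=len(montage))])
    acts = np.vstack([brain, white])
    cs = ComponentSet(unmixing=np.linalg.pinv(mixing), mixing=mixing,
                      activations=acts, ch_names=[f"c{i}" for i in
                                                  range(len(montage))],
                      positions=montage, fs=FS)
    cs = score_components(cs)
    sc = cs.scores
    assert bool(sc.loc[0, "retained"])
    assert not bool(sc.loc[1, "retained"])
    assert sc.loc[0, "brain_score"] > sc.loc[1, "brain_score"]
    assert sc.loc[0, "dipole_rv"] < 0.05


def test_cluster_components_blob_agreement(rng):
    """k-means assignment matches known blob labels with > 0.95 agreement."""
    centers = np.array([[-40, -20, 45], [40, -20, 45], [0, -60, 30]])
    rows = []
    labels = []
    for subj in range(8):
        for b, c in enumerate(centers):
            loc = c + rng.normal(0, 4, size=3)
            rows.append({"subject": f"s{subj:02d}",
                         "group": "young" if subj < 4 else "old",
                         "component": b, "brain_score": 0.8,
                         "dipole_x": loc[0], "dipole_y": loc[1],
                         "dipole_z": loc[2]})
            labels.append(b)
    table = pd.DataFrame(rows)
    cm = cluster_components(table, k=3, seed=1)
    assign = cm.assignments["cluster"].to_numpy()
    # best label permutation agreement
    from itertools import permutations
    best = max(np.mean(assign == np.array([p[l] for l in labels]))
               for p in permutations(range(3)))
    assert best > 0.95
    assert set(cm.retained_clusters) == set(np.unique(assign))


def test_clean_recording_full_chain(tiny_dataset, pipe_cfg):
    rec = tiny_dataset.recordings[1]  # a walking trial
    log = []
    out, mask, rejected = clean_recording(rec, pipe_cfg, log)
    assert out.n_samples == rec.n_samples
    assert mask.dtype == bool and mask.shape == (rec.n_samples,)
    # 60 Hz line power on scalp channels drops by > 20 dB
    s0 = rec.data[rec.pick("scalp")][0]
    i0 = list(out.ch_names).index(rec.ch_names[0]) if rec.ch_names[0] in \
        out.ch_names else 0
    s1 = out.data[out.pick("scalp")][i0]
    f, p0 = signal.welch(s0, fs=rec.fs, nperseg=4096)
    _, p1 = signal.welch(s1, fs=rec.fs, nperseg=4096)
    i60 = np.argmin(np.abs(f - 60.0))
    assert 10 * np.log10(p1[i60] / p0[i60]) < -20
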