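"""Generator properties: determinism, gait statistics, injected spectra."""

import numpy as np
import pytest
from scipy import signal

from gaiteeg.config import GaitSpec, SimConfig, SourceSpec
from gaiteeg.core import DEFAULT_BANDS
from gaiteeg.gait_behavior import detect_gait_events
from gaiteeg.synthgen import (generate_dataset, make_scenario,
                              scenario_band_power_table, simulate_gait,
                              simulate_recording, sinusoid_modulation)


def test_simulate_gait_deterministic():
    spec = GaitSpec()
    a = simulate_gait(spec, 30.0, seed=7)
    b = simulate_gait(spec, 30.0, seed=7)
    assert np.allclose(a[0].column("t_RFS"), b[0].column("t_RFS"))
    assert np.allclose(a[1]["left"].samples, b[1]["left"].samples)
    c = simulate_gait(spec, 30.0, seed=8)
    assert not np.allclose(a[0].column("t_RFS")[:5], c[0].column("t_RFS")[:5])


def test_simulate_gait_zero_cv_constant_strides():
    spec = GaitSpec(stride_cv=0.0)
    ev, _, _ = simulate_gait(spec, 30.0, seed=1)
    assert np.allclose(ev.stride_durations(), spec.stride_mean)


def test_force_crossings_match_events():
    """Threshold detection on the simulated forces recovers the ground-truth
    event times to within one sample."""
    spec = GaitSpec()
    fs = 500.0
    ev, forces, _ = simulate_gait(spec, 60.0, seed=5, fs=fs)
    det = detect_gait_events(forces["left"], forces["right"], 20.0)
    assert len(det) >= len(ev) - 2  # edge strides may be dropped
    # align on RFS and compare all five event columns
    t_true = ev.column("t_RFS")
    t_det = det.column("t_RFS")
    common = [(i, j) for i, t in enumerate(t_true)
              for j, u in enumerate(t_det) if abs(t - u) < 0.05]
    assert len(common) >= len(det) - 1
    for col in ("t_RFS", "t_LFO", "t_LFS", "t_RFO", "t_RFS_next"):
        for i, j in common:
            assert abs(ev.column(col)[i] - det.column(col)[j]) <= 1.01 / fs


def test_stride_cv_matches_target():
    spec = GaitSpec(stride_cv=0.06)
    ev, _, _ = simulate_gait(spec, 600.0, seed=3)
    cv = ev.stride_durations().std(ddof=1) / ev.stride_durations().mean()
    assert abs(cv - 0.06) < 0.01


def test_recording_deterministic_and_shapes():
    cfg = SimConfig(n_scalp=8, n_emg=2, trial_duration=5.0, fs=500.0)
    src = [SourceSpec(name="s", location_mm=(0, -40, 40))]
    gait, _, _ = simulate_gait(GaitSpec(), 5.0, seed=2)
    a = simulate_recording(src, gait, cfg, "Flat", "young", seed=9)
    b = simulate_recording(src, gait, cfg, "Flat", "young", seed=9)
    assert np.array_equal(a.data, b.data)
    assert a.n_channels == cfg.n_scalp + cfg.n_noise + cfg.n_emg
    assert a.n_samples == int(cfg.trial_duration * cfg.fs)
    with pytest.raises(ValueError):
        simulate_recording(src, gait, cfg, "Uphill", "young", seed=9)


def test_injected_aperiodic_exponent_recovered():
    cfg = SimConfig(n_scalp=8, n_emg=2, trial_duration=60.0)
    src = SourceSpec(name="s", aperiodic_offset=1.2, aperiodic_exponent=1.4,
                     peaks=())
    rec, truth = simulate_recording([src], None, cfg, "rest", "young",
                                    seed=4, return_truth=True)
    x = truth["sources"][0]
    f, p = signal.welch(x, fs=cfg.fs, nperseg=int(4 * cfg.fs))
    sel = (f >= 3) & (f <= 40)
    slope = np.polyfit(np.log10(f[sel]), np.log10(p[sel]), 1)[0]
    assert abs(-slope - 1.4) < 0.1


def test_injected_condition_shift_recovered_in_band_power():
    """A -2 dB alpha shift between conditions appears as a -2 dB Welch
    band-power ratio on the source signal."""
    cfg = SimConfig(n_scalp=8, n_emg=2, trial_duration=120.0)
    src = SourceSpec(name="s", peaks=((10.0, 0.6, 1.5),),
                     condition_shift={("alpha", "High"): -2.0})
    gait, _, _ = simulate_gait(GaitSpec(), 120.0, seed=11)
    out = {}
    for cond in ("Flat", "High"):
        _, truth = simulate_recording([src], gait, cfg, cond, "young",
                                      seed=13, return_truth=True)
        f, p = signal.welch(truth["sources"][0], fs=cfg.fs,
                            nperseg=int(2 * cfg.fs))
        sel = (f >= 8) & (f < 13)
        out[cond] = 10 * np.log10(np.trapezoid(p[sel], f[sel]))
    assert abs((out["High"] - out["Flat"]) - (-2.0)) < 0.5


def test_sinusoid_modulation_properties():
    f = sinusoid_modulation(3.0, cycles_per_stride=2)
    ph = np.linspace(0, 100, 400, endpoint=False)
    vals = f(ph)
    assert abs(vals.mean()) < 1e-12
    assert abs((vals.max() - vals.min()) - 3.0) < 1e-9


def test_scenarios_and_dataset_layout():
    null = make_scenario("null")
    paper = make_scenario("paper-like")
    assert all(v == 0.0 for v in null.band_effects.values())
    assert any(v != 0.0 for v in paper.band_effects.values())
    cfg = SimConfig(n_young=1, n_old=1, n_scalp=8, n_emg=2,
                    trial_duration=8.0, n_walking_trials=1,
                    conditions=("rest", "Flat"), seed=5)
    ds = generate_dataset(cfg, "null")
    # per subject: 1 rest + 1 walking trial
    assert len(ds.recordings) == 2 * 2
    assert len(ds.walking_keys()) == 2
    assert set(ds.subjects["group"]) == {"young", "old"}
    ds2 = generate_dataset(cfg, "null")
    assert np.array_equal(ds.recordings[0].data, ds2.recordings[0].data)


def test_scenario_band_power_table_effects():
    tab = scenario_band_power_table("paper-like", 30, 30, seed=2,
                                    noise_sd=0.05, intercept_sd=0.0)
    sub = tab[(tab.cluster == "parietal") & (tab.band == "alpha")]
    young = sub[sub.group == "young"].groupby("condition")["value"].mean()
    old = sub[sub.group == "old"].groupby("condition")["value"].mean()
    # young show a steep High-vs-Flat alpha reduction, old a shallow one
    assert young["High"] - young["Flat"] < -1.5
    assert old["High"] - old["Flat"] > -0.5
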