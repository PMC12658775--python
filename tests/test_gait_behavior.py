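"""Gait-event detection oracles and behavioral summary properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from gaiteeg.core import ForceTrace
from gaiteeg.gait_behavior import (behavior_table, coefficient_of_variation,
                                   detect_gait_events, remove_outliers,
                                   sacral_excursion)
from gaiteeg.config import GaitSpec
from gaiteeg.synthgen import simulate_gait


def _oracle_crossings(x, fs, threshold):
    """Independent linear-scan crossing oracle (first sample at/past)."""
    ups, downs = [], []
    for i in range(1, len(x)):
        if x[i] >= threshold and x[i - 1] < threshold:
            ups.append(i / fs)
        elif x[i] < threshold and x[i - 1] >= threshold:
            downs.append(i / fs)
    return np.array(ups), np.array(downs)


def test_detection_matches_linear_scan_oracle():
    """On clean simulated forces (no chatter) the assembled event times must
    equal what a naive linear scan over both feet produces."""
    ev, forces, _ = simulate_gait(GaitSpec(), 40.0, seed=21)
    fs = forces["right"].fs
    r_up, r_down = _oracle_crossings(forces["right"].samples, fs, 20.0)
    l_up, l_down = _oracle_crossings(forces["left"].samples, fs, 20.0)
    det = detect_gait_events(forces["left"], forces["right"], 20.0)
    # every detected RFS/RFO/LFS/LFO equals an oracle crossing exactly
    for col, pool in (("t_RFS", r_up), ("t_RFO", r_down),
                      ("t_LFS", l_up), ("t_LFO", l_down)):
        for t in det.column(col):
            assert np.min(np.abs(pool - t)) < 1e-12


def test_debounce_suppresses_chatter():
    fs = 500.0
    t = np.arange(int(4 * fs)) / fs
    x = np.where((t > 1.0) & (t < 3.0), 100.0, 0.0)
    # 4 ms dropout inside the stance: must be ignored at 50 ms debounce
    x[(t > 2.0) & (t < 2.004)] = 0.0
    tr = ForceTrace(x, fs, "right")
    from gaiteeg.gait_behavior import _threshold_crossings
    ups, downs = _threshold_crossings(tr, 20.0, 0.05)
    assert len(ups) == 1 and len(downs) == 1


def test_detect_input_validation():
    tr = ForceTrace(np.zeros(100), 100.0, "left")
    short = ForceTrace(np.zeros(50), 100.0, "right")
    with pytest.raises(ValueError):
        detect_gait_events(tr, short)
    with pytest.raises(ValueError):
        detect_gait_events(tr, tr, threshold=0.0)
    assert len(detect_gait_events(tr, tr)) == 0  # no crossings -> empty


def test_remove_outliers_frozen_cases():
    assert np.array_equal(remove_outliers([5.0, 5.0, 5.0, 5.0]),
                          [5.0, 5.0, 5.0, 5.0])  # zero variance unchanged
    vals = [1.0, 1.02, 0.98, 1.01, 0.99, 1.03, 0.97, 1.0, 1.01, 100.0]
    out = remove_outliers(vals, 2.5)
    assert 100.0 not in out and len(out) == 9
    # single pass only: after removing 100, 1.03 would NOT be re-tested
    with pytest.raises(ValueError):
        remove_outliers([1.0])


def test_cov_frozen_value():
    assert np.isclose(coefficient_of_variation([1.0, 2.0, 3.0]), 0.5)
    with pytest.raises(ValueError):
        coefficient_of_variation([-1.0, 1.0])  # zero mean


@settings(max_examples=50, deadline=None)
@given(hst.lists(hst.floats(0.5, 2.0), min_size=3, max_size=40),
       hst.floats(0.1, 10.0))
def test_cov_scale_invariant(values, scale):
    v = np.asarray(values)
    if v.std(ddof=1) == 0 or v.mean() == 0:
        return
    assert np.isclose(coefficient_of_variation(v),
                      coefficient_of_variation(v * scale), rtol=1e-9)


def test_sacral_excursion_sinusoid_oracle():
    """A per-stride sinusoid of amplitude A has peak-to-peak excursion 2A."""
    fs = 500.0
    ev, _, _ = simulate_gait(GaitSpec(stride_cv=0.0), 20.0, seed=2, fs=fs)
    t = np.arange(int(20.0 * fs)) / fs
    amp = 12.5
    trace = amp * np.sin(2 * np.pi * t / 1.2)
    exc = sacral_excursion(trace, fs, ev)
    assert len(exc) == len(ev)
    assert np.allclose(exc, 2 * amp, rtol=5e-3)


def test_behavior_table_pools_and_excludes():
    ev, forces, sac = simulate_gait(GaitSpec(stride_cv=0.05), 60.0, seed=9)
    trial = {"subject": "y00", "group": "young", "condition": "Flat",
             "speed": 1.0, "events": ev, "sacrum": sac, "fs": 500.0}
    tab = behavior_table([trial, dict(trial)])  # two trials pooled
    assert set(tab["metric"]) == {"step_duration_cov", "sacral_ap_cov",
                                  "sacral_ml_cov"}
    row = tab[tab.metric == "step_duration_cov"].iloc[0]
    assert row["n_strides_used"] == 2 * len(ev)
    assert 0.0 < row["value"] < 0.2

    # a trial with < min_strides strides is excluded entirely
    ev2, _, sac2 = simulate_gait(GaitSpec(), 5.0, seed=9)
    short = dict(trial, condition="High", events=ev2, sacrum=sac2)
    tab2 = behavior_table([short], min_strides=5)
    assert len(tab2) == 0 or (tab2["condition"] != "High").all()
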