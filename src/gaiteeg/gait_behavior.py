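"""Gait event detection from insole forces and behavioral variability.

Foot strikes and foot offs are threshold crossings of the vertical ground
reaction force (20 N by default, with a 50 ms debounce against chatter);
strides are anchored at right foot strikes.  Variability measures are
coefficients of variation of step durations and of per-stride sacral
excursions, after a single per-trial +/-2.5 SD outlier pass.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import ForceTrace, GaitEventTable

logger = logging.getLogger(__name__)

__all__ = [
    "detect_gait_events",
    "remove_outliers",
    "coefficient_of_variation",
    "sacral_excursion",
    "behavior_table",
]


def _threshold_crossings(trace: ForceTrace, threshold: float, debounce_s: float):
    """Upward/downward crossing times (first sample at/past the threshold)."""
    x = trace.samples
    above = x >= threshold
    changes = np.flatnonzero(np.diff(above.astype(np.int8)))
    min_gap = int(round(debounce_s * trace.fs))
    # Chatter shows up as excursions (state runs between consecutive
    # crossings) shorter than the debounce window; both bounding edges of
    # such an excursion are spurious and must be dropped together.
    kept: list[int] = []
    i = 0
    while i < len(changes):
        if i + 1 < len(changes) and changes[i + 1] - changes[i] < min_gap:
            i += 2
            continue
        kept.append(changes[i])
        i += 1
    ups, downs = [], []
    for idx in kept:
        t = (idx + 1) / trace.fs
        if above[idx + 1]:
            ups.append(t)
        else:
            downs.append(t)
    return np.asarray(ups), np.asarray(downs)


def detect_gait_events(
    left: ForceTrace,
    right: ForceTrace,
    threshold: float = 20.0,
    debounce_s: float = 0.05,
) -> GaitEventTable:
    """Assemble strides (RFS, LFO, LFS, RFO, next RFS) from force crossings.

    Strides missing any interior event or with out-of-order events are
    dropped, as are incomplete leading/trailing strides.  No crossings at
    all yields an empty table.
    """
    if len(left.samples) != len(right.samples) or left.fs != right.fs:
        raise ValueError("left/right traces must share duration and rate")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    r_up, r_down = _threshold_crossings(right, threshold, debounce_s)
    l_up, l_down = _threshold_crossings(left, threshold, debounce_s)
    rows = []
    for i in range(len(r_up) - 1):
        t0, t1 = r_up[i], r_up[i + 1]
        lfo = l_down[(l_down > t0) & (l_down < t1)]
        lfs = l_up[(l_up > t0) & (l_up < t1)]
        rfo = r_down[(r_down > t0) & (r_down < t1)]
        if len(lfo) != 1 or len(lfs) != 1 or len(rfo) != 1:
            continue
        if not (t0 < lfo[0] < lfs[0] < rfo[0] < t1):
            continue
        rows.append({"t_RFS": t0, "t_LFO": lfo[0], "t_LFS": lfs[0],
                     "t_RFO": rfo[0], "t_RFS_next": t1})
    return GaitEventTable(pd.DataFrame(
        rows, columns=list(GaitEventTable.COLUMNS)))


def remove_outliers(values, k_sd: float = 2.5) -> np.ndarray:
    """Single-pass removal of values beyond k_sd sample SDs from the mean.

    Applied once, non-iteratively, per trial.  Zero-variance input is
    returned unchanged.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    sd = v.std(ddof=1)
    if sd == 0:
        return v.copy()
    keep = np.abs(v - v.mean()) <= k_sd * sd
    return v[keep]


def coefficient_of_variation(values) -> float:
    """Sample standard deviation over mean (unitless)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    m = v.mean()
    if m == 0:
        raise ValueError("coefficient of variation undefined for zero mean")
    return float(v.std(ddof=1) / m)


def sacral_excursion(trace: np.ndarray, fs: float,
                     events: GaitEventTable) -> np.ndarray:
    """Per-stride peak-to-peak excursion (max - min between RFS and next RFS)."""
    trace = np.asarray(trace, dtype=float)
    out = []
    n = len(trace)
    for t0, t1 in zip(events.column("t_RFS"), events.column("t_RFS_next")):
        i0, i1 = int(np.floor(t0 * fs)), int(np.ceil(t1 * fs))
        if i0 < 0 or i1 > n:
            logger.warning("stride [%0.2f, %0.2f] s outside trace; skipped", t0, t1)
            continue
        seg = trace[i0:i1]
        out.append(seg.max() - seg.min())
    return np.asarray(out)


def behavior_table(
    trials: list[dict],
    k_sd: float = 2.5,
    min_strides: int = 5,
) -> pd.DataFrame:
    """Per-(subject, condition) behavioral variability summary.

    Each trial dict needs keys: subject, group, condition, speed, events
    (GaitEventTable), sacrum ({'ap','ml'} arrays), fs.  Step durations and
    sacral excursions are outlier-trimmed per trial (single +/-k_sd pass)
    and pooled across a condition's trials before the CoV; cells retaining
    fewer than `min_strides` strides are flagged unusable and excluded.
    """
    pooled: dict = {}
    for tr in trials:
        ev: GaitEventTable = tr["events"]
        if ev.empty:
            continue
        key = (tr["subject"], tr["group"], tr["condition"], tr.get("speed", np.nan))
        cell = pooled.setdefault(key, {"step": [], "ap": [], "ml": [], "n": 0})
        steps = ev.step_durations()
        ap = sacral_excursion(tr["sacrum"]["ap"], tr["fs"], ev)
        ml = sacral_excursion(tr["sacrum"]["ml"], tr["fs"], ev)
        if len(steps) >= 2:
            cell["step"].append(remove_outliers(steps, k_sd))
        if len(ap) >= 2:
            cell["ap"].append(remove_outliers(ap, k_sd))
        if len(ml) >= 2:
            cell["ml"].append(remove_outliers(ml, k_sd))
        cell["n"] += len(ev)

    rows = []
    for (subj, group, cond, speed), cell in pooled.items():
        if cell["n"] < min_strides:
            logger.info("excluding %s/%s: only %d strides", subj, cond, cell["n"])
            continue
        metrics = {}
        for name, parts in (("step_duration_cov", cell["step"]),
                            ("sacral_ap_cov", cell["ap"]),
                            ("sacral_ml_cov", cell["ml"])):
            vals = np.concatenate(parts) if parts else np.array([])
            metrics[name] = (coefficient_of_variation(vals)
                             if len(vals) >= 2 else np.nan)
        for metric, value in metrics.items():
            rows.append({"subject": subj, "group": group, "condition": cond,
                         "speed": speed, "metric": metric, "value": value,
                         "n_strides_used": cell["n"]})
    return pd.DataFrame(rows)
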