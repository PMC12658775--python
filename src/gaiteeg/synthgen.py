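"""Synthetic multi-subject gait-EEG datasets with known ground truth.

Every downstream stage of the pipeline (event detection, artifact
cleaning, component selection, time-warped spectral analysis, statistics)
is given a parameter-recovery surface by this module: cortical sources are
1/f-background-plus-oscillation processes mixed through the same
three-shell spherical forward model used for dipole fitting, band powers
are shifted per terrain condition and age group in dB, band amplitudes are
modulated within the gait cycle, EMG-like artifacts contaminate a subset
of scalp channels (with correlated copies on the paired noise electrodes),
and 60/120 Hz line noise is added throughout.

Sources are amplitude-modulated filtered noise rather than autoregressive
processes: a band-limited component scaled by ``10^(dB/20)`` changes band
power by exactly the stated dB, which keeps the ground-truth bookkeeping
exact.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import SimConfig, GaitSpec, SourceSpec, TERRAINS, DEFAULT_CONDITIONS
from .core import DEFAULT_BANDS, ForceTrace, GaitEventTable, Recording
from .forward import HeadModel, dipole_potential, scalp_montage

__all__ = [
    "simulate_gait",
    "simulate_recording",
    "generate_dataset",
    "SyntheticDataset",
    "make_scenario",
    "scenario_band_power_table",
    "sinusoid_modulation",
]

_TRUNC_SD = 3.0  # stride-duration truncation, in SDs


# ---------------------------------------------------------------------------
# gait kinematics / kinetics
# ---------------------------------------------------------------------------

def simulate_gait(
    spec: GaitSpec,
    duration: float,
    seed: int,
    fs: float = 500.0,
    f_max: float = 700.0,
    ramp_s: float = 0.1,
    threshold: float = 20.0,
):
    """Simulate stride timing, insole forces, and sacral excursions.

    Stride durations are drawn from a normal distribution truncated at
    +/- 3 SD; per-foot vertical forces are trapezoidal loading curves built
    so that the rising edge crosses `threshold` Newtons exactly at each
    foot strike and the falling edge crosses it exactly at each foot off.
    Sacral anteroposterior/mediolateral traces are per-stride sinusoids
    whose peak-to-peak amplitudes have the stated mean and CV.

    Returns ``(GaitEventTable, {'left','right'} ForceTrace, {'ap','ml'})``.
    """
    spec.validate()
    if duration < 3 * spec.stride_mean:
        raise ValueError("duration must cover at least three strides")
    rng = np.random.default_rng(seed)
    m, sd = spec.stride_mean, spec.stride_cv * spec.stride_mean
    n_guess = int(duration / m * 1.5) + 8
    if sd > 0:
        durs = sps.truncnorm.rvs(-_TRUNC_SD, _TRUNC_SD, loc=m, scale=sd,
                                 size=n_guess, random_state=rng)
    else:
        durs = np.full(n_guess, m)
    t_rfs = np.concatenate([[0.6], 0.6 + np.cumsum(durs)])
    t_rfs = t_rfs[t_rfs < duration - 0.6]
    durs = np.diff(t_rfs)
    if len(durs) < 2:
        raise ValueError("duration too short for the requested stride statistics")

    rows = []
    for i, (t0, T) in enumerate(zip(t_rfs[:-1], durs)):
        rows.append(
            {
                "t_RFS": t0,
                "t_LFO": t0 + spec.event_phase_lfo * T,
                "t_LFS": t0 + spec.event_phase_lfs * T,
                "t_RFO": t0 + spec.event_phase_rfo * T,
                "t_RFS_next": t0 + T,
            }
        )
    events = GaitEventTable(pd.DataFrame(rows))

    n = int(round(duration * fs))
    t = np.arange(n) / fs
    right = np.zeros(n)
    left = np.zeros(n)
    # right stance: RFS -> RFO of the same stride
    stances_r = list(zip(events.column("t_RFS"), events.column("t_RFO")))
    # left stance: LFS of stride i -> LFO of stride i+1
    lfs = events.column("t_LFS")
    lfo = events.column("t_LFO")
    stances_l = list(zip(lfs[:-1], lfo[1:]))
    # leading partial left stance before the first recorded LFO
    if lfo[0] > 0:
        stances_l.insert(0, (max(0.0, lfo[0] - 0.6), lfo[0]))
    for arr, stances in ((right, stances_r), (left, stances_l)):
        for t_on, t_off in stances:
            _add_stance(arr, t, t_on, t_off, f_max, ramp_s, threshold)

    def _sacral(mean_pp, cv):
        out = np.zeros(n)
        for t0, T in zip(t_rfs[:-1], durs):
            amp = mean_pp
            if cv > 0:
                amp = sps.truncnorm.rvs(-_TRUNC_SD, _TRUNC_SD, loc=mean_pp,
                                        scale=cv * mean_pp, random_state=rng)
            amp = max(amp, 0.0)
            sel = (t >= t0) & (t < t0 + T)
            out[sel] = amp / 2 * np.sin(2 * np.pi * (t[sel] - t0) / T)
        return out

    sacrum = {"ap": _sacral(spec.sacral_ap_mean, spec.sacral_ap_cv),
              "ml": _sacral(spec.sacral_ml_mean, spec.sacral_ml_cv)}
    forces = {"left": ForceTrace(left, fs, "left"),
              "right": ForceTrace(right, fs, "right")}
    return events, forces, sacrum


def _add_stance(arr, t, t_on, t_off, f_max, ramp_s, threshold):
    """Trapezoidal loading curve crossing `threshold` exactly at t_on/t_off."""
    frac = threshold / f_max
    rise0 = t_on - ramp_s * frac
    fall0 = t_off - ramp_s * (1 - frac)
    up = np.clip((t - rise0) / ramp_s, 0.0, 1.0)
    down = np.clip(1.0 - (t - fall0) / ramp_s, 0.0, 1.0)
    arr += f_max * np.minimum(up, down) * (t > rise0 - ramp_s) * (t < fall0 + 2 * ramp_s)


# ---------------------------------------------------------------------------
# source and recording synthesis
# ---------------------------------------------------------------------------

def sinusoid_modulation(p2p_db: float, cycles_per_stride: int = 1,
                        phase_deg: float = 0.0):
    """Zero-mean sinusoidal dB modulation over the gait cycle (phase in %)."""

    def f(phase_pct):
        return (p2p_db / 2) * np.cos(
            2 * np.pi * cycles_per_stride * np.asarray(phase_pct) / 100.0
            - np.deg2rad(phase_deg)
        )

    return f


def _band_windows(freqs: np.ndarray, bands: dict, trans_hz: float = 1.0):
    """Power-domain partition of unity over frequency: one window per band
    plus a remainder window, with raised-cosine crossfades of width trans_hz."""

    def smooth_up(f, edge):
        x = np.clip((f - (edge - trans_hz / 2)) / trans_hz, 0, 1)
        return 0.5 - 0.5 * np.cos(np.pi * x)

    wins = {}
    total = np.zeros_like(freqs)
    for name, (lo, hi) in bands.items():
        w2 = smooth_up(freqs, lo) * (1 - smooth_up(freqs, hi))
        wins[name] = w2
        total = total + w2
    wins["_rest"] = np.clip(1.0 - total, 0.0, None)
    return wins


def _shaped_noise_bands(rng, n, fs, src: SourceSpec, bands: dict):
    """Generate the source as per-band time series (power partition).

    The target one-sided PSD is 10^(offset - exponent*log10 f) times
    10^(sum of Gaussian peak bumps); splitting by band windows in the
    frequency domain yields components whose powers add to the target.
    """
    freqs = np.fft.rfftfreq(n, 1 / fs)
    logp = np.full_like(freqs, -np.inf)
    pos = freqs > 0
    logp[pos] = src.aperiodic_offset - src.aperiodic_exponent * np.log10(freqs[pos])
    bump = np.zeros_like(freqs)
    for c, h, w in src.peaks:
        bump += h * np.exp(-((freqs - c) ** 2) / (2 * w**2))
    target_psd = np.where(pos, 10.0 ** (logp + bump), 0.0)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    shaped = spec * np.sqrt(target_psd / (2.0 / fs))
    wins = _band_windows(freqs, bands)
    out = {}
    for name, w2 in wins.items():
        out[name] = np.fft.irfft(shaped * np.sqrt(w2), n=n)
    return out


def _gait_phase_pct(t: np.ndarray, events: GaitEventTable | None) -> np.ndarray:
    """Piecewise-linear gait phase in percent of stride (0 at each RFS)."""
    if events is None or events.empty:
        return np.zeros_like(t)
    rfs = np.concatenate([events.column("t_RFS"), [events.column("t_RFS_next")[-1]]])
    mean_T = float(np.mean(np.diff(rfs)))
    idx = np.clip(np.searchsorted(rfs, t, side="right") - 1, 0, len(rfs) - 2)
    frac = (t - rfs[idx]) / (rfs[idx + 1] - rfs[idx])
    before = t < rfs[0]
    frac[before] = ((t[before] - rfs[0]) / mean_T) % 1.0
    after = t >= rfs[-1]
    frac[after] = ((t[after] - rfs[-1]) / mean_T) % 1.0
    return 100.0 * np.clip(frac, 0.0, 1.0)


def _emg_artifact(rng, n, fs, rms_uv=15.0, knee_hz=20.0, rise_db_per_hz=0.3,
                  plateau_hz=120.0):
    """EMG-like broadband artifact: flat below the knee, then a monotone
    +0.3 dB/Hz power rise up to a plateau frequency."""
    freqs = np.fft.rfftfreq(n, 1 / fs)
    rise = np.clip(freqs - knee_hz, 0.0, plateau_hz - knee_hz) * rise_db_per_hz
    psd = 10.0 ** (rise / 10.0)
    psd[freqs == 0] = 0.0
    x = np.fft.irfft(np.fft.rfft(rng.standard_normal(n)) * np.sqrt(psd), n=n)
    return x / x.std() * rms_uv


def simulate_recording(
    sources: list[SourceSpec],
    gait: GaitEventTable | None,
    cfg: SimConfig,
    condition: str,
    group: str,
    seed: int,
    return_truth: bool = False,
    intercepts: dict | None = None,
    clean: bool = False,
) -> Recording:
    """Mix modulated cortical sources plus artifacts into a Recording.

    Each source is colored noise shaped to its 1/f-plus-peaks spectrum;
    per-band amplitude is scaled by the source's condition + group dB shift
    (plus optional per-(source, band) subject intercepts) and modulated
    within each stride by its gait-modulation profile.  Sources are mixed
    to scalp channels through the three-shell spherical forward model.  EMG
    artifacts (low below 20 Hz, rising monotonically above) contaminate the
    EMG channels and a configured fraction of scalp channels; 60/120 Hz
    line noise is added; noise-role channels carry the artifact/line
    mixture of their paired scalp electrode but no cortical signal.

    With ``clean=True`` artifacts, line noise, and sensor noise are all
    omitted (oracle pathway).  With ``return_truth=True`` returns
    ``(recording, truth)`` where truth holds the clean per-source signals
    and the mixing matrix.
    """
    if condition not in cfg.conditions:
        raise ValueError(f"unknown condition label {condition!r}")
    if not sources:
        raise ValueError("at least one source is required")
    for s in sources:
        s.validate(cfg.fs)
    cfg.validate()
    rng = np.random.default_rng(seed)
    n = int(round(cfg.trial_duration * cfg.fs))
    t = np.arange(n) / cfg.fs
    phase = _gait_phase_pct(t, gait if condition != "rest" else None)

    head = HeadModel()
    montage = scalp_montage(cfg.n_scalp, head)
    src_ts = np.zeros((len(sources), n))
    mixing = np.zeros((cfg.n_scalp, len(sources)))
    for i, src in enumerate(sources):
        parts = _shaped_noise_bands(rng, n, cfg.fs, src, cfg.bands)
        sig = parts.pop("_rest")
        for band, comp in parts.items():
            shift = src.total_shift_db(band, condition, group)
            if intercepts:
                shift += intercepts.get((src.name, band), 0.0)
            gain = 10.0 ** (shift / 20.0)
            mod = _lookup_modulation(src, band, condition)
            if mod is not None and condition != "rest":
                gain = gain * 10.0 ** (np.asarray(mod(phase)) / 20.0)
            sig = sig + gain * comp
        src_ts[i] = sig
        topo = dipole_potential(src.location_mm, src.orientation, montage, head)
        mixing[:, i] = topo / np.abs(topo).max()

    scalp = mixing @ src_ts

    n_total = cfg.n_scalp + cfg.n_noise + cfg.n_emg
    data = np.zeros((n_total, n))
    roles = np.array(["scalp"] * cfg.n_scalp + ["noise"] * cfg.n_noise
                     + ["emg"] * cfg.n_emg)
    positions = np.full((n_total, 3), np.nan)
    positions[: cfg.n_scalp] = montage
    positions[cfg.n_scalp: cfg.n_scalp + cfg.n_noise] = montage
    names = ([f"S{i+1:02d}" for i in range(cfg.n_scalp)]
             + [f"N{i+1:02d}" for i in range(cfg.n_noise)]
             + [f"EMG{i+1}" for i in range(cfg.n_emg)])

    data[: cfg.n_scalp] = scalp
    artifact_scalp = np.zeros((cfg.n_scalp, n))
    emg_srcs = np.zeros((cfg.n_emg, n))
    if not clean:
        for k in range(cfg.n_emg):
            emg_srcs[k] = _emg_artifact(rng, n, cfg.fs)
        n_cont = int(round(cfg.emg_scalp_fraction * cfg.n_scalp))
        contaminated = rng.choice(cfg.n_scalp, size=n_cont, replace=False)
        for ch in contaminated:
            k = rng.integers(cfg.n_emg)
            artifact_scalp[ch] = rng.uniform(0.3, 0.6) * emg_srcs[k]
        line = np.zeros(n)
        for f0 in cfg.line_freqs:
            line += np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
        line_gain = cfg.line_amp_uv * rng.uniform(0.5, 1.5, size=n_total)
        data[: cfg.n_scalp] += artifact_scalp
        # noise electrodes: paired artifact + line, no cortical signal
        data[cfg.n_scalp: cfg.n_scalp + cfg.n_noise] = artifact_scalp
        for k in range(cfg.n_emg):
            data[cfg.n_scalp + cfg.n_noise + k] = emg_srcs[k]
        data += line_gain[:, None] * line[None, :]
        data += rng.normal(0, cfg.sensor_noise_uv, size=data.shape)

    rec = Recording(data=data, fs=cfg.fs, roles=roles, positions=positions,
                    ch_names=names, condition=condition, group=group)
    if return_truth:
        truth = {"sources": src_ts, "mixing": mixing, "montage": montage,
                 "emg": emg_srcs, "artifact_scalp": artifact_scalp}
        return rec, truth
    return rec


def _lookup_modulation(src: SourceSpec, band: str, condition: str):
    gm = src.gait_modulation
    return gm.get((band, condition), gm.get(band))


# ---------------------------------------------------------------------------
# scenarios and datasets
# ---------------------------------------------------------------------------

def _terrain_ramp(values):
    return dict(zip(TERRAINS, values))


@dataclass
class Scenario:
    """Named effect template: per-group source specs, gait specs, truth."""

    name: str
    sources: dict          # group -> list[SourceSpec]
    gait: dict             # (condition, group) -> GaitSpec
    band_effects: dict     # (source, band, condition, group) -> dB truth shift
    p2p_truth: dict        # (source, band, condition, group) -> dB peak-to-peak


def _base_sources():
    return [
        SourceSpec(name="sensorimotor_L", location_mm=(-35.0, -10.0, 55.0),
                   orientation=(-0.45, -0.13, 0.88),
                   aperiodic_offset=1.3, aperiodic_exponent=1.4,
                   peaks=((10.0, 0.6, 1.5), (20.0, 0.5, 3.0))),
        SourceSpec(name="sensorimotor_R", location_mm=(35.0, -10.0, 55.0),
                   orientation=(0.45, -0.13, 0.88),
                   aperiodic_offset=1.3, aperiodic_exponent=1.4,
                   peaks=((10.0, 0.6, 1.5), (20.0, 0.5, 3.0))),
        SourceSpec(name="parietal", location_mm=(-25.0, -45.0, 40.0),
                   orientation=(-0.3, -0.6, 0.74),
                   aperiodic_offset=1.25, aperiodic_exponent=1.5,
                   peaks=((10.0, 0.8, 2.0), (18.0, 0.4, 3.0))),
        SourceSpec(name="occipital", location_mm=(5.0, -55.0, 20.0),
                   orientation=(0.1, -0.9, 0.42),
                   aperiodic_offset=1.2, aperiodic_exponent=1.6,
                   peaks=((6.0, 0.5, 1.5), (10.0, 1.0, 2.0))),
    ]


def _gait_specs(name):
    """Stride/sacral variability per condition and group; variability rises
    with terrain unevenness (more strongly in older adults), stride period
    is slightly longer in older adults."""
    out = {}
    young_cv = _terrain_ramp((0.03, 0.05, 0.07, 0.10))
    old_cv = _terrain_ramp((0.04, 0.065, 0.09, 0.13))
    if name == "null":
        young_cv = old_cv = _terrain_ramp((0.05, 0.05, 0.05, 0.05))
    for cond in TERRAINS:
        for group, cvs, sm in (("young", young_cv, 1.15), ("old", old_cv, 1.25)):
            cv = cvs[cond]
            out[(cond, group)] = GaitSpec(
                stride_mean=sm, stride_cv=cv,
                sacral_ap_cv=cv * 1.2, sacral_ml_cv=cv * 1.5,
            )
    return out


def make_scenario(name: str, bands: dict | None = None) -> Scenario:
    """Build a named effect template.

    ``"null"`` injects no condition, group, or gait-phase effects (for
    error-rate checks).  ``"paper-like"`` mirrors the qualitative findings
    on uneven-terrain walking: a young-only parieto-occipital alpha/beta
    reduction that grows with terrain unevenness (terrain-by-age
    interaction), a terrain-only beta/alpha reduction over sensorimotor
    cortex in both groups, a terrain-only occipital theta increase, and
    intra-stride beta modulation over sensorimotor cortex.
    """
    bands = bands or DEFAULT_BANDS
    srcs = {"young": _base_sources(), "old": _base_sources()}
    band_effects: dict = {}
    p2p: dict = {}

    if name == "paper-like":
        young_alpha = _terrain_ramp((0.0, -1.0, -1.5, -2.0))
        old_alpha = _terrain_ramp((0.0, -0.1, -0.15, -0.2))
        young_beta = _terrain_ramp((0.0, -0.8, -1.2, -1.8))
        old_beta = _terrain_ramp((0.0, -0.3, -0.45, -0.6))
        both_beta = _terrain_ramp((0.0, -0.8, -1.2, -1.8))
        both_alpha_sm = _terrain_ramp((0.0, -0.5, -1.0, -1.5))
        theta_up = _terrain_ramp((0.0, 0.6, 0.9, 1.5))
        for group in ("young", "old"):
            for src in srcs[group]:
                shifts = {}
                if src.name in ("parietal", "occipital"):
                    a = young_alpha if group == "young" else old_alpha
                    b = young_beta if group == "young" else old_beta
                    for cond in TERRAINS:
                        shifts[("alpha", cond)] = a[cond]
                        shifts[("beta", cond)] = b[cond]
                if src.name.startswith("sensorimotor"):
                    for cond in TERRAINS:
                        shifts[("beta", cond)] = both_beta[cond]
                        shifts[("alpha", cond)] = both_alpha_sm[cond]
                    src.gait_modulation = {"beta": sinusoid_modulation(3.0, 2)}
                    for cond in TERRAINS:
                        p2p[(src.name, "beta", cond, group)] = 3.0
                if src.name == "occipital":
                    for cond in TERRAINS:
                        shifts[("theta", cond)] = theta_up[cond]
                src.condition_shift = shifts
                for (band, cond), v in shifts.items():
                    band_effects[(src.name, band, cond, group)] = v
    elif name != "null":
        raise ValueError(f"unknown scenario {name!r}")

    return Scenario(name=name, sources=srcs, gait=_gait_specs(name),
                    band_effects=band_effects, p2p_truth=p2p)


@dataclass
class SyntheticDataset:
    """Recordings plus gait traces and complete ground truth."""

    cfg: SimConfig
    scenario: Scenario
    recordings: list = field(default_factory=list)
    events: dict = field(default_factory=dict)
    forces: dict = field(default_factory=dict)
    sacrum: dict = field(default_factory=dict)
    subjects: pd.DataFrame | None = None
    truth: dict = field(default_factory=dict)

    def walking_keys(self):
        return [k for k in self.events if k[1] != "rest"]

    def recording(self, subject, condition, trial) -> Recording:
        for r in self.recordings:
            if (r.subject, r.condition, r.trial) == (subject, condition, trial):
                return r
        raise KeyError((subject, condition, trial))


def generate_dataset(cfg: SimConfig, scenario: str | Scenario) -> SyntheticDataset:
    """Simulate the full study layout for one scenario.

    One recording per (subject, condition, trial): ``n_walking_trials``
    per terrain condition plus a single seated rest trial.  Per-subject
    random intercepts (SD 0.3 dB per source-band) are added to every band
    effect; subject walking speeds are drawn per group.  All randomness
    descends deterministically from ``cfg.seed``.
    """
    cfg.validate()
    if isinstance(scenario, str):
        scenario = make_scenario(scenario, cfg.bands)
    ds = SyntheticDataset(cfg=cfg, scenario=scenario)
    master = np.random.SeedSequence(cfg.seed)
    rows = []
    subj_idx = 0
    intercept_rng = np.random.default_rng(master.spawn(1)[0])
    for group, n_subj, speed_mu in (("young", cfg.n_young, 0.75),
                                    ("old", cfg.n_old, 0.55)):
        for _ in range(n_subj):
            subj = f"{group[0]}{subj_idx:02d}"
            speed = float(np.round(intercept_rng.normal(speed_mu, 0.08), 3))
            intercepts = {
                (src.name, band): float(intercept_rng.normal(0, 0.3))
                for src in scenario.sources[group]
                for band in cfg.bands
            }
            rows.append({"subject": subj, "group": group, "speed": speed})
            ds.truth[subj] = {"intercepts": intercepts}
            for ci, cond in enumerate(cfg.conditions):
                n_trials = 1 if cond == "rest" else cfg.n_walking_trials
                for trial in range(n_trials):
                    ss = np.random.SeedSequence([cfg.seed, subj_idx, ci, trial])
                    s_gait, s_rec = [int(s.generate_state(1)[0] % (2**31))
                                     for s in ss.spawn(2)]
                    key = (subj, cond, trial)
                    gait = None
                    if cond != "rest":
                        gspec = scenario.gait[(cond, group)]
                        gait, forces, sac = simulate_gait(
                            gspec, cfg.trial_duration, s_gait, fs=cfg.fs)
                        ds.events[key] = gait
                        ds.forces[key] = forces
                        ds.sacrum[key] = sac
                    rec = simulate_recording(
                        scenario.sources[group], gait, cfg, cond, group,
                        s_rec, intercepts=intercepts)
                    rec.subject, rec.trial, rec.speed = subj, trial, speed
                    ds.recordings.append(rec)
            subj_idx += 1
    ds.subjects = pd.DataFrame(rows)
    return ds


def scenario_band_power_table(
    scenario: str | Scenario,
    n_young: int,
    n_old: int,
    seed: int,
    noise_sd: float = 0.5,
    intercept_sd: float = 0.3,
    baseline_db: float = 2.0,
) -> pd.DataFrame:
    """Subject-level band-power outcomes drawn from a scenario's truth.

    Emulates the table the spectral stage produces (subject, group,
    condition, speed, cluster, band, value in dB), with the scenario's
    ground-truth shifts plus subject random intercepts and residual noise.
    Used for statistical power / error-rate studies at arbitrary n without
    rerunning the signal chain.
    """
    if isinstance(scenario, str):
        scenario = make_scenario(scenario)
    rng = np.random.default_rng(seed)
    rows = []
    idx = 0
    for group, n_subj, speed_mu in (("young", n_young, 0.75), ("old", n_old, 0.55)):
        for _ in range(n_subj):
            subj = f"{group[0]}{idx:02d}"
            speed = rng.normal(speed_mu, 0.08)
            for src in scenario.sources[group]:
                for band in DEFAULT_BANDS:
                    icpt = rng.normal(0, intercept_sd)
                    for cond in TERRAINS:
                        shift = scenario.band_effects.get(
                            (src.name, band, cond, group), 0.0)
                        val = baseline_db + icpt + shift + rng.normal(0, noise_sd)
                        rows.append({
                            "subject": subj, "group": group, "condition": cond,
                            "speed": speed, "cluster": src.name, "band": band,
                            "value": val,
                        })
            idx += 1
    return pd.DataFrame(rows)
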