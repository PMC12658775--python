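"""Configuration objects for simulation and the processing pipeline.

Every parameter that the analysis chain depends on appears here exactly
once, with its conventional default (filter cutoffs, correlation
thresholds, iteration counts, cluster count, band edges, seeds).  Configs
round-trip losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .core import DEFAULT_BANDS

DEFAULT_CONDITIONS = ("rest", "Flat", "Low", "Med", "High")
TERRAINS = ("Flat", "Low", "Med", "High")


@dataclass
class SimConfig:
    """Desk-scale synthetic study layout.

    The full study used 120 scalp + 120 coupled noise electrodes and 3-min
    trials; the desk-scale defaults (32 channels, 60-s trials, 4+4
    subjects) keep every stage exercisable in seconds while remaining
    configurable up to study scale.
    """

    n_young: int = 4
    n_old: int = 4
    conditions: tuple = DEFAULT_CONDITIONS
    fs: float = 500.0
    n_scalp: int = 32
    n_emg: int = 4
    trial_duration: float = 60.0
    n_walking_trials: int = 2
    seed: int = 0
    emg_scalp_fraction: float = 0.3  # fraction of scalp channels contaminated
    sensor_noise_uv: float = 0.5
    line_freqs: tuple = (60.0, 120.0)
    line_amp_uv: float = 5.0
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))

    @property
    def n_noise(self) -> int:
        # one mechanically coupled noise electrode per scalp electrode
        return self.n_scalp

    def validate(self, max_freq: float | None = None) -> None:
        if max_freq is None:
            # line harmonics are the highest deterministic simulated
            # frequency; keep a 10 Hz guard band above them
            max_freq = max([*self.line_freqs, 60.0]) + 10.0
        if self.fs <= 2 * max_freq:
            raise ValueError("fs must exceed twice the highest simulated frequency")
        if self.trial_duration <= 0:
            raise ValueError("trial_duration must be positive")
        if self.n_scalp < 4 or self.n_emg < 1:
            raise ValueError("too few channels")


@dataclass
class GaitSpec:
    """Stride-timing and sacral-excursion statistics for one walking context.

    event_phase_* are fractions of the stride (anchored at right foot
    strike) at which left foot off, left foot strike, and right foot off
    occur; they must be ordered 0 < LFO < LFS < RFO < 1.
    """

    stride_mean: float = 1.2
    stride_cv: float = 0.05
    event_phase_lfo: float = 0.12
    event_phase_lfs: float = 0.50
    event_phase_rfo: float = 0.62
    sacral_ap_mean: float = 20.0  # mm peak-to-peak
    sacral_ap_cv: float = 0.10
    sacral_ml_mean: float = 30.0
    sacral_ml_cv: float = 0.10

    def validate(self) -> None:
        if self.stride_mean <= 0:
            raise ValueError("stride_mean must be positive")
        if not (0 < self.event_phase_lfo < self.event_phase_lfs
                < self.event_phase_rfo < 1):
            raise ValueError("event phases must satisfy 0 < LFO < LFS < RFO < 1")
        for cv in (self.stride_cv, self.sacral_ap_cv, self.sacral_ml_cv):
            if cv < 0:
                raise ValueError("coefficients of variation must be >= 0")


@dataclass
class SourceSpec:
    """One cortical source: 1/f background plus oscillatory peaks.

    peaks are (center_hz, height_log10, width_hz) Gaussian bumps added to
    the log10 aperiodic spectrum.  condition_shift / group_shift are dB
    band-power offsets keyed ``(band, condition)`` / ``(band, group)``;
    gait_modulation maps band -> callable on gait phase in [0, 100] percent
    returning dB (zero mean over the stride).
    """

    name: str
    location_mm: tuple = (0.0, 0.0, 50.0)
    orientation: tuple = (0.0, 0.0, 1.0)
    aperiodic_offset: float = 1.3  # log10(uV^2/Hz) at 1 Hz
    aperiodic_exponent: float = 1.5
    peaks: tuple = ((10.0, 1.0, 2.0),)
    condition_shift: dict = field(default_factory=dict)
    group_shift: dict = field(default_factory=dict)
    gait_modulation: dict = field(default_factory=dict)

    def validate(self, fs: float) -> None:
        if self.aperiodic_exponent < 0:
            raise ValueError("aperiodic_exponent must be >= 0")
        for c, h, w in self.peaks:
            if not (0 < c < fs / 2):
                raise ValueError("peak centers must lie in (0, fs/2)")
            if w <= 0:
                raise ValueError("peak widths must be positive")

    def total_shift_db(self, band: str, condition: str, group: str) -> float:
        return (self.condition_shift.get((band, condition), 0.0)
                + self.group_shift.get((band, group), 0.0))


@dataclass
class PipelineConfig:
    """All tunables of the processing chain, with conventional defaults."""

    # gait behavior
    force_threshold_n: float = 20.0          # insole contact threshold
    outlier_k_sd: float = 2.5                # per-trial behavioral outlier cut
    debounce_s: float = 0.05                 # crossing chatter guard
    min_strides: int = 5
    # preprocessing
    highpass_hz: float = 1.0                 # -6 dB at half this cutoff
    emg_highpass_hz: float = 20.0
    line_freqs: tuple = (60.0, 120.0)
    bad_channel_k_sd: float = 3.0
    noise_r2: float = 0.65                   # reference-guided cleaning, noise layer
    emg_r2: float = 0.4                      # reference-guided cleaning, EMG refs
    clean_window_s: float = 4.0
    chan_crit: float = 0.7                   # window rejection channel correlation
    win_crit: float = 0.4                    # fraction of bad channels per window
    amp_z_tol: float = 10.0                  # upper amplitude z tolerance
    ica_seed: int = 97
    n_components: int | None = None
    # component retention
    brain_score_min: float = 0.5
    psd_slope_range: tuple = (2.0, 40.0)
    dipole_rv_max: float = 0.15
    # clustering
    k_clusters: int = 11
    kmeans_seed: int = 11
    cluster_outlier_sd: float = 3.0
    # spectral
    epoch_pre_s: float = 1.0
    epoch_post_s: float = 4.25
    epoch_latency_k_sd: float = 3.0
    welch_window_s: float = 2.0
    morlet_cycles: tuple = (3.0, 0.8)
    ersp_freqs: tuple = (3.0, 40.0, 1.0)     # lo, hi, step
    gait_grid: int = 200
    fit_range_hz: tuple = (3.0, 40.0)
    peak_width_limits: tuple = (1.0, 8.0)
    min_peak_height: float = 0.05
    max_n_peaks: int = 2
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    spca_remove: tuple = (1,)
    # statistics
    alpha: float = 0.05
    n_boot: int = 4000
    n_perm_psd: int = 2000
    n_perm_cluster: int = 10000
    lmm_outlier_sd: float = 8.0
    stats_seed: int = 7

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_as_plain(dataclasses.asdict(self)), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            v = raw[f.name]
            if isinstance(getattr(cls(), f.name), tuple) and isinstance(v, list):
                v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
            if f.name == "bands":
                v = {k: tuple(b) for k, b in v.items()}
            kwargs[f.name] = v
        return cls(**kwargs)


def _as_plain(obj):
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    return obj
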