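"""Shared containers for recordings, gait events, and frequency bands."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical frequency bands (Hz).  Theta is sometimes taken as 3-8 Hz in
#: the literature; the 4-8 Hz convention is the default here and all band
#: edges are configurable wherever bands are consumed.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

EVENT_ORDER = ("RFS", "LFO", "LFS", "RFO", "RFS_next")


@dataclass
class Recording:
    """Multi-channel time series with channel roles.

    data is (n_channels, n_samples) in microvolts; roles label each channel
    as ``scalp`` (EEG), ``noise`` (mechanically coupled artifact reference),
    or ``emg`` (neck-muscle electrode).  positions are 3-vectors in mm on
    the scalp sphere for scalp/noise channels (noise electrodes sit at their
    paired scalp electrode's position).
    """

    data: np.ndarray
    fs: float
    roles: np.ndarray  # dtype '<U5'
    positions: np.ndarray  # (n_channels, 3) mm; NaN rows for emg
    ch_names: list[str]
    subject: str = ""
    group: str = ""
    condition: str = ""
    trial: int = 0
    speed: float = np.nan

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.roles = np.asarray(self.roles)
        if self.data.ndim != 2:
            raise ValueError("data must be (channels, samples)")
        if self.data.shape[0] != len(self.roles):
            raise ValueError("role count does not match channel count")
        if np.isnan(self.data).any():
            raise ValueError("recording contains NaNs")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def pick(self, role: str) -> np.ndarray:
        """Boolean channel mask for a role."""
        return self.roles == role

    def copy(self, data: np.ndarray | None = None) -> "Recording":
        return Recording(
            data=self.data.copy() if data is None else data,
            fs=self.fs,
            roles=self.roles.copy(),
            positions=self.positions.copy(),
            ch_names=list(self.ch_names),
            subject=self.subject,
            group=self.group,
            condition=self.condition,
            trial=self.trial,
            speed=self.speed,
        )


class GaitEventTable:
    """Ordered per-stride gait event times (seconds).

    Columns: t_RFS, t_LFO, t_LFS, t_RFO, t_RFS_next.  Events are strictly
    increasing within a stride and strides do not overlap (each stride's
    t_RFS_next equals the next stride's t_RFS when strides are contiguous).
    """

    COLUMNS = ("t_RFS", "t_LFO", "t_LFS", "t_RFO", "t_RFS_next")

    def __init__(self, frame: pd.DataFrame):
        frame = frame.reset_index(drop=True)
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"missing event columns: {sorted(missing)}")
        vals = frame[list(self.COLUMNS)].to_numpy()
        if len(vals) and not (np.diff(vals, axis=1) > 0).all():
            raise ValueError("events must be strictly increasing within each stride")
        if len(vals) > 1 and not (vals[1:, 0] >= vals[:-1, 0]).all():
            raise ValueError("strides must be ordered")
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def empty(self) -> bool:
        return len(self.frame) == 0

    def column(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy()

    def stride_durations(self) -> np.ndarray:
        return self.column("t_RFS_next") - self.column("t_RFS")

    def step_durations(self) -> np.ndarray:
        """Two steps per stride: RFS->LFS and LFS->next RFS."""
        first = self.column("t_LFS") - self.column("t_RFS")
        second = self.column("t_RFS_next") - self.column("t_LFS")
        return np.concatenate([first, second])

    def latencies_relative_to_rfs(self) -> np.ndarray:
        """(n_strides, 4) latencies of LFO, LFS, RFO, next RFS after RFS."""
        base = self.column("t_RFS")[:, None]
        rest = self.frame[["t_LFO", "t_LFS", "t_RFO", "t_RFS_next"]].to_numpy()
        return rest - base

    def to_tsv(self, path) -> None:
        """BIDS-style long-format events table.

        All five events of every stride are written (the closing right
        foot strike under the label RFS_next), so the round-trip is exact
        even when strides are non-contiguous (intervening strides dropped
        by detection)."""
        rows = []
        for i, row in self.frame.iterrows():
            for col, label in zip(self.COLUMNS, EVENT_ORDER):
                rows.append({"onset_s": row[col], "event": label, "stride_index": i})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GaitEventTable":
        long = pd.read_csv(path, sep="\t")
        wide = long.pivot_table(index="stride_index", columns="event", values="onset_s")
        missing = [lbl for lbl in EVENT_ORDER if lbl not in wide.columns]
        if missing:
            raise ValueError(f"events TSV missing labels: {missing}")
        frame = pd.DataFrame(
            {col: wide[label] for col, label in zip(cls.COLUMNS, EVENT_ORDER)}
        ).dropna()
        return cls(frame.reset_index(drop=True))


@dataclass
class ForceTrace:
    """Single-foot vertical insole force (Newtons)."""

    samples: np.ndarray
    fs: float
    foot: str  # 'left' | 'right'

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.isfinite(self.samples).all():
            raise ValueError("force trace contains non-finite values")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs
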