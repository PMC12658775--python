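"""Standard-format I/O: EDF recordings, events TSV, manifests, truth JSON.

Recordings are written as plain EDF (16-bit) with a JSON sidecar carrying
channel roles, electrode positions, and trial metadata; reading goes
through MNE's EDF reader so round-trips are checked against an independent
parser.  Events use a BIDS-style TSV (onset_s, event, stride_index).
"""

from __future__ import annotations

import hashlib
import json
import struct
from pathlib import Path

import numpy as np
import yaml

from .core import GaitEventTable, Recording

__all__ = ["write_recording", "read_recording", "write_dataset", "sha256_of"]

_SIDECAR_FIELDS = ("roles", "positions", "subject", "group", "condition",
                   "trial", "speed", "fs")


def write_recording(rec: Recording, path) -> None:
    """Write a Recording as plain EDF plus a JSON sidecar.

    Each channel is scaled to its own physical min/max over the 16-bit
    digital range, so quantization error is at most one step of
    (max - min) / 65535.  The trace is zero-padded to whole 1-s records.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s record
    n_rec = int(np.ceil(rec.n_samples / spr))
    data = np.zeros((rec.n_channels, n_rec * spr))
    data[:, : rec.n_samples] = rec.data

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    flat = phys_max - phys_min < 1e-12
    phys_max[flat] = phys_min[flat] + 1.0
    dig_min, dig_max = -32768, 32767
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.round((data - phys_min[:, None]) / scale[:, None]
                       + dig_min).astype("<i2")

    ns = rec.n_channels
    header = bytearray()

    def put(text, width):
        header.extend(f"{text:<{width}.{width}}".encode("ascii"))

    put("0", 8)
    put(f"subject {rec.subject or 'X'}", 80)
    put(f"{rec.condition} trial {rec.trial}", 80)
    put("01.01.20", 8)
    put("00.00.00", 8)
    put(str(256 * (ns + 1)), 8)
    put("", 44)
    put(str(n_rec), 8)
    put("1", 8)
    put(str(ns), 4)
    for name in rec.ch_names:
        put(name, 16)
    for _ in range(ns):
        put("", 80)  # transducer
    for _ in range(ns):
        put("uV", 8)
    for v in phys_min:
        put(f"{v:.8g}"[:8], 8)
    for v in phys_max:
        put(f"{v:.8g}"[:8], 8)
    for _ in range(ns):
        put(str(dig_min), 8)
    for _ in range(ns):
        put(str(dig_max), 8)
    for _ in range(ns):
        put("", 80)  # prefiltering
    for _ in range(ns):
        put(str(spr), 8)
    for _ in range(ns):
        put("", 32)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_rec):
            chunk = digital[:, r * spr:(r + 1) * spr]
            fh.write(chunk.tobytes())

    sidecar = {
        "roles": [str(r) for r in rec.roles],
        "positions": np.where(np.isfinite(rec.positions),
                              rec.positions, None).tolist(),
        "subject": rec.subject, "group": rec.group,
        "condition": rec.condition, "trial": rec.trial,
        "speed": None if np.isnan(rec.speed) else rec.speed,
        "fs": fs, "n_samples": rec.n_samples,
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_recording(path) -> Recording:
    """Read an EDF written by :func:`write_recording` (via MNE's parser)."""
    import mne

    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"missing sidecar {sidecar_path.name}; required fields: "
            + ", ".join(_SIDECAR_FIELDS))
    with open(sidecar_path) as fh:
        sc = json.load(fh)
    missing = [f for f in _SIDECAR_FIELDS if f not in sc]
    if missing:
        raise ValueError(f"sidecar missing fields: {missing}")
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on bad headers
        raise ValueError(f"could not parse EDF file {path.name}: {exc}") from exc
    data = raw.get_data() * 1e6  # volts -> microvolts
    n = int(sc.get("n_samples", data.shape[1]))
    positions = np.array(
        [[np.nan if v is None else v for v in row] for row in sc["positions"]])
    return Recording(
        data=data[:, :n], fs=float(sc["fs"]),
        roles=np.array(sc["roles"]), positions=positions,
        ch_names=list(raw.ch_names),
        subject=sc["subject"], group=sc["group"], condition=sc["condition"],
        trial=int(sc["trial"]),
        speed=np.nan if sc["speed"] is None else float(sc["speed"]))


def write_dataset(ds, outdir) -> dict:
    """Serialize a SyntheticDataset: EDF + events TSV per trial, manifest
    YAML, and the ground truth as JSON.  Returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": ds.cfg.seed, "scenario": ds.scenario.name,
                "conditions": list(ds.cfg.conditions), "files": []}
    for rec in ds.recordings:
        stem = f"{rec.subject}_{rec.condition}_t{rec.trial}"
        write_recording(rec, outdir / f"{stem}.edf")
        key = (rec.subject, rec.condition, rec.trial)
        if key in ds.events:
            ds.events[key].to_tsv(outdir / f"{stem}_events.tsv")
        manifest["files"].append(f"{stem}.edf")
    manifest["subjects"] = ds.subjects.to_dict(orient="records")
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
    truth = {
        "band_effects": {"|".join(map(str, k)): v
                         for k, v in ds.scenario.band_effects.items()},
        "p2p_truth": {"|".join(map(str, k)): v
                      for k, v in ds.scenario.p2p_truth.items()},
        "intercepts": {s: {"|".join(k): v
                           for k, v in d["intercepts"].items()}
                       for s, d in ds.truth.items()},
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return manifest


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
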