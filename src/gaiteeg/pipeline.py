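"""One-command end-to-end driver: simulate -> behavior -> preprocess ->
spectral -> statistics, with a run manifest.

The driver operates at whatever scale the SimConfig requests; each stage
writes its tables under the output directory and appends its rejection
decisions to a shared log.  Stage order and parameters follow the fixed
cleaning chain documented in :mod:`gaiteeg.preprocess`.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gait_behavior, preprocess, spectral, stats
from .config import PipelineConfig, SimConfig, TERRAINS
from .core import Recording
from .synthgen import SyntheticDataset, generate_dataset

logger = logging.getLogger(__name__)

__all__ = ["run_all", "process_subject", "spectral_tables", "stats_stage"]


@dataclass
class SubjectDerivatives:
    subject: str
    group: str
    speed: float
    components: preprocess.ComponentSet
    trial_slices: dict            # (condition, trial) -> slice into activations
    masks: dict                   # (condition, trial) -> bad-sample mask
    events: dict                  # (condition, trial) -> GaitEventTable


def process_subject(ds: SyntheticDataset, subject: str,
                    cfg: PipelineConfig, log: list) -> SubjectDerivatives:
    """Clean every trial of a subject, run ICA on the concatenation, score.

    Channels rejected in any trial are dropped from all trials so the
    concatenated decomposition shares a channel space; ICA fitting excludes
    masked windows but activations cover the full recordings.
    """
    recs = [r for r in ds.recordings if r.subject == subject]
    cleaned, masks = [], {}
    for rec in recs:
        c, mask, _ = preprocess.clean_recording(rec, cfg, log)
        cleaned.append(c)
        masks[(rec.condition, rec.trial)] = mask
    common = set.intersection(*[set(np.array(c.ch_names)[c.pick("scalp")])
                                for c in cleaned])
    keep_names = [n for n in cleaned[0].ch_names if n in common]

    datas, slices, pos = [], {}, None
    offset = 0
    full_mask = []
    for c in cleaned:
        idx = [c.ch_names.index(n) for n in keep_names]
        datas.append(c.data[idx])
        pos = c.positions[idx]
        n = c.n_samples
        slices[(c.condition, c.trial)] = slice(offset, offset + n)
        full_mask.append(masks[(c.condition, c.trial)])
        offset += n
    concat = Recording(
        data=np.concatenate(datas, axis=1), fs=cleaned[0].fs,
        roles=np.array(["scalp"] * len(keep_names)), positions=pos,
        ch_names=keep_names, subject=subject, group=recs[0].group)
    mask = np.concatenate(full_mask)
    cs = preprocess.run_ica(concat, cfg.n_components, mask=mask,
                            seed=cfg.ica_seed)
    cs = preprocess.score_components(cs, cfg, log=log)
    events = {(c, t): ds.events[(subject, c, t)]
              for (s, c, t) in ds.events if s == subject}
    return SubjectDerivatives(
        subject=subject, group=recs[0].group, speed=recs[0].speed,
        components=cs, trial_slices=slices, masks=masks, events=events)


def spectral_tables(derivs: list, cluster_map: dict, cfg: PipelineConfig,
                    conditions=TERRAINS):
    """Band-power and peak-to-peak tables for clustered components.

    cluster_map maps (subject, component_index) -> cluster id.  For each
    retained (subject, cluster): walking epochs are built per condition,
    outlier epochs rejected, Morlet maps warped to the gait grid; PSDs are
    muscle-corrected with the subject's sPCA model (PC1 removal, rest PSD
    added back), parameterized into aperiodic + peaks, and averaged into
    band powers of the flattened spectrum; intra-stride peak-to-peak
    fluctuations come from the within-condition-normalized maps.

    Returns (band_power_df, p2p_df, ersp_store) where ersp_store maps
    (subject, cluster, condition) -> dict with per-epoch warped maps.
    """
    f_lo, f_hi, f_step = cfg.ersp_freqs
    tf_freqs = np.arange(f_lo, f_hi + 1e-9, f_step)
    bp_rows, p2p_rows, store = [], [], {}
    for d in derivs:
        comp_ids = sorted({ci for (s, ci) in cluster_map if s == d.subject})
        if not comp_ids:
            continue
        acts = d.components.activations
        fs = d.components.fs
        rest_sl = [sl for (c, t), sl in d.trial_slices.items() if c == "rest"]
        rest_act = acts[comp_ids][:, rest_sl[0]] if rest_sl else None
        freqs_psd, rest_psd = spectral.compute_psd(rest_act, fs,
                                                   cfg.welch_window_s)
        psd_by_cond, warped_by_cond = {}, {}
        for cond in conditions:
            trial_keys = [k for k in d.trial_slices if k[0] == cond]
            segs, epoch_sets = [], []
            for key in trial_keys:
                sl = d.trial_slices[key]
                seg = acts[comp_ids][:, sl]
                mask = d.masks[key]
                segs.append(seg[:, ~mask])
                es = spectral.epoch_walking(
                    seg, fs, d.events[key], mask=mask,
                    pre_s=cfg.epoch_pre_s, post_s=cfg.epoch_post_s,
                    condition=cond)
                if len(es):
                    epoch_sets.append(es)
            if not epoch_sets:
                continue
            _, psd_by_cond[cond] = spectral.compute_psd(
                np.concatenate(segs, axis=1), fs, cfg.welch_window_s)
            es = epoch_sets[0] if len(epoch_sets) == 1 else spectral.EpochSet(
                np.concatenate([e.data for e in epoch_sets]), fs,
                cfg.epoch_pre_s,
                np.concatenate([e.latencies for e in epoch_sets]), cond)
            if len(es) >= 5:
                es = spectral.reject_epoch_outliers(es, cfg.epoch_latency_k_sd)
            tf, times, used_freqs = spectral.morlet_tf(es, tf_freqs,
                                                       cfg.morlet_cycles)
            warped, grid, anchors = spectral.timewarp_gait(
                tf, times, es, cfg.gait_grid)
            warped_by_cond[cond] = (warped, used_freqs, grid, anchors)

        # sPCA on PSD change vs rest, averaged across conditions
        changes = {c: p - rest_psd for c, p in psd_by_cond.items()}
        avg_change = np.mean(list(changes.values()), axis=0)
        spca = spectral.fit_spca(avg_change, removed=cfg.spca_remove)
        mean_within = {
            c: spectral.normalize_ersp(
                {c: w[0].mean(axis=0)}, "within-condition")[c]
            for c, w in warped_by_cond.items()}

        for row_i, ci in enumerate(comp_ids):
            cluster = cluster_map[(d.subject, ci)]
            for cond in psd_by_cond:
                corrected = spectral.apply_spca(
                    spca, changes[cond][row_i], rest_psd=rest_psd[row_i])[0]
                lin = 10 ** (corrected / 10.0)
                fit, flat_db = spectral.fit_spectral_model(
                    freqs_psd, lin, cfg.fit_range_hz, cfg.peak_width_limits,
                    cfg.min_peak_height, cfg.max_n_peaks)
                for band, edges in cfg.bands.items():
                    bp_rows.append({
                        "subject": d.subject, "group": d.group,
                        "condition": cond, "speed": d.speed,
                        "cluster": cluster, "band": band,
                        "value": spectral.band_power(flat_db, freqs_psd, edges),
                        "exponent": fit.exponent})
                if cond in warped_by_cond:
                    w, used_freqs, grid, anchors = warped_by_cond[cond]
                    store[(d.subject, cluster, cond)] = {
                        "epoch_maps": w[:, row_i], "freqs": used_freqs,
                        "grid": grid, "anchors": anchors}
                    for band, edges in cfg.bands.items():
                        p2p_rows.append({
                            "subject": d.subject, "group": d.group,
                            "condition": cond, "speed": d.speed,
                            "cluster": cluster, "band": band,
                            "value": spectral.peak_to_peak_fluctuation(
                                mean_within[cond][row_i], used_freqs, edges)})
    return pd.DataFrame(bp_rows), pd.DataFrame(p2p_rows), store


def stats_stage(band_power: pd.DataFrame, p2p: pd.DataFrame,
                cfg: PipelineConfig, seed: int | None = None):
    """Mixed-model contrasts per (cluster, band) for both outcome tables."""
    out = []
    for label, table in (("band_power", band_power), ("p2p", p2p)):
        if table.empty:
            continue
        for (cluster, band), sub in table.groupby(["cluster", "band"]):
            if sub["subject"].nunique() < 4:
                continue
            res = stats.lmm_contrasts(sub, alpha=cfg.alpha,
                                      outlier_sd=cfg.lmm_outlier_sd)
            terms = res.terms.copy()
            terms["outcome"] = label
            terms["cluster"] = cluster
            terms["band"] = band
            terms["model_variant"] = res.model_variant
            out.append(terms)
    return (pd.concat(out, ignore_index=True) if out
            else pd.DataFrame(columns=["term", "F", "p"]))


def run_all(sim_cfg: SimConfig, cfg: PipelineConfig, outdir,
            scenario: str = "paper-like", write_edf: bool = False) -> dict:
    """Full chain on a synthetic dataset; returns the run manifest."""
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list = []
    ds = generate_dataset(sim_cfg, scenario)
    if write_edf:
        from .io import write_dataset
        write_dataset(ds, outdir / "dataset")

    trials = [{"subject": s, "group": ds.subjects.set_index("subject")
               .loc[s, "group"],
               "condition": c, "speed": ds.recording(s, c, t).speed,
               "events": ev, "sacrum": ds.sacrum[(s, c, t)], "fs": sim_cfg.fs}
              for (s, c, t), ev in ds.events.items()]
    behavior = gait_behavior.behavior_table(trials, cfg.outlier_k_sd,
                                            cfg.min_strides)
    behavior.to_csv(outdir / "behavior.csv", index=False)

    derivs = [process_subject(ds, s, cfg, log)
              for s in ds.subjects["subject"]]
    comp_rows = []
    for d in derivs:
        sc = d.components.scores
        kept = sc[sc["retained"]]
        for _, r in kept.iterrows():
            comp_rows.append({"subject": d.subject, "group": d.group,
                              "component": int(r["component"]),
                              "brain_score": r["brain_score"],
                              "dipole_x": r["dipole_x"],
                              "dipole_y": r["dipole_y"],
                              "dipole_z": r["dipole_z"]})
    comp_table = pd.DataFrame(comp_rows)
    n_src = len(ds.scenario.sources["young"])
    k = min(cfg.k_clusters, max(len(comp_table) - 1, 1), n_src * 3)
    cm = preprocess.cluster_components(comp_table, k=k, seed=cfg.kmeans_seed,
                                       outlier_sd=cfg.cluster_outlier_sd)
    cluster_map = {
        (r["subject"], int(r["component"])): int(r["cluster"])
        for _, r in cm.assignments.iterrows()
        if r["kept"] and r["cluster"] in cm.retained_clusters}
    comp_table.to_csv(outdir / "components.csv", index=False)

    conditions = [c for c in sim_cfg.conditions if c != "rest"]
    band_power, p2p, store = spectral_tables(derivs, cluster_map, cfg,
                                             conditions)
    band_power.to_csv(outdir / "band_power.csv", index=False)
    p2p.to_csv(outdir / "p2p.csv", index=False)

    contrasts = stats_stage(band_power, p2p, cfg)
    contrasts.to_csv(outdir / "contrasts.csv", index=False)
    pd.DataFrame(log).to_csv(outdir / "rejection_log.tsv", sep="\t",
                             index=False)

    manifest = {
        "scenario": scenario, "seed": sim_cfg.seed,
        "n_subjects": int(len(ds.subjects)),
        "n_retained_components": int(len(comp_table)),
        "retained_clusters": [int(c) for c in cm.retained_clusters],
        "n_band_power_rows": int(len(band_power)),
        "elapsed_s": round(time.time() - t0, 1),
        "outputs": sorted(p.name for p in outdir.glob("*.csv")),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
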