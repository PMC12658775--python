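"""Monte-Carlo error-rate and pattern-recovery studies.

These routines regenerate their own synthetic inputs from scratch on every
call (driven only by the given seed) and push them through the same public
analysis functions the pipeline uses, so they measure the behavior of the
shipped code, not cached artifacts.
"""

from __future__ import annotations

import numpy as np

from .config import GaitSpec, SourceSpec
from .core import DEFAULT_BANDS
from .spectral import epoch_walking, morlet_tf, timewarp_gait
from .stats import bootstrap_ersp_mask, lmm_contrasts, permutation_psd_test
from .synthgen import (_shaped_noise_bands, scenario_band_power_table,
                       simulate_gait)

__all__ = ["null_epoch_maps", "t1_null_flag_fraction", "t2_type_one_rate",
           "paper_like_detection_rates"]

_NULL_SOURCE = SourceSpec(name="null", aperiodic_offset=1.2,
                          aperiodic_exponent=1.5,
                          peaks=((10.0, 0.8, 2.0),))


def _source_signal(rng, n, fs, src=_NULL_SOURCE):
    parts = _shaped_noise_bands(rng, n, fs, src, DEFAULT_BANDS)
    return np.sum(list(parts.values()), axis=0)


def null_epoch_maps(seed: int, duration: float = 70.0, fs: float = 250.0,
                    freqs=None, n_grid: int = 100) -> np.ndarray:
    """Gait-warped ERSP epoch maps of a stationary (null) component.

    The component is 1/f background plus an unmodulated alpha oscillation;
    stride events come from the gait simulator, so the maps carry realistic
    stride-duration jitter but zero gait-phase power structure.  Returns
    (n_epochs, n_freq, n_grid) in dB.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    x = _source_signal(rng, n, fs)
    events, _, _ = simulate_gait(GaitSpec(), duration, seed + 1, fs=fs)
    es = epoch_walking(x[None, :], fs, events)
    freqs = np.arange(3.0, 41.0) if freqs is None else np.asarray(freqs)
    tf, times, _ = morlet_tf(es, freqs)
    warped, _, _ = timewarp_gait(tf, times, es, n_grid=n_grid)
    return warped[:, 0]


def t1_null_flag_fraction(n_replicates: int = 50, n_boot: int = 500,
                          seed: int = 0, n_grid: int = 100):
    """Mean FDR-flagged bin fraction of the bootstrap ERSP mask on null maps.

    Returns (mean_fraction, per-replicate fractions).  Each replicate uses
    an independent stationary epoch set with >= 40 epochs.
    """
    fracs = []
    for r in range(n_replicates):
        maps = null_epoch_maps(1000 * seed + 17 * r)
        if len(maps) < 40:
            raise RuntimeError(f"replicate {r} yielded only {len(maps)} epochs")
        m = bootstrap_ersp_mask(maps, n_boot=n_boot, seed=seed + r)
        fracs.append(float(m.mask.mean()))
    fracs = np.asarray(fracs)
    return float(fracs.mean()), fracs


def _subject_psds(rng, n_subjects, fs=250.0, duration=60.0,
                  fit_range=(3.0, 40.0)):
    from .spectral import compute_psd

    n = int(round(duration * fs))
    psds = []
    for _ in range(n_subjects):
        x = _source_signal(rng, n, fs)
        freqs, psd_db = compute_psd(x[None, :], fs, 2.0)
        sel = (freqs >= fit_range[0]) & (freqs <= fit_range[1])
        psds.append(psd_db[0, sel])
    return np.asarray(psds)


def t2_type_one_rate(n_datasets: int = 100, n_subjects: int = 20,
                     n_perm: int = 500, seed: int = 0):
    """Raw per-frequency type-I rate of the permutation PSD test.

    Every dataset's subjects share identical spectral-generating
    parameters; group labels are assigned at random.  Returns
    (mean_rate, per-replicate mean raw rejection rates)."""
    rng = np.random.default_rng(seed)
    rates = []
    labels = np.array(["a"] * (n_subjects // 2) + ["b"] * (n_subjects // 2))
    for r in range(n_datasets):
        psds = _subject_psds(rng, n_subjects)
        res = permutation_psd_test(psds, rng.permutation(labels), "age",
                                   n_perm=n_perm, seed=seed + 31 * r)
        rates.append(float((res.p_raw <= 0.05).mean()))
    rates = np.asarray(rates)
    return float(rates.mean()), rates


def paper_like_detection_rates(n_seeds: int = 10, n_young: int = 15,
                               n_old: int = 15, seed0: int = 100,
                               alpha: float = 0.05) -> dict:
    """Detection rates of the designed qualitative pattern across seeds.

    For each seed a fresh subject-level band-power table is drawn from the
    "paper-like" scenario and the mixed-model contrasts are run.  Reported
    rates: parieto-occipital alpha terrain x age interaction (young-only
    reduction), and sensorimotor beta terrain main effect with no
    interaction claimed."""
    hits = {"parietal_alpha_interaction": 0,
            "occipital_alpha_interaction": 0,
            "sensorimotor_beta_terrain_only": 0}
    for s in range(n_seeds):
        tab = scenario_band_power_table("paper-like", n_young, n_old,
                                        seed=seed0 + s)
        for key, cluster, band in (
                ("parietal_alpha_interaction", "parietal", "alpha"),
                ("occipital_alpha_interaction", "occipital", "alpha")):
            sub = tab[(tab.cluster == cluster) & (tab.band == band)]
            t = lmm_contrasts(sub, alpha=alpha).terms.set_index("term")
            if t.loc["terrain:age", "p"] < alpha:
                hits[key] += 1
        sub = tab[(tab.cluster == "sensorimotor_L") & (tab.band == "beta")]
        t = lmm_contrasts(sub, alpha=alpha).terms.set_index("term")
        if (t.loc["terrain", "p"] < alpha
                and t.loc["terrain:age", "p"] >= alpha):
            hits["sensorimotor_beta_terrain_only"] += 1
    return {k: v / n_seeds for k, v in hits.items()}
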