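"""Statistical machinery: FDR, bootstrap, permutation, mixed models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from gaiteeg.stats import (bootstrap_ersp_mask, cluster_permutation_tf,
                           fdr_bh, lmm_contrasts, permutation_psd_test)
from gaiteeg.synthgen import scenario_band_power_table


def _bh_reference(p, q):
    """Direct textbook BH step-up, written independently of the package."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    k_max = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= q * k / m:
            k_max = k
    rej = np.zeros(m, dtype=bool)
    rej[order[:k_max]] = True
    return rej


def test_fdr_matches_reference_and_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests
    for _ in range(20):
        p = rng.uniform(size=rng.integers(5, 200)) ** rng.uniform(0.5, 3)
        adj, rej = fdr_bh(p, 0.05)
        assert np.array_equal(rej, _bh_reference(p, 0.05))
        sm_rej, sm_adj = multipletests(p, 0.05, method="fdr_bh")[:2]
        assert np.allclose(adj, sm_adj)
        assert np.array_equal(rej, sm_rej)


@settings(max_examples=30, deadline=None)
@given(hst.lists(hst.floats(0.0, 1.0), min_size=2, max_size=60))
def test_fdr_properties(pvals):
    adj, rej = fdr_bh(np.array(pvals), 0.05)
    assert ((adj >= np.array(pvals) - 1e-12) & (adj <= 1.0)).all()
    assert np.array_equal(rej, _bh_reference(pvals, 0.05))


def test_fdr_rejects_invalid():
    with pytest.raises(ValueError):
        fdr_bh([0.2, 1.5])


def _null_epoch_maps(rng, n_ep=30, n_f=6, n_g=20):
    """Stationary maps: per-epoch random spectra, no gait-phase structure."""
    base = rng.normal(size=(n_ep, n_f, 1))
    return base + 0.5 * rng.normal(size=(n_ep, n_f, n_g))


def test_bootstrap_null_controlled_and_effect_detected(rng):
    null = _null_epoch_maps(rng)
    m0 = bootstrap_ersp_mask(null, n_boot=300, seed=1)
    assert m0.mask.mean() <= 0.05
    # inject a gait-locked modulation in two frequency rows
    g = np.linspace(0, 100, 20)
    mod = 1.5 * np.cos(2 * np.pi * g / 100)
    sig = _null_epoch_maps(rng)
    sig[:, 2:4, :] += mod[None, None, :]
    m1 = bootstrap_ersp_mask(sig, n_boot=300, seed=1)
    assert m1.mask[2:4].mean() > 0.5
    assert m1.mask[[0, 1, 4, 5]].mean() < 0.2
    with pytest.raises(ValueError):
        bootstrap_ersp_mask(null[:10], n_boot=50)


def test_permutation_age_detects_group_difference(rng):
    psds = rng.normal(size=(20, 40))
    labels = np.array(["young"] * 10 + ["old"] * 10)
    psds[10:, 15:20] += 1.5  # old differ in 5 bins
    res = permutation_psd_test(psds, labels, "age", n_perm=500, seed=2)
    assert res.mask[15:20].mean() > 0.5
    assert res.mask[:10].mean() <= 0.1
    with pytest.raises(ValueError):
        permutation_psd_test(psds, np.array(["a"] * 20), "age")


def test_permutation_terrain_detects_condition_effect(rng):
    psds = rng.normal(size=(12, 4, 30))
    psds[:, 3, 10:14] += 2.0  # one condition clearly deviates in 4 bins
    res = permutation_psd_test(psds, None, "terrain", n_perm=500, seed=3)
    assert res.mask[10:14].mean() > 0.5
    assert res.mask[20:].mean() <= 0.1


def test_cluster_permutation_finds_block(rng):
    a = rng.normal(size=(14, 10, 30))
    b = rng.normal(size=(14, 10, 30))
    a[:, 3:6, 10:20] += 2.0
    res = cluster_permutation_tf(a, b, n_perm=500, seed=4)
    assert res.mask[3:6, 10:20].mean() > 0.6
    assert res.mask[7:, :5].mean() < 0.1
    null = cluster_permutation_tf(rng.normal(size=(14, 10, 30)),
                                  rng.normal(size=(14, 10, 30)),
                                  n_perm=300, seed=5)
    assert null.mask.mean() < 0.05


def test_lmm_recovers_interaction_and_main_effects():
    tab = scenario_band_power_table("paper-like", 15, 15, seed=11)
    # parieto-occipital alpha: young-only terrain reduction -> interaction
    sub = tab[(tab.cluster == "parietal") & (tab.band == "alpha")]
    res = lmm_contrasts(sub)
    inter = res.terms.set_index("term")
    assert inter.loc["terrain:age", "p"] < 0.05
    assert res.model_variant == "with-interaction"
    assert res.pairwise is not None and "p_fdr" in res.pairwise
    # sensorimotor beta: common terrain effect, no interaction
    sub2 = tab[(tab.cluster == "sensorimotor_L") & (tab.band == "beta")]
    res2 = lmm_contrasts(sub2)
    t2 = res2.terms.set_index("term")
    assert t2.loc["terrain", "p"] < 0.05
    assert t2.loc["terrain:age", "p"] >= 0.05
    assert res2.model_variant == "refit-no-interaction"
    assert (res2.terms["partial_eta_sq"].between(0, 1)).all()


def test_lmm_outlier_exclusion_and_columns():
    tab = scenario_band_power_table("null", 8, 8, seed=4)
    sub = tab[(tab.cluster == "parietal") & (tab.band == "theta")].copy()
    sub.loc[sub.index[0], "value"] = 1e4  # absurd outlier, > 8 SD
    res = lmm_contrasts(sub)
    assert res.n_excluded == 1
    assert list(res.terms.columns) == ["term", "F", "df1", "df2", "p",
                                       "partial_eta_sq"]
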