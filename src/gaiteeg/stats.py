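"""Resampling significance tests and terrain-by-age mixed-model contrasts.

Implements the study's inference toolkit: bootstrap masking of intra-stride
ERSP fluctuations (4,000 iterations, BH-FDR across the time-frequency
grid), nonparametric permutation tests of flattened PSDs across frequency
(2,000 permutations, BH-FDR), cluster-based permutation tests in
time-frequency (10,000 permutations, max-sum statistic), Benjamini-
Hochberg FDR control, and linear mixed-effect models with a subject random
intercept, walking speed covariate, and an 8-SD outlier rule.  All alphas
default to 0.05 and all iteration counts are configurable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

__all__ = [
    "SigMask", "ContrastResult", "fdr_bh", "bootstrap_ersp_mask",
    "permutation_psd_test", "cluster_permutation_tf", "lmm_contrasts",
]


@dataclass
class SigMask:
    """Boolean significance grid with its provenance."""

    mask: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    method: str
    n_iterations: int
    alpha: float = 0.05
    correction: str = "fdr"
    extra: dict = field(default_factory=dict)


def fdr_bh(pvals, q: float = 0.05):
    """Benjamini-Hochberg step-up: adjusted p-values and the <= q mask."""
    p = np.asarray(pvals, dtype=float)
    flat = p.ravel()
    if ((flat < 0) | (flat > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = flat.size
    order = np.argsort(flat)
    ranked = flat[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    out = out.reshape(p.shape)
    return out, out <= q


def bootstrap_ersp_mask(
    epoch_maps: np.ndarray,
    alpha: float = 0.05,
    n_boot: int = 4000,
    seed: int = 0,
    q: float = 0.05,
) -> SigMask:
    """Bootstrap significance of intra-stride power fluctuations.

    epoch_maps is (n_epochs, n_freq, n_gait) in dB.  The per-bin statistic
    is the epoch mean of the deviation from each epoch's own gait-cycle
    mean.  The null resamples epochs with replacement while shuffling the
    gait axis within each epoch (destroying any gait-phase structure while
    preserving the marginal power distribution); two-sided p-values are
    BH-FDR corrected across the whole grid.
    """
    maps = np.asarray(epoch_maps, dtype=float)
    n_ep, n_f, n_g = maps.shape
    if n_ep < 20:
        raise ValueError("need at least 20 epochs for the bootstrap")
    rng = np.random.default_rng(seed)
    dev = maps - maps.mean(axis=2, keepdims=True)
    obs = dev.mean(axis=0)
    count = np.zeros((n_f, n_g), dtype=np.int64)
    abs_obs = np.abs(obs)
    for _ in range(n_boot):
        idx = rng.integers(n_ep, size=n_ep)
        perms = np.argsort(rng.random((n_ep, n_g)), axis=1)
        shuf = np.take_along_axis(dev[idx], perms[:, None, :], axis=2)
        count += np.abs(shuf.mean(axis=0)) >= abs_obs
    p_raw = (1.0 + count) / (n_boot + 1.0)
    p_adj, mask = fdr_bh(p_raw, q)
    return SigMask(mask=mask, p_raw=p_raw, p_adj=p_adj, method="bootstrap",
                   n_iterations=n_boot, alpha=alpha)


def _rm_anova_f(data: np.ndarray) -> np.ndarray:
    """Repeated-measures one-way F across conditions, per trailing column.

    data is (n_subjects, n_conditions, n_freq)."""
    n, k = data.shape[:2]
    grand = data.mean(axis=(0, 1))
    cond_m = data.mean(axis=0)
    subj_m = data.mean(axis=1)
    ss_cond = n * ((cond_m - grand) ** 2).sum(axis=0)
    resid = data - cond_m[None] - subj_m[:, None] + grand
    ss_err = (resid**2).sum(axis=(0, 1))
    df1, df2 = k - 1, (k - 1) * (n - 1)
    return (ss_cond / df1) / np.maximum(ss_err / df2, 1e-30)


def permutation_psd_test(
    psds: np.ndarray,
    labels,
    factor: str,
    alpha: float = 0.05,
    n_perm: int = 2000,
    seed: int = 0,
    q: float = 0.05,
) -> SigMask:
    """Nonparametric permutation test of flattened PSDs across frequency.

    factor="age" (between-subject): psds is (n_subjects, n_freq) and labels
    the group per subject; the statistic is the squared two-sample t and
    the null permutes group labels across subjects.  factor="terrain"
    (within-subject): psds is (n_subjects, n_conditions, n_freq); the
    statistic is the repeated-measures F and the null permutes condition
    labels within each subject.  Main effects only.  Raw p-values are
    BH-FDR corrected across frequency.
    """
    rng = np.random.default_rng(seed)
    psds = np.asarray(psds, dtype=float)
    if factor == "age":
        labels = np.asarray(labels)
        lvls = np.unique(labels)
        if len(lvls) != 2:
            raise ValueError("age factor needs exactly two groups")
        ga, gb = psds[labels == lvls[0]], psds[labels == lvls[1]]

        def stat(a, b):
            t = sps.ttest_ind(a, b, axis=0).statistic
            return t**2

        obs = stat(ga, gb)
        n_a = len(ga)
        pool = psds
        count = np.zeros_like(obs, dtype=np.int64)
        for _ in range(n_perm):
            perm = rng.permutation(len(pool))
            count += stat(pool[perm[:n_a]], pool[perm[n_a:]]) >= obs
    elif factor == "terrain":
        if psds.ndim != 3:
            raise ValueError("terrain factor needs (subjects, conditions, freq)")
        obs = _rm_anova_f(psds)
        count = np.zeros_like(obs, dtype=np.int64)
        n, k = psds.shape[:2]
        for _ in range(n_perm):
            perms = np.argsort(rng.random((n, k)), axis=1)
            shuffled = np.take_along_axis(psds, perms[:, :, None], axis=1)
            count += _rm_anova_f(shuffled) >= obs
    else:
        raise ValueError("factor must be 'age' or 'terrain'")
    p_raw = (1.0 + count) / (n_perm + 1.0)
    p_adj, mask = fdr_bh(p_raw, q)
    return SigMask(mask=mask, p_raw=p_raw, p_adj=p_adj,
                   method="permutation", n_iterations=n_perm, alpha=alpha)


def cluster_permutation_tf(
    group_a: np.ndarray,
    group_b: np.ndarray | None = None,
    alpha: float = 0.05,
    n_perm: int = 10000,
    seed: int = 0,
) -> SigMask:
    """Cluster-based permutation test on time-frequency maps.

    Two-sample mode: group_a (n_a, F, T) vs group_b (n_b, F, T), label
    permutation null.  One-sample mode (group_b=None): group_a holds
    difference maps tested against zero with a sign-flip null.  Bin-level
    t statistics are thresholded at the two-sided bin alpha; contiguous
    supra-threshold clusters are scored by their summed t (max-sum), and
    clusters whose score exceeds the permutation distribution of the
    maximum score at level alpha are retained.
    """
    rng = np.random.default_rng(seed)
    a = np.asarray(group_a, dtype=float)

    if group_b is None:
        if a.shape[0] < 8:
            raise ValueError("need at least 8 units")
        df = a.shape[0] - 1

        def stat(x):
            return sps.ttest_1samp(x, 0, axis=0).statistic

        def null_draw():
            signs = rng.choice([-1.0, 1.0], size=(a.shape[0], 1, 1))
            return stat(a * signs)

        t_obs = stat(a)
    else:
        b = np.asarray(group_b, dtype=float)
        if min(a.shape[0], b.shape[0]) < 8:
            raise ValueError("need at least 8 units per group")
        df = a.shape[0] + b.shape[0] - 2
        pool = np.concatenate([a, b], axis=0)
        n_a = a.shape[0]

        def stat(x, y):
            return sps.ttest_ind(x, y, axis=0).statistic

        def null_draw():
            perm = rng.permutation(len(pool))
            return stat(pool[perm[:n_a]], pool[perm[n_a:]])

        t_obs = stat(a, b)

    t_crit = sps.t.ppf(1 - alpha / 2, df)

    def cluster_scores(t_map):
        lab, n_lab = ndimage.label(np.abs(t_map) > t_crit)
        if n_lab == 0:
            return lab, np.array([])
        sums = ndimage.sum_labels(t_map, lab, index=np.arange(1, n_lab + 1))
        return lab, sums

    lab_obs, sums_obs = cluster_scores(t_obs)
    null_max = np.empty(n_perm)
    for i in range(n_perm):
        _, s = cluster_scores(null_draw())
        null_max[i] = np.abs(s).max() if len(s) else 0.0

    p_raw = np.ones_like(t_obs)
    mask = np.zeros(t_obs.shape, dtype=bool)
    cluster_p = []
    for ci, s in enumerate(sums_obs, start=1):
        p = (1.0 + np.sum(null_max >= abs(s))) / (n_perm + 1.0)
        cluster_p.append(p)
        p_raw[lab_obs == ci] = p
        if p <= alpha:
            mask[lab_obs == ci] = True
    return SigMask(mask=mask, p_raw=p_raw, p_adj=p_raw, method="cluster-permutation",
                   n_iterations=n_perm, alpha=alpha, correction="cluster",
                   extra={"t_obs": t_obs, "cluster_p": cluster_p,
                          "labels": lab_obs})


# ---------------------------------------------------------------------------
# linear mixed-effect contrasts
# ---------------------------------------------------------------------------

@dataclass
class ContrastResult:
    terms: pd.DataFrame          # term, F, df1, df2, p, partial_eta_sq
    pairwise: pd.DataFrame       # contrast, estimate, p, p_fdr
    model_variant: str           # with-interaction | refit-no-interaction
    n_excluded: int = 0


def _fit_lmm(data: pd.DataFrame, formula: str):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data, groups=data["subject"])
        try:
            res = model.fit(reml=True)
            if not np.isfinite(res.params).all():
                raise np.linalg.LinAlgError("non-finite parameters")
            return res, "mixed"
        except (np.linalg.LinAlgError, ValueError):
            logger.warning("singular mixed-model fit; falling back to OLS "
                           "with independent errors")
            ols = smf.ols(formula, data).fit()
            return ols, "ols"


def _wald_f(res, names, df2):
    """Wald F test of the listed coefficients being jointly zero."""
    exog_names = res.model.exog_names
    idx = [exog_names.index(n) for n in names]
    L = np.zeros((len(idx), len(exog_names)))
    for r, i in enumerate(idx):
        L[r, i] = 1.0
    # MixedLM params include variance terms; pad the restriction matrix
    k_extra = len(res.params) - len(exog_names)
    if k_extra > 0:
        L = np.hstack([L, np.zeros((len(idx), k_extra))])
    w = res.wald_test(L, scalar=True)
    chi2 = float(np.squeeze(w.statistic))
    df1 = len(idx)
    f = chi2 / df1 if w.distribution == "chi2" else chi2
    p = 1 - sps.f.cdf(f, df1, df2)
    eta = f * df1 / (f * df1 + df2)
    return f, df1, p, eta


def lmm_contrasts(
    table: pd.DataFrame,
    alpha: float = 0.05,
    outlier_sd: float = 8.0,
    reference_condition: str = "Flat",
    reference_group: str = "young",
) -> ContrastResult:
    """Terrain x age mixed model with speed covariate for one outcome.

    table needs columns subject, group, condition, speed, value.  Values
    beyond ``outlier_sd`` robust SDs (MAD scale) from the median are
    excluded; a linear mixed
    model with subject random intercept is fit; Wald F-tests are reported
    for the interaction and the two main effects with a between-within
    denominator-df approximation.  If the interaction is not significant
    the model is refit without it.  Pairwise terrain contrasts (within
    each group under an interaction, pooled otherwise) are BH-FDR
    adjusted.
    """
    data = table.dropna(subset=["value"]).copy()
    # robust center/scale (median, MAD in SD units): a gross outlier inflates
    # the plain sample SD so much that no value can ever exceed sqrt(n) SDs,
    # which would make the rule vacuous at these sample sizes
    med = data["value"].median()
    mad = (data["value"] - med).abs().median() * 1.4826
    scale = mad if mad > 0 else data["value"].std(ddof=1)
    if scale > 0:
        keep = (data["value"] - med).abs() <= outlier_sd * scale
        n_excluded = int((~keep).sum())
        data = data[keep]
    else:
        n_excluded = 0

    cond = f"C(condition, Treatment('{reference_condition}'))"
    grp = f"C(group, Treatment('{reference_group}'))"
    full = f"value ~ {cond} * {grp} + speed"
    res, kind = _fit_lmm(data, full)
    exog_names = res.model.exog_names
    inter_names = [n for n in exog_names if ":" in n]
    cond_names = [n for n in exog_names
                  if n.startswith("C(condition") and ":" not in n]
    grp_names = [n for n in exog_names
                 if n.startswith("C(group") and ":" not in n]
    n_obs = len(data)
    n_subj = data["subject"].nunique()
    df2 = max(n_obs - n_subj - len(exog_names) + 1, 1)

    rows = []
    f, d1, p, eta = _wald_f(res, inter_names, df2)
    rows.append({"term": "terrain:age", "F": f, "df1": d1, "df2": df2,
                 "p": p, "partial_eta_sq": eta})
    interaction_sig = p < alpha

    variant = "with-interaction"
    if not interaction_sig:
        variant = "refit-no-interaction"
        res, kind = _fit_lmm(data, f"value ~ {cond} + {grp} + speed")
        exog_names = res.model.exog_names
        cond_names = [n for n in exog_names
                      if n.startswith("C(condition") and ":" not in n]
        grp_names = [n for n in exog_names
                     if n.startswith("C(group") and ":" not in n]
        df2 = max(n_obs - n_subj - len(exog_names) + 1, 1)
    for term, names in (("terrain", cond_names), ("age", grp_names)):
        f, d1, p, eta = _wald_f(res, names, df2)
        rows.append({"term": term, "F": f, "df1": d1, "df2": df2, "p": p,
                     "partial_eta_sq": eta})

    pairwise = _pairwise_terrain(data, res, interaction_sig, df2)
    if len(pairwise):
        pairwise["p_fdr"] = fdr_bh(pairwise["p"].to_numpy())[0]
    return ContrastResult(terms=pd.DataFrame(rows), pairwise=pairwise,
                          model_variant=variant, n_excluded=n_excluded)


def _pairwise_terrain(data, res, interaction_sig, df2):
    """Estimated marginal terrain differences from the fixed effects."""
    conditions = sorted(data["condition"].unique())
    groups = sorted(data["group"].unique())
    exog_names = res.model.exog_names
    k_extra = len(res.params) - len(exog_names)
    params = np.asarray(res.params)[: len(exog_names)]
    cov = np.asarray(res.cov_params())[: len(exog_names), : len(exog_names)]

    def coef_vec(condition, group):
        """Fixed-effect design row for a cell (at mean speed)."""
        v = np.zeros(len(exog_names))
        for i, name in enumerate(exog_names):
            if name == "Intercept":
                v[i] = 1.0
            elif name == "speed":
                v[i] = data["speed"].mean()
            else:
                hit_c = f"[T.{condition}]" in name and "condition" in name
                hit_g = f"[T.{group}]" in name and "group" in name
                if ":" in name:
                    v[i] = 1.0 if (hit_c and hit_g) else 0.0
                elif "condition" in name:
                    v[i] = 1.0 if hit_c else 0.0
                elif "group" in name:
                    v[i] = 1.0 if hit_g else 0.0
        return v

    rows = []
    group_sets = groups if interaction_sig else [None]
    for g in group_sets:
        for i in range(len(conditions)):
            for j in range(i + 1, len(conditions)):
                if g is None:
                    L = np.mean([coef_vec(conditions[i], gg)
                                 - coef_vec(conditions[j], gg)
                                 for gg in groups], axis=0)
                    label = f"{conditions[i]}-{conditions[j]}"
                else:
                    L = coef_vec(conditions[i], g) - coef_vec(conditions[j], g)
                    label = f"{g}: {conditions[i]}-{conditions[j]}"
                est = float(L @ params)
                se = float(np.sqrt(L @ cov @ L))
                tval = est / max(se, 1e-30)
                p = 2 * (1 - sps.t.cdf(abs(tval), df2))
                rows.append({"contrast": label, "estimate": est,
                             "se": se, "t": tval, "p": p})
    return pd.DataFrame(rows)
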