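"""Spike-in normalized differential abundance across depletion experiments.

Size factors follow the spike-in convention: each sample's spike-in total
divided by the cross-sample mean of spike-in totals, so the factors average
to exactly 1 and normalized counts are on an absolute (per-spike) scale.
This is the right normalization when a depletion is expected to move most
of the miRNA complement in the same direction, which breaks the usual
median-of-ratios assumption.

The significance machinery is a deliberately simple negative-binomial Wald
test: per-feature method-of-moments dispersion (pooled within-group
variance), moderated toward the across-feature median, and a delta-method
standard error on the log2 fold change of group means.  With very few
replicates a raw per-feature moment estimate makes the Wald statistic
behave like a t variable read off a normal table; moderation across
features restores calibration at nominal levels.  This is an approximation
to a full GLM analysis, adequate for two-group contrasts with planted
effects of a unit or more.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import CountMatrix, ValidationError

__all__ = [
    "spike_size_factors",
    "normalized_counts",
    "log2_fold_change",
    "nb_test",
    "bh_adjust",
    "diff_table",
]

LN2_SQ = np.log(2.0) ** 2


def spike_size_factors(cm: CountMatrix) -> pd.Series:
    """Per-sample size factor: spike-in reads / mean spike-in reads.

    Normalized count = raw / size factor; mean(sf) == 1 by construction.
    """
    spikes = cm.spike_counts.astype(float)
    if (spikes <= 0).any():
        raise ValidationError("all samples must have positive spike-in totals")
    return spikes / spikes.mean()


def normalized_counts(cm: CountMatrix, sf: pd.Series | None = None) -> pd.DataFrame:
    sf = spike_size_factors(cm) if sf is None else sf
    return cm.counts.astype(float).div(sf, axis=1)


def _group_columns(cm: CountMatrix, contrast: tuple[str, str]):
    treat, ctrl = contrast
    t_cols = cm.samples_for(treat)
    c_cols = cm.samples_for(ctrl)
    if not t_cols or not c_cols:
        missing = treat if not t_cols else ctrl
        raise ValidationError(f"condition {missing!r} has no samples")
    return t_cols, c_cols


def log2_fold_change(
    cm: CountMatrix,
    sf: pd.Series,
    contrast: tuple[str, str],
    pseudocount: float = 0.5,
) -> pd.Series:
    """log2((mean normalized treat + pc) / (mean normalized ctrl + pc))."""
    t_cols, c_cols = _group_columns(cm, contrast)
    norm = cm.counts.astype(float).div(sf, axis=1)
    m_t = norm[t_cols].mean(axis=1)
    m_c = norm[c_cols].mean(axis=1)
    return np.log2(m_t + pseudocount) - np.log2(m_c + pseudocount)


def nb_test(
    cm: CountMatrix,
    sf: pd.Series,
    contrast: tuple[str, str],
    pseudocount: float = 0.5,
    moderate_dispersion: bool = True,
) -> pd.DataFrame:
    """Two-group NB Wald test on spike-normalized counts.

    Dispersion alpha (Var = mu + alpha mu^2) is estimated per feature by
    method of moments from the pooled within-group variance,
    ``alpha = max(0, (s2 - m) / m^2)``, then averaged 50:50 with the
    across-feature median (``moderate_dispersion``).  The Wald statistic is
    lfc / SE(lfc) with a delta-method SE under NB(mu_g, alpha) per group
    and a two-sided normal p value.

    Returns a DataFrame with baseMean (mean normalized count over ALL
    samples), lfc, and p.
    """
    t_cols, c_cols = _group_columns(cm, contrast)
    if len(t_cols) < 2 or len(c_cols) < 2:
        raise ValidationError(
            "need >= 2 replicates per condition for a test; report lfc only"
        )
    norm = cm.counts.astype(float).div(sf, axis=1)
    T = norm[t_cols].to_numpy()
    C = norm[c_cols].to_numpy()
    n_t, n_c = T.shape[1], C.shape[1]

    m_t, m_c = T.mean(axis=1), C.mean(axis=1)
    v_t = T.var(axis=1, ddof=1)
    v_c = C.var(axis=1, ddof=1)
    s2 = ((n_t - 1) * v_t + (n_c - 1) * v_c) / (n_t + n_c - 2)
    m_pool = (n_t * m_t + n_c * m_c) / (n_t + n_c)

    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(m_pool > 0, (s2 - m_pool) / np.square(m_pool), 0.0)
    alpha = np.clip(alpha, 0.0, None)
    if moderate_dispersion and len(alpha):
        expressed = m_pool > 0
        alpha0 = float(np.median(alpha[expressed])) if expressed.any() else 0.0
        alpha = 0.5 * (alpha + alpha0)

    lfc = np.log2(m_t + pseudocount) - np.log2(m_c + pseudocount)
    var_mt = (m_t + alpha * np.square(m_t)) / n_t
    var_mc = (m_c + alpha * np.square(m_c)) / n_c
    var_lfc = (
        var_mt / np.square(m_t + pseudocount) + var_mc / np.square(m_c + pseudocount)
    ) / LN2_SQ
    se = np.sqrt(var_lfc)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / se, 0.0)
    p = np.where(se > 0, 2.0 * stats.norm.sf(np.abs(z)), 1.0)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    return pd.DataFrame(
        {
            "baseMean": norm.mean(axis=1).to_numpy(),
            "lfc": lfc,
            "p": p,
        },
        index=cm.counts.index,
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def diff_table(
    cm: CountMatrix,
    contrast: tuple[str, str],
    pseudocount: float = 0.5,
    base_mean_filter: float = 10.0,
) -> pd.DataFrame:
    """Full per-contrast results: baseMean, lfc, p, p_adj, flag_low."""
    sf = spike_size_factors(cm)
    res = nb_test(cm, sf, contrast, pseudocount=pseudocount)
    res["p_adj"] = bh_adjust(res["p"].to_numpy())
    res["flag_low"] = res["baseMean"] < base_mean_filter
    return res
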