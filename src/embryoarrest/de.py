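"""Per-feature differential expression between sample groups.

The workhorse is a simplified negative-binomial Wald test on size-factor
normalized counts: per-gene dispersion by method of moments pooled within
groups, a delta-method standard error for the log fold change, a two-sided
normal p-value, and Benjamini-Hochberg correction.  A feature is called
differentially expressed when it changes at least ``2**fc_threshold_log2``
fold with q <= q_threshold (defaults: 4-fold, q <= 0.01).

Deliberate simplifications relative to full DESeq2-style machinery: no
dispersion shrinkage toward a fitted trend, no outlier (Cook's) filtering,
and no fold-change shrinkage — downstream logic only consumes the
fold/q-value flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .datamodel import AnalysisConfig, ExpressionMatrix

log = logging.getLogger("embryoarrest")

LN2_SQ = np.log(2.0) ** 2
DISPERSION_FLOOR = 1e-8
MEAN_FLOOR = 0.5


@dataclass
class DETable:
    """Result of one two-group contrast.

    ``table`` has one row per tested feature (feature_id index) with columns
    base_mean, log2fc (group B over group A), p, q, is_de, direction;
    ``excluded`` lists features with zero counts in every sample of both
    groups, which are not tested.
    """

    table: pd.DataFrame
    excluded: list[str]
    params: dict = field(default_factory=dict)

    @property
    def n_de(self) -> int:
        return int(self.table["is_de"].sum())

    def de_features(self, direction: Optional[str] = None) -> list[str]:
        t = self.table[self.table["is_de"]]
        if direction is not None:
            t = t[t["direction"] == direction]
        return t.index.tolist()


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def welch_t(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Welch's t test (unequal variances, Welch-Satterthwaite df)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Welch's t requires >= 2 values per side")
    res = scipy.stats.ttest_ind(a, b, equal_var=False)
    t, p = float(res.statistic), float(res.pvalue)
    if not np.isfinite(t):  # identical constant inputs
        t, p = 0.0, 1.0
    return t, p


def _check_groups(
    m: ExpressionMatrix, group_a: Sequence[str], group_b: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)[:5]}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    return m.sample_index(group_a), m.sample_index(group_b)


def nb_wald_de(
    m: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    size_factors: pd.Series,
    config: Optional[AnalysisConfig] = None,
) -> DETable:
    """Simplified NB Wald test of group B versus group A on raw counts.

    Per feature: size-factor normalized group means (floored at 0.5),
    log2fc = log2(muB / muA), pooled method-of-moments NB dispersion
    (var = mu + alpha mu^2) floored at 1e-8, Wald SE of the log fold change
    from the NB variance of the two group means, two-sided normal p and BH q
    over tested features.  Features with zero counts in all samples of both
    groups are excluded and reported separately.
    """
    cfg = config or AnalysisConfig()
    m.require_layer("raw")
    ia, ib = _check_groups(m, group_a, group_b)
    sf = size_factors.reindex(m.sample_ids)
    if sf.isna().any():
        raise ValueError("size factors missing for some samples")
    y = m.values / sf.to_numpy()[None, :]
    ya, yb = y[:, ia], y[:, ib]
    na, nb = ya.shape[1], yb.shape[1]

    nonzero = (m.values[:, np.concatenate([ia, ib])].sum(axis=1)) > 0
    excluded = list(np.asarray(m.feature_ids, dtype=object)[~nonzero])
    ya, yb = ya[nonzero], yb[nonzero]
    fids = np.asarray(m.feature_ids, dtype=object)[nonzero]

    mean_a = np.maximum(ya.mean(axis=1), MEAN_FLOOR)
    mean_b = np.maximum(yb.mean(axis=1), MEAN_FLOOR)
    log2fc = np.log2(mean_b / mean_a)

    var_a = ya.var(axis=1, ddof=1)
    var_b = yb.var(axis=1, ddof=1)
    alpha_a = (var_a - mean_a) / mean_a**2
    alpha_b = (var_b - mean_b) / mean_b**2
    alpha = ((na - 1) * alpha_a + (nb - 1) * alpha_b) / (na + nb - 2)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)

    # delta method: Var(ln muhat) = (1/mu + alpha)/n for an NB mean of n draws
    se_log2 = np.sqrt(
        ((1.0 / mean_a + alpha) / na + (1.0 / mean_b + alpha) / nb) / LN2_SQ
    )
    wald = log2fc / se_log2
    p = 2.0 * scipy.stats.norm.sf(np.abs(wald))
    q = bh_adjust(p)

    is_de = (np.abs(log2fc) >= cfg.fc_threshold_log2) & (q <= cfg.q_threshold)
    direction = np.where(~is_de, "none", np.where(log2fc > 0, "up", "down"))
    table = pd.DataFrame(
        {
            "base_mean": (mean_a * na + mean_b * nb) / (na + nb),
            "log2fc": log2fc,
            "stat": wald,
            "p": p,
            "q": q,
            "is_de": is_de,
            "direction": direction,
        },
        index=pd.Index(fids, name="feature_id"),
    )
    log.info(
        "NB Wald %d vs %d samples: %d/%d features DE",
        na, nb, int(is_de.sum()), len(table),
    )
    return DETable(
        table=table,
        excluded=excluded,
        params={
            "group_a": list(group_a),
            "group_b": list(group_b),
            "fc_threshold_log2": cfg.fc_threshold_log2,
            "q_threshold": cfg.q_threshold,
        },
    )


def de_count(
    m: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    size_factors: pd.Series,
    config: Optional[AnalysisConfig] = None,
) -> int:
    """Number of features passing the DE rule for one contrast."""
    return nb_wald_de(m, group_a, group_b, size_factors, config).n_de
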