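"""Gene-set activity scores, TE expression fraction, and preranked GSEA.

Set activity is the sum (or mean) of per-gene Z-scores over a set's members,
as used for ribosome/nucleosome/p53-target rankings and for the 2-D
metabolic-state plots (glycolysis on x, oxidative phosphorylation on y).
Preranked GSEA is the classic weighted Kolmogorov-Smirnov enrichment
statistic with gene-label permutations for the normalized enrichment score.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix, GeneSetCollection
from .de import bh_adjust

log = logging.getLogger("embryoarrest")


def set_score(
    z: ExpressionMatrix,
    sets: GeneSetCollection,
    reduction: str = "sum",
    min_present: float = 0.5,
) -> pd.DataFrame:
    """Per-sample activity score of each gene set (samples x sets).

    ``reduction`` is ``sum`` or ``mean`` over the set members present in the
    matrix; members missing from the matrix are dropped with a warning, and
    a set with fewer than ``min_present`` of its members present is an error.
    """
    z.require_layer("zscore")
    if reduction not in ("sum", "mean"):
        raise ValueError("reduction must be 'sum' or 'mean'")
    present = set(map(str, z.feature_ids))
    out = {}
    for name in sets.names():
        members = sets[name]
        found = [g for g in members if g in present]
        if len(found) < min_present * len(members):
            raise ValueError(
                f"set {name!r}: only {len(found)}/{len(members)} members present"
            )
        if len(found) < len(members):
            log.warning("set %s: %d members missing", name, len(members) - len(found))
        vals = z.values[z.feature_index(found), :]
        out[name] = vals.sum(axis=0) if reduction == "sum" else vals.mean(axis=0)
    df = pd.DataFrame(out, index=pd.Index(z.sample_ids, name="sample_id"))
    df.attrs["reduction"] = reduction
    return df


def rank_samples(scores: pd.DataFrame, set_name: str) -> list[str]:
    """Samples in descending score order for one set; ties break by id."""
    if set_name not in scores.columns:
        raise ValueError(f"unknown set {set_name!r}")
    s = scores[set_name]
    order = sorted(s.index, key=lambda sid: (-s[sid], sid))
    return order


def te_fraction(
    m: ExpressionMatrix,
    ann: pd.DataFrame,
    samples: Optional[Sequence[str]] = None,
) -> pd.Series:
    """Percent of normalized tags mapping to TE features, per sample."""
    m.require_layer("gc_normalized", "size_normalized")
    sub = m.subset_samples(list(samples)) if samples is not None else m
    is_te = ann["kind"].reindex(sub.feature_ids).eq("TE").to_numpy()
    if not is_te.any():
        raise ValueError("no TE features in matrix")
    totals = sub.values.sum(axis=0)
    if (totals == 0).any():
        bad = sub.sample_ids[np.flatnonzero(totals == 0)[0]]
        raise ValueError(f"sample {bad!r} has zero total signal")
    frac = 100.0 * sub.values[is_te, :].sum(axis=0) / totals
    return pd.Series(frac, index=sub.sample_ids, name="te_percent")


def metabolic_coordinates(
    scores: pd.DataFrame, x_set: str, y_set: str
) -> pd.DataFrame:
    """2-D metabolic-state coordinates: (x_set score, y_set score) per sample."""
    for name in (x_set, y_set):
        if name not in scores.columns:
            raise ValueError(f"set {name!r} not scored")
    return pd.DataFrame(
        {"x": scores[x_set], "y": scores[y_set]}, index=scores.index
    )


# ---------------------------------------------------------------------------
# Preranked GSEA
# ---------------------------------------------------------------------------

def _running_es(
    positions: np.ndarray, weights_at_pos: np.ndarray, total_w: np.ndarray, n_total: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Enrichment score(s) from sorted hit positions.

    ``positions``: (batch, m) sorted 0-based hit indices in the ranking;
    ``weights_at_pos``: matching |metric|^p weights; ``total_w``: (batch,)
    weight sums.  Returns (es, peak_kind, peak_index) where peak_kind is +1
    when the extremum is just after a hit and -1 when just before, and
    peak_index is the hit ordinal of the extremum (for the leading edge).
    The running sum gains w/W at each hit and loses 1/(N-m) per miss, so its
    extrema sit adjacent to hits and only those points need evaluating.
    """
    batch, m = positions.shape
    miss = 1.0 / (n_total - m)
    ranks = np.arange(m)[None, :]
    hit_cum = np.cumsum(weights_at_pos, axis=1) / total_w[:, None]
    after = hit_cum - (positions + 1 - (ranks + 1)) * miss
    before = hit_cum - weights_at_pos / total_w[:, None] - (positions - ranks) * miss
    i_max = np.argmax(after, axis=1)
    i_min = np.argmin(before, axis=1)
    rows = np.arange(batch)
    hi = after[rows, i_max]
    lo = before[rows, i_min]
    take_hi = np.abs(hi) >= np.abs(lo)
    es = np.where(take_hi, hi, lo)
    peak_kind = np.where(take_hi, 1, -1)
    peak_index = np.where(take_hi, i_max, i_min)
    return es, peak_kind, peak_index


def gsea_preranked(
    ranking: pd.Series,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    weight_p: float = 1.0,
    seed: int = 0,
    min_perm_warn: int = 100,
) -> pd.DataFrame:
    """Preranked GSEA with gene-label permutations.

    ``ranking`` maps feature id -> real metric (e.g. a signed Wald
    statistic); features are ordered by decreasing metric with lexicographic
    tie-breaks.  ES is the maximal deviation of the weighted running sum
    (hit increments |metric|^weight_p normalized to the set total, miss
    decrements 1/(N - m)); NES divides ES by the mean |ES| of same-sign
    scores from ``n_perm`` random same-size gene sets, the permutation p uses
    the same-sign tail with a +1 correction, and q is BH over the tested
    sets.  The leading edge is the members at or before the ES extremum.
    Fixed seed gives bit-identical output.
    """
    metric = ranking.astype(float)
    if not np.isfinite(metric.to_numpy()).all():
        raise ValueError("ranking metric must be finite")
    if n_perm < min_perm_warn:
        log.warning("n_perm=%d is small; NES/p will be coarse", n_perm)
    order = sorted(metric.index, key=lambda f: (-metric[f], f))
    ordered = np.asarray(order, dtype=object)
    vals = metric[order].to_numpy()
    n_total = len(ordered)
    pos_of = {f: i for i, f in enumerate(ordered)}
    w_all = np.abs(vals) ** weight_p

    rng = np.random.default_rng(seed)
    perm_cache: dict[int, np.ndarray] = {}

    def perm_es(m: int) -> np.ndarray:
        if m not in perm_cache:
            mat = np.empty((n_perm, m), dtype=np.int64)
            for i in range(n_perm):
                mat[i] = rng.choice(n_total, size=m, replace=False)
            mat.sort(axis=1)
            wp = w_all[mat]
            total = wp.sum(axis=1)
            total = np.where(total == 0, 1.0, total)
            es, _, _ = _running_es(mat, wp, total, n_total)
            perm_cache[m] = es
        return perm_cache[m]

    rows = []
    for name in sets.names():
        members = sets[name]
        missing = [g for g in members if g not in pos_of]
        if missing:
            raise ValueError(
                f"set {name!r}: {len(missing)} members absent from the ranking"
            )
        msize = len(members)
        if msize >= n_total:
            raise ValueError(f"set {name!r} covers the whole ranking")
        pos = np.sort(np.array([pos_of[g] for g in members], dtype=np.int64))
        wp = w_all[pos][None, :]
        total = np.array([max(wp.sum(), 1e-300)])
        es_arr, kind, peak = _running_es(pos[None, :], wp, total, n_total)
        es = float(es_arr[0])
        if kind[0] > 0:
            leading = list(ordered[pos[: peak[0] + 1]])
        else:
            leading = list(ordered[pos[peak[0]:]])
        null = perm_es(msize)
        same_sign = null[null > 0] if es >= 0 else -null[null < 0]
        if same_sign.size:
            nes = es / same_sign.mean() if es >= 0 else -abs(es) / same_sign.mean()
            p = (1.0 + float((same_sign >= abs(es)).sum())) / (1.0 + same_sign.size)
        else:
            nes, p = 0.0, 1.0
        rows.append(
            {
                "set_name": name,
                "size": msize,
                "es": es,
                "nes": nes,
                "p": p,
                "leading_edge": leading,
                "n_permutations": n_perm,
            }
        )
    out = pd.DataFrame(rows).set_index("set_name")
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out


def wald_ranking(de_table: pd.DataFrame) -> pd.Series:
    """Signed Wald statistic as the default GSEA ranking metric."""
    return de_table["stat"].rename("metric")
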