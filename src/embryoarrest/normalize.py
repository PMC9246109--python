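"""Depth and GC-content normalization to normalized tag counts (NTC).

The processing chain is: raw counts -> median-of-ratios size factors ->
within-sample full-quantile GC normalization (binned by GC content) ->
log2(NTC + 1) -> per-feature Z-scores.  Each step returns a new
ExpressionMatrix with the appropriate layer tag.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix

log = logging.getLogger("embryoarrest")


def size_factors_median_of_ratios(m: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For every gene expressed in all samples the ratio of its count to its
    across-sample geometric mean is formed; the per-sample median of these
    ratios is the size factor.  Requires at least one gene positive in every
    sample.
    """
    m.require_layer("raw")
    counts = m.values
    positive = np.all(counts > 0, axis=1)
    if not positive.any():
        raise ValueError(
            "no gene is positive in all samples; median-of-ratios undefined "
            "(consider a pseudo-reference fallback on filtered genes)"
        )
    sub = counts[positive, :]
    log_geomean = np.mean(np.log(sub), axis=1)
    ratios = sub / np.exp(log_geomean)[:, None]
    sf = np.median(ratios, axis=0)
    sf = sf / np.exp(np.mean(np.log(sf)))
    out = pd.Series(sf, index=m.sample_ids, name="size_factor")
    log.info("size factors from %d reference genes", int(positive.sum()))
    return out


def apply_size_factors(m: ExpressionMatrix, sf: pd.Series) -> ExpressionMatrix:
    m.require_layer("raw")
    factors = sf.reindex(m.sample_ids)
    if factors.isna().any():
        missing = factors.index[factors.isna()].tolist()
        raise ValueError(f"size factors missing for samples {missing[:5]}")
    return m.with_values(m.values / factors.to_numpy()[None, :], "size_normalized")


def gc_normalize(
    m: ExpressionMatrix,
    ann: pd.DataFrame,
    n_bins: int = 10,
    min_bin_features: int = 10,
) -> ExpressionMatrix:
    """Within-sample full-quantile normalization across GC-content bins.

    Gene features with a known GC fraction are split into ``n_bins``
    equal-occupancy bins; within each sample, every bin's value distribution
    is quantile-mapped onto the pooled distribution of all binned features in
    that sample, removing any smooth dependence of expression on GC content
    while preserving ranks within bins.  Features without a GC value (TE
    aggregates) pass through unchanged; the per-sample total over binned
    features is preserved exactly by a final rescale.
    """
    m.require_layer("size_normalized")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2 (single-bin normalization is a no-op)")
    gc = pd.to_numeric(ann["gc_fraction"].reindex(m.feature_ids), errors="coerce")
    is_gene = ann["kind"].reindex(m.feature_ids).eq("gene").to_numpy()
    has_gc = gc.notna().to_numpy() & is_gene
    n_gene = int(is_gene.sum())
    if n_gene and has_gc.sum() < 0.9 * n_gene:
        raise ValueError(
            f"gc_fraction known for only {has_gc.sum()}/{n_gene} gene features "
            "(>= 90% required)"
        )
    binned_idx = np.flatnonzero(has_gc)
    order = binned_idx[np.argsort(gc.to_numpy()[binned_idx], kind="stable")]
    bins = np.array_split(order, n_bins)
    smallest = min(len(b) for b in bins)
    if smallest < min_bin_features:
        raise ValueError(
            f"a GC bin has only {smallest} features (< {min_bin_features}); "
            "use fewer bins"
        )

    values = m.values.copy()
    for j in range(m.n_samples):
        col = values[:, j]
        pooled = np.sort(col[binned_idx])
        total_before = col[binned_idx].sum()
        for b in bins:
            v = col[b]
            ranks = np.argsort(v, kind="stable")
            q = (np.arange(len(b)) + 0.5) / len(b)
            mapped = np.quantile(pooled, q)
            new = np.empty_like(v)
            new[ranks] = mapped
            col[b] = new
        total_after = col[binned_idx].sum()
        if total_after > 0:
            col[binned_idx] *= total_before / total_after
        values[:, j] = col
    out = m.with_values(values, "gc_normalized")
    log.info("GC-normalized %d features in %d bins", len(binned_idx), n_bins)
    return out


def log2_ntc(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Elementwise log2(NTC + pseudocount)."""
    m.require_layer("size_normalized", "gc_normalized")
    if np.any(m.values < 0):
        raise ValueError("negative value in normalized matrix")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return m.with_values(np.log2(m.values + pseudocount), "log2ntc")


def zscore_by_feature(
    m: ExpressionMatrix, reference_samples: Optional[Sequence[str]] = None
) -> ExpressionMatrix:
    """Per-feature Z-scores against a reference sample set.

    Each feature is centred on the reference mean and scaled by the reference
    population standard deviation (ddof=0); the reference defaults to all
    samples.  Zero-variance features yield all-zero Z rows (logged).
    """
    m.require_layer("log2ntc")
    if reference_samples is None:
        ref = np.arange(m.n_samples)
    else:
        ref = m.sample_index(reference_samples)
    if len(ref) < 2:
        raise ValueError("need >= 2 reference samples for Z-scoring")
    refvals = m.values[:, ref]
    mean = refvals.mean(axis=1)
    sd = refvals.std(axis=1, ddof=0)
    flat = sd == 0
    if flat.any():
        log.warning("%d zero-variance features set to Z = 0", int(flat.sum()))
    safe_sd = np.where(flat, 1.0, sd)
    z = (m.values - mean[:, None]) / safe_sd[:, None]
    z[flat, :] = 0.0
    return m.with_values(z, "zscore")
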