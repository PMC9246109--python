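"""Expression-based karyotyping: whole-chromosome gains and losses from RNA.

Each chromosome's share of a sample's normalized gene expression is compared
with stage-matched reference embryos; a robust Z-score (median centre, MAD
scale) beyond the threshold calls a gain (z > t) or loss (z < -t).  Robust
statistics are used because real reference stages themselves contain true
aneuploids.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import CHROMOSOMES, ExpressionMatrix

log = logging.getLogger("embryoarrest")

MAD_SCALE = 1.4826  # consistency factor for normal data


def chromosome_proportions(
    m: ExpressionMatrix,
    ann: pd.DataFrame,
    samples: Optional[Sequence[str]] = None,
    autosomes_only: bool = False,
) -> pd.DataFrame:
    """Per-sample share of normalized signal on each chromosome.

    Only gene features with a placed chromosome contribute; TE aggregates
    (chromosome "NA") are excluded.  Rows sum to 1.
    """
    m.require_layer("gc_normalized", "size_normalized")
    sub = m.subset_samples(list(samples)) if samples is not None else m
    chrom = ann["chromosome"].reindex(sub.feature_ids).fillna("NA")
    kind = ann["kind"].reindex(sub.feature_ids)
    keep_chroms = [c for c in CHROMOSOMES if not (autosomes_only and c in ("chrX", "chrY"))]
    keep = kind.eq("gene").to_numpy() & chrom.isin(keep_chroms).to_numpy()
    values = sub.values[keep, :]
    chrom_kept = chrom.to_numpy()[keep]
    sums = pd.DataFrame(
        {c: values[chrom_kept == c, :].sum(axis=0) for c in keep_chroms},
        index=sub.sample_ids,
    )
    totals = sums.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero placed-gene signal")
    return sums.div(totals, axis=0)


def dosage_zscores(
    props: pd.DataFrame,
    sample_table: pd.DataFrame,
    min_reference: int = 5,
    pool_stages: bool = False,
) -> pd.DataFrame:
    """Robust per-chromosome Z-scores against stage-matched normal references.

    For each stage, the reference is the normal samples of that stage; every
    sample at the stage (normal, arrested or treated) is scored against it:
    z = (p - median_ref) / (1.4826 * MAD_ref), falling back to the standard
    deviation when the MAD is zero.  ``pool_stages`` scores everything
    against the pooled normal reference instead (for small stage groups).
    """
    st = sample_table.reindex(props.index)
    if st["stage"].isna().any():
        missing = st.index[st["stage"].isna()].tolist()
        raise ValueError(f"samples missing from sample table: {missing[:5]}")
    normal = st["group"] == "normal"
    z = pd.DataFrame(np.nan, index=props.index, columns=props.columns)

    def score(block: pd.DataFrame, ref: pd.DataFrame, label: str) -> None:
        if len(ref) < min_reference:
            raise ValueError(
                f"reference group {label!r} has {len(ref)} normal samples "
                f"(< {min_reference}); consider pool_stages=True"
            )
        centre = ref.median(axis=0)
        mad = (ref - centre).abs().median(axis=0) * MAD_SCALE
        sd = ref.std(axis=0, ddof=1)
        scale = mad.where(mad > 0, sd)
        if (scale <= 0).any():
            bad = scale.index[scale <= 0][0]
            raise ValueError(f"zero dispersion for chromosome {bad!r} in {label!r}")
        z.loc[block.index] = (block - centre) / scale

    if pool_stages:
        score(props, props.loc[normal], "pooled")
    else:
        for stage, block in props.groupby(st["stage"], sort=False):
            ref = block.loc[normal.reindex(block.index).to_numpy()]
            score(block, ref, stage)
    return z


def call_aneuploidy(
    z: pd.DataFrame, props: pd.DataFrame, threshold: float = 3.0
) -> tuple[pd.DataFrame, pd.Series]:
    """Gain/neutral/loss calls per (sample, chromosome) plus per-sample flags.

    A sample is aneuploid when at least one chromosome is non-neutral.
    Returns a long-format call table and a boolean per-sample Series.
    """
    if not np.isfinite(z.to_numpy()).all():
        raise ValueError("non-finite Z-scores")
    call = np.where(z > threshold, "gain", np.where(z < -threshold, "loss", "neutral"))
    long = (
        pd.DataFrame(call, index=z.index, columns=z.columns)
        .stack()
        .rename("call")
        .reset_index()
    )
    long.columns = ["sample_id", "chromosome", "call"]
    long["z"] = z.stack().to_numpy()
    long["proportion"] = props.stack().reindex(
        pd.MultiIndex.from_frame(long[["sample_id", "chromosome"]])
    ).to_numpy()
    flags = (
        long[long["call"] != "neutral"].groupby("sample_id").size()
        .reindex(z.index, fill_value=0) > 0
    )
    flags.name = "aneuploid"
    log.info("aneuploidy: %d/%d samples flagged at |z| > %g",
             int(flags.sum()), len(flags), threshold)
    return long, flags


def summarize_by_stage(
    calls: pd.DataFrame, flags: pd.Series, sample_table: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aneuploid counts per stage and gain/loss tallies per chromosome."""
    st = sample_table.reindex(flags.index)
    by_stage = (
        pd.DataFrame({"stage": st["stage"], "aneuploid": flags})
        .groupby("stage", sort=False)
        .agg(n_samples=("aneuploid", "size"), n_aneuploid=("aneuploid", "sum"))
    )
    by_stage["fraction"] = by_stage["n_aneuploid"] / by_stage["n_samples"]
    nonneutral = calls[calls["call"] != "neutral"]
    by_chrom = (
        nonneutral.groupby(["chromosome", "call"]).size().unstack(fill_value=0)
        .reindex(columns=["gain", "loss"], fill_value=0)
    )
    return by_stage.reset_index(), by_chrom.reset_index()
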