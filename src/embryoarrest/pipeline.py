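"""End-to-end orchestration of the analysis stages on one dataset.

Bundles the normalization chain and the downstream modules so callers (CLI,
tests, batch evaluations) can run the whole analysis with one call and pick
the pieces they need.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .datamodel import AnalysisConfig, ExpressionMatrix
from . import normalize as enorm
from .mzt import MZTSets, classify_mzt_failure, derive_mzt_sets, mzt_scores
from .arrest_typing import TypingResult, type_arrested_embryos
from .aneuploidy import call_aneuploidy, chromosome_proportions, dosage_zscores
from .signatures import te_fraction

log = logging.getLogger("embryoarrest")


@dataclass
class PipelineResult:
    size_factors: pd.Series
    m_size: ExpressionMatrix
    m_gc: ExpressionMatrix
    m_log: ExpressionMatrix
    m_z: ExpressionMatrix
    mzt_sets: Optional[MZTSets] = None
    mzt_table: Optional[pd.DataFrame] = None
    mzt_cutoff: Optional[float] = None
    typing: Optional[TypingResult] = None
    chromosome_props: Optional[pd.DataFrame] = None
    dosage_z: Optional[pd.DataFrame] = None
    aneuploidy_calls: Optional[pd.DataFrame] = None
    aneuploid: Optional[pd.Series] = None
    te_percent: Optional[pd.Series] = None


def normalize_chain(
    m: ExpressionMatrix, ann: pd.DataFrame, config: Optional[AnalysisConfig] = None
) -> PipelineResult:
    """Raw counts -> size factors -> GC-normalized NTC -> log2 -> Z."""
    cfg = config or AnalysisConfig()
    sf = enorm.size_factors_median_of_ratios(m)
    m_size = enorm.apply_size_factors(m, sf)
    m_gc = enorm.gc_normalize(m_size, ann, n_bins=cfg.gc_bins)
    m_log = enorm.log2_ntc(m_gc, pseudocount=cfg.log2_pseudocount)
    m_z = enorm.zscore_by_feature(m_log)
    return PipelineResult(sf, m_size, m_gc, m_log, m_z)


def run_pipeline(
    m: ExpressionMatrix,
    ann: pd.DataFrame,
    st: pd.DataFrame,
    config: Optional[AnalysisConfig] = None,
    with_typing: bool = True,
    with_mzt: bool = True,
    with_aneuploidy: bool = True,
) -> PipelineResult:
    cfg = config or AnalysisConfig()
    res = normalize_chain(m, ann, cfg)
    if with_mzt:
        res.mzt_sets = derive_mzt_sets(m, ann, st, res.size_factors, cfg)
        scores = mzt_scores(res.m_z, res.mzt_sets)
        res.mzt_table, res.mzt_cutoff = classify_mzt_failure(scores, st)
    if with_typing:
        res.typing = type_arrested_embryos(
            m, res.m_log, ann, st, res.size_factors, cfg
        )
    if with_aneuploidy:
        res.chromosome_props = chromosome_proportions(res.m_gc, ann)
        res.dosage_z = dosage_zscores(res.chromosome_props, st)
        res.aneuploidy_calls, res.aneuploid = call_aneuploidy(
            res.dosage_z, res.chromosome_props, cfg.aneuploidy_z_threshold
        )
    res.te_percent = te_fraction(res.m_gc, ann)
    return res
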