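"""Maternal-to-zygotic transition (MZT) gene sets, scoring and failure calls.

Major-ZGA genes are those significantly up-regulated more than 4-fold from
the 2-cell to the 8-cell stage, maternal-clearance genes those significantly
down-regulated, both under the standard DE rule.  Each embryo is then scored
by the mean Z of the two sets; the completion index (ZGA score minus
maternal score) separates embryos that traversed the MZT from those that did
not, and Type I arrested embryos are flagged as MZT failures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    AnalysisConfig,
    ExpressionMatrix,
    STAGE_INDEX,
)
from .de import nb_wald_de

log = logging.getLogger("embryoarrest")


@dataclass
class MZTSets:
    """ZGA and maternal-clearance gene lists plus the contrast that made them."""

    zga_genes: list[str]
    maternal_genes: list[str]
    contrast_provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.zga_genes) & set(self.maternal_genes)
        if overlap:
            raise ValueError(f"ZGA/maternal sets overlap: {sorted(overlap)[:5]}")


def derive_mzt_sets(
    m: ExpressionMatrix,
    ann: pd.DataFrame,
    sample_table: pd.DataFrame,
    size_factors: pd.Series,
    config: Optional[AnalysisConfig] = None,
) -> MZTSets:
    """Derive the MZT gene sets from the normal 2-cell vs 8-cell contrast.

    TE features are excluded even when they pass the DE rule; TE dynamics
    are analyzed separately.  The derivation only consumes the normal c2/c8
    samples, so adding arrested samples to a dataset cannot change it.
    """
    cfg = config or AnalysisConfig()
    normals = sample_table[sample_table["group"] == "normal"]
    c2 = normals.index[normals["stage"] == "c2"].tolist()
    c8 = normals.index[normals["stage"] == "c8"].tolist()
    if len(c2) < 2 or len(c8) < 2:
        raise ValueError(
            f"need >= 2 normal samples at c2 and c8 (found {len(c2)}, {len(c8)})"
        )
    res = nb_wald_de(m, c2, c8, size_factors, cfg)
    gene_ids = set(ann.index[ann["kind"] == "gene"].astype(str))
    zga = [f for f in res.de_features("up") if f in gene_ids]
    maternal = [f for f in res.de_features("down") if f in gene_ids]
    log.info("MZT sets: %d ZGA genes, %d maternal-clearance genes", len(zga), len(maternal))
    return MZTSets(
        zga_genes=zga,
        maternal_genes=maternal,
        contrast_provenance={
            "contrast": "c8_vs_c2_normals",
            "n_c2": len(c2),
            "n_c8": len(c8),
            **res.params,
        },
    )


def mzt_scores(
    z: ExpressionMatrix,
    sets: MZTSets,
    samples: Optional[Sequence[str]] = None,
    min_present: float = 0.5,
) -> pd.DataFrame:
    """Per-sample ZGA score, maternal score and completion index.

    Scores are the mean Z over the set members present in the matrix; if
    fewer than ``min_present`` of a set's members are present an error is
    raised (missing members are otherwise dropped with a warning).
    completion_index = zga_score - maternal_score.
    """
    z.require_layer("zscore")
    sample_ids = list(samples) if samples is not None else list(z.sample_ids)
    cols = z.sample_index(sample_ids)
    present = set(map(str, z.feature_ids))
    means = {}
    for name, members in (("zga", sets.zga_genes), ("maternal", sets.maternal_genes)):
        if not members:
            raise ValueError(f"MZT {name} set is empty")
        found = [g for g in members if g in present]
        if len(found) < min_present * len(members):
            raise ValueError(
                f"only {len(found)}/{len(members)} {name} genes present "
                f"(>= {min_present:.0%} required)"
            )
        if len(found) < len(members):
            log.warning("%d %s genes missing from matrix", len(members) - len(found), name)
        means[name] = z.values[np.ix_(z.feature_index(found), cols)].mean(axis=0)
    out = pd.DataFrame(
        {
            "zga_score": means["zga"],
            "maternal_score": means["maternal"],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    out["completion_index"] = out["zga_score"] - out["maternal_score"]
    return out


def classify_mzt_failure(
    scores: pd.DataFrame,
    sample_table: pd.DataFrame,
    placements: Optional[Mapping[str, str]] = None,
    cutoff: Optional[float] = None,
) -> tuple[pd.DataFrame, float]:
    """Flag embryos that failed the MZT.

    The cutoff defaults to the midpoint between the median completion index
    of normal 4-cell and normal 8-cell embryos (overridable).  Eligibility:
    normal samples are candidates only when developmentally at or past the
    8-cell stage (so pre-MZT embryos are never called failures); arrested
    and treated embryos — collected days after the MZT should have completed
    — are always candidates.  ``placements`` can override the developmental
    placement of individual samples by stage name.

    Returns the scores table with an ``mzt_failed`` column and the cutoff.
    """
    st = sample_table.reindex(scores.index)
    if st["stage"].isna().any():
        missing = st.index[st["stage"].isna()].tolist()
        raise ValueError(f"samples missing from sample table: {missing[:5]}")
    if cutoff is None:
        normals = sample_table[sample_table["group"] == "normal"]
        med = {}
        for stage in ("c4", "c8"):
            ids = [
                s for s in normals.index[normals["stage"] == stage]
                if s in scores.index
            ]
            if not ids:
                raise ValueError(f"no normal {stage} samples among scores; "
                                 "cannot set the completion cutoff")
            med[stage] = float(scores.loc[ids, "completion_index"].median())
        cutoff = 0.5 * (med["c4"] + med["c8"])

    c8_order = STAGE_INDEX["c8"]
    eligible = np.empty(len(scores), dtype=bool)
    for i, sid in enumerate(scores.index):
        group = st.loc[sid, "group"]
        if group in ("arrested", "treated"):
            eligible[i] = True
        else:
            stage = placements.get(sid, st.loc[sid, "stage"]) if placements else st.loc[sid, "stage"]
            eligible[i] = STAGE_INDEX[stage] >= c8_order
    out = scores.copy()
    out["mzt_failed"] = eligible & (out["completion_index"] < cutoff)
    log.info(
        "MZT failure: %d/%d eligible samples flagged (cutoff %.3f)",
        int(out["mzt_failed"].sum()), int(eligible.sum()), cutoff,
    )
    return out, float(cutoff)
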