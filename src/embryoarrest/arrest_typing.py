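"""Classify arrested embryos into Types I-III by co-correlation clustering.

Arrested embryos are clustered on the pairwise Pearson co-correlation matrix
of their log2 NTC profiles (Euclidean distance between correlation-matrix
rows, complete linkage, optimal leaf ordering).  Each cluster is then
assigned its nearest developmental stage — the candidate stage with the
smallest number of significantly DE genes against the cluster — and clusters
are labelled Type I/II/III in developmental order of their nearest stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .datamodel import AnalysisConfig, ExpressionMatrix, stage_order_key
from .de import de_count

log = logging.getLogger("embryoarrest")


def select_variable_features(
    m: ExpressionMatrix, ann: pd.DataFrame, n: int
) -> list[str]:
    """Top-n gene features by variance of log2 NTC across all samples.

    TE features are never selected.  Ties break lexicographically by feature
    id so the selection is deterministic.
    """
    m.require_layer("log2ntc")
    if n <= 0:
        raise ValueError("n must be positive")
    is_gene = ann["kind"].reindex(m.feature_ids).eq("gene").to_numpy()
    gene_ids = np.asarray(m.feature_ids, dtype=object)[is_gene]
    if n > len(gene_ids):
        raise ValueError(f"requested {n} features but only {len(gene_ids)} genes")
    var = m.values[is_gene, :].var(axis=1, ddof=1)
    order = np.lexsort((gene_ids, -var))  # primary: variance desc; tie: id asc
    return list(gene_ids[order[:n]])


def cocorrelation_matrix(
    m: ExpressionMatrix,
    samples: Sequence[str],
    features: Sequence[str],
) -> pd.DataFrame:
    """Pairwise Pearson correlation between samples over the given features."""
    m.require_layer("log2ntc")
    if len(samples) < 3:
        raise ValueError("need >= 3 samples for a co-correlation matrix")
    if len(features) < 10:
        raise ValueError("need >= 10 features for a co-correlation matrix")
    sub = m.subset_features(features).subset_samples(samples)
    sd = sub.values.std(axis=0)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(
            f"zero-variance sample {sub.sample_ids[flat[0]]!r} over selected features"
        )
    corr = np.corrcoef(sub.values, rowvar=False)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=list(samples), columns=list(samples))


@dataclass
class TypingResult:
    """Cluster membership and labelling for the arrested embryos."""

    sample_ids: list[str]
    cluster_id: pd.Series               # sample -> 1..k
    linkage: np.ndarray                 # scipy linkage matrix, leaf-ordered
    leaf_order: list[str]
    correlation: pd.DataFrame
    nearest_stage: dict[int, str] = field(default_factory=dict)
    type_label: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for sid, cid in self.cluster_id.items():
            out.setdefault(int(cid), []).append(sid)
        return out


def hierarchical_types(corr: pd.DataFrame, k: int) -> TypingResult:
    """Complete-linkage clustering of the co-correlation matrix into k groups.

    Distance is the Euclidean distance between rows of the correlation
    matrix; leaves are arranged by optimal leaf ordering (minimal sum of
    adjacent-leaf distances), which affects display order, not membership.
    """
    n = corr.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds {n} samples")
    dist = ssd.pdist(corr.to_numpy(), metric="euclidean")
    linkage = sch.linkage(dist, method="complete")
    linkage = sch.optimal_leaf_ordering(linkage, dist)
    raw_labels = sch.fcluster(linkage, t=k, criterion="maxclust")
    leaf_idx = sch.leaves_list(linkage)
    samples = list(corr.index)
    # renumber clusters by first appearance in leaf order for determinism
    remap: dict[int, int] = {}
    for i in leaf_idx:
        remap.setdefault(int(raw_labels[i]), len(remap) + 1)
    labels = pd.Series(
        [remap[int(l)] for l in raw_labels], index=samples, name="cluster_id"
    )
    return TypingResult(
        sample_ids=samples,
        cluster_id=labels,
        linkage=linkage,
        leaf_order=[samples[i] for i in leaf_idx],
        correlation=corr,
    )


def assign_nearest_stage(
    m: ExpressionMatrix,
    sample_table: pd.DataFrame,
    cluster_samples: Sequence[str],
    candidate_stages: Sequence[str],
    size_factors: pd.Series,
    config: Optional[AnalysisConfig] = None,
) -> tuple[str, dict[str, int]]:
    """Nearest developmental stage of a cluster by minimal DE-gene count.

    Runs the standard DE contrast of the cluster against the normal samples
    of every candidate stage and returns the stage with the smallest number
    of significant genes; ties break toward the earlier stage.  Also returns
    the full stage -> DE count map.
    """
    if not candidate_stages:
        raise ValueError("candidate stage list is empty")
    normals = sample_table[sample_table["group"] == "normal"]
    counts: dict[str, int] = {}
    for stage in candidate_stages:
        ref = normals.index[normals["stage"] == stage].tolist()
        if len(ref) < 2:
            raise ValueError(f"candidate stage {stage!r} has {len(ref)} normal samples (< 2)")
        counts[stage] = de_count(m, ref, list(cluster_samples), size_factors, config)
    best = min(counts, key=lambda s: (counts[s], stage_order_key(s)))
    return best, counts


def label_types_by_stage(
    clusters: dict[int, list[str]], nearest_stages: dict[int, str]
) -> dict[int, str]:
    """Label three clusters I/II/III by developmental order of nearest stage.

    The cluster with the earliest nearest stage is Type I; of the remaining
    two the earlier is Type II and the later Type III.  Stage ties break by
    cluster size (larger cluster gets the lower type number), then by
    cluster id.
    """
    if len(clusters) != 3 or set(clusters) != set(nearest_stages):
        raise ValueError(
            "type labelling requires exactly 3 clusters with assigned stages; "
            "use numeric cluster ids for other k"
        )
    order = sorted(
        clusters,
        key=lambda cid: (
            stage_order_key(nearest_stages[cid]),
            -len(clusters[cid]),
            cid,
        ),
    )
    return {cid: label for cid, label in zip(order, ("I", "II", "III"))}


def type_arrested_embryos(
    m_raw: ExpressionMatrix,
    m_log2: ExpressionMatrix,
    ann: pd.DataFrame,
    sample_table: pd.DataFrame,
    size_factors: pd.Series,
    config: Optional[AnalysisConfig] = None,
    candidate_stages: Sequence[str] = ("c2", "c4", "c8", "morula", "E3", "E4"),
) -> TypingResult:
    """Full typing pipeline for the arrested embryos of a dataset."""
    cfg = config or AnalysisConfig()
    arrested = sample_table.index[sample_table["group"] == "arrested"].tolist()
    if len(arrested) < cfg.k_types:
        raise ValueError(
            f"{len(arrested)} arrested samples for k={cfg.k_types} clusters"
        )
    n_genes = int(ann["kind"].reindex(m_log2.feature_ids).eq("gene").sum())
    n_var = min(cfg.n_variable_features, n_genes)
    if n_var < cfg.n_variable_features:
        log.warning("only %d gene features; using all of them", n_genes)
    features = select_variable_features(m_log2, ann, n_var)
    corr = cocorrelation_matrix(m_log2, arrested, features)
    result = hierarchical_types(corr, cfg.k_types)
    for cid, members in result.clusters().items():
        stage, counts = assign_nearest_stage(
            m_raw, sample_table, members, candidate_stages, size_factors, cfg
        )
        result.nearest_stage[cid] = stage
        log.info("cluster %d (n=%d): nearest stage %s %s", cid, len(members), stage, counts)
    if cfg.k_types == 3:
        labels = label_types_by_stage(result.clusters(), result.nearest_stage)
        result.type_label = result.cluster_id.map(labels)
    else:
        result.type_label = result.cluster_id.astype(str)
    return result
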