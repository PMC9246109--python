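"""Core containers for the embryo-arrest expression pipeline.

The central object is :class:`ExpressionMatrix`, a dense features x samples
matrix tagged with the processing layer it represents (raw counts through
per-gene Z-scores).  Feature and sample metadata travel as plain pandas
DataFrames validated by :func:`check_feature_annotation` /
:func:`check_sample_table`, mirroring the var/obs convention of AnnData
without pulling in that dependency for a pipeline this size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("embryoarrest")

#: Developmental stage vocabulary, in developmental order.  ``c2``/``c4``/``c8``
#: are the 2-/4-/8-cell cleavage stages; ``E3``..``E7`` are embryonic-day
#: labels for morula through late blastocyst.
STAGES: tuple[str, ...] = (
    "oocyte", "zygote", "c2", "c4", "c8", "morula", "E3", "E4", "E5", "E6", "E7",
)
STAGE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STAGES)}

GROUPS: tuple[str, ...] = ("normal", "arrested", "treated")
ARREST_TYPES: tuple[str, ...] = ("none", "I", "II", "III", "unknown")

LAYERS: tuple[str, ...] = (
    "raw", "size_normalized", "gc_normalized", "log2ntc", "zscore",
)
#: Layers whose values must be non-negative.
COUNT_LAYERS: tuple[str, ...] = ("raw", "size_normalized", "gc_normalized")

#: Chromosome names used by the generator and the karyotyping module.
CHROMOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX", "chrY")


class LayerError(ValueError):
    """An operation received an ExpressionMatrix on the wrong processing layer."""


def _as_str_array(ids: Iterable[str], what: str) -> np.ndarray:
    arr = np.asarray(list(ids), dtype=object)
    if arr.ndim != 1:
        raise ValueError(f"{what} must be a flat sequence of strings")
    if len(set(arr)) != len(arr):
        dupes = pd.Index(arr)[pd.Index(arr).duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dupes[:5]}")
    return arr


@dataclass
class ExpressionMatrix:
    """Dense features x samples expression matrix with a layer tag.

    Parameters
    ----------
    values
        Non-negative matrix, one row per feature, one column per sample.
        Raw-layer matrices must be integer-valued (they are counts).
    feature_ids, sample_ids
        Unique ordered identifiers matching the matrix dimensions.
    layer
        One of ``raw``, ``size_normalized``, ``gc_normalized``, ``log2ntc``,
        ``zscore``.  Downstream operations check this tag so that, e.g.,
        Z-scoring is never applied to raw counts by accident.
    """

    values: np.ndarray
    feature_ids: np.ndarray
    sample_ids: np.ndarray
    layer: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (features x samples)")
        self.feature_ids = _as_str_array(self.feature_ids, "feature ids")
        self.sample_ids = _as_str_array(self.sample_ids, "sample ids")
        nf, ns = self.values.shape
        if len(self.feature_ids) != nf:
            raise ValueError(
                f"{len(self.feature_ids)} feature ids for {nf} matrix rows"
            )
        if len(self.sample_ids) != ns:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {ns} matrix columns"
            )
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix contains non-finite values")
        if self.layer in COUNT_LAYERS and np.any(self.values < 0):
            raise ValueError(f"layer {self.layer!r} requires non-negative values")
        if self.layer == "raw" and not np.allclose(self.values, np.round(self.values)):
            bad = np.argwhere(~np.isclose(self.values, np.round(self.values)))[0]
            raise ValueError(
                "raw layer requires integer counts; first non-integer at "
                f"feature {self.feature_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
            )

    # -- basic introspection -------------------------------------------------
    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def require_layer(self, *layers: str) -> None:
        if self.layer not in layers:
            raise LayerError(
                f"operation requires layer in {layers}, got {self.layer!r}"
            )

    # -- indexing helpers ----------------------------------------------------
    def feature_index(self, ids: Sequence[str]) -> np.ndarray:
        idx = pd.Index(self.feature_ids)
        locs = idx.get_indexer(list(ids))
        if (locs < 0).any():
            missing = [i for i, l in zip(ids, locs) if l < 0]
            raise KeyError(f"unknown feature ids: {missing[:5]}")
        return locs

    def sample_index(self, ids: Sequence[str]) -> np.ndarray:
        idx = pd.Index(self.sample_ids)
        locs = idx.get_indexer(list(ids))
        if (locs < 0).any():
            missing = [i for i, l in zip(ids, locs) if l < 0]
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        return locs

    def subset_features(self, ids: Sequence[str]) -> "ExpressionMatrix":
        locs = self.feature_index(ids)
        return replace(
            self, values=self.values[locs, :], feature_ids=self.feature_ids[locs]
        )

    def subset_samples(self, ids: Sequence[str]) -> "ExpressionMatrix":
        locs = self.sample_index(ids)
        return replace(
            self, values=self.values[:, locs], sample_ids=self.sample_ids[locs]
        )

    def with_values(self, values: np.ndarray, layer: str) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=values,
            feature_ids=self.feature_ids.copy(),
            sample_ids=self.sample_ids.copy(),
            layer=layer,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )


# ---------------------------------------------------------------------------
# Metadata tables (validated DataFrames)
# ---------------------------------------------------------------------------

FEATURE_COLUMNS = ("kind", "chromosome", "gc_fraction", "te_family", "symbol")
SAMPLE_COLUMNS = ("stage", "group", "arrest_type")


def check_feature_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Validate a feature annotation table (indexed by feature_id).

    Required columns: ``kind`` (gene|TE), ``chromosome`` ("chr1".."chrY" or
    "NA" for genome-wide TE aggregates), ``gc_fraction`` in [0, 1] or NaN.
    ``te_family`` and ``symbol`` are optional and filled with NA if absent.
    """
    ann = ann.copy()
    if ann.index.has_duplicates:
        raise ValueError("duplicate feature ids in annotation")
    for col in ("kind", "chromosome", "gc_fraction"):
        if col not in ann.columns:
            raise ValueError(f"feature annotation missing column {col!r}")
    for col in ("te_family", "symbol"):
        if col not in ann.columns:
            ann[col] = pd.NA
    bad_kind = set(ann["kind"].unique()) - {"gene", "TE"}
    if bad_kind:
        raise ValueError(f"unknown feature kinds: {sorted(bad_kind)}")
    gc = pd.to_numeric(ann["gc_fraction"], errors="coerce")
    out_of_range = gc.dropna()[(gc.dropna() < 0) | (gc.dropna() > 1)]
    if len(out_of_range):
        raise ValueError(
            f"gc_fraction outside [0,1] for {out_of_range.index[:5].tolist()}"
        )
    ann["gc_fraction"] = gc
    return ann


def check_sample_table(st: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample table (indexed by sample_id).

    Enforces the stage/group/arrest_type vocabularies and the invariant that
    normal samples carry arrest_type ``none`` while arrested samples carry one
    of I/II/III/unknown.
    """
    st = st.copy()
    if st.index.has_duplicates:
        raise ValueError("duplicate sample ids in sample table")
    for col in SAMPLE_COLUMNS:
        if col not in st.columns:
            raise ValueError(f"sample table missing column {col!r}")
    bad_stage = set(st["stage"].unique()) - set(STAGES)
    if bad_stage:
        raise ValueError(f"unknown stages: {sorted(bad_stage)}")
    bad_group = set(st["group"].unique()) - set(GROUPS)
    if bad_group:
        raise ValueError(f"unknown groups: {sorted(bad_group)}")
    bad_type = set(st["arrest_type"].unique()) - set(ARREST_TYPES)
    if bad_type:
        raise ValueError(f"unknown arrest types: {sorted(bad_type)}")
    for viol in sample_table_violations(st):
        raise ValueError(viol)
    return st


def sample_table_violations(st: pd.DataFrame) -> list[str]:
    """Invariant violations of the group/arrest_type contract (report form)."""
    out: list[str] = []
    normal_bad = st[(st["group"] == "normal") & (st["arrest_type"] != "none")]
    for sid in normal_bad.index:
        out.append(f"sample {sid!r}: group 'normal' requires arrest_type 'none'")
    arrested_bad = st[(st["group"] == "arrested") & (st["arrest_type"] == "none")]
    for sid in arrested_bad.index:
        out.append(
            f"sample {sid!r}: group 'arrested' requires arrest_type in I/II/III/unknown"
        )
    return out


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Ordered, deduplicated named gene sets (GMT semantics)."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, list[str]] = {}
        for name, members in self.sets.items():
            seen: dict[str, None] = {}
            for m in members:
                seen.setdefault(m, None)
            if not seen:
                raise ValueError(f"gene set {name!r} is empty")
            clean[name] = list(seen)
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)

    def subset(self, names: Sequence[str]) -> "GeneSetCollection":
        return GeneSetCollection(
            sets={n: list(self.sets[n]) for n in names},
            descriptions={n: self.descriptions.get(n, "") for n in names},
        )


# ---------------------------------------------------------------------------
# Analysis configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Pipeline-wide thresholds and knobs.

    fc_threshold_log2=2.0 with q_threshold=0.01 encodes the significance rule
    used throughout: a feature is differentially expressed when it changes at
    least 4-fold with a Benjamini-Hochberg q-value of 0.01 or less.
    """

    fc_threshold_log2: float = 2.0
    q_threshold: float = 0.01
    gsea_permutations: int = 1000
    gsea_q_threshold: float = 0.05
    gsea_weight: float = 1.0
    aneuploidy_z_threshold: float = 3.0
    n_variable_features: int = 2000
    k_types: int = 3
    seed: int = 0
    gc_bins: int = 10
    log2_pseudocount: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "fc_threshold_log2", "q_threshold", "gsea_q_threshold",
            "aneuploidy_z_threshold", "gc_bins", "gsea_permutations",
            "n_variable_features",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.k_types < 2:
            raise ValueError("k_types must be >= 2")

    @classmethod
    def from_mapping(cls, data: Mapping[str, object]) -> "AnalysisConfig":
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)  # type: ignore[arg-type]

    def to_dict(self) -> dict[str, object]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def stage_order_key(stage: str) -> int:
    """Developmental order of a stage label (oocyte first)."""
    try:
        return STAGE_INDEX[stage]
    except KeyError:
        raise ValueError(f"unknown stage {stage!r}") from None
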