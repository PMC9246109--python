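"""Readers and writers for the pipeline's on-disk formats.

Count matrices travel either as MatrixMarket coordinate files with
``features.tsv`` / ``samples.tsv`` identifier sidecars (sparse dialect) or as
dense TSV with the feature id in the first column and sample ids in the
header.  Gene sets use GMT.  Metadata tables are plain TSV.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datamodel import (
    ExpressionMatrix,
    GeneSetCollection,
    check_feature_annotation,
    check_sample_table,
    sample_table_violations,
)

log = logging.getLogger("embryoarrest")


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


def _read_id_sidecar(path: Path, kind: str) -> list[str]:
    ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            ids.append(line.split("\t")[0])
    # tolerate a header row naming the column
    if ids and ids[0] in (f"{kind}_id", kind):
        ids = ids[1:]
    if not ids:
        raise FormatError(f"no {kind} ids found in {path}")
    return ids


def read_counts(
    matrix_path: str | Path,
    features_path: Optional[str | Path] = None,
    samples_path: Optional[str | Path] = None,
    dialect: str = "mtx",
) -> ExpressionMatrix:
    """Load a raw count matrix (features x samples).

    ``dialect='mtx'`` expects a MatrixMarket coordinate file (1-based indices
    per the standard) plus feature/sample id sidecars; ``dialect='tsv'``
    expects a dense table with a header row of sample ids and feature ids in
    the first column.  The result is a raw-layer matrix, so non-integer
    values are rejected with their coordinates.
    """
    matrix_path = Path(matrix_path)
    if dialect == "mtx":
        if features_path is None or samples_path is None:
            raise ValueError("mtx dialect requires features_path and samples_path")
        mat = scipy.io.mmread(matrix_path)
        dense = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        feature_ids = _read_id_sidecar(Path(features_path), "feature")
        sample_ids = _read_id_sidecar(Path(samples_path), "sample")
        if dense.shape[0] != len(feature_ids):
            raise FormatError(
                f"{matrix_path} has {dense.shape[0]} rows but "
                f"{features_path} lists {len(feature_ids)} features"
            )
        if dense.shape[1] != len(sample_ids):
            raise FormatError(
                f"{matrix_path} has {dense.shape[1]} columns but "
                f"{samples_path} lists {len(sample_ids)} samples"
            )
    elif dialect == "tsv":
        df = pd.read_csv(matrix_path, sep="\t", index_col=0)
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature ids in {matrix_path}: {dupes[:5]}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids in {matrix_path}: {dupes[:5]}")
        dense = df.to_numpy(dtype=float)
        feature_ids = [str(i) for i in df.index]
        sample_ids = [str(c) for c in df.columns]
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'mtx' or 'tsv'")

    if not np.allclose(dense, np.round(dense)):
        bad = np.argwhere(~np.isclose(dense, np.round(dense)))[0]
        raise FormatError(
            f"non-integer value {dense[bad[0], bad[1]]!r} in raw matrix at "
            f"feature {feature_ids[bad[0]]!r}, sample {sample_ids[bad[1]]!r}"
        )
    m = ExpressionMatrix(
        values=np.round(dense),
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        layer="raw",
    )
    log.info("read %d x %d raw matrix from %s", m.n_features, m.n_samples, matrix_path)
    return m


def write_counts(
    m: ExpressionMatrix,
    matrix_path: str | Path,
    features_path: Optional[str | Path] = None,
    samples_path: Optional[str | Path] = None,
    dialect: str = "mtx",
) -> None:
    """Write a count matrix in the given dialect (inverse of read_counts)."""
    matrix_path = Path(matrix_path)
    if dialect == "mtx":
        if features_path is None or samples_path is None:
            raise ValueError("mtx dialect requires features_path and samples_path")
        values = m.values
        if m.layer == "raw":
            sparse = scipy.sparse.coo_matrix(values.astype(np.int64))
        else:
            sparse = scipy.sparse.coo_matrix(values)
        # pass a handle so the exact path is respected (mmwrite appends .mtx
        # to bare filenames)
        with open(matrix_path, "wb") as fh:
            scipy.io.mmwrite(fh, sparse)
        Path(features_path).write_text(
            "feature_id\n" + "".join(f"{i}\n" for i in m.feature_ids)
        )
        Path(samples_path).write_text(
            "sample_id\n" + "".join(f"{i}\n" for i in m.sample_ids)
        )
    elif dialect == "tsv":
        df = m.to_frame()
        if m.layer == "raw":
            df = df.astype(np.int64)
        df.to_csv(matrix_path, sep="\t", index_label="feature_id")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name TAB description TAB member [TAB member ...].

    Duplicate members within a set are collapsed keeping first occurrence;
    set order follows the file.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f">=1 member ({len(fields)} fields found)"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sets.names():
            desc = sets.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sets[name]]) + "\n")


def read_feature_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(
        path, sep="\t", index_col=0, dtype={0: str},
        na_values=["NA", ""], keep_default_na=True,
    )
    ann.index = ann.index.astype(str)
    if "chromosome" in ann.columns:
        ann["chromosome"] = ann["chromosome"].fillna("NA").astype(str)
    return check_feature_annotation(ann)


def write_feature_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    check_feature_annotation(ann).to_csv(
        path, sep="\t", index_label="feature_id", na_rep="NA"
    )


def read_sample_table(path: str | Path) -> pd.DataFrame:
    st = pd.read_csv(path, sep="\t", index_col=0)
    st.index = st.index.astype(str)
    return check_sample_table(st)


def write_sample_table(st: pd.DataFrame, path: str | Path) -> None:
    check_sample_table(st).to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Dataset validation (report, not exception)
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    missing_annotation: list[str] = field(default_factory=list)
    missing_sample: list[str] = field(default_factory=list)
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.missing_annotation or self.missing_sample or self.violations)

    def to_dict(self) -> dict[str, list[str]]:
        return {
            "missing_annotation": self.missing_annotation,
            "missing_sample": self.missing_sample,
            "violations": self.violations,
        }


def validate_dataset(
    m: ExpressionMatrix, ann: pd.DataFrame, st: pd.DataFrame
) -> ValidationReport:
    """Cross-check a matrix against its annotation and sample tables.

    Report-only: lists features without annotation rows, samples without
    sample-table rows, and metadata invariant violations.  Pipeline stages
    that need chromosome/GC/stage information require an all-clear report.
    """
    report = ValidationReport()
    ann_ids = set(ann.index.astype(str))
    st_ids = set(st.index.astype(str))
    report.missing_annotation = [f for f in m.feature_ids if f not in ann_ids]
    report.missing_sample = [s for s in m.sample_ids if s not in st_ids]
    report.violations = sample_table_violations(st)
    gc = pd.to_numeric(ann.get("gc_fraction"), errors="coerce")
    bad_gc = gc.dropna()[(gc.dropna() < 0) | (gc.dropna() > 1)]
    for fid in bad_gc.index:
        report.violations.append(f"feature {fid!r}: gc_fraction outside [0,1]")
    return report


def write_manifest(path: str | Path, **entries: object) -> None:
    """Write a JSON run manifest (parameters, seed, package version)."""
    from . import __version__

    payload = {"package": "embryoarrest", "version": __version__, **entries}
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
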