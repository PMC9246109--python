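"""Synthetic staged single-embryo count matrices with planted ground truth.

The generator emulates a combined single-embryo / single-cell RNA-seq dataset
spanning oocyte through late blastocyst, plus arrested and treated embryos:

* stage-specific expression programs including maternal-transcript decay
  (monotone >=4-fold drop from oocyte to the 8-cell stage) and major zygotic
  genome activation (>=4-fold step at the 8-cell stage),
* negative-binomial counts with log-normal library-size variation and a
  smooth logistic GC-content bias,
* three planted arrest classes — Type I (4-cell-like, MZT failure, global TE
  up-regulation), Type II (morula-like, senescent: ribosomes/histones/
  glycolysis/MYC targets down, OXPHOS/p53 targets up), Type III (E4-like,
  ribosomes/glycolysis/OXPHOS down, p53 targets up) — and a treated state
  with the glycolytic/fatty-acid programs restored,
* planted whole-chromosome gains/losses (dosage 1.5 / 0.5).

Every planted choice is recorded in :class:`GroundTruth` so recovery can be
tested without external data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .datamodel import (
    CHROMOSOMES,
    STAGES,
    ExpressionMatrix,
    GeneSetCollection,
    check_feature_annotation,
    check_sample_table,
)
from . import io as eio

log = logging.getLogger("embryoarrest")

SIGNATURE_SETS: tuple[str, ...] = (
    "ribosome_small", "ribosome_large", "nucleosome", "p53_targets",
    "myc_targets", "glycolysis", "oxphos", "fatty_acid",
)

TE_FAMILIES: tuple[str, ...] = ("ERV1", "ERVK", "ERVL", "L1", "L2", "Alu", "MIR", "SVA")

DEFAULT_EFFECTS: dict[str, float] = {
    "te_up_typeI": 2.0,
    "ribosome_down": -1.5,
    "nucleosome_down": -1.5,
    "p53_up": 1.5,
    "myc_down": -1.0,
    "glycolysis_down": -1.0,
    "oxphos_up_typeII": 1.0,
    "oxphos_down_typeIII": -1.0,
    "cdkn1a_up": 2.0,
    "ccna2_down": -2.0,
    "fatty_acid_up_treated": 1.0,
}

#: Transcriptomic stage each arrest class resembles.
ARREST_STAGE: dict[str, str] = {"I": "c4", "II": "morula", "III": "E4"}


@dataclass
class GeneratorParams:
    """Knobs of the synthetic dataset; defaults define the study conditions.

    ``n_arrested`` is the (Type I, Type II, Type III) embryo count; the
    default (10, 7, 6) gives 23 arrested embryos.  ``effect_log2`` holds the
    planted arrest effect sizes on the log2 scale.  ``aneuploid_samples``
    lists (sample_id, chromosome, dosage) with dosage 1.5 for a gain and 0.5
    for a loss; when None, ``n_aneuploid`` samples are picked automatically.
    """

    n_genes: int = 6000
    n_te_features: int = 400
    genes_per_chromosome: Optional[dict[str, int]] = None
    embryos_per_stage: int = 8
    n_arrested: tuple[int, int, int] = (10, 7, 6)
    n_treated: int = 4
    stage_profile_sd: float = 1.0
    stage_correlation: float = 0.5
    cleavage_damping: float = 0.3
    nb_dispersion: float = 0.1
    libsize_sigma: float = 0.3
    gc_bias_amplitude: float = 0.3
    maternal_fraction: float = 0.10
    zga_fraction: float = 0.10
    signature_fractions: dict[str, float] = field(
        default_factory=lambda: {name: 0.01 for name in SIGNATURE_SETS}
    )
    effect_log2: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    mean_depth: float = 1e6
    aneuploid_samples: Optional[list[tuple[str, str, float]]] = None
    n_aneuploid: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_te_features < 0:
            raise ValueError("feature counts must be positive")
        if self.embryos_per_stage <= 0 or any(n < 0 for n in self.n_arrested):
            raise ValueError("sample counts must be non-negative")
        if self.nb_dispersion < 0 or self.libsize_sigma < 0:
            raise ValueError("dispersion and libsize_sigma must be >= 0")
        unknown = set(self.signature_fractions) - set(SIGNATURE_SETS)
        if unknown:
            raise ValueError(f"unknown signature sets: {sorted(unknown)}")
        # partial overrides keep the remaining defaults
        self.signature_fractions = {
            name: self.signature_fractions.get(name, 0.01) for name in SIGNATURE_SETS
        }
        self.effect_log2 = {**DEFAULT_EFFECTS, **self.effect_log2}
        total_frac = (
            self.maternal_fraction
            + self.zga_fraction
            + sum(self.signature_fractions.values())
        )
        if total_frac >= 1:
            raise ValueError(
                f"disjoint set fractions sum to {total_frac:.3f} >= 1; infeasible"
            )
        if self.aneuploid_samples is not None:
            for _, _, dosage in self.aneuploid_samples:
                if dosage not in (0.5, 1.5):
                    raise ValueError("aneuploidy dosage must be 0.5 or 1.5")

    def chromosome_split(self) -> dict[str, int]:
        """Near-equal split of genes across the 24 chromosomes."""
        if self.genes_per_chromosome is not None:
            if sum(self.genes_per_chromosome.values()) != self.n_genes:
                raise ValueError("genes_per_chromosome must sum to n_genes")
            return dict(self.genes_per_chromosome)
        base, extra = divmod(self.n_genes, len(CHROMOSOMES))
        return {
            c: base + (1 if i < extra else 0) for i, c in enumerate(CHROMOSOMES)
        }


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery tests."""

    stage: dict[str, str]
    group: dict[str, str]
    arrest_type: dict[str, str]
    maternal_genes: list[str]
    zga_genes: list[str]
    signature_genes: dict[str, list[str]]
    te_family: dict[str, str]
    aneuploidies: list[tuple[str, str, float]]
    effects_applied: dict[str, float]
    depth_factors: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        data = json.loads(Path(path).read_text())
        data["aneuploidies"] = [tuple(a) for a in data["aneuploidies"]]
        return cls(**data)

    def samples_of_type(self, arrest_type: str) -> list[str]:
        return [s for s, t in self.arrest_type.items() if t == arrest_type]


def gc_bias_factor(gc_fraction: np.ndarray, amplitude: float) -> np.ndarray:
    """Smooth monotone GC bias multiplier, 1.0 at GC = 0.5.

    A scaled logistic in GC fraction: multiplier exp(A * (2 * sigmoid(8 *
    (gc - 0.5)) - 1)), spanning about exp(-A)..exp(A).  amplitude = 0 gives a
    flat profile (no GC dependence); NaN GC (TE aggregates) maps to 1.0.
    """
    gc = np.asarray(gc_fraction, dtype=float)
    out = np.ones_like(gc)
    mask = np.isfinite(gc)
    s = 1.0 / (1.0 + np.exp(-8.0 * (gc[mask] - 0.5)))
    out[mask] = np.exp(amplitude * (2.0 * s - 1.0))
    return out


# ---------------------------------------------------------------------------
# Feature layout
# ---------------------------------------------------------------------------

@dataclass
class _FeatureLayout:
    feature_ids: list[str]
    annotation: pd.DataFrame
    maternal: np.ndarray        # index arrays into the feature axis
    zga: np.ndarray
    signature: dict[str, np.ndarray]
    te: np.ndarray
    gene: np.ndarray
    cdkn1a: int
    ccna2: int


def _build_features(p: GeneratorParams, rng: np.random.Generator) -> _FeatureLayout:
    split = p.chromosome_split()
    gene_ids = [f"G{i:05d}" for i in range(p.n_genes)]
    chroms: list[str] = []
    for c in CHROMOSOMES:
        chroms.extend([c] * split[c])
    gc = np.clip(rng.normal(0.46, 0.09, size=p.n_genes), 0.25, 0.75)

    # Disjoint program memberships drawn from a single permutation.
    perm = rng.permutation(p.n_genes)
    cursor = 0

    def take(frac: float) -> np.ndarray:
        nonlocal cursor
        k = int(round(frac * p.n_genes))
        sel = perm[cursor:cursor + k]
        cursor += k
        return np.sort(sel)

    maternal = take(p.maternal_fraction)
    zga = take(p.zga_fraction)
    signature = {name: take(p.signature_fractions[name]) for name in SIGNATURE_SETS}

    # Named marker genes for per-gene senescence checks: p21 (CDKN1A) inside
    # the p53-target program, cyclin A2 (CCNA2) inside the MYC-target program.
    cdkn1a = int(signature["p53_targets"][0]) if len(signature["p53_targets"]) else -1
    ccna2 = int(signature["myc_targets"][0]) if len(signature["myc_targets"]) else -1
    if cdkn1a >= 0:
        gene_ids[cdkn1a] = "CDKN1A"
    if ccna2 >= 0:
        gene_ids[ccna2] = "CCNA2"

    te_families = rng.choice(TE_FAMILIES, size=p.n_te_features, replace=True)
    te_ids = [f"TE:{fam}_{i:04d}" for i, fam in enumerate(te_families)]

    feature_ids = gene_ids + te_ids
    ann = pd.DataFrame(
        {
            "kind": ["gene"] * p.n_genes + ["TE"] * p.n_te_features,
            "chromosome": chroms + ["NA"] * p.n_te_features,
            "gc_fraction": np.concatenate([gc, np.full(p.n_te_features, np.nan)]),
            "te_family": [pd.NA] * p.n_genes + list(te_families),
            "symbol": gene_ids + [pd.NA] * p.n_te_features,
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    return _FeatureLayout(
        feature_ids=feature_ids,
        annotation=check_feature_annotation(ann),
        maternal=maternal,
        zga=zga,
        signature=signature,
        te=np.arange(p.n_genes, p.n_genes + p.n_te_features),
        gene=np.arange(p.n_genes),
        cdkn1a=cdkn1a,
        ccna2=ccna2,
    )


# ---------------------------------------------------------------------------
# Stage profiles
# ---------------------------------------------------------------------------

def build_reference_profiles(
    p: GeneratorParams,
) -> tuple[pd.DataFrame, _FeatureLayout]:
    """Per-stage expected expression for every feature (strictly positive).

    Returns a (features x stages) DataFrame of expected counts at the nominal
    sequencing depth, together with the feature layout that defines program
    memberships.  Maternal genes decay monotonically (log-linear) from oocyte
    to the 8-cell stage by >= 4-fold total and stay low; ZGA genes step up
    >= 4-fold at the 8-cell stage and stay high; all other genes follow a
    smooth random walk over the stage order.
    """
    rng = np.random.default_rng(p.seed)
    layout = _build_features(p, rng)
    n_feat = p.n_genes + p.n_te_features
    n_stages = len(STAGES)

    # Baseline log2 abundance: spread 1.5 log2 keeps the expression
    # distribution log-normal without letting single genes dominate a
    # chromosome's tag share — same-stage embryos then differ in per-
    # chromosome share by a few percent, as expression karyotyping assumes.
    base = np.empty(n_feat)
    base[layout.gene] = rng.normal(3.0, 1.5, size=p.n_genes)
    base[layout.te] = rng.normal(1.5, 1.5, size=p.n_te_features)

    # Background stage programs: a smooth mean-reverting walk in log2 around
    # each gene's baseline.  The per-stage deviation has standard deviation
    # stage_profile_sd with correlation stage_correlation between adjacent
    # stages, so adjacent stages differ by program effects of order
    # stage_profile_sd without the dynamic range growing without bound along
    # the trajectory.  In the cleavage window (through the 8-cell stage) the
    # deviation is damped by cleavage_damping: there, transcriptome dynamics
    # are dominated by the separately planted maternal-decay and ZGA
    # programs, mirroring the biology of the MZT.
    i_c8_tmp = STAGES.index("c8")
    target_sd = np.array(
        [
            p.stage_profile_sd * (p.cleavage_damping if t <= i_c8_tmp else 1.0)
            for t in range(n_stages)
        ]
    )
    rho = p.stage_correlation
    dev = np.empty((n_feat, n_stages))
    dev[:, 0] = rng.normal(0.0, target_sd[0], size=n_feat)
    for t in range(1, n_stages):
        carry = rho * (target_sd[t] / max(target_sd[t - 1], 1e-12)) * dev[:, t - 1]
        innov_sd = target_sd[t] * np.sqrt(max(1.0 - rho**2, 0.0))
        dev[:, t] = carry + rng.normal(0.0, innov_sd, size=n_feat)
    log2_prof = base[:, None] + dev

    i_c2, i_c8 = STAGES.index("c2"), STAGES.index("c8")

    # Maternal decay: replace the walk by a monotone log-linear decline from
    # oocyte to c8 (total drop 2.2-4 log2, i.e. >= 4.6-fold), flat afterwards.
    drop = rng.uniform(2.2, 4.0, size=len(layout.maternal))
    ramp = np.linspace(0.0, 1.0, i_c8 + 1)
    for k, g in enumerate(layout.maternal):
        log2_prof[g, : i_c8 + 1] = base[g] - drop[k] * ramp
        log2_prof[g, i_c8 + 1:] = base[g] - drop[k]

    # Major ZGA: low plateau through c4, step at c8, high plateau afterwards.
    step = rng.uniform(2.2, 4.0, size=len(layout.zga))
    for k, g in enumerate(layout.zga):
        log2_prof[g, :i_c8] = base[g]
        log2_prof[g, i_c8:] = base[g] + step[k]

    intensity = np.exp2(log2_prof)
    # One global scale so stage-to-stage fold changes are preserved exactly;
    # per-stage renormalization would dilute the planted ZGA step.
    totals = intensity.sum(axis=0)
    scale = p.mean_depth / np.exp(np.mean(np.log(totals)))
    profiles = pd.DataFrame(
        intensity * scale, index=layout.feature_ids, columns=list(STAGES)
    )
    return profiles, layout


# ---------------------------------------------------------------------------
# Dataset simulation
# ---------------------------------------------------------------------------

def _sample_ids_for(p: GeneratorParams) -> tuple[list[str], pd.DataFrame]:
    rows = []
    for stage in STAGES:
        for i in range(p.embryos_per_stage):
            rows.append((f"{stage}_{i:02d}", stage, "normal", "none"))
    for t, n in zip(("I", "II", "III"), p.n_arrested):
        for i in range(n):
            rows.append((f"arrest{t}_{i:02d}", ARREST_STAGE[t], "arrested", t))
    for i in range(p.n_treated):
        rows.append((f"treated_{i:02d}", ARREST_STAGE["III"], "treated", "none"))
    st = pd.DataFrame(
        rows, columns=["sample_id", "stage", "group", "arrest_type"]
    ).set_index("sample_id")
    return list(st.index), check_sample_table(st)


def _arrest_multipliers(
    p: GeneratorParams, layout: _FeatureLayout
) -> dict[str, np.ndarray]:
    """log2 effect vector (per feature) for each non-normal state."""
    n_feat = p.n_genes + p.n_te_features
    e = p.effect_log2
    sig = layout.signature

    eff: dict[str, np.ndarray] = {}

    v = np.zeros(n_feat)
    v[layout.te] += e["te_up_typeI"]
    eff["I"] = v

    v = np.zeros(n_feat)
    v[sig["ribosome_small"]] += e["ribosome_down"]
    v[sig["ribosome_large"]] += e["ribosome_down"]
    v[sig["nucleosome"]] += e["nucleosome_down"]
    v[sig["glycolysis"]] += e["glycolysis_down"]
    v[sig["oxphos"]] += e["oxphos_up_typeII"]
    v[sig["p53_targets"]] += e["p53_up"]
    v[sig["myc_targets"]] += e["myc_down"]
    if layout.cdkn1a >= 0:
        v[layout.cdkn1a] += e["cdkn1a_up"]
    if layout.ccna2 >= 0:
        v[layout.ccna2] += e["ccna2_down"]
    eff["II"] = v

    v = np.zeros(n_feat)
    v[sig["ribosome_small"]] += e["ribosome_down"]
    v[sig["ribosome_large"]] += e["ribosome_down"]
    v[sig["glycolysis"]] += e["glycolysis_down"]
    v[sig["oxphos"]] += e["oxphos_down_typeIII"]
    v[sig["p53_targets"]] += e["p53_up"]
    eff["III"] = v

    # Treated embryos: Type III-like but with glycolysis restored and the
    # fatty-acid oxidation program induced.
    v = np.zeros(n_feat)
    v[sig["ribosome_small"]] += e["ribosome_down"]
    v[sig["ribosome_large"]] += e["ribosome_down"]
    v[sig["oxphos"]] += e["oxphos_down_typeIII"]
    v[sig["p53_targets"]] += e["p53_up"]
    v[sig["fatty_acid"]] += e["fatty_acid_up_treated"]
    eff["treated"] = v
    return eff


def _auto_aneuploidies(
    p: GeneratorParams, st: pd.DataFrame, rng: np.random.Generator
) -> list[tuple[str, str, float]]:
    if p.n_aneuploid <= 0:
        return []
    normals = st.index[st["group"] == "normal"].to_numpy()
    arrested = st.index[st["group"] == "arrested"].to_numpy()
    n_arr = min(2, p.n_aneuploid, len(arrested))
    n_norm = p.n_aneuploid - n_arr
    chosen = list(rng.choice(normals, size=n_norm, replace=False)) + list(
        rng.choice(arrested, size=n_arr, replace=False)
    )
    autosomes = [c for c in CHROMOSOMES if c not in ("chrX", "chrY")]
    out = []
    for i, sid in enumerate(chosen):
        chrom = str(rng.choice(autosomes))
        dosage = 1.5 if i % 2 == 0 else 0.5
        out.append((str(sid), chrom, dosage))
    return out


def expected_means(
    p: GeneratorParams,
    profiles: pd.DataFrame,
    layout: _FeatureLayout,
    st: pd.DataFrame,
    depth_factors: pd.Series,
    aneuploidies: list[tuple[str, str, float]],
) -> pd.DataFrame:
    """Noise-free expected count matrix (features x samples)."""
    eff = _arrest_multipliers(p, layout)
    gc_mult = gc_bias_factor(
        layout.annotation["gc_fraction"].to_numpy(), p.gc_bias_amplitude
    )
    chrom = layout.annotation["chromosome"].to_numpy()
    aneu_by_sample: dict[str, list[tuple[str, float]]] = {}
    for sid, c, d in aneuploidies:
        aneu_by_sample.setdefault(sid, []).append((c, d))

    cols = {}
    for sid, row in st.iterrows():
        mu = profiles[row["stage"]].to_numpy().copy()
        if row["group"] == "arrested":
            mu = mu * np.exp2(eff[row["arrest_type"]])
        elif row["group"] == "treated":
            mu = mu * np.exp2(eff["treated"])
        mu = mu * gc_mult * depth_factors[sid]
        for c, d in aneu_by_sample.get(sid, []):
            mu = np.where(chrom == c, mu * d, mu)
        cols[sid] = mu
    return pd.DataFrame(cols, index=profiles.index)


def simulate_dataset(
    p: GeneratorParams,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw a complete synthetic dataset.

    Returns (raw ExpressionMatrix, feature annotation, sample table, ground
    truth).  Counts are negative binomial with variance mu + dispersion*mu^2
    (gamma-Poisson mixture); dispersion 0 degrades to Poisson.  The same seed
    yields a bit-identical dataset.
    """
    profiles, layout = build_reference_profiles(p)
    rng = np.random.default_rng(p.seed + 1)  # independent of profile stream

    sample_ids, st = _sample_ids_for(p)
    depth = pd.Series(
        np.exp(rng.normal(0.0, p.libsize_sigma, size=len(sample_ids))),
        index=sample_ids,
    )
    aneuploidies = (
        list(p.aneuploid_samples)
        if p.aneuploid_samples is not None
        else _auto_aneuploidies(p, st, rng)
    )
    for sid, chrom, dosage in aneuploidies:
        if sid not in st.index:
            raise ValueError(f"aneuploid sample {sid!r} not in sample table")
        if chrom not in CHROMOSOMES:
            raise ValueError(f"unknown chromosome {chrom!r}")

    mu = expected_means(p, profiles, layout, st, depth, aneuploidies).to_numpy()
    if p.nb_dispersion > 0:
        shape = 1.0 / p.nb_dispersion
        lam = rng.gamma(shape, mu * p.nb_dispersion)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)

    m = ExpressionMatrix(
        values=counts.astype(float),
        feature_ids=layout.feature_ids,
        sample_ids=sample_ids,
        layer="raw",
    )
    fids = np.asarray(layout.feature_ids, dtype=object)
    truth = GroundTruth(
        stage=st["stage"].to_dict(),
        group=st["group"].to_dict(),
        arrest_type=st["arrest_type"].to_dict(),
        maternal_genes=list(fids[layout.maternal]),
        zga_genes=list(fids[layout.zga]),
        signature_genes={k: list(fids[v]) for k, v in layout.signature.items()},
        te_family={
            fid: str(layout.annotation.loc[fid, "te_family"])
            for fid in fids[layout.te]
        },
        aneuploidies=aneuploidies,
        effects_applied=dict(p.effect_log2),
        depth_factors=depth.round(6).to_dict(),
    )
    log.info(
        "simulated %d features x %d samples (seed=%d, %d aneuploidies)",
        m.n_features, m.n_samples, p.seed, len(aneuploidies),
    )
    return m, layout.annotation, st, truth


def truth_gene_sets(truth: GroundTruth) -> GeneSetCollection:
    """Planted program memberships as a GMT-ready collection."""
    sets = {name: members for name, members in truth.signature_genes.items()}
    sets["maternal"] = list(truth.maternal_genes)
    sets["zga"] = list(truth.zga_genes)
    desc = {name: "planted synthetic program" for name in sets}
    return GeneSetCollection(sets=sets, descriptions=desc)


def emit_default_fixture(
    out_dir: str | Path, seed: int = 0, params: Optional[GeneratorParams] = None
) -> dict[str, Path]:
    """Write the full fixture file set for the default (or given) parameters.

    Emits the MTX matrix with id sidecars, annotation and sample TSVs, the
    planted gene sets as GMT, the ground-truth JSON, the generator parameters
    and a run manifest — nine files total.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = params if params is not None else GeneratorParams(seed=seed)
    if params is not None and seed != p.seed:
        p = GeneratorParams(**{**asdict(p), "seed": seed})
    m, ann, st, truth = simulate_dataset(p)

    paths = {
        "matrix": out / "matrix.mtx",
        "features": out / "features.tsv",
        "samples": out / "samples.tsv",
        "annotation": out / "feature_annotation.tsv",
        "sample_table": out / "sample_table.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "truth": out / "truth.json",
        "params": out / "params.json",
        "manifest": out / "manifest.json",
    }
    eio.write_counts(m, paths["matrix"], paths["features"], paths["samples"], "mtx")
    eio.write_feature_annotation(ann, paths["annotation"])
    eio.write_sample_table(st, paths["sample_table"])
    eio.write_gmt(truth_gene_sets(truth), paths["gene_sets"])
    truth.to_json(paths["truth"])
    Path(paths["params"]).write_text(json.dumps(asdict(p), indent=2) + "\n")
    eio.write_manifest(paths["manifest"], seed=p.seed, stage="simulate",
                       shape=[m.n_features, m.n_samples])
    return paths
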