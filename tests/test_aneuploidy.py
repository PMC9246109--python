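"""Expression karyotyping: proportions, robust Z-scores and calls."""

import numpy as np
import pandas as pd
import pytest

from embryoarrest.datamodel import ExpressionMatrix
from embryoarrest.aneuploidy import (
    call_aneuploidy,
    chromosome_proportions,
    dosage_zscores,
    summarize_by_stage,
)


def _norm_matrix(values, fids, sids):
    return ExpressionMatrix(values, fids, sids, "gc_normalized")


def _ann(fids, chroms):
    return pd.DataFrame(
        {"kind": ["gene"] * len(fids), "chromosome": chroms,
         "gc_fraction": 0.5},
        index=pd.Index(fids, name="feature_id"),
    )


def test_proportions_split_and_degenerate_cases():
    m = _norm_matrix([[6.0], [4.0]], ["g1", "g2"], ["s1"])
    ann = _ann(["g1", "g2"], ["chr1", "chr2"])
    props = chromosome_proportions(m, ann)
    assert props.loc["s1", "chr1"] == pytest.approx(0.6)
    assert props.loc["s1", "chr2"] == pytest.approx(0.4)
    assert props.sum(axis=1).iloc[0] == pytest.approx(1.0, abs=1e-9)

    ann_all1 = _ann(["g1", "g2"], ["chr1", "chr1"])
    assert chromosome_proportions(m, ann_all1).loc["s1", "chr1"] == pytest.approx(1.0)

    with pytest.raises(ValueError, match="zero"):
        chromosome_proportions(
            _norm_matrix([[0.0], [0.0]], ["g1", "g2"], ["s1"]), ann
        )


def test_te_features_do_not_contribute():
    m = _norm_matrix([[5.0], [5.0], [100.0]], ["g1", "g2", "TE:a"], ["s1"])
    ann = _ann(["g1", "g2", "TE:a"], ["chr1", "chr2", "NA"])
    ann.loc["TE:a", "kind"] = "TE"
    props = chromosome_proportions(m, ann)
    assert props.loc["s1", "chr1"] == pytest.approx(0.5)


def test_proportions_invariant_to_library_depth():
    rng = np.random.default_rng(0)
    values = rng.poisson(50, size=(40, 6)).astype(float) + 1
    fids = [f"g{i}" for i in range(40)]
    chroms = [f"chr{1 + i % 4}" for i in range(40)]
    m = _norm_matrix(values, fids, [f"s{i}" for i in range(6)])
    scaled = values.copy()
    scaled[:, 2] *= 7.3
    m2 = _norm_matrix(scaled, fids, list(m.sample_ids))
    ann = _ann(fids, chroms)
    pd.testing.assert_frame_equal(
        chromosome_proportions(m, ann), chromosome_proportions(m2, ann)
    )


def brute_force_robust_z(props, ref):
    out = pd.DataFrame(index=props.index, columns=props.columns, dtype=float)
    for c in props.columns:
        centre = np.median(ref[c])
        mad = np.median(np.abs(ref[c] - centre)) * 1.4826
        scale = mad if mad > 0 else ref[c].std(ddof=1)
        out[c] = (props[c] - centre) / scale
    return out


def _stage_table(sids, stage="c8", group="normal"):
    return pd.DataFrame(
        {"stage": stage, "group": group,
         "arrest_type": "none" if group == "normal" else "I"},
        index=pd.Index(sids, name="sample_id"),
    )


def test_dosage_z_matches_brute_force_oracle():
    rng = np.random.default_rng(1)
    props = pd.DataFrame(
        rng.dirichlet(np.full(5, 40.0), size=8),
        index=[f"s{i}" for i in range(8)],
        columns=[f"chr{i}" for i in range(1, 6)],
    )
    st = _stage_table(props.index)
    z = dosage_zscores(props, st)
    expected = brute_force_robust_z(props, props)
    np.testing.assert_allclose(z.to_numpy(), expected.to_numpy(), atol=1e-12)


def test_sample_at_group_median_scores_zero():
    base = np.array([0.2, 0.3, 0.5])
    props = pd.DataFrame(
        [base + d for d in (-0.02, -0.01, 0.0, 0.01, 0.02)],
        index=[f"s{i}" for i in range(5)],
        columns=["chr1", "chr2", "chr3"],
    )
    st = _stage_table(props.index)
    z = dosage_zscores(props, st)
    np.testing.assert_allclose(z.loc["s2"], 0.0, atol=1e-12)


def test_shifted_sample_scores_about_three_scales():
    rng = np.random.default_rng(3)
    props = pd.DataFrame(
        0.25 + rng.normal(0, 0.01, size=(10, 4)),
        index=[f"s{i}" for i in range(10)],
        columns=[f"chr{i}" for i in range(1, 5)],
    )
    ref = props.copy()
    mad = (ref["chr1"] - ref["chr1"].median()).abs().median() * 1.4826
    probe = props.iloc[[0]].copy()
    probe.index = ["probe"]
    probe["chr1"] = props["chr1"].median() + 3 * mad
    all_props = pd.concat([props, probe])
    st = _stage_table(props.index)
    st = pd.concat([st, _stage_table(["probe"], group="arrested")])
    z = dosage_zscores(all_props, st)
    assert z.loc["probe", "chr1"] == pytest.approx(3.0, abs=1e-9)


def test_small_reference_group_is_an_error():
    props = pd.DataFrame(
        np.full((3, 2), 0.5), index=["a", "b", "c"], columns=["chr1", "chr2"]
    )
    with pytest.raises(ValueError, match="pool_stages"):
        dosage_zscores(props, _stage_table(props.index))


def test_calls_threshold_semantics():
    z = pd.DataFrame(
        [[0.0, 4.0], [0.0, -3.5], [0.0, 0.0]],
        index=["s1", "s2", "s3"], columns=["chr1", "chr2"],
    )
    props = z * 0 + 0.5
    calls, flags = call_aneuploidy(z, props, threshold=3.0)
    tab = calls.set_index(["sample_id", "chromosome"])["call"]
    assert tab[("s1", "chr2")] == "gain"
    assert tab[("s2", "chr2")] == "loss"
    assert tab[("s3", "chr2")] == "neutral"
    assert flags.tolist() == [True, True, False]

    _, none_flags = call_aneuploidy(z, props, threshold=np.inf)
    assert not none_flags.any()

    zero_calls, zero_flags = call_aneuploidy(z * 0, props, threshold=3.0)
    assert (zero_calls["call"] == "neutral").all()
    assert not zero_flags.any()


def test_stage_summary_bookkeeping():
    sids = [f"s{i}" for i in range(10)]
    st = _stage_table(sids, stage="morula")
    z = pd.DataFrame(0.0, index=sids, columns=["chr1", "chr2"])
    z.iloc[:3, 0] = 5.0
    props = z * 0 + 0.5
    calls, flags = call_aneuploidy(z, props, threshold=3.0)
    by_stage, by_chrom = summarize_by_stage(calls, flags, st)
    row = by_stage.set_index("stage").loc["morula"]
    assert row["n_samples"] == 10
    assert row["n_aneuploid"] == 3
    assert row["fraction"] == pytest.approx(0.3)
    assert ((by_stage["fraction"] >= 0) & (by_stage["fraction"] <= 1)).all()
    assert by_chrom.set_index("chromosome").loc["chr1", "gain"] == 3


def test_dosage_monotone_in_planted_dosage(small_dataset):
    """Noise-free planted dosages 1.1 < 1.25 < 1.5 give increasing z."""
    from embryoarrest.simulate import GeneratorParams, simulate_dataset
    from embryoarrest.normalize import apply_size_factors, size_factors_median_of_ratios
    from conftest import SMALL

    zs = []
    for dosage in (1.1, 1.25, 1.5):
        p = GeneratorParams(
            **{**SMALL, "nb_dispersion": 0.0, "libsize_sigma": 0.0,
               "gc_bias_amplitude": 0.0, "embryos_per_stage": 6,
               "aneuploid_samples": [("c8_00", "chr7", 1.5)]}
        )
        m, ann, st, _ = simulate_dataset(p)
        # rescale the planted chromosome to the probed dosage analytically
        chr7 = (ann["chromosome"].reindex(m.feature_ids) == "chr7").to_numpy()
        values = m.values.copy().astype(float)
        col = m.sample_index(["c8_00"])[0]
        values[chr7, col] = np.round(values[chr7, col] / 1.5 * dosage)
        m2 = ExpressionMatrix(values, m.feature_ids, m.sample_ids, "raw")
        sf = size_factors_median_of_ratios(m2)
        m_size = apply_size_factors(m2, sf)
        props = chromosome_proportions(m_size, ann)
        z = dosage_zscores(props, st)
        zs.append(z.loc["c8_00", "chr7"])
    assert zs[0] < zs[1] < zs[2]
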