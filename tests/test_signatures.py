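"""Set scores, rankings, TE fraction, metabolic coordinates and GSEA."""

import numpy as np
import pandas as pd
import pytest

from embryoarrest.datamodel import ExpressionMatrix, GeneSetCollection
from embryoarrest.de import nb_wald_de, welch_t
from embryoarrest.normalize import size_factors_median_of_ratios
from embryoarrest.signatures import (
    gsea_preranked,
    metabolic_coordinates,
    rank_samples,
    set_score,
    te_fraction,
)
from embryoarrest.simulate import truth_gene_sets


def _z(values, fids, sids):
    return ExpressionMatrix(values, fids, sids, "zscore")


def test_set_score_identities():
    z = _z(np.array([[1.0, -1.0], [3.0, 0.0], [0.0, 0.0]]),
           ["a", "b", "c"], ["s1", "s2"])
    sets = GeneSetCollection(sets={"pair": ["a", "b"], "single": ["c"]})
    sums = set_score(z, sets, "sum")
    means = set_score(z, sets, "mean")
    assert sums.loc["s1", "pair"] == pytest.approx(4.0)
    assert means.loc["s1", "pair"] == pytest.approx(2.0)
    np.testing.assert_allclose(sums["pair"], means["pair"] * 2)
    # singleton score is that gene's Z
    np.testing.assert_allclose(sums["single"], z.values[2])
    # all-zero Z gives zero scores
    zero = set_score(_z(np.zeros((3, 2)), ["a", "b", "c"], ["s1", "s2"]), sets, "sum")
    assert (zero.to_numpy() == 0).all()


def test_set_score_linearity_in_z():
    rng = np.random.default_rng(0)
    vals = rng.normal(size=(10, 4))
    fids = [f"g{i}" for i in range(10)]
    sets = GeneSetCollection(sets={"s": fids[:5]})
    a = set_score(_z(vals, fids, list("wxyz")), sets, "sum")
    b = set_score(_z(vals * 3.5, fids, list("wxyz")), sets, "sum")
    np.testing.assert_allclose(b.to_numpy(), a.to_numpy() * 3.5)


def test_set_score_missing_members_guard():
    z = _z(np.zeros((1, 2)), ["a"], ["s1", "s2"])
    with pytest.raises(ValueError, match="mostly_absent"):
        set_score(z, GeneSetCollection(sets={"mostly_absent": ["a", "b", "c"]}), "sum")


def test_ranking_descending_with_deterministic_ties():
    scores = pd.DataFrame({"s": [2.0, 5.0, 2.0]}, index=["b", "a", "c"])
    assert rank_samples(scores, "s") == ["a", "b", "c"]
    flipped = rank_samples(-scores, "s")
    assert flipped[-1] == "a" and set(flipped[:2]) == {"b", "c"}
    with pytest.raises(ValueError):
        rank_samples(scores, "nope")


def test_te_fraction_extremes():
    fids = ["g1", "TE:a"]
    ann = pd.DataFrame(
        {"kind": ["gene", "TE"], "chromosome": ["chr1", "NA"],
         "gc_fraction": [0.5, np.nan]},
        index=pd.Index(fids, name="feature_id"),
    )
    all_te = ExpressionMatrix([[0.0], [50.0]], fids, ["s1"], "gc_normalized")
    assert te_fraction(all_te, ann)["s1"] == pytest.approx(100.0)
    no_te = ExpressionMatrix([[50.0], [0.0]], fids, ["s1"], "gc_normalized")
    assert te_fraction(no_te, ann)["s1"] == pytest.approx(0.0)
    with pytest.raises(ValueError, match="zero total"):
        te_fraction(ExpressionMatrix([[0.0], [0.0]], fids, ["s1"], "gc_normalized"), ann)


def test_type_one_te_fraction_elevated(default_dataset, default_layers):
    m, ann, st, truth = default_dataset
    tef = te_fraction(default_layers.m_gc, ann)
    t1 = truth.samples_of_type("I")
    c4 = st.index[(st["group"] == "normal") & (st["stage"] == "c4")]
    assert tef[t1].mean() > tef[c4].mean()
    _, p = welch_t(tef[t1], tef[c4])
    assert p < 0.05


def test_metabolic_coordinates_pass_through(default_dataset, default_layers):
    m, ann, st, truth = default_dataset
    scores = set_score(default_layers.m_z, truth_gene_sets(truth), "sum")
    coords = metabolic_coordinates(scores, "glycolysis", "oxphos")
    np.testing.assert_allclose(coords["x"], scores["glycolysis"])
    np.testing.assert_allclose(coords["y"], scores["oxphos"])
    # planted metabolic states: Type II below/above the morula centroid
    t2 = truth.samples_of_type("II")
    t3 = truth.samples_of_type("III")
    treated = st.index[st["group"] == "treated"]
    morula = st.index[(st["group"] == "normal") & (st["stage"] == "morula")]
    assert coords.loc[t2, "x"].mean() < coords.loc[morula, "x"].mean()
    assert coords.loc[t2, "y"].mean() > coords.loc[morula, "y"].mean()
    assert coords.loc[treated, "x"].mean() > coords.loc[t3, "x"].mean()


def test_arrested_embryos_rank_low_on_ribosomes_high_on_p53(
    default_dataset, default_layers
):
    m, ann, st, truth = default_dataset
    sets = truth_gene_sets(truth)
    scores = set_score(default_layers.m_z, sets, "sum")
    combined = (
        scores[["ribosome_small", "ribosome_large", "nucleosome"]].sum(axis=1)
        .to_frame("ribosome_nucleosome")
    )
    arrested = set(truth.samples_of_type("II") + truth.samples_of_type("III"))
    order = rank_samples(combined, "ribosome_nucleosome")
    bottom = set(order[-(len(order) // 4):])
    assert np.mean([s in bottom for s in arrested]) >= 0.8
    order_p53 = rank_samples(scores, "p53_targets")
    top = set(order_p53[: len(order_p53) // 4])
    assert np.mean([s in top for s in arrested]) >= 0.8


# ---------------------------------------------------------------------------
# GSEA
# ---------------------------------------------------------------------------

def brute_force_es(metric: pd.Series, members, weight_p):
    """Running-sum enrichment score computed position by position."""
    order = sorted(metric.index, key=lambda f: (-metric[f], f))
    hits = set(members)
    w = np.array([abs(metric[f]) ** weight_p if f in hits else 0.0 for f in order])
    total_w = w.sum()
    miss = 1.0 / (len(order) - len(members))
    running = 0.0
    best = 0.0
    for f, wi in zip(order, w):
        if f in hits:
            running += wi / total_w
        else:
            running -= miss
        if abs(running) > abs(best):
            best = running
    return best


@pytest.fixture()
def toy_ranking():
    rng = np.random.default_rng(12)
    metric = pd.Series(
        np.sort(rng.normal(size=100))[::-1], index=[f"g{i:03d}" for i in range(100)]
    )
    return metric


@pytest.mark.parametrize("weight_p", [0.0, 1.0])
def test_es_matches_brute_force_running_sum(toy_ranking, weight_p):
    top5 = list(toy_ranking.index[:5])
    rng = np.random.default_rng(3)
    rand20 = list(rng.choice(toy_ranking.index, 20, replace=False))
    sets = GeneSetCollection(sets={"top5": top5, "rand20": rand20})
    res = gsea_preranked(toy_ranking, sets, n_perm=200, weight_p=weight_p, seed=0)
    for name, members in (("top5", top5), ("rand20", rand20)):
        expected = brute_force_es(toy_ranking, members, weight_p)
        assert res.loc[name, "es"] == pytest.approx(expected, abs=1e-12)
        assert -1.0 <= res.loc[name, "es"] <= 1.0
        assert set(res.loc[name, "leading_edge"]) <= set(members)
        assert 0.0 < res.loc[name, "p"] <= 1.0


def test_es_negates_when_metric_negated(toy_ranking):
    members = list(toy_ranking.index[:10])
    sets = GeneSetCollection(sets={"s": members})
    fwd = gsea_preranked(toy_ranking, sets, n_perm=200, seed=0)
    rev = gsea_preranked(-toy_ranking, sets, n_perm=200, seed=0)
    assert rev.loc["s", "es"] == pytest.approx(-fwd.loc["s", "es"], abs=1e-12)


def test_gsea_is_bit_reproducible(toy_ranking):
    sets = GeneSetCollection(sets={"s": list(toy_ranking.index[:8])})
    a = gsea_preranked(toy_ranking, sets, n_perm=300, seed=42)
    b = gsea_preranked(toy_ranking, sets, n_perm=300, seed=42)
    pd.testing.assert_frame_equal(a, b)


def test_gsea_rejects_whole_ranking_set(toy_ranking):
    sets = GeneSetCollection(sets={"all": list(toy_ranking.index)})
    with pytest.raises(ValueError, match="whole ranking"):
        gsea_preranked(toy_ranking, sets, n_perm=200, seed=0)


def test_planted_up_set_enriched_in_wald_ranking(default_dataset):
    m, ann, st, truth = default_dataset
    sf = size_factors_median_of_ratios(m)
    morula = st.index[(st["group"] == "normal") & (st["stage"] == "morula")].tolist()
    res = nb_wald_de(m, morula, truth.samples_of_type("II"), sf)
    metric = res.table["stat"]
    rng = np.random.default_rng(0)
    background = [f for f in metric.index if f.startswith("G")]
    set_map = {
        "p53": [g for g in truth.signature_genes["p53_targets"] if g in metric.index],
    }
    for k in range(5):
        set_map[f"random{k}"] = list(rng.choice(background, 60, replace=False))
    out = gsea_preranked(metric, GeneSetCollection(sets=set_map), n_perm=500, seed=1)
    assert out.loc["p53", "nes"] > 0
    assert out.loc["p53", "q"] < 0.05
    random_q = out.loc[[f"random{k}" for k in range(5)], "q"]
    assert np.median(random_q) >= 0.05
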