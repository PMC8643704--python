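"""Unit tests for gene classification, distances, KS curves, and enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from hicarch.features import (
    annotate_switch_overlap, boundary_enrichment, classify_genes,
    cumulative_curves_ks, nearest_distance,
)

from conftest import brute_nearest


# ---- classify_genes ----------------------------------------------------------

def test_classify_threshold_edges():
    de = pd.DataFrame({
        "gene": list("abcdefg"),
        "log2fc": [2.0, -2.0, 1.5, -1.5, 1.6, -1.6, 0.0],
        "fdr": [0.01, 0.01, 0.01, 0.01, 0.05, 0.049, 0.001],
    })
    cls = classify_genes(de)
    # strict inequalities: |lfc| = 1.5 and fdr = 0.05 are both 'non'
    assert list(cls) == ["up", "down", "non", "non", "non", "down", "non"]


def test_classify_missing_fdr_warns():
    de = pd.DataFrame({"gene": ["a", "b"], "log2fc": [3.0, 3.0],
                       "fdr": [np.nan, 0.01]})
    with pytest.warns(RuntimeWarning, match="missing FDR"):
        cls = classify_genes(de)
    assert list(cls) == ["non", "up"]


def test_classify_threshold_validation():
    de = pd.DataFrame({"gene": ["a"], "log2fc": [1.0], "fdr": [0.5]})
    with pytest.raises(ValueError):
        classify_genes(de, fdr_max=0.0)


@given(st.floats(-8, 8, allow_nan=False), st.floats(0, 1, allow_nan=False))
def test_classify_rule_property(lfc, fdr):
    de = pd.DataFrame({"gene": ["g"], "log2fc": [lfc], "fdr": [fdr]})
    got = classify_genes(de).iloc[0]
    if fdr < 0.05 and lfc > 1.5:
        assert got == "up"
    elif fdr < 0.05 and lfc < -1.5:
        assert got == "down"
    else:
        assert got == "non"


# ---- nearest_distance ----------------------------------------------------------

def _tss(positions, chrom="chrT"):
    return pd.DataFrame({"chrom": chrom, "start": positions,
                         "end": np.asarray(positions) + 1})


def test_nearest_distance_basic():
    targets = pd.DataFrame({"chrom": "chrT", "start": [100, 500],
                            "end": [200, 600]})
    tss = _tss([50, 150, 200, 350, 700])
    d = nearest_distance(tss, targets)
    assert list(d) == [50.0, 0.0, 0.0, 150.0, 100.0]


def test_nearest_distance_other_chrom_nan():
    targets = pd.DataFrame({"chrom": ["chrZ"], "start": [0], "end": [10]})
    d = nearest_distance(_tss([5]), targets)
    assert np.isnan(d[0])


def test_nearest_distance_nested_intervals():
    targets = pd.DataFrame({"chrom": "chrT", "start": [100, 120],
                            "end": [400, 150]})
    d = nearest_distance(_tss([300, 500]), targets)
    assert d[0] == 0.0
    assert d[1] == 100.0


def test_nearest_distance_matches_brute_force():
    rng = np.random.default_rng(0)
    for trial in range(20):
        starts = rng.integers(0, 10_000, size=15)
        lens = rng.integers(1, 500, size=15)
        targets = pd.DataFrame({
            "chrom": rng.choice(["chrA", "chrB"], size=15),
            "start": starts, "end": starts + lens})
        tss = pd.DataFrame({
            "chrom": rng.choice(["chrA", "chrB", "chrC"], size=30),
            "start": rng.integers(0, 11_000, size=30)})
        tss["end"] = tss["start"] + 1
        got = nearest_distance(tss, targets)
        ref = brute_nearest(tss, targets)
        assert np.allclose(got, ref, equal_nan=True)


@given(st.integers(0, 4_000))
def test_nearest_distance_translation_invariance(shift):
    rng = np.random.default_rng(42)
    starts = rng.integers(0, 5_000, size=10)
    targets = pd.DataFrame({"chrom": "chrT", "start": starts,
                            "end": starts + 100})
    tss = _tss(rng.integers(0, 6_000, size=12))
    d0 = nearest_distance(tss, targets)
    d1 = nearest_distance(
        tss.assign(start=tss["start"] + shift),
        targets.assign(start=targets["start"] + shift,
                       end=targets["end"] + shift))
    assert np.allclose(d0, d1)


# ---- cumulative curves / KS -------------------------------------------------------

def test_cdf_values_and_ks():
    d = {"up": [1.0, 2.0, 3.0, 4.0, 5.0],
         "non": [10.0, 20.0, 30.0, 40.0, 50.0, 60.0]}
    curves, ks = cumulative_curves_ks(d)
    up = curves[curves["cls"] == "up"]
    assert np.allclose(up["cdf"], np.arange(1, 6) / 5)
    ref = stats.ks_2samp(d["up"], d["non"], alternative="two-sided")
    assert ks.iloc[0]["ks_d"] == pytest.approx(ref.statistic)
    assert ks.iloc[0]["p_value"] == pytest.approx(ref.pvalue)


def test_small_class_excluded():
    d = {"up": [1.0, 2.0], "non": np.arange(10.0), "down": np.arange(8.0)}
    with pytest.warns(RuntimeWarning, match="excluded"):
        curves, ks = cumulative_curves_ks(d)
    assert set(curves["cls"]) == {"non", "down"}


def test_too_few_classes():
    with pytest.raises(ValueError):
        cumulative_curves_ks({"up": np.arange(10.0), "non": [1.0]})


# ---- switch-overlap annotation ------------------------------------------------------

def test_annotate_switch_overlap():
    genes = pd.DataFrame({"chrom": "chrT", "start": [5, 15, 25, 95],
                          "end": [6, 16, 26, 96],
                          "name": list("abcd"),
                          "cls": ["up", "up", "non", "up"]})
    switch = np.array(["A->B", "stable-A", "B->A", "NA"] + ["NA"] * 6,
                      dtype=object)
    per_gene, fracs = annotate_switch_overlap(genes, switch, bin_size=10)
    assert list(per_gene) == ["A->B", "stable-A", "B->A", "NA"]
    up = fracs[fracs["gene_class"] == "up"].set_index("switch_class")
    assert up.loc["A->B", "fraction"] == pytest.approx(0.5)
    assert up.loc["stable-A", "fraction"] == pytest.approx(0.5)


# ---- boundary enrichment -------------------------------------------------------------

def _enh(mids, chrom="chrT", width=2):
    mids = np.asarray(mids)
    return pd.DataFrame({"chrom": chrom, "start": mids - width // 2,
                         "end": mids + width - width // 2,
                         "name": [f"e{k}" for k in range(mids.size)]})


def test_enrichment_hand_example():
    # two up genes: promoters 1000 and 5000, nearest enhancers 1400 and 5600;
    # boundaries: 1200 (inside (1000,1400)) and 4500 (inside (4400,5000),
    # the mirror of gene 2) -> observed 1, control 1
    genes = pd.DataFrame({"chrom": "chrT", "start": [1000, 5000],
                          "end": [1001, 5001], "name": ["g1", "g2"],
                          "cls": ["up", "up"]})
    enh = _enh([1400, 5600])
    res = boundary_enrichment(genes, enh, {"chrT": np.array([1200, 4500])},
                              {"chrT": 100_000})
    r = {e.gene_class: e for e in res}["up"]
    assert r.n_genes == 2
    assert r.observed_count == 1
    assert r.control_count == 1
    assert r.enrichment == pytest.approx(1.0)


def test_enrichment_open_interval_strict():
    genes = pd.DataFrame({"chrom": "chrT", "start": [1000], "end": [1001],
                          "name": ["g"], "cls": ["up"]})
    enh = _enh([2000])
    # boundaries exactly at the promoter and the enhancer midpoint: no hit
    res = boundary_enrichment(genes, enh, {"chrT": np.array([1000, 2000])},
                              {"chrT": 100_000})
    assert res[0].observed_count == 0
    res2 = boundary_enrichment(genes, enh, {"chrT": np.array([1001])},
                               {"chrT": 100_000})
    assert res2[0].observed_count == 1


def test_enrichment_mirror_off_chromosome_drops_gene():
    genes = pd.DataFrame({"chrom": "chrT", "start": [100], "end": [101],
                          "name": ["g"], "cls": ["up"]})
    enh = _enh([900])   # mirror c = 2*100 - 900 = -700 < 0
    res = boundary_enrichment(genes, enh, {"chrT": np.array([500])},
                              {"chrT": 100_000})
    assert res[0].n_genes == 0
    assert res[0].observed_count == 0


def test_enrichment_zero_control_warns_nan():
    genes = pd.DataFrame({"chrom": "chrT", "start": [1000], "end": [1001],
                          "name": ["g"], "cls": ["up"]})
    enh = _enh([2000])
    with pytest.warns(RuntimeWarning, match="control count 0"):
        res = boundary_enrichment(genes, enh, {"chrT": np.array([1500])},
                                  {"chrT": 100_000})
    assert res[0].observed_count == 1
    assert np.isnan(res[0].enrichment)


@given(st.integers(0, 50_000))
def test_enrichment_translation_invariance(shift):
    rng = np.random.default_rng(9)
    p = np.sort(rng.integers(10_000, 40_000, size=12))
    genes = pd.DataFrame({"chrom": "chrT", "start": p, "end": p + 1,
                          "name": [f"g{k}" for k in range(12)],
                          "cls": ["up"] * 12})
    enh = _enh(rng.integers(10_000, 40_000, size=12))
    bpos = np.sort(rng.integers(0, 50_000, size=30))
    base = boundary_enrichment(genes, enh, {"chrT": bpos},
                               {"chrT": 10_000_000})[0]
    moved = boundary_enrichment(
        genes.assign(start=genes["start"] + shift, end=genes["end"] + shift),
        enh.assign(start=enh["start"] + shift, end=enh["end"] + shift),
        {"chrT": bpos + shift}, {"chrT": 10_000_000})[0]
    assert (base.observed_count, base.control_count, base.n_genes) == \
        (moved.observed_count, moved.control_count, moved.n_genes)
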