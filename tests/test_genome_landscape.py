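"""Chromosome bias, sliding windows, GLC clustering and operon analyses."""

import numpy as np
import pandas as pd
import pytest

from seesawtx import genome_landscape as gl
from seesawtx.seesaw_core import classify_quadrant

from conftest import make_annotation, make_de


def brute_force_clusters(flags, min_size, max_gap):
    """Oracle: enumerate all candidate attribute-index segments, keep those
    satisfying gap/size constraints that no extension preserves."""
    idx = [i for i, f in enumerate(flags) if f]
    out = []
    for si in range(len(idx)):
        for ei in range(si, len(idx)):
            members = idx[si:ei + 1]
            if len(members) < min_size:
                continue
            gaps_ok = all(members[k + 1] - members[k] - 1 <= max_gap
                          for k in range(len(members) - 1))
            if not gaps_ok:
                continue
            left_ok = si == 0 or members[0] - idx[si - 1] - 1 > max_gap
            right_ok = ei == len(idx) - 1 or idx[ei + 1] - members[-1] - 1 > max_gap
            if left_ok and right_ok:
                out.append(tuple(members))
    return sorted(set(out))


# --- chromosomal bias --------------------------------------------------------

def test_yates_chi2_hand_value():
    assert gl.yates_chi2_2x2([[30, 70], [10, 90]]) == pytest.approx(11.281, abs=5e-4)


def test_yates_chi2_clamps_small_deviations():
    # |O-E| <= 0.5 in every cell -> statistic exactly 0
    assert gl.yates_chi2_2x2([[20, 80], [20, 80]]) == 0.0


def test_chrom_bias_proportional_class_gives_zero_chi2():
    ann = make_annotation(["I"] * 40 + ["II"] * 40,
                          list(range(0, 400000, 10000)) * 2)
    cls = set(ann.loc[ann["chrom"] == "I", "gene_id"][:10]) | \
        set(ann.loc[ann["chrom"] == "II", "gene_id"][:10])
    res = gl.chrom_bias_chi2(cls, ann)
    assert (res["chi2"] == 0).all()


def test_chrom_bias_detects_planted_concentration():
    ann = make_annotation(["I"] * 100 + ["II"] * 100 + ["III"] * 100,
                          list(range(0, 1000000, 10000)) * 3)
    cls = set(ann.loc[ann["chrom"] == "I", "gene_id"][:60])  # all on I
    res = gl.chrom_bias_chi2(cls, ann).set_index("chrom")
    assert res.loc["I", "direction"] == "over"
    assert res.loc["I", "pvalue"] < 1e-6
    assert res.loc["II", "direction"] == "under"


def test_chrom_bias_observed_sums_to_class_size(small_dataset):
    ds = small_dataset
    cls = set(ds.truth.loc[ds.truth["attribute"], "gene_id"])
    res = gl.chrom_bias_chi2(cls, ds.annotation)
    assert res["observed"].sum() == len(cls)


# --- sliding windows ----------------------------------------------------------

def test_window_enrichment_all_genes_is_one(small_dataset):
    ds = small_dataset
    track = gl.sliding_window_enrichment(set(ds.annotation["gene_id"]),
                                         ds.annotation, ds.genome.lengths)
    ok = track[~track["sparse"]]
    assert np.allclose(ok["enrichment"], 1.0)


def test_window_enrichment_toy_two_blocks():
    """10 genes on a 5 Mb chromosome: class in [0, 2.5 Mb), rest beyond."""
    mids = [200000, 400000, 800000, 1200000, 1800000,
            2600000, 3000000, 3400000, 3800000, 4200000]
    ann = make_annotation(["I"] * 10, [m - 500 for m in mids], lengths=1000)
    cls = set(ann.sort_values("start")["gene_id"][:5])
    track = gl.sliding_window_enrichment(cls, ann, {"I": 5_000_000},
                                         window=2_500_000, step=2_500_000,
                                         min_genes=1)
    assert track.loc[0, "enrichment"] == pytest.approx(2.0)
    assert track.loc[1, "enrichment"] == pytest.approx(0.0)


def test_window_sparse_is_na_not_error():
    ann = make_annotation(["I"], [100])
    track = gl.sliding_window_enrichment(set(), ann, {"I": 10_000_000},
                                         min_genes=10)
    assert track["sparse"].all()
    assert track["enrichment"].isna().all()


def test_window_coverage_every_gene_hits_a_window(small_dataset):
    ds = small_dataset
    cls = set(ds.truth.loc[ds.truth["planted_class"] == "seesaw_up_down", "gene_id"])
    track = gl.sliding_window_enrichment(cls, ds.annotation, ds.genome.lengths)
    # windows overlap (window >= step) so summed class counts >= class size
    assert track["n_class"].sum() >= len(cls)


def test_window_validation():
    ann = make_annotation(["I"], [0])
    with pytest.raises(ValueError):
        gl.sliding_window_enrichment(set(), ann, {"I": 100}, window=0)


# --- GLC clustering -------------------------------------------------------------

def test_glc_simple_run():
    ann = make_annotation(["I"] * 3, [0, 2000, 4000])
    cs = gl.glc_cluster([1, 1, 1], ann, min_size=3, max_gap=0)
    assert cs.n_clusters == 1 and cs.clusters[0].size == 3


def test_glc_gap_sensitivity():
    flags = [1, 1, 0, 1, 0, 0, 1, 1, 1]
    ann = make_annotation(["I"] * 9, range(0, 9000, 1000))
    got1 = gl.glc_cluster(flags, ann, min_size=3, max_gap=1)
    assert sorted(len(c.gene_ids) for c in got1.clusters) == [3, 3]
    got0 = gl.glc_cluster(flags, ann, min_size=3, max_gap=0)
    assert [c.size for c in got0.clusters] == [3]


def test_glc_no_flags_no_clusters():
    ann = make_annotation(["I"] * 5, range(0, 5000, 1000))
    assert gl.glc_cluster([0] * 5, ann).n_clusters == 0


def test_glc_respects_chromosome_boundaries():
    ann = make_annotation(["I"] * 3 + ["II"] * 3, [0, 1000, 2000] * 2)
    cs = gl.glc_cluster([1] * 6, ann, min_size=3, max_gap=2)
    assert cs.n_clusters == 2
    assert {c.chrom for c in cs.clusters} == {"I", "II"}


def test_glc_matches_brute_force_oracle():
    rng = np.random.default_rng(3)
    for _ in range(200):
        n = int(rng.integers(5, 120))
        flags = rng.random(n) < rng.uniform(0.1, 0.6)
        min_size = int(rng.integers(2, 5))
        max_gap = int(rng.integers(0, 3))
        ann = make_annotation(["I"] * n, range(0, n * 1000, 1000))
        got = gl.glc_cluster(flags, ann, min_size=min_size, max_gap=max_gap)
        gid_to_pos = {g: i for i, g in enumerate(ann["gene_id"])}
        got_pos = sorted(tuple(gid_to_pos[g] for g in c.gene_ids) for c in got.clusters)
        assert got_pos == brute_force_clusters(flags, min_size, max_gap)


def test_glc_cluster_maximality(small_dataset):
    ds = small_dataset
    flags = ds.truth["attribute"].to_numpy()
    cs = gl.glc_cluster(flags, ds.annotation, min_size=3, max_gap=2)
    pos = {g: i for i, g in enumerate(ds.annotation["gene_id"])}
    attr_pos = np.flatnonzero(flags)
    chrom = ds.annotation["chrom"].to_numpy()
    for c in cs.clusters:
        first, last = pos[c.gene_ids[0]], pos[c.gene_ids[-1]]
        before = attr_pos[attr_pos < first]
        after = attr_pos[attr_pos > last]
        if before.size and chrom[before[-1]] == chrom[first]:
            assert first - before[-1] - 1 > cs.max_gap
        if after.size and chrom[after[0]] == chrom[last]:
            assert after[0] - last - 1 > cs.max_gap


def test_glc_flag_length_mismatch():
    ann = make_annotation(["I"] * 3, [0, 1000, 2000])
    with pytest.raises(ValueError):
        gl.glc_cluster([1, 1], ann)


# --- cluster null ----------------------------------------------------------------

def test_cluster_null_all_genes_fold_one(small_dataset):
    ds = small_dataset
    n = len(ds.annotation)
    cs = gl.cluster_null(np.ones(n, dtype=bool), ds.annotation, S=20, seed=0)
    assert cs.fold_n_clusters == pytest.approx(1.0)
    assert cs.fold_n_clustered == pytest.approx(1.0)


def test_cluster_null_detects_planted_clusters(small_dataset):
    ds = small_dataset
    flags = ds.truth["attribute"].to_numpy()
    cs = gl.cluster_null(flags, ds.annotation, S=500, seed=5)
    assert cs.fold_n_clustered > 1
    assert cs.p_n_clustered == 0.0  # report as < 1/S


def test_cluster_null_random_attribute_fold_near_one(small_dataset):
    ds = small_dataset
    rng = np.random.default_rng(8)
    flags = np.zeros(len(ds.annotation), dtype=bool)
    flags[rng.choice(len(flags), 300, replace=False)] = True
    cs = gl.cluster_null(flags, ds.annotation, S=500, seed=8)
    for fold, mean in ((cs.fold_n_clusters, cs.null_mean_n_clusters),
                       (cs.fold_n_clustered, cs.null_mean_n_clustered)):
        # within 3 null SD of 1 (SD on the fold scale)
        assert abs(fold - 1.0) < 3 * np.sqrt(mean) / mean + 0.2


# --- operons --------------------------------------------------------------------

def test_operon_membership_counts():
    operons = {"op1": ["a", "b"], "op2": ["c", "d"]}
    count, pct = gl.operon_membership({"a", "b", "x", "y"}, operons)
    assert (count, pct) == (2, 50)


def test_operon_membership_paper_arithmetic():
    operons = {f"op{i}": [f"m{i}a", f"m{i}b"] for i in range(46)}
    members = [g for ms in operons.values() for g in ms][:91]
    gene_set = set(members) | {f"z{i}" for i in range(512 - 91)}
    count, pct = gl.operon_membership(gene_set, operons)
    assert (count, pct) == (91, 18)


def test_operon_quadrant_on_means():
    operons = {"op1": ["a", "b"], "op2": ["c", "d"], "op3": ["zz"]}
    phe = make_de(["a", "b", "c", "d"], [1.0, 0.5, 1.0, -1.0])
    stv = make_de(["a", "b", "c", "d"], [-1.0, -0.2, 2.0, -2.0])
    table, tally, skipped = gl.operon_quadrant_classify(operons, phe, stv)
    by_op = table.set_index("operon_id")["quadrant"]
    assert by_op["op1"] == "Q1"
    assert by_op["op2"] == "BOUNDARY"  # both means exactly 0
    assert skipped == ["op3"]
    assert tally["Q1"] == 1


def test_operon_quadrant_tally_matches_brute_force(small_dataset):
    ds = small_dataset
    operons = ds.operons
    table, tally, _ = gl.operon_quadrant_classify(operons, ds.de_phe, ds.de_stv)
    phe = ds.de_phe.set_index("gene_id")["log2fc"]
    stv = ds.de_stv.set_index("gene_id")["log2fc"]
    for row in table.itertuples(index=False):
        members = operons[row.operon_id]
        assert row.quadrant == classify_quadrant(
            float(np.mean([phe[g] for g in members])),
            float(np.mean([stv[g] for g in members])))
    assert sum(tally.values()) == len(table)
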