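"""Generator contracts: determinism, planted fractions, placement bias,
operon/attribute structure, DE table sign structure and recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seesawtx import synthetic_data as sd
from seesawtx.seesaw_core import call_significant_seesaw


def binomial_band(frac, n, k=3):
    sd_ = np.sqrt(frac * (1 - frac) / n)
    return frac - k * sd_, frac + k * sd_


def test_genome_spec_invariants():
    with pytest.raises(ValueError):
        sd.GenomeSpec((("I", 100), ("I", 200)))
    with pytest.raises(ValueError):
        sd.GenomeSpec((("I", 0),))


def test_config_validation():
    with pytest.raises(ValueError):
        sd.GeneratorConfig(n_genes=5).validate()
    with pytest.raises(ValueError):
        sd.GeneratorConfig(noise_sd=0).validate()
    with pytest.raises(ValueError):
        sd.GeneratorConfig(operon_size_range=(1, 3)).validate()
    with pytest.raises(ValueError):
        sd.GeneratorConfig(n_samples=1).validate()


def test_determinism_bit_identical(tmp_path):
    cfg = sd.GeneratorConfig(n_genes=500, seed=7)
    a = sd.simulate(cfg)
    b = sd.simulate(sd.GeneratorConfig(n_genes=500, seed=7))
    pd.testing.assert_frame_equal(a.annotation, b.annotation)
    pd.testing.assert_frame_equal(a.truth, b.truth)
    pd.testing.assert_frame_equal(a.de_phe, b.de_phe)
    pd.testing.assert_frame_equal(a.counts, b.counts)
    pa = sd.write_dataset(a, tmp_path / "a")
    pb = sd.write_dataset(b, tmp_path / "b")
    for name in pa:
        assert pa[name].read_bytes() == pb[name].read_bytes(), name


def test_genes_sorted_nonoverlapping_within_bounds(small_dataset):
    ds = small_dataset
    lengths = ds.genome.lengths
    for chrom, grp in ds.annotation.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        assert (starts[1:] >= ends[:-1]).all(), chrom  # no overlap
        assert starts.min() >= 0 and ends.max() <= lengths[chrom]
        assert (np.diff(starts) >= 0).all()


def test_infeasible_packing_raises():
    genome = sd.GenomeSpec((("I", 40_000),))
    cfg = sd.GeneratorConfig(n_genes=50, genome=genome,
                             gene_length_range=(1000, 1000),
                             class_chromosome_weights={},
                             attribute_chromosome_weights={})
    with pytest.raises(ValueError, match="infeasible"):
        sd.generate_genome(cfg)


def test_class_fractions_within_binomial_band(small_dataset):
    ds = small_dataset
    cfg = ds.config
    frac = ds.truth["planted_class"].isin(["seesaw_up_down", "seesaw_down_up"]).mean()
    lo, hi = binomial_band(cfg.seesaw_fraction_significant, cfg.n_genes)
    assert lo <= frac <= hi
    lo, hi = binomial_band(cfg.attribute_fraction, cfg.n_genes)
    assert lo <= ds.truth["attribute"].mean() <= hi


def test_no_central_bias_when_concentration_zero():
    # class fractions raised so every class has enough genes for the mean
    # of relative midpoints to be a stable statistic
    cfg = sd.GeneratorConfig(n_genes=5000, seed=11, central_concentration=0.0,
                             seesaw_fraction_significant=0.2,
                             concordant_fraction=0.2,
                             class_chromosome_weights={})
    _, ann, truth = sd.generate_genome(cfg)
    lengths = cfg.genome.lengths
    mid = (ann["start"] + ann["end"]) / 2
    rel = mid / ann["chrom"].map(lengths)
    for cls, grp in truth.groupby("planted_class"):
        sel = rel[ann["gene_id"].isin(grp["gene_id"])]
        assert 0.45 <= sel.mean() <= 0.55, cls


def test_central_bias_concentrates_seesaw_class():
    cfg = sd.GeneratorConfig(n_genes=5000, seed=12, central_concentration=0.9)
    _, ann, truth = sd.generate_genome(cfg)
    lengths = cfg.genome.lengths
    mid = (ann["start"] + ann["end"]) / 2
    dev = (mid / ann["chrom"].map(lengths) - 0.5).abs()
    by_class = truth.set_index("gene_id")["planted_class"]
    dev_ss = dev[ann["gene_id"].map(by_class) == "seesaw_up_down"]
    dev_null = dev[ann["gene_id"].map(by_class) == "null"]
    assert dev_ss.mean() < dev_null.mean()
    # two-sample rank test oracle on the positional deviations
    assert stats.mannwhitneyu(dev_ss, dev_null, alternative="less").pvalue < 1e-6


# --- operons -----------------------------------------------------------------

def test_operons_zero_fraction_all_none(small_dataset):
    cfg = sd.GeneratorConfig(n_genes=200, seed=1, operon_fraction=0.0)
    _, ann, _ = sd.generate_genome(cfg)
    out = sd.assign_operons(ann, cfg)
    assert out["operon_id"].isna().all()


def test_operon_fraction_within_band():
    cfg = sd.GeneratorConfig(n_genes=2000, seed=13, operon_fraction=0.15,
                             operon_size_range=(2, 3))
    _, ann, _ = sd.generate_genome(cfg)
    out = sd.assign_operons(ann, cfg)
    frac = out["operon_id"].notna().mean()
    assert 0.12 <= frac <= 0.18


def test_operon_members_consecutive_same_strand_same_chrom(small_dataset):
    ann = small_dataset.annotation
    pos = {g: i for i, g in enumerate(ann["gene_id"])}
    by_gene = ann.set_index("gene_id")
    for op, members in sd.operon_mapping(ann).items():
        assert len(members) >= 2
        idx = [pos[g] for g in members]
        assert idx == list(range(idx[0], idx[0] + len(idx))), op
        assert by_gene.loc[members, "chrom"].nunique() == 1
        assert by_gene.loc[members, "strand"].nunique() == 1


# --- attribute genes -----------------------------------------------------------

def test_attribute_fraction_one_flags_everything():
    cfg = sd.GeneratorConfig(n_genes=300, seed=2, attribute_fraction=1.0)
    _, ann, _ = sd.generate_genome(cfg)
    attr = sd.assign_attribute(ann, cfg)
    assert attr["attribute"].all()


def test_attribute_per_chromosome_fractions_uniform_weights():
    cfg = sd.GeneratorConfig(n_genes=6000, seed=14, attribute_fraction=0.2,
                             attribute_chromosome_weights={})
    _, ann, _ = sd.generate_genome(cfg)
    attr = sd.assign_attribute(ann, cfg)
    merged = ann.merge(attr, on="gene_id")
    for chrom, grp in merged.groupby("chrom", sort=False):
        lo, hi = binomial_band(0.2, len(grp))
        assert lo <= grp["attribute"].mean() <= hi, chrom


def test_attribute_biased_chromosomes_enriched(small_dataset):
    ds = small_dataset
    merged = ds.annotation.merge(ds.truth[["gene_id", "attribute"]], on="gene_id")
    frac = merged.groupby("chrom", sort=False)["attribute"].mean()
    assert min(frac["I"], frac["III"]) > max(frac["II"], frac["IV"], frac["V"], frac["X"])


# --- DE tables ------------------------------------------------------------------

def test_planted_sign_structure(small_dataset):
    ds = small_dataset
    merged = ds.truth.merge(ds.de_phe, on="gene_id").merge(
        ds.de_stv, on="gene_id", suffixes=("_phe", "_stv"))
    ud = merged[merged["planted_class"] == "seesaw_up_down"]
    assert (ud["log2fc_phe"] > 0).all() and (ud["log2fc_stv"] < 0).all()
    du = merged[merged["planted_class"] == "seesaw_down_up"]
    assert (du["log2fc_phe"] < 0).all() and (du["log2fc_stv"] > 0).all()


def test_pvalue_model_limit_zero_fold_change():
    from scipy.special import ndtr
    assert 2 * ndtr(-0.0 / 0.3) == 1.0  # formula limit the generator uses
    cfg = sd.GeneratorConfig(n_genes=100, seed=3)
    _, _, truth = sd.generate_genome(cfg)
    phe, _ = sd.generate_de_tables(truth, cfg)
    # p is a monotone function of |log2fc|
    srt = phe.sort_values("log2fc", key=lambda s: s.abs())
    assert (np.diff(srt["pvalue"]) <= 1e-12).all()


def test_no_planted_signal_yields_chance_level_calls():
    cfg = sd.GeneratorConfig(n_genes=10_000, seed=4,
                             seesaw_fraction_significant=0.0,
                             concordant_fraction=0.0)
    _, _, truth = sd.generate_genome(cfg)
    phe, stv = sd.generate_de_tables(truth, cfg)
    calls = call_significant_seesaw(phe, stv, alpha=0.05)
    # analytic chance bound: BH discoveries per table are near zero under a
    # uniform null; the cross-table overlap is below the hypergeometric
    # mean + 3 SD for the realized per-table discovery counts
    n1 = int((phe["fdr"] < 0.05).sum())
    n2 = int((stv["fdr"] < 0.05).sum())
    from seesawtx.overlap_null import hypergeometric_expected
    mean, var = hypergeometric_expected(n1, n2, 10_000)
    bound = mean + 3 * np.sqrt(var)
    assert len(calls.up_down) <= max(bound, 1)
    assert len(calls.down_up) <= max(bound, 1)


def test_caller_recovery_on_default_fixture(default_dataset):
    ds = default_dataset
    calls = call_significant_seesaw(ds.de_phe, ds.de_stv, alpha=0.05)
    truth_ud = set(ds.truth.loc[ds.truth["planted_class"] == "seesaw_up_down", "gene_id"])
    truth_du = set(ds.truth.loc[ds.truth["planted_class"] == "seesaw_down_up", "gene_id"])
    planted = truth_ud | truth_du
    called = set(calls.seesaw)
    tp = len(called & planted)
    assert tp / len(planted) >= 0.95
    assert tp / len(called) >= 0.90
    assert calls.up_down >= truth_ud - (called - set(calls.up_down))


# --- counts ---------------------------------------------------------------------

def test_counts_nonnegative_integers(small_dataset):
    counts = small_dataset.counts
    assert (counts.to_numpy() >= 0).all()
    assert np.issubdtype(counts.to_numpy().dtype, np.integer)


def test_counts_need_two_samples():
    with pytest.raises(ValueError):
        sd.GeneratorConfig(n_samples=1).validate()


def test_germline_scaling_in_ablated_strain(small_dataset):
    ds = small_dataset
    germ = ds.truth["germline"].to_numpy()
    ratio = (ds.fpkm["ablated"].to_numpy() + 0.1) / (ds.fpkm["wildtype"].to_numpy() + 0.1)
    assert np.median(ratio[germ]) < 0.5 < np.median(ratio[~germ])
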