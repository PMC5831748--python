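"""Synthetic genomes, annotations, DE tables and count matrices.

The generator plants the statistical structure the downstream analyses look
for, together with a per-gene truth table for recovery tests:

* a six-chromosome nematode-like genome with non-overlapping genes;
* planted response classes (seesaw_up_down, seesaw_down_up, concordant_up,
  concordant_down, null) with class-specific chromosome weights and a
  center-of-chromosome placement bias for the seesaw classes;
* locally clustered attribute (CSR-1-target-like) genes enriched on chosen
  chromosomes;
* operons as runs of adjacent same-strand genes;
* paired DE tables (pheromone and starvation contrasts) in which planted
  seesaw genes have opposite-signed fold changes, with a normal-tail p-value
  surrogate and BH FDR within each table;
* overdispersed replicate count matrices for a wild-type-like and a
  germline-ablated-like strain, plus per-gene FPKM vectors.

Determinism: a single master seed fans out to per-stage child seeds through
``numpy.random.SeedSequence(seed).spawn()`` in a fixed stage order
(placement, operons, attribute, DE tables, counts), so identical configs
yield bit-identical artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_tables
from .expression_qc import compute_fpkm
from .seesaw_core import bh_fdr
from scipy.special import ndtr

CLASSES = ("seesaw_up_down", "seesaw_down_up", "concordant_up",
           "concordant_down", "null")

#: Default chromosome lengths (bp), C. elegans-like.
DEFAULT_CHROMOSOMES = (
    ("I", 15_100_000), ("II", 15_300_000), ("III", 13_800_000),
    ("IV", 17_500_000), ("V", 20_900_000), ("X", 17_700_000),
)

# Beta concentration for central placement: alpha = 1 + _BETA_GAIN * c, so
# c = 0 is exactly uniform and c = 1 is strongly center-peaked.
_BETA_GAIN = 9.0


@dataclass(frozen=True)
class GenomeSpec:
    """Ordered chromosomes with lengths in bp."""

    chromosomes: tuple = DEFAULT_CHROMOSOMES

    def __post_init__(self):
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic-data generator (all proportions in [0, 1])."""

    n_genes: int = 18_570
    seed: int = 1
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    # planted response classes
    seesaw_fraction_significant: float = 500 / 18_570
    concordant_fraction: float = 0.02
    inverse_trend_fraction: float = 0.671  # Q1+Q3 share among null genes
    effect_size_location: float = 1.5  # minimum |log2fc| of planted classes
    effect_size_scale: float = 0.3  # half-normal excess above the location
    noise_sd: float = 0.3  # standard error in the p-value surrogate
    null_effect_scale: float | None = None  # defaults to noise_sd
    # spatial placement
    central_concentration: float = 0.7  # 0 = uniform, 1 = strongly central
    class_chromosome_weights: dict = field(default_factory=lambda: {
        "seesaw_up_down": {"I": 4.0, "III": 4.0},
        "seesaw_down_up": {"II": 4.0, "V": 4.0, "X": 4.0},
    })
    gene_length_range: tuple = (1_000, 4_000)
    # attribute (CSR-1-target-like) genes
    attribute_fraction: float = 0.21
    attribute_cluster_size_range: tuple = (3, 10)
    attribute_cluster_gap: int = 0
    attribute_chromosome_weights: dict = field(default_factory=lambda: {"I": 4.0, "III": 4.0})
    # operons
    operon_fraction: float = 0.15
    operon_size_range: tuple = (2, 3)
    # count matrices
    n_samples: int = 3  # replicates per strain
    dispersion: float = 0.05
    count_mean_log: float = 5.0  # ln-scale lognormal location of gene means
    count_mean_sd: float = 1.5
    germline_scale: float = 0.2  # ablated/wild-type mean ratio for germline genes

    def validate(self) -> None:
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        for name in ("seesaw_fraction_significant", "concordant_fraction",
                     "inverse_trend_fraction", "attribute_fraction",
                     "operon_fraction", "central_concentration"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.gene_length_range[0] < 1 or self.gene_length_range[1] < self.gene_length_range[0]:
            raise ValueError("invalid gene_length_range")
        if self.operon_size_range[0] < 2:
            raise ValueError("operon sizes must be >= 2")
        if self.attribute_cluster_size_range[0] < 1:
            raise ValueError("attribute cluster sizes must be >= 1")
        if self.attribute_cluster_gap < 0:
            raise ValueError("attribute_cluster_gap must be >= 0")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0 < self.germline_scale:
            raise ValueError("germline_scale must be positive")

    def child_rngs(self) -> dict:
        """Per-stage generators spawned from the master seed (fixed order)."""
        children = np.random.SeedSequence(self.seed).spawn(5)
        names = ("placement", "operons", "attribute", "de", "counts")
        return {n: np.random.default_rng(ss) for n, ss in zip(names, children)}


# ---------------------------------------------------------------------------
# genome + planted classes


def _class_counts(config: GeneratorConfig) -> dict[str, int]:
    n = config.n_genes
    n_ss = round(n * config.seesaw_fraction_significant)
    n_cc = round(n * config.concordant_fraction)
    counts = {
        "seesaw_up_down": (n_ss + 1) // 2,
        "seesaw_down_up": n_ss // 2,
        "concordant_up": (n_cc + 1) // 2,
        "concordant_down": n_cc // 2,
    }
    counts["null"] = n - sum(counts.values())
    if counts["null"] < 0:
        raise ValueError("class fractions exceed 1")
    return counts


def generate_genome(config: GeneratorConfig, rng=None):
    """Generate (GenomeSpec, annotation, truth) with planted response classes.

    Genes are placed without overlap; planted seesaw-class genes are drawn
    toward chromosome centers via a symmetric Beta(a, a) relative midpoint
    with a = 1 + 9 * central_concentration, on chromosomes favored by the
    class weights. Raises on infeasible packing.
    """
    config.validate()
    if rng is None:
        rng = config.child_rngs()["placement"]
    genome = config.genome
    names = genome.names
    lengths = np.array([genome.lengths[c] for c in names], dtype=float)

    counts = _class_counts(config)
    classes = np.concatenate([np.full(k, c, dtype=object) for c, k in counts.items()])
    rng.shuffle(classes)
    n = config.n_genes

    # chromosome per gene: class weight x chromosome length share
    chrom_idx = np.empty(n, dtype=np.int64)
    for cls in CLASSES:
        sel = classes == cls
        if not sel.any():
            continue
        w = np.array([config.class_chromosome_weights.get(cls, {}).get(c, 1.0)
                      for c in names]) * lengths
        chrom_idx[sel] = rng.choice(len(names), size=int(sel.sum()), p=w / w.sum())

    # relative midpoint: Beta for seesaw classes, uniform otherwise
    rel = rng.uniform(0, 1, n)
    a = 1.0 + _BETA_GAIN * config.central_concentration
    for cls in ("seesaw_up_down", "seesaw_down_up"):
        sel = classes == cls
        if sel.any() and a != 1.0:
            rel[sel] = rng.beta(a, a, int(sel.sum()))

    lo, hi = config.gene_length_range
    gene_len = rng.integers(lo, hi + 1, n)

    starts = np.empty(n, dtype=np.int64)
    for ci, cname in enumerate(names):
        on_c = np.flatnonzero(chrom_idx == ci)
        L = int(lengths[ci])
        if gene_len[on_c].sum() > L:
            raise ValueError(
                f"infeasible packing: {on_c.size} genes "
                f"({int(gene_len[on_c].sum())} bp) exceed chromosome {cname} ({L} bp)")
        order = on_c[np.argsort(rel[on_c], kind="mergesort")]
        desired = np.maximum(
            np.round(rel[order] * L).astype(np.int64) - gene_len[order] // 2, 0)
        # forward sweep removes overlaps; backward sweep pulls back past the end
        placed = np.empty(order.size, dtype=np.int64)
        prev_end = 0
        for j, (d, gl) in enumerate(zip(desired, gene_len[order])):
            placed[j] = max(int(d), prev_end)
            prev_end = placed[j] + int(gl)
        allowed_end = L
        for j in range(order.size - 1, -1, -1):
            gl = int(gene_len[order[j]])
            end_j = min(placed[j] + gl, allowed_end)
            placed[j] = end_j - gl
            allowed_end = placed[j]
        starts[order] = placed

    df = pd.DataFrame({
        "chrom": pd.Categorical([names[i] for i in chrom_idx], categories=names, ordered=True),
        "start": starts,
        "end": starts + gene_len,
        "strand": rng.choice(["+", "-"], size=n),
        "planted_class": classes,
    })
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    df.insert(0, "gene_id", [f"g{i:05d}" for i in range(1, n + 1)])
    df["chrom"] = df["chrom"].astype(str)
    df["operon_id"] = None

    annotation = df[io_tables.ANNOTATION_COLUMNS].copy()
    truth = pd.DataFrame({
        "gene_id": df["gene_id"],
        "planted_class": df["planted_class"],
        "attribute": False,
        "operon_id": None,
        "cluster_id": None,
        "germline": False,
    })
    return genome, annotation, truth


# ---------------------------------------------------------------------------
# operons


def assign_operons(annotation: pd.DataFrame, config: GeneratorConfig,
                   rng=None) -> pd.DataFrame:
    """Assign operon ids to runs of adjacent genes (members share a strand).

    A renewal walk along each chromosome starts an operon with probability
    q = f / (E[s](1-f) + f) per gene, which makes the expected in-operon gene
    fraction equal the configured ``operon_fraction`` f.
    """
    config.validate()
    f = config.operon_fraction
    out = annotation.copy()
    out["operon_id"] = None
    if f == 0:
        return out
    if rng is None:
        rng = config.child_rngs()["operons"]
    lo, hi = config.operon_size_range
    mean_size = (lo + hi) / 2.0
    q = f / (mean_size * (1 - f) + f)
    strands = out["strand"].to_numpy().copy()
    operon_ids = np.full(len(out), None, dtype=object)
    op_counter = 0
    for _, grp in out.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        i = 0
        while i < idx.size:
            if idx.size - i >= 2 and rng.random() < q:
                s = int(min(rng.integers(lo, hi + 1), idx.size - i))
                op_counter += 1
                members = idx[i:i + s]
                operon_ids[members] = f"op{op_counter:04d}"
                strands[members] = rng.choice(["+", "-"])
                i += s
            else:
                i += 1
    out["operon_id"] = operon_ids
    out["strand"] = strands
    return out


def operon_mapping(annotation: pd.DataFrame) -> dict[str, list[str]]:
    """operon_id -> ordered member gene ids, from an annotated table."""
    mapping: dict[str, list[str]] = {}
    for row in annotation.itertuples(index=False):
        if row.operon_id:
            mapping.setdefault(row.operon_id, []).append(row.gene_id)
    return mapping


# ---------------------------------------------------------------------------
# attribute genes


def assign_attribute(annotation: pd.DataFrame, config: GeneratorConfig,
                     rng=None) -> pd.DataFrame:
    """Plant locally clustered attribute genes biased to chosen chromosomes.

    Clusters of configured size are planted as runs (internal gaps drawn
    uniformly in [0, attribute_cluster_gap]) at random positions. The overall
    attribute budget is apportioned across chromosomes in proportion to
    weight x gene count, and clusters are planted per chromosome until its
    quota is met, which keeps per-chromosome fractions at their targets.
    Returns gene_id / attribute / cluster_id.
    """
    config.validate()
    if rng is None:
        rng = config.child_rngs()["attribute"]
    n = len(annotation)
    target = round(config.attribute_fraction * n)
    flags = np.zeros(n, dtype=bool)
    cluster_ids = np.full(n, None, dtype=object)
    names = list(dict.fromkeys(annotation["chrom"]))
    chrom_pos = {c: annotation.index[annotation["chrom"] == c].to_numpy() for c in names}
    weights = np.array([config.attribute_chromosome_weights.get(c, 1.0) for c in names])
    sizes_per_chrom = np.array([chrom_pos[c].size for c in names], dtype=float)
    alloc = weights * sizes_per_chrom
    capacity = sizes_per_chrom.astype(int)
    quotas = np.minimum(np.round(target * alloc / alloc.sum()).astype(int), capacity)
    # redistribute budget lost to rounding/capacity clipping
    while quotas.sum() < target and (quotas < capacity).any():
        spare = np.flatnonzero(quotas < capacity)
        share = alloc[spare] / alloc[spare].sum()
        add = np.maximum((share * (target - quotas.sum())).astype(int), 1)
        quotas[spare] = np.minimum(quotas[spare] + add, capacity[spare])
    while quotas.sum() > target:
        i = int(np.argmax(quotas))
        quotas[i] -= min(quotas[i], quotas.sum() - target)
    lo, hi = config.attribute_cluster_size_range
    gap_max = config.attribute_cluster_gap
    cid = 0
    for c, quota in zip(names, quotas):
        pos = chrom_pos[c]
        planted = 0
        while planted < quota:
            size = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(0, pos.size))
            cid += 1
            j = start
            for _ in range(size):
                if j >= pos.size:
                    break
                gi = pos[j]
                if not flags[gi]:
                    flags[gi] = True
                    cluster_ids[gi] = f"cl{cid:04d}"
                    planted += 1
                j += 1 + (int(rng.integers(0, gap_max + 1)) if gap_max else 0)
    return pd.DataFrame({"gene_id": annotation["gene_id"],
                         "attribute": flags, "cluster_id": cluster_ids})


# ---------------------------------------------------------------------------
# DE tables


def _planted_magnitude(rng, k: int, config: GeneratorConfig) -> np.ndarray:
    # shifted half-normal: |log2fc| >= effect_size_location by construction,
    # so planted "significant" classes are unambiguously callable
    return config.effect_size_location + config.effect_size_scale * np.abs(rng.standard_normal(k))


def generate_de_tables(truth: pd.DataFrame, config: GeneratorConfig,
                       rng=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired DE tables (Phe, Stv) over the identical gene universe.

    Planted seesaw_up_down genes get log2fc_phe = +|e|, log2fc_stv = -|e'|;
    seesaw_down_up is symmetric; concordant classes share a sign; null genes
    get zero-centered N(0, null_effect_scale) magnitudes with opposite signs
    across the two tables with probability ``inverse_trend_fraction``.
    p = two-sided standard-normal tail at |log2fc| / noise_sd; q by BH within
    each table.
    """
    config.validate()
    if rng is None:
        rng = config.child_rngs()["de"]
    n = len(truth)
    cls = truth["planted_class"].to_numpy()
    phe = np.empty(n)
    stv = np.empty(n)

    for name, sign_phe, sign_stv in (("seesaw_up_down", 1, -1),
                                     ("seesaw_down_up", -1, 1),
                                     ("concordant_up", 1, 1),
                                     ("concordant_down", -1, -1)):
        sel = np.flatnonzero(cls == name)
        phe[sel] = sign_phe * _planted_magnitude(rng, sel.size, config)
        stv[sel] = sign_stv * _planted_magnitude(rng, sel.size, config)

    sel = np.flatnonzero(cls == "null")
    scale = config.null_effect_scale if config.null_effect_scale is not None else config.noise_sd
    m1 = np.abs(rng.normal(0, scale, sel.size))
    m2 = np.abs(rng.normal(0, scale, sel.size))
    s1 = rng.choice([-1.0, 1.0], sel.size)
    opposite = rng.random(sel.size) < config.inverse_trend_fraction
    s2 = np.where(opposite, -s1, s1)
    phe[sel] = s1 * m1
    stv[sel] = s2 * m2

    def table(fc: np.ndarray, condition: str) -> pd.DataFrame:
        p = 2.0 * ndtr(-np.abs(fc) / config.noise_sd)
        df = pd.DataFrame({
            "gene_id": truth["gene_id"].to_numpy(),
            "log2fc": fc,
            "pvalue": p,
            "fdr": bh_fdr(p),
            "mean_expr": rng.lognormal(config.count_mean_log, config.count_mean_sd, n),
        })
        df.attrs["condition"] = condition
        return df

    return table(phe, "Phe"), table(stv, "Stv")


# ---------------------------------------------------------------------------
# count matrices


def generate_count_matrix(annotation: pd.DataFrame, truth: pd.DataFrame,
                          config: GeneratorConfig, rng=None):
    """Replicate count matrices for two strains plus per-gene FPKM vectors.

    Counts follow a gamma-Poisson (negative binomial) model with variance
    mu + dispersion * mu^2; replicate samples within a strain share means.
    Genes flagged germline in the truth table have their mean scaled by
    ``germline_scale`` in the germline-ablated-like strain.
    """
    config.validate()
    if rng is None:
        rng = config.child_rngs()["counts"]
    n = len(annotation)
    base = rng.lognormal(config.count_mean_log, config.count_mean_sd, n)
    germline = truth["germline"].to_numpy(dtype=bool)
    means = {"wildtype": base,
             "ablated": np.where(germline, base * config.germline_scale, base)}
    cols = {}
    for strain, mu in means.items():
        for s in range(1, config.n_samples + 1):
            if config.dispersion <= 1e-12:
                counts = rng.poisson(mu)
            else:
                shape = 1.0 / config.dispersion
                counts = rng.poisson(rng.gamma(shape, mu / shape))
            cols[f"{strain}_{s}"] = counts
    counts_df = pd.DataFrame(cols, index=annotation["gene_id"].to_numpy())
    counts_df.index.name = "gene_id"

    lengths = (annotation["end"] - annotation["start"]).to_numpy()
    fpkm = {}
    for strain in means:
        strain_cols = [c for c in counts_df.columns if c.startswith(strain)]
        summed = counts_df[strain_cols].sum(axis=1).to_numpy()
        fpkm[strain] = compute_fpkm(summed, lengths, summed.sum())
    fpkm_df = pd.DataFrame(fpkm, index=counts_df.index)
    return counts_df, fpkm_df


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class SimulatedDataset:
    config: GeneratorConfig
    genome: GenomeSpec
    annotation: pd.DataFrame
    truth: pd.DataFrame
    attribute_ids: frozenset
    de_phe: pd.DataFrame
    de_stv: pd.DataFrame
    counts: pd.DataFrame
    fpkm: pd.DataFrame

    @property
    def operons(self) -> dict[str, list[str]]:
        return operon_mapping(self.annotation)


def simulate(config: GeneratorConfig) -> SimulatedDataset:
    """Run every generator stage with spawned child seeds and merge truth."""
    rngs = config.child_rngs()
    genome, annotation, truth = generate_genome(config, rng=rngs["placement"])
    annotation = assign_operons(annotation, config, rng=rngs["operons"])
    attr = assign_attribute(annotation, config, rng=rngs["attribute"])
    truth = truth.drop(columns=["attribute", "operon_id", "cluster_id", "germline"])
    truth = truth.merge(attr, on="gene_id")
    truth["operon_id"] = annotation["operon_id"].to_numpy()
    # CSR-1-target-like attribute genes double as the germline-enriched set
    truth["germline"] = truth["attribute"]
    de_phe, de_stv = generate_de_tables(truth, config, rng=rngs["de"])
    counts, fpkm = generate_count_matrix(annotation, truth, config, rng=rngs["counts"])
    return SimulatedDataset(
        config=config, genome=genome, annotation=annotation, truth=truth,
        attribute_ids=frozenset(truth.loc[truth["attribute"], "gene_id"]),
        de_phe=de_phe, de_stv=de_stv, counts=counts, fpkm=fpkm,
    )


def write_dataset(ds: SimulatedDataset, out_dir) -> dict[str, Path]:
    """Write every artifact in its on-disk format; returns name -> path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation_gff3": out / "annotation.gff3",
        "annotation_bed": out / "annotation.bed",
        "de_phe": out / "de_phe.tsv",
        "de_stv": out / "de_stv.tsv",
        "attribute_list": out / "attribute_genes.txt",
        "operon_table": out / "operons.tsv",
        "truth": out / "truth.tsv",
        "counts": out / "counts.tsv",
        "fpkm": out / "fpkm.tsv",
        "config": out / "generator_config.txt",
    }
    io_tables.write_annotation_gff3(ds.annotation, paths["annotation_gff3"])
    io_tables.write_annotation_bed6(ds.annotation, paths["annotation_bed"])
    io_tables.write_de_table(ds.de_phe, paths["de_phe"])
    io_tables.write_de_table(ds.de_stv, paths["de_stv"])
    io_tables.write_gene_list(ds.attribute_ids, paths["attribute_list"])
    io_tables.write_operon_table(ds.operons, paths["operon_table"])
    ds.truth.to_csv(paths["truth"], sep="\t", index=False, lineterminator="\n")
    ds.counts.to_csv(paths["counts"], sep="\t", lineterminator="\n")
    ds.fpkm.to_csv(paths["fpkm"], sep="\t", lineterminator="\n")
    with open(paths["config"], "w", encoding="utf-8", newline="\n") as fh:
        for key, val in vars(ds.config).items():
            if key == "genome":
                val = list(ds.config.genome.chromosomes)
            fh.write(f"{key}\t{val!r}\n")
    return paths
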