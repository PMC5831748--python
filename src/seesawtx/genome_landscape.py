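"""Chromosome-scale spatial statistics.

Four analyses:

* per-chromosome bias of a gene class (2x2 Yates-corrected chi-square of each
  chromosome against the remaining chromosomes, or optionally a one-sample
  chi-square against gene-count-proportional expectations);
* sliding-window enrichment tracks (default 2.5 Mb windows advancing in
  500 kb steps, genes assigned to windows by midpoint);
* gap-tolerant maximal-run clustering of attribute genes (GLC-style) with a
  randomized-gene-order null;
* operon membership and per-operon quadrant classification.

Gene positions enter only through ordering and midpoints; strand is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .seesaw_core import classify_quadrant, percentage_report


# ---------------------------------------------------------------------------
# chromosomal bias


def yates_chi2_2x2(table) -> float:
    """Yates-corrected chi-square for a 2x2 table: sum of
    (max(|O-E|-0.5, 0))^2 / E over the four cells."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    row = t.sum(axis=1, keepdims=True)
    col = t.sum(axis=0, keepdims=True)
    total = t.sum()
    if total <= 0:
        raise ValueError("empty table")
    expected = row * col / total
    if (expected == 0).any():
        raise ValueError("zero expected cell")
    dev = np.maximum(np.abs(t - expected) - 0.5, 0.0)
    return float((dev**2 / expected).sum())


def chrom_bias_chi2(class_genes, annotation: pd.DataFrame,
                    method: str = "two_by_two") -> pd.DataFrame:
    """Per-chromosome over/under-representation of a gene class.

    ``method="two_by_two"`` (default) tests each chromosome against the
    remaining chromosomes with a Yates-corrected 2x2 chi-square;
    ``method="proportional"`` is the one-sample variant against gene-count-
    proportional expectations (single chi-square across chromosomes, reported
    per chromosome via its standardized contribution).
    """
    class_genes = set(class_genes)
    known = set(annotation["gene_id"])
    if not class_genes <= known:
        raise ValueError("class contains genes absent from the annotation")
    chroms = list(dict.fromkeys(annotation["chrom"]))
    if len(chroms) < 2:
        raise ValueError("need >= 2 chromosomes")
    per_chrom_total = annotation.groupby("chrom", sort=False)["gene_id"].count()
    in_class = annotation["gene_id"].isin(class_genes)
    per_chrom_class = annotation.loc[in_class].groupby("chrom", sort=False)["gene_id"].count()
    n_class = int(in_class.sum())
    n_total = len(annotation)

    rows = []
    for c in chroms:
        tot_c = int(per_chrom_total.get(c, 0))
        obs = int(per_chrom_class.get(c, 0))
        expected = n_class * tot_c / n_total
        testable = True
        if method == "two_by_two":
            table = [[obs, n_class - obs],
                     [tot_c - obs, (n_total - n_class) - (tot_c - obs)]]
            try:
                chi2 = yates_chi2_2x2(table)
                p = float(stats.chi2.sf(chi2, df=1))
            except ValueError:
                chi2, p, testable = float("nan"), float("nan"), False
        elif method == "proportional":
            if expected == 0:
                chi2, p, testable = float("nan"), float("nan"), False
            else:
                dev = max(abs(obs - expected) - 0.5, 0.0)
                chi2 = dev**2 / expected + dev**2 / max(n_class - expected, 1e-300)
                p = float(stats.chi2.sf(chi2, df=1))
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append({
            "chrom": c, "observed": obs, "expected": expected,
            "chi2": chi2, "pvalue": p,
            "direction": "over" if obs > expected else ("under" if obs < expected else "none"),
            "testable": testable,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sliding windows


def sliding_window_enrichment(class_genes, annotation: pd.DataFrame,
                              chrom_lengths: dict, window: int = 2_500_000,
                              step: int = 500_000, min_genes: int = 10) -> pd.DataFrame:
    """Sliding-window enrichment of a gene class along each chromosome.

    Windows start at 0 and advance by ``step`` while start < chromosome
    length; terminal windows are truncated and flagged. A gene belongs to a
    window iff its midpoint lies in [start, end). Enrichment is the in-window
    class fraction divided by the genome-wide class fraction; windows with
    fewer than ``min_genes`` genes are NA.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if step <= 0:
        raise ValueError("step must be positive")
    class_genes = set(class_genes)
    in_class = annotation["gene_id"].isin(class_genes).to_numpy()
    n_class, n_total = int(in_class.sum()), len(annotation)
    if n_total == 0:
        raise ValueError("empty annotation")
    genome_frac = n_class / n_total

    mids = ((annotation["start"].to_numpy() + annotation["end"].to_numpy()) / 2.0)
    rows = []
    for chrom, length in chrom_lengths.items():
        on_c = (annotation["chrom"] == chrom).to_numpy()
        m = mids[on_c]
        order = np.argsort(m, kind="mergesort")
        m_sorted = m[order]
        cls_sorted = in_class[on_c][order]
        cls_cum = np.concatenate([[0], np.cumsum(cls_sorted)])
        start = 0
        while start < length:
            end = min(start + window, length)
            i0 = int(np.searchsorted(m_sorted, start, side="left"))
            i1 = int(np.searchsorted(m_sorted, end, side="left"))
            n_genes = i1 - i0
            n_cls = int(cls_cum[i1] - cls_cum[i0])
            sparse = n_genes < min_genes
            enr = float("nan")
            if not sparse and genome_frac > 0:
                enr = (n_cls / n_genes) / genome_frac
            rows.append({
                "chrom": chrom, "start": start, "end": end,
                "n_genes": n_genes, "n_class": n_cls,
                "enrichment": enr, "sparse": sparse,
                "truncated": end - start < window,
            })
            start += step
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GLC-style clustering


@dataclass(frozen=True)
class Cluster:
    chrom: str
    gene_ids: tuple
    start: int  # bp, start of first member
    end: int  # bp, end of last member

    @property
    def size(self) -> int:
        return len(self.gene_ids)

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class ClusterSet:
    """Maximal co-localized attribute-gene clusters (plus optional null)."""

    min_size: int
    max_gap: int
    clusters: list
    n_attribute: int  # total attribute genes in the annotation
    fold_n_clusters: float | None = None
    fold_n_clustered: float | None = None
    p_n_clusters: float | None = None
    p_n_clustered: float | None = None
    p_is_upper_bound: bool = False
    null_mean_n_clusters: float | None = None
    null_mean_n_clustered: float | None = None
    S: int | None = None
    seed: int | None = None

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_clustered_genes(self) -> int:
        return sum(c.size for c in self.clusters)

    @property
    def fraction_clustered(self) -> float:
        return self.n_clustered_genes / self.n_attribute if self.n_attribute else float("nan")


def _run_counts(flags: np.ndarray, chrom_codes: np.ndarray,
                min_size: int, max_gap: int):
    """(n_clusters, n_clustered, run-boundary indices) for flagged genes.

    A cluster is a maximal same-chromosome run of flagged genes in which
    consecutive flagged genes are separated by <= max_gap unflagged genes.
    """
    idx = np.flatnonzero(flags)
    if idx.size == 0:
        return 0, 0, idx, np.empty(0, dtype=np.int64)
    breaks = np.flatnonzero(
        (chrom_codes[idx[1:]] != chrom_codes[idx[:-1]])
        | (idx[1:] - idx[:-1] - 1 > max_gap)
    )
    bounds = np.concatenate([[0], breaks + 1, [idx.size]])
    run_lengths = np.diff(bounds)
    keep = run_lengths >= min_size
    return int(keep.sum()), int(run_lengths[keep].sum()), idx, bounds


def glc_cluster(attribute_flags, annotation: pd.DataFrame,
                min_size: int = 3, max_gap: int = 2) -> ClusterSet:
    """Maximal gap-tolerant runs of attribute genes along each chromosome.

    ``attribute_flags`` is a boolean vector aligned with the annotation's
    (chromosome, start)-sorted gene order. Cluster size counts attribute
    genes only; intervening non-attribute (gap) genes are not members.
    """
    flags = np.asarray(attribute_flags, dtype=bool)
    if len(flags) != len(annotation):
        raise ValueError("flag vector length does not match annotation")
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    chrom_codes = pd.factorize(annotation["chrom"])[0]
    _, _, idx, bounds = _run_counts(flags, chrom_codes, min_size, max_gap)
    gid = annotation["gene_id"].to_numpy()
    chrom = annotation["chrom"].to_numpy()
    start = annotation["start"].to_numpy()
    end = annotation["end"].to_numpy()
    clusters = []
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        members = idx[b0:b1]
        if members.size < min_size:
            continue
        clusters.append(Cluster(
            chrom=str(chrom[members[0]]),
            gene_ids=tuple(gid[members]),
            start=int(start[members[0]]),
            end=int(end[members[-1]]),
        ))
    return ClusterSet(min_size=min_size, max_gap=max_gap, clusters=clusters,
                      n_attribute=int(flags.sum()))


def cluster_null(attribute_flags, annotation: pd.DataFrame,
                 min_size: int = 3, max_gap: int = 2, S: int = 10_000,
                 seed=None) -> ClusterSet:
    """GLC clustering with a randomized-gene-order null.

    Each replicate permutes the attribute labels uniformly over gene
    positions (gene order and chromosome structure fixed), re-clusters, and
    records the number of clusters and of clustered attribute genes. Folds
    are observed/null-mean; empirical p as in the overlap null (>= tail,
    "< 1/S" on zero exceedances).
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    observed = glc_cluster(attribute_flags, annotation, min_size=min_size, max_gap=max_gap)
    flags = np.asarray(attribute_flags, dtype=bool)
    chrom_codes = pd.factorize(annotation["chrom"])[0]
    rng = np.random.default_rng(seed)
    sims_c = np.empty(S, dtype=np.int64)
    sims_g = np.empty(S, dtype=np.int64)
    for i in range(S):
        perm = rng.permutation(flags)
        nc, ng, _, _ = _run_counts(perm, chrom_codes, min_size, max_gap)
        sims_c[i] = nc
        sims_g[i] = ng
    mean_c, mean_g = float(sims_c.mean()), float(sims_g.mean())
    exc_c = int((sims_c >= observed.n_clusters).sum())
    exc_g = int((sims_g >= observed.n_clustered_genes).sum())
    return replace(
        observed,
        fold_n_clusters=observed.n_clusters / mean_c if mean_c > 0 else float("nan"),
        fold_n_clustered=observed.n_clustered_genes / mean_g if mean_g > 0 else float("nan"),
        p_n_clusters=exc_c / S,
        p_n_clustered=exc_g / S,
        p_is_upper_bound=(exc_c == 0 or exc_g == 0),
        null_mean_n_clusters=mean_c,
        null_mean_n_clustered=mean_g,
        S=S, seed=seed,
    )


# ---------------------------------------------------------------------------
# operons


def operon_membership(gene_set, operons: dict[str, list[str]]) -> tuple[int, float]:
    """(count, percentage) of set members that reside in an operon."""
    gene_set = set(gene_set)
    in_operons = set()
    for members in operons.values():
        in_operons.update(members)
    count = len(gene_set & in_operons)
    pct = percentage_report(count, len(gene_set), 0)
    return count, pct


def operon_quadrant_classify(operons: dict[str, list[str]],
                             de_phe: pd.DataFrame, de_stv: pd.DataFrame):
    """Per-operon quadrant labels (on mean member fold changes) and a tally.

    Operons with no member quantified in both tables are skipped (returned in
    the skipped list). Any condition mean of exactly 0 -> BOUNDARY.
    """
    phe = de_phe.set_index("gene_id")["log2fc"]
    stv = de_stv.set_index("gene_id")["log2fc"]
    common = phe.index.intersection(stv.index)
    phe, stv = phe.loc[common], stv.loc[common]
    rows, skipped = [], []
    for op, members in operons.items():
        quant = [g for g in members if g in phe.index]
        if not quant:
            skipped.append(op)
            continue
        mean_phe = float(phe.loc[quant].mean())
        mean_stv = float(stv.loc[quant].mean())
        rows.append({"operon_id": op, "n_members": len(members),
                     "n_quantified": len(quant),
                     "mean_log2fc_phe": mean_phe, "mean_log2fc_stv": mean_stv,
                     "quadrant": classify_quadrant(mean_phe, mean_stv)})
    table = pd.DataFrame(rows, columns=["operon_id", "n_members", "n_quantified",
                                        "mean_log2fc_phe", "mean_log2fc_stv", "quadrant"])
    tally = table["quadrant"].value_counts().to_dict() if len(table) else {}
    return table, tally, skipped
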