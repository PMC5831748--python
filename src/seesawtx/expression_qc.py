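"""Library-level QC and germline-enrichment classification.

Replicate agreement (Pearson r on log2(count+1)), principal-component
retention for the sample-correlation structure (Kaiser criterion and
broken-stick model), FPKM computation, and classification of genes whose
expression collapses in germline-ablated animals relative to wild-type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .overlap_null import fisher_two_tailed


def compute_fpkm(counts, gene_lengths_bp, total_mapped_reads) -> np.ndarray:
    """FPKM = counts * 1e9 / (length_bp * total_mapped_reads)."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(gene_lengths_bp, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive")
    if total_mapped_reads <= 0:
        raise ValueError("total mapped reads must be positive")
    return counts * 1e9 / (lengths * total_mapped_reads)


def replicate_pearson(x, y, df_mode: str = "paper",
                      transform: str = "log2") -> tuple[float, float]:
    """Pearson correlation between two replicate count vectors.

    Vectors are log2(count+1)-transformed by default (``transform="raw"``
    skips this). The p-value comes from the t-transform
    t = r*sqrt(df/(1-r^2)) with df = n-1 in ``"paper"`` mode (as printed in
    the study's replicate panels) or the conventional df = n-2 in
    ``"standard"`` mode.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if transform == "log2":
        x, y = np.log2(x + 1), np.log2(y + 1)
    elif transform != "raw":
        raise ValueError(f"unknown transform {transform!r}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Pearson r undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    if df_mode == "paper":
        df = x.size - 1
    elif df_mode == "standard":
        df = x.size - 2
    else:
        raise ValueError(f"unknown df_mode {df_mode!r}")
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p


def broken_stick(p: int) -> np.ndarray:
    """Broken-stick expected variance shares b_k = (1/p) * sum_{i=k..p} 1/i."""
    if p < 1:
        raise ValueError("p must be >= 1")
    inv = 1.0 / np.arange(1, p + 1)
    return np.cumsum(inv[::-1])[::-1] / p


@dataclass
class PCAResult:
    """Eigen-structure of the sample-correlation matrix with retention flags."""

    eigenvalues: np.ndarray  # non-increasing, length = n_samples
    variance_shares: np.ndarray
    broken_stick_shares: np.ndarray
    kaiser_significant: np.ndarray  # lambda_k > 1
    broken_stick_significant: np.ndarray  # share_k > b_k
    n_genes_used: int
    n_genes_dropped: int  # zero-variance genes removed


def pc_significance(counts: pd.DataFrame | np.ndarray,
                    transform: str = "log2") -> PCAResult:
    """PCA retention for a genes x samples count matrix.

    Counts are log2(count+1)-transformed (configurable), genes with zero
    variance across samples are dropped, and the eigenvalues of the
    samples x samples correlation matrix are assessed with the Kaiser
    criterion (lambda > 1) and the broken-stick model.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a genes x samples matrix with >= 2 samples")
    if transform == "log2":
        x = np.log2(x + 1)
    elif transform != "raw":
        raise ValueError(f"unknown transform {transform!r}")
    keep = x.std(axis=1) > 0
    dropped = int((~keep).sum())
    x = x[keep]
    if x.shape[0] < 2:
        raise ValueError("fewer than 2 genes with non-zero variance")
    corr = np.corrcoef(x, rowvar=False)
    if not np.all(np.isfinite(corr)):
        raise ValueError("degenerate samples: correlation matrix has NaNs")
    lam = np.linalg.eigvalsh(corr)[::-1]
    lam = np.clip(lam, 0.0, None)
    p = lam.size
    shares = lam / lam.sum()
    b = broken_stick(p)
    return PCAResult(
        eigenvalues=lam,
        variance_shares=shares,
        broken_stick_shares=b,
        kaiser_significant=lam > 1.0,
        broken_stick_significant=shares > b,
        n_genes_used=int(keep.sum()),
        n_genes_dropped=dropped,
    )


@dataclass
class GermlineEnrichmentResult:
    calls: pd.DataFrame  # gene_id, fpkm_wt, fpkm_ablated, ratio, label
    median_ratio: float
    n_enriched: int
    fraction_enriched: float
    fisher_p: float | None = None  # vs a reference germline list, when given


def germline_enrichment_classify(fpkm_wt, fpkm_ablated, gene_ids=None,
                                 ratio_threshold: float = 0.5,
                                 pseudocount: float = 0.1,
                                 reference_list=None) -> GermlineEnrichmentResult:
    """Classify genes as germline-enriched from wild-type vs germline-ablated
    FPKM.

    ratio = (fpkm_ablated + pseudocount) / (fpkm_wt + pseudocount);
    ``germline_enriched`` iff ratio <= ratio_threshold. Genes with
    fpkm_wt <= pseudocount are ``undetermined`` (too lowly expressed to
    judge). When a reference germline gene list is supplied, enrichment of
    the called set within it is tested with a two-tailed Fisher's exact test.
    """
    wt = np.asarray(fpkm_wt, dtype=float)
    ab = np.asarray(fpkm_ablated, dtype=float)
    if wt.shape != ab.shape:
        raise ValueError("FPKM vectors must cover the same genes")
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(wt.size)]
    gene_ids = np.asarray(gene_ids, dtype=object)
    ratio = (ab + pseudocount) / (wt + pseudocount)
    label = np.where(ratio <= ratio_threshold, "germline_enriched", "not_enriched")
    label = np.where(wt <= pseudocount, "undetermined", label)
    calls = pd.DataFrame({"gene_id": gene_ids, "fpkm_wt": wt,
                          "fpkm_ablated": ab, "ratio": ratio, "label": label})
    determined = calls[calls["label"] != "undetermined"]
    n_enr = int((determined["label"] == "germline_enriched").sum())
    fisher_p = None
    if reference_list is not None:
        ref = set(reference_list)
        enr = set(determined.loc[determined["label"] == "germline_enriched", "gene_id"])
        uni = set(determined["gene_id"])
        a = len(enr & ref)
        b = len(enr - ref)
        c = len((uni - enr) & ref)
        d = len((uni - enr) - ref)
        fisher_p = fisher_two_tailed(a, b, c, d)
    return GermlineEnrichmentResult(
        calls=calls,
        median_ratio=float(np.median(ratio)),
        n_enriched=n_enr,
        fraction_enriched=n_enr / len(determined) if len(determined) else float("nan"),
        fisher_p=fisher_p,
    )
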