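import numpy as np
import pandas as pd
import pytest

from seesawtx.synthetic_data import GeneratorConfig, simulate


def make_de(genes, log2fc, fdr=None, pvalue=None, condition=None):
    """Small hand-built DE table."""
    n = len(genes)
    df = pd.DataFrame({
        "gene_id": list(genes),
        "log2fc": list(log2fc),
        "pvalue": list(pvalue) if pvalue is not None else [0.01] * n,
        "fdr": list(fdr) if fdr is not None else [0.01] * n,
        "mean_expr": [10.0] * n,
    })
    df.attrs["condition"] = condition
    return df


def make_annotation(chroms, starts, lengths=1000, gene_ids=None, strands=None):
    """Annotation table from parallel chromosome/start lists."""
    n = len(chroms)
    if np.isscalar(lengths):
        lengths = [lengths] * n
    starts = list(starts)
    df = pd.DataFrame({
        "gene_id": gene_ids or [f"g{i:03d}" for i in range(n)],
        "chrom": list(chroms),
        "start": starts,
        "end": [s + l for s, l in zip(starts, lengths)],
        "strand": strands or ["+"] * n,
        "operon_id": [None] * n,
    })
    return df.sort_values(["chrom", "start", "gene_id"]).reset_index(drop=True)


@pytest.fixture(scope="session")
def small_dataset():
    """A 3,000-gene synthetic dataset shared across tests."""
    return simulate(GeneratorConfig(n_genes=3000, seed=42))


@pytest.fixture(scope="session")
def default_dataset():
    """The default study-scale fixture: 18,570 genes, 500 planted seesaw
    genes, effect location 1.5, noise 0.3, seed 1."""
    return simulate(GeneratorConfig(seed=1))
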