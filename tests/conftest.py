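import numpy as np
import pandas as pd
import pytest

from crossatlas import (ExpressionMatrix, SyntheticConfig, collapse_replicates,
                        generate_truth, simulate_microarray, simulate_rnaseq)
from crossatlas.network import remove_constant_genes
from crossatlas.transforms import platform_transform


def make_matrix(values, genes=None, tissues=None, platform="rnaseq",
                units=None, replicates=None):
    """Build a small ExpressionMatrix from a 2-D array.

    ``replicates``: number of replicates per tissue; when given, ``values``
    columns are ordered tissue-major ((t1, r1), (t1, r2), ...).
    """
    values = np.asarray(values, dtype=float)
    n_genes, n_cols = values.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    if replicates:
        n_tissues = n_cols // replicates
        tissues = tissues or [f"t{j}" for j in range(n_tissues)]
        cols = pd.MultiIndex.from_tuples(
            [(t, r + 1) for t in tissues for r in range(replicates)],
            names=["tissue", "replicate"])
    else:
        tissues = tissues or [f"t{j}" for j in range(n_cols)]
        cols = pd.Index(tissues)
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=cols)
    if units is None:
        units = "FPKM" if platform == "rnaseq" else "intensity"
    return ExpressionMatrix(values=df, platform=platform, units=units)


SMALL_SCALE = dict(n_genes=500, n_modules=25)


@pytest.fixture(scope="session")
def artifact_dataset():
    """One artifacts-on simulated dataset shared across tests (seed 3)."""
    cfg = SyntheticConfig(seed=3, **SMALL_SCALE)
    truth = generate_truth(cfg)
    rnaseq = simulate_rnaseq(truth, cfg)
    microarray = simulate_microarray(truth, cfg)
    return cfg, truth, rnaseq, microarray


@pytest.fixture(scope="session")
def aligned_networks_input(artifact_dataset):
    """Transformed, constant-free, gene-aligned platform matrices."""
    cfg, truth, rnaseq, microarray = artifact_dataset
    ta = platform_transform(collapse_replicates(microarray))
    tb = platform_transform(collapse_replicates(rnaseq))
    ta, _ = remove_constant_genes(ta)
    tb, _ = remove_constant_genes(tb)
    keep = [g for g in ta.gene_ids if g in set(tb.gene_ids)]
    return truth, ta.subset_genes(keep), tb.subset_genes(keep)
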