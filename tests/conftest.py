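import numpy as np
import pandas as pd
import pytest

from orgbench.dataset import ExpressionDataset
from orgbench.simulate import GeneratorConfig, simulate_reference


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(counts, unit="counts", stages=None, lines=None, biotypes=None, lengths=None):
    """Small ExpressionDataset from a 2-D array, with synthetic metadata."""
    counts = np.asarray(counts)
    n_genes, n_samples = counts.shape
    genes = pd.Index([f"g{i}" for i in range(n_genes)])
    samples = pd.Index([f"s{j}" for j in range(n_samples)])
    if stages is None:
        stages = [f"st{j}" for j in range(n_samples)]
    stage_numeric = {s: i for i, s in enumerate(dict.fromkeys(stages))}
    sample_meta = pd.DataFrame(
        {
            "stage_label": stages,
            "stage_numeric": [float(stage_numeric[s]) for s in stages],
            "line": lines if lines is not None else ["l1"] * n_samples,
            "batch": ["b1"] * n_samples,
        },
        index=samples,
    )
    gene_meta = pd.DataFrame(
        {
            "symbol": genes,
            "biotype": biotypes if biotypes is not None else ["protein_coding"] * n_genes,
        },
        index=genes,
    )
    if lengths is not None:
        gene_meta["length_bp"] = lengths
    matrix = pd.DataFrame(counts, index=genes, columns=samples, dtype=float)
    return ExpressionDataset(matrix=matrix, unit=unit, sample_meta=sample_meta, gene_meta=gene_meta)


@pytest.fixture(scope="session")
def reference_pair():
    """Default reference simulation shared across tests (read-only)."""
    config = GeneratorConfig(seed=1)
    return simulate_reference(config)
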