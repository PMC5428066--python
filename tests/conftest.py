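import numpy as np
import pandas as pd
import pytest

from genelen import (ExpressionMatrix, GeneAnnotation, SyntheticConfig,
                     simulate_expression, simulate_lengths)


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples, log2 scale, 2 case + 2 control."""
    values = pd.DataFrame(
        [[4.0, 4.0, 2.0, 2.0],
         [1.0, 3.0, 0.0, 0.0],
         [5.0, 5.0, 5.0, 5.0]],
        index=["G1", "G2", "G3"],
        columns=["c1", "c2", "k1", "k2"],
    )
    conditions = {"c1": "case", "c2": "case", "k1": "control",
                  "k2": "control"}
    return ExpressionMatrix(values, "log2", conditions)


@pytest.fixture
def tiny_annot() -> GeneAnnotation:
    table = pd.DataFrame(
        {"gene_length": [1000.0, 5000.0, 20000.0],
         "exon_length": [800.0, 2000.0, 4000.0],
         "biotype": ["protein_coding"] * 3},
        index=pd.Index(["G1", "G2", "G3"], name="gene_id"),
    )
    return GeneAnnotation(table)


@pytest.fixture(scope="session")
def planted_profile():
    """A 2000-gene profile with a planted slope of 0.4, fixed seed."""
    cfg = SyntheticConfig(n_genes=2000, beta=0.4, noise_sd=0.5,
                          n_case=5, n_control=5, seed=20)
    annot = simulate_lengths(cfg)
    matrix, truth = simulate_expression(cfg, annot)
    return cfg, annot, matrix, truth
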