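import numpy as np
import pandas as pd
import pytest

from dimorph.core import ExpressionMatrix, GeneAnnotation, SampleAnnotation


@pytest.fixture
def small_matrix():
    """2 genes x 4 samples (2 female, 2 male)."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 7.0, 8.0]],
        index=["g1", "g2"],
        columns=["F1", "F2", "M1", "M2"],
    )
    samples = [
        SampleAnnotation("F1", sex="female", stage="ES"),
        SampleAnnotation("F2", sex="female", stage="ES"),
        SampleAnnotation("M1", sex="male", stage="ES"),
        SampleAnnotation("M2", sex="male", stage="ES"),
    ]
    genes = [GeneAnnotation("g1"), GeneAnnotation("g2")]
    return ExpressionMatrix(values, genes, samples)


def make_matrix(arr, gene_ids=None, sample_ids=None, sexes=None, stage="ES"):
    arr = np.asarray(arr, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(arr.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(arr.shape[1])]
    sexes = sexes or ["unknown"] * arr.shape[1]
    return ExpressionMatrix(
        pd.DataFrame(arr, index=gene_ids, columns=sample_ids),
        [GeneAnnotation(g) for g in gene_ids],
        [SampleAnnotation(s, sex=x, stage=stage) for s, x in zip(sample_ids, sexes)],
    )
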