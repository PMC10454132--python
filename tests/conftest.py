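import numpy as np
import pytest

from knoxnet.expression_io import ExpressionMatrix, SampleDesign


@pytest.fixture
def small_design():
    """3 (condition, day) groups x 2 replicates."""
    return [
        SampleDesign(f"{c}_{d}_r{r}", c, d, r)
        for c, d in [("watered", 2), ("drought", 2), ("drought", 4)]
        for r in (1, 2)
    ]


@pytest.fixture
def small_matrix(small_design):
    rng = np.random.default_rng(11)
    values = rng.uniform(10, 1000, size=(5, 6))
    return ExpressionMatrix(
        probe_ids=[f"p{i}" for i in range(1, 6)],
        samples=small_design,
        values=values,
    )


def write_matrix_tsv(matrix: ExpressionMatrix, matrix_path, design_path):
    from knoxnet.expression_io import write_expression

    write_expression(matrix, matrix_path, design_path)
    return matrix_path, design_path
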