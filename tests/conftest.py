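import numpy as np
import pytest

from seclass.data_io import ExpressionMatrix, LabelVector


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes × 4 samples with hand-set values."""
    return ExpressionMatrix(
        values=np.array(
            [
                [1.0, 2.0, 3.0, 4.0],
                [2.0, 4.0, 6.0, 8.0],
                [5.0, 1.0, 4.0, 2.0],
            ]
        ),
        gene_ids=["gA", "gB", "gC"],
        sample_ids=["s1", "s2", "s3", "s4"],
    )


@pytest.fixture
def tiny_labels() -> LabelVector:
    return LabelVector(labels=np.array([1, 1, 2, 2]))
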