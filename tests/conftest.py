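import numpy as np
import pandas as pd
import pytest

from cernet.study import ExpressionStudy


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_study(matrix: np.ndarray, scale="log2", tissue="LB", genes=None, samples=None,
               conditions=None, batch=None) -> ExpressionStudy:
    n_genes, n_samples = matrix.shape
    genes = genes or [f"G{i}" for i in range(n_genes)]
    samples = samples or [f"S{i}" for i in range(n_samples)]
    conditions = conditions or ["case"] * (n_samples // 2) + ["control"] * (n_samples - n_samples // 2)
    meta = pd.DataFrame({"tissue": tissue, "condition": conditions}, index=samples)
    if batch is not None:
        meta["batch"] = batch
    return ExpressionStudy(
        matrix=pd.DataFrame(matrix, index=genes, columns=samples),
        scale=scale,
        sample_meta=meta,
    )
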