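"""Core expression-study container shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = ["ExpressionStudy"]


@dataclass
class ExpressionStudy:
    """A genes x samples expression matrix with aligned sample metadata.

    Attributes
    ----------
    matrix
        Expression values, rows indexed by gene/probe symbol, columns by
        sample id. No missing values allowed.
    scale
        ``"linear"`` (strictly positive intensities) or ``"log2"``.
    sample_meta
        One row per sample (index = sample id), with at least ``tissue``
        and ``condition`` (``case``/``control``) columns; covariate and
        ``batch`` columns as available.
    """

    matrix: pd.DataFrame
    scale: str
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        if self.matrix.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if list(self.matrix.columns) != list(self.sample_meta.index):
            raise ValueError("matrix columns and sample_meta index do not match 1:1")
        if not self.matrix.index.is_unique:
            raise ValueError("gene ids are not unique")
        if self.scale == "linear" and (self.matrix.to_numpy() <= 0).any():
            raise ValueError("linear-scale matrix must be strictly positive")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def to_log2(self) -> "ExpressionStudy":
        if self.scale == "log2":
            return self
        return replace(self, matrix=np.log2(self.matrix), scale="log2")

    def to_linear(self) -> "ExpressionStudy":
        if self.scale == "linear":
            return self
        return replace(self, matrix=np.power(2.0, self.matrix), scale="linear")

    def subset_genes(self, genes) -> "ExpressionStudy":
        return replace(self, matrix=self.matrix.loc[list(genes)])

    def subset_samples(self, samples) -> "ExpressionStudy":
        samples = list(samples)
        return replace(
            self,
            matrix=self.matrix.loc[:, samples],
            sample_meta=self.sample_meta.loc[samples],
        )

    def drop_samples(self, samples) -> "ExpressionStudy":
        keep = [s for s in self.matrix.columns if s not in set(samples)]
        return self.subset_samples(keep)
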