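"""Normalization, non-specific filtering, sample QC, and batch adjustment.

The preprocessing chain mirrors a standard two-color-free microarray
workflow: quantile normalization of the intensity matrix, an intensity
filter (expressed above background in enough arrays), an interquartile-range
filter (variable across samples on the log2 scale), correlation/PCA-based
sample QC with an automated outlier flag, and linear-model batch-effect
removal that protects the condition contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .study import ExpressionStudy

__all__ = [
    "QCReport",
    "quantile_normalize",
    "iqr_filter",
    "intensity_filter",
    "qc_report",
    "flag_outliers",
    "remove_batch_effect",
]


def quantile_normalize(study: ExpressionStudy) -> ExpressionStudy:
    """Force every sample onto the common (row-mean) reference distribution.

    Each column's sorted values are replaced by the across-column mean of
    sorted values; tied values within a column receive the mean of the
    reference values at their tied ranks (so ties stay tied). On tie-free
    columns the operation is idempotent and leaves every column with the
    identical value multiset; columns containing ties deviate from exact
    multiset equality by the tie averaging. Operates on whichever scale
    the study carries.
    """
    x = study.matrix.to_numpy(dtype=float)
    n_genes, n_samples = x.shape
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(n_samples):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n_genes)
        assigned[order] = reference
        if np.unique(col).size < n_genes:
            # tied input values receive the mean reference value of their run
            tied = (
                pd.Series(assigned[order])
                .groupby(pd.Series(col[order]))
                .transform("mean")
                .to_numpy()
            )
            assigned[order] = tied
        out[:, j] = assigned
    matrix = pd.DataFrame(out, index=study.matrix.index, columns=study.matrix.columns)
    return replace(study, matrix=matrix)


def gene_iqr(matrix: pd.DataFrame) -> pd.Series:
    """Per-gene interquartile range using linear-interpolation quartiles."""
    q75, q25 = np.percentile(matrix.to_numpy(dtype=float), [75, 25], axis=1)
    return pd.Series(q75 - q25, index=matrix.index)


def iqr_filter(study: ExpressionStudy) -> list[str]:
    """Keep genes whose across-sample IQR strictly exceeds the median gene IQR.

    Requires log2-scale data; a non-specific filter removing genes that do
    not vary between samples.
    """
    if study.scale != "log2":
        raise ValueError("iqr_filter expects log2-scale data")
    if study.n_samples < 2:
        raise ValueError("iqr_filter needs at least 2 samples")
    iqr = gene_iqr(study.matrix)
    return list(iqr.index[iqr > iqr.median()])


def intensity_filter(
    study: ExpressionStudy,
    min_signal: float = 100.0,
    min_frac: float = 0.25,
) -> list[str]:
    """Keep genes with signal > ``min_signal`` in at least ``min_frac`` of arrays.

    Requires linear-scale intensities; the signal cutoff is strict and the
    array-fraction cutoff is inclusive.
    """
    if study.scale != "linear":
        raise ValueError("intensity_filter expects linear-scale data")
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must be in (0, 1]")
    frac = (study.matrix > min_signal).mean(axis=1)
    return list(frac.index[frac >= min_frac])


@dataclass
class QCReport:
    """Sample-level quality-control summary.

    Holds per-sample medians, the sample-sample Pearson correlation matrix,
    an average-linkage two-cluster assignment, scores on the first two
    principal components of the centered log2 data (with explained-variance
    fractions), and the flagged samples with reasons.
    """

    medians: pd.Series
    correlation: pd.DataFrame
    cluster_labels: pd.Series
    pc_scores: pd.DataFrame
    variance_fractions: tuple[float, float]
    flagged_samples: list[tuple[str, str]]

    def to_dict(self) -> dict:
        return {
            "medians": self.medians.to_dict(),
            "cluster_labels": {k: int(v) for k, v in self.cluster_labels.items()},
            "pc_scores": {s: list(map(float, row)) for s, row in self.pc_scores.iterrows()},
            "variance_fractions": list(self.variance_fractions),
            "flagged_samples": [list(f) for f in self.flagged_samples],
        }


def qc_report(study: ExpressionStudy, flag_k: float = 5.0) -> QCReport:
    """Compute correlation/cluster/PCA QC and flag distance outliers.

    A sample is flagged when its Euclidean distance from its
    (tissue, condition) group centroid in PC1-PC2 space exceeds ``flag_k``
    times the median such distance within its group.
    """
    log2 = study.to_log2()
    x = log2.matrix.to_numpy(dtype=float)
    if np.allclose(x, x[:, :1]):
        raise ValueError("constant matrix: QC is degenerate")
    samples = list(log2.matrix.columns)

    medians = log2.matrix.median(axis=0)
    corr = log2.matrix.corr(method="pearson")

    dist = squareform(np.clip(1.0 - corr.to_numpy(), 0.0, None), checks=False)
    labels = fcluster(linkage(dist, method="average"), t=2, criterion="maxclust")
    cluster_labels = pd.Series(labels, index=samples)

    centered = x.T - x.mean(axis=1)
    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(centered)
    pc_scores = pd.DataFrame(scores, index=samples, columns=["PC1", "PC2"])
    var_frac = tuple(float(v) for v in pca.explained_variance_ratio_[:2])

    flagged = _distance_flags(pc_scores, log2.sample_meta, flag_k)
    return QCReport(
        medians=medians,
        correlation=corr,
        cluster_labels=cluster_labels,
        pc_scores=pc_scores,
        variance_fractions=var_frac,
        flagged_samples=flagged,
    )


def _distance_flags(
    pc_scores: pd.DataFrame, meta: pd.DataFrame, k: float
) -> list[tuple[str, str]]:
    flagged: list[tuple[str, str]] = []
    groups = meta.groupby(["tissue", "condition"], sort=True).groups
    for (tissue, condition), samples in groups.items():
        samples = list(samples)
        if len(samples) < 3:
            raise ValueError(
                f"group ({tissue}, {condition}) has fewer than 3 samples"
            )
        pts = pc_scores.loc[samples].to_numpy()
        dist = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
        med = np.median(dist)
        if med <= 0:
            continue
        for s, d in zip(samples, dist):
            if d > k * med:
                flagged.append(
                    (s, f"PC1-2 distance {d:.2f} > {k:g} x group median {med:.2f}")
                )
    return sorted(flagged)


def flag_outliers(report: QCReport) -> list[str]:
    """Sample ids flagged by the QC distance rule."""
    return [s for s, _ in report.flagged_samples]


def remove_batch_effect(
    study: ExpressionStudy,
    batch: pd.Series | None = None,
    condition_col: str = "condition",
) -> ExpressionStudy:
    """Regress out batch terms while protecting the condition contrast.

    Fits, per gene, least squares on intercept + condition indicator +
    batch indicators and subtracts only the fitted batch component. The
    adjusted matrix is intended for visualization/QC; inference downstream
    models covariates directly.
    """
    log2 = study.to_log2()
    if batch is None:
        if "batch" not in log2.sample_meta.columns:
            raise ValueError("no batch labels supplied and no 'batch' metadata column")
        batch = log2.sample_meta["batch"]
    batch = batch.loc[log2.matrix.columns]
    if batch.isna().any():
        raise ValueError("batch labels incomplete")
    if batch.nunique() == 1:
        return log2

    cond = pd.get_dummies(log2.sample_meta[condition_col], drop_first=True, dtype=float)
    bat = pd.get_dummies(batch.astype(str), prefix="batch", drop_first=True, dtype=float)
    design = pd.concat(
        [pd.Series(1.0, index=log2.matrix.columns, name="intercept"), cond, bat], axis=1
    )
    x = design.to_numpy()
    rank_full = np.linalg.matrix_rank(x)
    if rank_full < x.shape[1]:
        raise ValueError(
            "batch is exactly confounded with condition: the joint "
            "condition+batch design is rank deficient, so batch effects "
            "cannot be separated from the condition contrast"
        )
    y = log2.matrix.to_numpy(dtype=float).T  # samples x genes
    beta = np.linalg.lstsq(x, y, rcond=None)[0]
    batch_cols = [i for i, c in enumerate(design.columns) if c.startswith("batch_")]
    fitted_batch = x[:, batch_cols] @ beta[batch_cols]
    adjusted = pd.DataFrame(
        (y - fitted_batch).T, index=log2.matrix.index, columns=log2.matrix.columns
    )
    return replace(log2, matrix=adjusted)
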