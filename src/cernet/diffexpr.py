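"""Covariate-adjusted linear models with empirical-Bayes moderated t tests.

Per gene g, log2 expression is modeled by least squares on a design with an
intercept, a case/control indicator, and optional covariates. The condition
coefficient is the log2 fold change (case - control). Residual variances
s_g^2 (d_g df each) are shrunk toward a prior s_0^2 with d_0 df estimated
by matching moments of log s_g^2 under the scaled-F sampling model:

    s~_g^2 = (d_0 s_0^2 + d_g s_g^2) / (d_0 + d_g)
    t~_g   = beta_g / (s~_g * u_g),   t~_g ~ t(d_0 + d_g) under H0,

where u_g is the unscaled standard error from the design. Moderation
borrows strength across genes and augments the residual degrees of freedom;
d_0 = 0 recovers the ordinary Student t, d_0 = +inf pools all variances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .preprocess import gene_iqr
from .study import ExpressionStudy

__all__ = [
    "LinearFit",
    "ModeratedTestParams",
    "build_design",
    "fit_linear_models",
    "moderate_and_test",
    "bh_adjust",
    "call_degs",
    "partition_gene_classes",
    "collapse_probes",
    "differential_expression",
]


@dataclass
class LinearFit:
    """Per-gene least-squares results for the condition contrast."""

    coef: pd.Series  # condition coefficient = log2FC (case - control)
    stdev_unscaled: float  # sqrt of (X'X)^-1 diagonal entry for condition
    s2: pd.Series  # residual variances
    df_residual: int
    design: pd.DataFrame


@dataclass
class ModeratedTestParams:
    """Empirical-Bayes hyperparameters and per-gene posterior variances."""

    d0: float  # prior degrees of freedom (may be +inf)
    s0_sq: float  # prior variance
    s_g_sq: pd.Series
    d_g: int
    s_tilde_sq: pd.Series


def build_design(
    meta: pd.DataFrame,
    covariates: tuple[str, ...] = (),
    condition_col: str = "condition",
) -> pd.DataFrame:
    """Design matrix: intercept + case indicator + covariate columns.

    Numeric covariates enter as-is; string/categorical covariates expand to
    treatment-coded indicator columns.
    """
    cols = {"intercept": pd.Series(1.0, index=meta.index)}
    cols["condition_case"] = (meta[condition_col] == "case").astype(float)
    design = pd.DataFrame(cols)
    for cov in covariates:
        col = meta[cov]
        if pd.api.types.is_numeric_dtype(col):
            design[cov] = col.astype(float)
        else:
            dummies = pd.get_dummies(col.astype(str), prefix=cov, drop_first=True, dtype=float)
            design = pd.concat([design, dummies], axis=1)
    return design


def _check_full_rank(design: pd.DataFrame) -> None:
    x = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(x) == x.shape[1]:
        return
    collinear = []
    for j in range(1, x.shape[1]):
        if np.linalg.matrix_rank(x[:, : j + 1]) == np.linalg.matrix_rank(x[:, :j]):
            collinear.append(design.columns[j])
    raise ValueError(f"design matrix is rank deficient; collinear columns: {collinear}")


def fit_linear_models(
    study: ExpressionStudy,
    covariates: tuple[str, ...] = (),
    condition_col: str = "condition",
) -> LinearFit:
    """Fit the per-gene linear model on log2 data.

    Returns the condition coefficient (log2FC), its unscaled standard
    error, and the residual variance/df shared pieces the moderated test
    consumes.
    """
    if study.scale != "log2":
        raise ValueError("differential expression expects log2-scale data")
    design = build_design(study.sample_meta, covariates, condition_col)
    _check_full_rank(design)
    x = design.to_numpy(dtype=float)
    y = study.matrix.to_numpy(dtype=float).T  # samples x genes
    n, p = x.shape
    if n <= p:
        raise ValueError(f"not enough residual df: {n} samples, {p} coefficients")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    df_residual = n - p
    s2 = (resid**2).sum(axis=0) / df_residual
    j = list(design.columns).index("condition_case")
    return LinearFit(
        coef=pd.Series(beta[j], index=study.matrix.index, name="log2fc"),
        stdev_unscaled=float(np.sqrt(xtx_inv[j, j])),
        s2=pd.Series(s2, index=study.matrix.index, name="s2"),
        df_residual=df_residual,
        design=design,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-8 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-match (d0, s0^2) from the distribution of log s_g^2.

    Under the hierarchical model, e_g = log s_g^2 - digamma(d_g/2) +
    log(d_g/2) has mean log s0^2 + digamma(d0/2) - log(d0/2) and variance
    trigamma(d_g/2) + trigamma(d0/2); solving the excess variance for d0
    (trigamma inversion) and back-substituting gives s0^2. A non-positive
    excess variance means the observed spread is fully explained by
    sampling noise, so d0 = +inf and all variances pool.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need at least 2 positive residual variances to estimate prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    n = e.size
    emean = e.mean()
    evar = ((e - emean) ** 2).sum() / (n - 1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = math.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_sq = math.exp(emean)
    return d0, s0_sq


def moderate_and_test(
    fit: LinearFit,
    d0: float | None = None,
    s0_sq: float | None = None,
) -> tuple[ModeratedTestParams, pd.DataFrame]:
    """Shrink variances and compute moderated t with d0 + d_g df.

    ``d0``/``s0_sq`` default to the moment estimates; forcing ``d0=0``
    yields the ordinary Student t and ``d0=inf`` fully pools variances.
    """
    s2 = fit.s2.to_numpy(dtype=float)
    df = fit.df_residual
    if d0 is None or s0_sq is None:
        est_d0, est_s0 = estimate_prior(s2, df)
        d0 = est_d0 if d0 is None else d0
        s0_sq = est_s0 if s0_sq is None else s0_sq
    if math.isinf(d0):
        s_tilde_sq = np.full_like(s2, s0_sq)
        df_total = math.inf
    elif d0 == 0:
        s_tilde_sq = s2.copy()
        df_total = df
    else:
        s_tilde_sq = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df
    se = np.sqrt(s_tilde_sq) * fit.stdev_unscaled
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fit.coef.to_numpy() / se
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    params = ModeratedTestParams(
        d0=float(d0),
        s0_sq=float(s0_sq),
        s_g_sq=fit.s2,
        d_g=df,
        s_tilde_sq=pd.Series(s_tilde_sq, index=fit.s2.index),
    )
    table = pd.DataFrame({"log2fc": fit.coef, "t": t, "p": p}, index=fit.coef.index)
    return params, table


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    table: pd.DataFrame,
    adjp_max: float = 0.001,
    min_abs_log2fc: float = 0.69,
) -> pd.DataFrame:
    """Annotate directions using strict adjP and |log2FC| cutoffs.

    A gene is differentially expressed iff adjP < ``adjp_max`` AND
    |log2FC| > ``min_abs_log2fc`` (both strict); direction is the sign of
    its log2FC, ``ns`` otherwise.
    """
    out = table.copy()
    de = (out["adj_p"] < adjp_max) & (out["log2fc"].abs() > min_abs_log2fc)
    out["direction"] = np.where(de, np.where(out["log2fc"] > 0, "up", "down"), "ns")
    return out


def partition_gene_classes(
    table: pd.DataFrame, lncrna_catalog: set[str]
) -> pd.DataFrame:
    """Assign each gene symbol to the lncRNA or mRNA class.

    Membership in the lncRNA symbol catalog is exact and case-sensitive;
    everything else is treated as protein-coding mRNA.
    """
    out = table.copy()
    out["gene_class"] = [
        "lncRNA" if g in lncrna_catalog else "mRNA" for g in out.index
    ]
    return out


def collapse_probes(
    study: ExpressionStudy, probe_to_gene: dict[str, str]
) -> ExpressionStudy:
    """Collapse probes to gene symbols, keeping the most variable probe.

    Probes without a gene symbol are discarded; among multiple probes for
    one symbol the probe with the largest log2-scale IQR is retained and
    re-indexed by the symbol.
    """
    log2 = study.to_log2()
    mapped = [p for p in log2.matrix.index if probe_to_gene.get(p)]
    matrix = log2.matrix.loc[mapped]
    iqr = gene_iqr(matrix)
    symbols = pd.Series([probe_to_gene[p] for p in mapped], index=mapped)
    best = iqr.groupby(symbols).idxmax()
    collapsed = matrix.loc[best.to_numpy()]
    collapsed.index = best.index
    collapsed = collapsed.sort_index()
    return replace(log2, matrix=collapsed)


def differential_expression(
    study: ExpressionStudy,
    covariates: tuple[str, ...] = (),
    lncrna_catalog: set[str] | None = None,
    adjp_max: float = 0.001,
    min_abs_log2fc: float = 0.69,
    moderated: bool = True,
) -> pd.DataFrame:
    """Full DE call: fit, (optionally) moderate, adjust, threshold, classify.

    Returns a per-gene table with log2fc, t, p, adj_p, direction,
    gene_class, plus the test flavour in ``attrs["statistic"]``.
    """
    fit = fit_linear_models(study, covariates)
    params, table = moderate_and_test(fit, d0=None if moderated else 0.0)
    table["adj_p"] = bh_adjust(table["p"].to_numpy())
    table = call_degs(table, adjp_max=adjp_max, min_abs_log2fc=min_abs_log2fc)
    table = partition_gene_classes(table, lncrna_catalog or set())
    table.attrs["statistic"] = "moderated_t" if moderated else "student_t"
    table.attrs["d0"] = params.d0
    table.attrs["s0_sq"] = params.s0_sq
    return table
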