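"""Signature-based immune-cell deconvolution of bulk expression.

Bulk tumor RNA is modelled as a non-negative combination of reference
expression profiles for ten immune cell subsets (B cells, M1/M2
macrophages, monocytes, neutrophils, NK cells, CD4/CD8 T cells, Tregs,
dendritic cells); an "Other" population absorbs non-immune content
(malignant cells, fibroblasts). Per sample, fractions are obtained by
non-negative least squares on the genes shared between the mixture and
the signature, after scaling signature columns and the mixture to unit
sum so that fractions are comparable across samples and invariant to
overall intensity.

The module also provides the RPKM pre-filter, quartile stratification
by a marker gene (e.g. CD276/B7-H3), gated group comparisons per cell
type, and Spearman correlation matrices between cell-type fractions
and marker expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls
from statsmodels.stats.multitest import multipletests

from .stats_utils import TestResult, compare_groups
from .transcriptomics import ExpressionMatrix

__all__ = [
    "DEFAULT_CELL_TYPES",
    "SignatureMatrix",
    "DeconvolutionResult",
    "filter_low_expression",
    "deconvolve",
    "stratify_by_gene",
    "compare_groups",
    "stratified_comparison",
    "correlation_matrix",
]

DEFAULT_CELL_TYPES = (
    "B cells",
    "M1 macrophages",
    "M2 macrophages",
    "Monocytes",
    "Neutrophils",
    "NK cells",
    "CD4 T cells",
    "CD8 T cells",
    "Tregs",
    "Dendritic cells",
)


@dataclass
class SignatureMatrix:
    """Gene-by-cell-type reference expression profiles (non-negative)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("signature profiles must be non-negative")
        if self.values.index.has_duplicates:
            raise ValueError("signature gene ids must be unique")
        zero_cols = self.values.columns[(self.values == 0).all(axis=0)]
        if len(zero_cols):
            raise ValueError(f"all-zero cell-type column(s): {list(zero_cols)}")

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class DeconvolutionResult:
    """Sample-by-(cell types + Other) fractions with per-sample residuals."""

    fractions: pd.DataFrame
    residual_norm: pd.Series = field(default_factory=pd.Series)

    def __post_init__(self) -> None:
        arr = self.fractions.to_numpy()
        if (arr < -1e-9).any() or (arr > 1 + 1e-9).any():
            raise ValueError("fractions must lie in [0, 1]")
        if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("per-sample fractions must sum to 1")


def filter_low_expression(expr: ExpressionMatrix, threshold: float = 0.5) -> ExpressionMatrix:
    """Drop genes whose cross-sample mean RPKM is strictly below ``threshold``."""
    if expr.unit != "rpkm":
        raise ValueError(f"RPKM filter needs unit='rpkm', got {expr.unit!r}")
    keep = expr.values.mean(axis=1) >= threshold
    lengths = expr.feature_lengths.loc[keep] if expr.feature_lengths is not None else None
    return ExpressionMatrix(
        values=expr.values.loc[keep],
        unit="rpkm",
        feature_lengths=lengths,
        sample_groups=dict(expr.sample_groups),
    )


def deconvolve(expr: ExpressionMatrix, sig: SignatureMatrix) -> DeconvolutionResult:
    """Estimate immune fractions per sample by non-negative least squares.

    Signature columns and each mixture column are scaled to unit sum on
    the shared genes; the NNLS coefficients are the immune fractions
    and ``Other = max(0, 1 - sum(immune))``. If the coefficients exceed
    1 in total (possible with noise) they are renormalized.
    """
    shared = expr.values.index.intersection(sig.values.index)
    k = len(sig.cell_types)
    if len(shared) < k:
        raise ValueError(f"only {len(shared)} shared genes for {k} cell types")
    S = sig.values.loc[shared].to_numpy(dtype=float)
    colsums = S.sum(axis=0)
    S = S / colsums  # equal (unit) column sums
    fractions = {}
    residuals = {}
    for sample in expr.samples:
        m = expr.values.loc[shared, sample].to_numpy(dtype=float)
        total = m.sum()
        if total <= 0:
            w = np.zeros(k)
            res = 0.0
        else:
            w, res = nnls(S, m / total)
        immune = w.sum()
        if immune > 1:
            w = w / immune
            other = 0.0
        else:
            other = 1.0 - immune
        fractions[sample] = np.append(w, other)
        residuals[sample] = float(res)
    frame = pd.DataFrame.from_dict(
        fractions, orient="index", columns=[*sig.cell_types, "Other"]
    )
    frame = frame.clip(lower=0.0)
    return DeconvolutionResult(
        fractions=frame, residual_norm=pd.Series(residuals, name="residual_norm")
    )


def stratify_by_gene(
    expr: ExpressionMatrix,
    gene: str,
    low_q: float = 0.25,
    high_q: float = 0.75,
) -> tuple[list[str], list[str]]:
    """Partition samples into expression tails of a stratifying gene.

    Rank-based tails: the ``floor(low_q * n)`` lowest-expressing samples
    form the low group and ``floor((1 - high_q) * n)`` highest form the
    high group; samples tied with the boundary value are included in the
    tail, so tail sizes are guaranteed minima. Depends only on the ranks
    of the gene, hence invariant under monotone transformation.
    """
    if gene not in expr.values.index:
        raise ValueError(f"gene {gene!r} not in the expression matrix")
    vals = expr.values.loc[gene]
    if vals.nunique() <= 1:
        raise ValueError("all samples have identical expression; cannot stratify")
    n = len(vals)
    k_low = int(np.floor(low_q * n))
    k_high = int(np.floor((1.0 - high_q) * n))
    order = vals.sort_values(kind="stable")
    low_cut = order.iloc[k_low - 1] if k_low else None
    high_cut = order.iloc[n - k_high] if k_high else None
    low = list(vals.index[vals <= low_cut]) if k_low else []
    high = list(vals.index[vals >= high_cut]) if k_high else []
    overlap = set(low) & set(high)
    if overlap:
        raise ValueError("tails overlap; quantiles too extreme for this sample size")
    return high, low


def stratified_comparison(
    result: DeconvolutionResult,
    high: Sequence[str],
    low: Sequence[str],
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Per-cell-type comparison of fractions between high and low strata.

    Uses the Shapiro-gated test from :mod:`surftarget.stats_utils`;
    reports the mean fraction per stratum, the test used, and the
    p-value (BH-adjusted across cell types when ``bh_adjust``).
    """
    rows = []
    for ct in result.fractions.columns:
        hi = result.fractions.loc[list(high), ct].to_numpy()
        lo = result.fractions.loc[list(low), ct].to_numpy()
        res: TestResult = compare_groups(hi, lo)
        rows.append(
            {
                "cell_type": ct,
                "mean_high": float(hi.mean()),
                "mean_low": float(lo.mean()),
                "test": res.test,
                "p_value": res.p_value,
            }
        )
    out = pd.DataFrame(rows).set_index("cell_type")
    if bh_adjust:
        _, padj, _, _ = multipletests(out["p_value"], method="fdr_bh")
        out["p_adj"] = padj
    return out


def correlation_matrix(
    result: DeconvolutionResult,
    gene_expr: pd.Series | None = None,
    gene_name: str = "marker",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman correlations among cell-type fractions (+ a marker).

    Returns ``(rho, p)`` DataFrames. Constant columns yield NaN rather
    than an error.
    """
    data = result.fractions.copy()
    if gene_expr is not None:
        data[gene_name] = gene_expr.reindex(data.index)
    if len(data) < 3:
        raise ValueError("need >=3 samples")
    cols = list(data.columns)
    k = len(cols)
    rho = np.full((k, k), np.nan)
    pval = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            x, y = data.iloc[:, i], data.iloc[:, j]
            if x.nunique() <= 1 or y.nunique() <= 1:
                continue
            r, p = stats.spearmanr(x, y)
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    return (
        pd.DataFrame(rho, index=cols, columns=cols),
        pd.DataFrame(pval, index=cols, columns=cols),
    )
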