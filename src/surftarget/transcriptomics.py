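"""Bulk RNA-seq differential expression for the validation arm.

A deliberately transparent negative-binomial pipeline: median-of-ratios
size factors, method-of-moments dispersion, a Wald test on the log2
fold change of normalized group means, and Benjamini-Hochberg
adjustment. It is not a numerical clone of shrinkage-based DE engines
(no fold-change moderation, no outlier filtering): the prioritization
built on top only needs calibrated p-values and unbiased fold-change
estimates, which this provides.

Counts are modelled as NB with Var = mu + alpha * mu^2 (single
dispersion alpha per gene). The Wald statistic uses a t reference with
n_a + n_b - 2 degrees of freedom, which keeps the type-I error near
nominal at the small group sizes typical of tumor-vs-normal designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "size_factors",
    "nb_wald_test",
    "compute_rpkm",
    "cross_omic_intersection",
]


@dataclass
class ExpressionMatrix:
    """Feature-by-sample expression values with unit bookkeeping.

    ``unit`` is one of ``"counts"``, ``"rpkm"`` or ``"linear"``;
    ``feature_lengths`` (bp) are required for RPKM conversion.
    """

    values: pd.DataFrame
    unit: str = "counts"
    feature_lengths: pd.Series | None = None
    sample_groups: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.unit not in ("counts", "rpkm", "linear"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.feature_lengths is not None:
            self.feature_lengths = self.feature_lengths.reindex(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def group_samples(self, group: str) -> list[str]:
        return [s for s in self.samples if self.sample_groups.get(s) == group]


def size_factors(counts: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios library-size factors, normalized to geometric mean 1.

    For each gene expressed in every sample, the ratio of its count to
    its across-sample geometric mean is formed; a sample's factor is the
    median of those ratios.
    """
    mat = counts.values.to_numpy(dtype=float)
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no gene is expressed in all samples; median-of-ratios undefined "
            "(consider a pseudo-reference fallback)"
        )
    logs = np.log(mat[all_pos])
    log_geomean = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geomean, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.samples, name="size_factor")


def nb_wald_test(
    counts: ExpressionMatrix,
    group_a: str,
    group_b: str,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-gene NB Wald test of ``group_a`` (tumor) vs ``group_b`` (normal).

    Returns a DataFrame with ``base_mean_a/b`` (means of size-factor
    normalized counts), ``log2_fc`` (positive = higher in ``group_a``),
    raw and BH-adjusted p-values, and a ``pass`` flag at the fold-change
    and FDR thresholds. Genes with zero counts in both groups get
    p = 1 and log2FC = 0 by convention.
    """
    a_samps = counts.group_samples(group_a)
    b_samps = counts.group_samples(group_b)
    if len(a_samps) < 2 or len(b_samps) < 2:
        raise ValueError("need >=2 samples per group")
    if (counts.values[a_samps].sum(axis=0) == 0).any() or (counts.values[b_samps].sum(axis=0) == 0).any():
        raise ValueError("a sample has an all-zero library")
    sf = size_factors(counts)
    norm = counts.values.divide(sf, axis=1)
    na, nb = len(a_samps), len(b_samps)
    A = norm[a_samps].to_numpy(dtype=float)
    B = norm[b_samps].to_numpy(dtype=float)
    inv_sa = float(np.mean(1.0 / sf[a_samps].to_numpy()))
    inv_sb = float(np.mean(1.0 / sf[b_samps].to_numpy()))

    mean_a = A.mean(axis=1)
    mean_b = B.mean(axis=1)
    mu = (na * mean_a + nb * mean_b) / (na + nb)

    # pooled method-of-moments dispersion: on the normalized scale,
    # Var(K_i/s_i) = mu/s_i + alpha mu^2; subtract the Poisson part.
    var_a = A.var(axis=1, ddof=1)
    var_b = B.var(axis=1, ddof=1)
    pooled_var = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
    mu_w = (na * mean_a * inv_sa + nb * mean_b * inv_sb) / (na + nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - mu_w) / np.where(mu > 0, mu, 1.0) ** 2
    alpha = np.clip(np.nan_to_num(alpha), 1e-8, None)

    pseudo = 0.5  # continuity on the normalized-count scale
    ma, mb = mean_a + pseudo, mean_b + pseudo
    log2_fc = np.log2(ma / mb)
    # delta-method SE of log2 of a group mean under the NB model
    var_mean_a = (mean_a * inv_sa + alpha * mean_a**2) / na
    var_mean_b = (mean_b * inv_sb + alpha * mean_b**2) / nb
    se = np.sqrt(var_mean_a / ma**2 + var_mean_b / mb**2) / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2_fc / se
    df = na + nb - 2
    p = 2.0 * stats.t.sf(np.abs(z), df=df)

    silent = (mean_a == 0) & (mean_b == 0)
    log2_fc = np.where(silent, 0.0, log2_fc)
    p = np.where(silent | ~np.isfinite(p), 1.0, p)
    _, padj, _, _ = multipletests(p, method="fdr_bh")
    out = pd.DataFrame(
        {
            "base_mean_a": mean_a,
            "base_mean_b": mean_b,
            "log2_fc": log2_fc,
            "p_raw": p,
            "p_adj": padj,
        },
        index=counts.values.index,
    )
    out["pass"] = (np.abs(out["log2_fc"]) >= np.log2(fc_threshold)) & (out["p_adj"] < fdr_threshold)
    out.attrs["groups"] = (group_a, group_b)
    out.attrs["fc_on"] = "normalized group means (+0.5 continuity)"
    return out


def compute_rpkm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Reads per kilobase per million mapped reads.

    RPKM_gs = count_gs * 1e9 / (length_g * total_s), with total_s the
    raw column sum.
    """
    if counts.feature_lengths is None or counts.feature_lengths.isna().any():
        raise ValueError("feature lengths (bp) required for RPKM")
    totals = counts.values.sum(axis=0)
    rpkm = counts.values.multiply(1e9).divide(counts.feature_lengths, axis=0).divide(totals, axis=1)
    return ExpressionMatrix(
        values=rpkm,
        unit="rpkm",
        feature_lengths=counts.feature_lengths,
        sample_groups=dict(counts.sample_groups),
    )


def cross_omic_intersection(
    prot: pd.DataFrame,
    rna: pd.DataFrame,
    prot_symbols: pd.Series | None = None,
) -> tuple[list[str], float]:
    """Candidates passing both the proteomic and transcriptomic screens.

    ``prot`` and ``rna`` are differential result frames carrying a
    boolean ``pass`` column; identifiers are matched on upper-cased
    gene symbols (``prot_symbols`` maps protein ids to symbols when the
    proteomic frame is indexed by accession). Returns the sorted
    candidate symbols and the concordance fraction
    |both| / |protein-level passers| (NaN when no protein passes).
    """
    if prot_symbols is not None:
        psym = prot_symbols.reindex(prot.index).astype(str).str.upper()
    elif "gene_symbol" in prot.columns:
        psym = prot["gene_symbol"].astype(str).str.upper()
    else:
        psym = pd.Series(prot.index.astype(str).str.upper(), index=prot.index)
    prot_pass = set(psym[prot["pass"].to_numpy(dtype=bool)])
    rna_pass = {str(g).upper() for g in rna.index[rna["pass"].to_numpy(dtype=bool)]}
    both = sorted(prot_pass & rna_pass)
    frac = float("nan") if not prot_pass else len(both) / len(prot_pass)
    return both, frac
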