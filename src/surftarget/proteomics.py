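"""Spectral-count proteomics: NSAF normalization and surfaceome filtering.

Label-free cell-surface-capture experiments quantify each protein by its
spectral count (SpC, the number of peptide-spectrum matches). Longer
proteins yield more tryptic peptides, so raw counts are length-biased;
the normalized spectral abundance factor corrects this:

    NSAF_i = (SpC_i / L_i) / sum_j (SpC_j / L_j)      (per sample)

where L_i is the protein length in amino acids. NSAF values sum to 1 in
each sample, which also removes differences in sequencing/acquisition
depth between samples.

The module further covers detection calling, plasma-membrane annotation
filtering (emulating a GO:0005886 gene set), per-group protein
repertoires and their overlaps, replicate correlation, average-linkage
hierarchical clustering of samples, and a fold-change + FDR screen for
tumor-enriched surface proteins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "SpectralCountMatrix",
    "NSAFMatrix",
    "AnnotationSet",
    "RepertoireSummary",
    "compute_tsc",
    "compute_nsaf",
    "filter_by_annotation",
    "repertoire_overlaps",
    "replicate_correlation",
    "cluster_samples",
    "differential_abundance",
]


@dataclass
class SpectralCountMatrix:
    """Protein-by-sample spectral counts with protein lengths.

    ``counts`` is a DataFrame (rows = proteins, columns = samples) of
    non-negative integers; ``lengths`` maps protein id -> amino acids;
    ``gene_symbols`` maps protein id -> gene symbol; ``sample_groups``
    maps every sample to its group label.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    gene_symbols: pd.Series
    sample_groups: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("protein ids must be unique")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("spectral counts must be integers")
            self.counts = self.counts.astype(int)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("spectral counts must be non-negative")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any() or (self.lengths < 1).any():
            raise ValueError("every protein needs a length >= 1")
        self.gene_symbols = self.gene_symbols.reindex(self.counts.index)
        missing = [s for s in self.counts.columns if s not in self.sample_groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def to_frame(self) -> pd.DataFrame:
        """Long-lived TSV layout: protein_id, gene_symbol, length, <samples>."""
        out = pd.DataFrame(
            {
                "protein_id": self.counts.index,
                "gene_symbol": self.gene_symbols.values,
                "length": self.lengths.values.astype(int),
            }
        )
        return pd.concat([out, self.counts.reset_index(drop=True)], axis=1)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, sample_groups: Mapping[str, str]) -> "SpectralCountMatrix":
        meta = {"protein_id", "gene_symbol", "length"}
        samples = [c for c in frame.columns if c not in meta]
        frame = frame.set_index("protein_id")
        return cls(
            counts=frame[samples].astype(int),
            lengths=frame["length"].astype(int),
            gene_symbols=frame["gene_symbol"].astype(str),
            sample_groups=dict(sample_groups),
        )


@dataclass
class NSAFMatrix:
    """Length-normalized abundance values in [0, 1], summing to 1 per sample."""

    values: pd.DataFrame
    detected_mask: pd.DataFrame
    gene_symbols: pd.Series
    sample_groups: Mapping[str, str]

    def __post_init__(self) -> None:
        vals = self.values.to_numpy()
        if (vals < 0).any() or (vals > 1).any():
            raise ValueError("NSAF values must lie in [0, 1]")
        if (np.asarray(self.values.to_numpy())[~self.detected_mask.to_numpy()] != 0).any():
            raise ValueError("non-detected entries must carry NSAF 0")
        colsums = vals.sum(axis=0)
        any_detected = self.detected_mask.to_numpy().any(axis=0)
        if not np.allclose(colsums[any_detected], 1.0, atol=1e-9):
            raise ValueError("per-sample NSAF must sum to 1 over detected proteins")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class AnnotationSet:
    """A named gene set, e.g. the plasma-membrane term GO:0005886."""

    name: str
    members: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.members = frozenset(str(m).upper() for m in self.members)
        if not self.members:
            raise ValueError(f"annotation set {self.name!r} is empty")

    @classmethod
    def from_gmt(cls, path, set_name: str | None = None) -> "AnnotationSet":
        """Read one set from a GMT file (set name, description, members...)."""
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                if set_name is None or parts[0] == set_name:
                    return cls(name=parts[0], members=frozenset(parts[2:]))
        raise ValueError(f"gene set {set_name!r} not found in {path}")


@dataclass
class RepertoireSummary:
    """Per-sample detection counts plus group-level common/exclusive sets."""

    per_sample_counts: pd.Series
    per_sample_membrane_counts: pd.Series | None
    group_common: dict[str, frozenset[str]]
    group_exclusive: dict[str, frozenset[str]]
    intersection_counts: dict[frozenset[str], int]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"group": g, "n_common": len(self.group_common[g]), "n_exclusive": len(self.group_exclusive[g])}
            for g in sorted(self.group_common)
        ]
        return pd.DataFrame(rows)


def compute_tsc(sc: SpectralCountMatrix) -> pd.Series:
    """Total spectral count (column sum) per sample."""
    return sc.counts.sum(axis=0)


def compute_nsaf(sc: SpectralCountMatrix, min_spc: int = 1) -> NSAFMatrix:
    """Length-normalize spectral counts to NSAF, per sample.

    Detection is SpC >= ``min_spc``. A sample with zero total counts
    yields an all-zero column and a warning rather than an error.
    """
    saf = sc.counts.divide(sc.lengths, axis=0).astype(float)
    totals = saf.sum(axis=0)
    empty = totals <= 0
    if empty.any():
        logger.warning("samples with zero total counts: %s", list(totals.index[empty]))
    denom = totals.where(~empty, 1.0)
    values = saf.divide(denom, axis=1)
    detected = sc.counts >= min_spc
    values = values.where(detected, 0.0)
    # re-normalize over detected proteins so the column identity is exact
    det_sums = values.sum(axis=0)
    det_sums = det_sums.where(det_sums > 0, 1.0)
    values = values.divide(det_sums, axis=1)
    return NSAFMatrix(
        values=values,
        detected_mask=detected,
        gene_symbols=sc.gene_symbols,
        sample_groups=dict(sc.sample_groups),
    )


def filter_by_annotation(
    features: pd.DataFrame | pd.Series | Iterable[str],
    ann: AnnotationSet,
    symbols: pd.Series | None = None,
    detected_mask: pd.DataFrame | None = None,
):
    """Restrict features to members of an annotation set.

    ``features`` may be a matrix (rows filtered by their symbol), a
    Series of symbols, or an iterable of symbols. Matching is on
    upper-cased gene symbols. Returns ``(filtered, retained)`` where
    ``retained`` is the overall retained fraction, or a per-sample
    Series when ``detected_mask`` is supplied (fraction of detected
    proteins annotated as membrane, per sample).
    """
    if isinstance(features, pd.DataFrame):
        if symbols is None:
            raise ValueError("a matrix needs a symbols Series aligned to its index")
        symbols = symbols.reindex(features.index).astype(str).str.upper()
        keep = symbols.isin(ann.members)
        filtered = features.loc[keep]
        if detected_mask is not None:
            det = detected_mask.reindex(features.index)
            n_det = det.sum(axis=0)
            n_mem = det.loc[keep].sum(axis=0)
            retained = (n_mem / n_det.where(n_det > 0, 1)).astype(float)
        else:
            retained = float(keep.mean()) if len(keep) else float("nan")
        if len(filtered) == 0:
            logger.warning("annotation %r retained no features", ann.name)
        return filtered, retained
    syms = pd.Series(list(features), dtype=str).str.upper()
    keep = syms.isin(ann.members)
    kept = [f for f, k in zip(features, keep) if k]
    if not kept:
        logger.warning("annotation %r retained no features", ann.name)
    return kept, (float(keep.mean()) if len(keep) else float("nan"))


def repertoire_overlaps(nsaf: NSAFMatrix, groups: Mapping[str, str] | None = None) -> RepertoireSummary:
    """Group-wise common and exclusive detected-protein sets.

    A protein is *common to a group* when detected in every sample of
    that group, and *exclusive* when additionally absent from the
    common set of every other group. All non-empty intersections of the
    group common sets are counted (Venn-style).
    """
    groups = dict(groups or nsaf.sample_groups)
    labels = sorted(set(groups[s] for s in nsaf.samples))
    det = nsaf.detected_mask
    per_sample = det.sum(axis=0)
    common: dict[str, frozenset[str]] = {}
    for g in labels:
        members = [s for s in nsaf.samples if groups[s] == g]
        if not members:
            raise ValueError(f"group {g!r} has no samples")
        mask = det[members].all(axis=1)
        common[g] = frozenset(det.index[mask])
    exclusive = {
        g: frozenset(common[g].difference(*[common[h] for h in labels if h != g]) if len(labels) > 1 else common[g])
        for g in labels
    }
    from itertools import combinations

    inter: dict[frozenset[str], int] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            sets = [common[g] for g in combo]
            inter[frozenset(combo)] = len(frozenset.intersection(*sets))
    return RepertoireSummary(
        per_sample_counts=per_sample,
        per_sample_membrane_counts=None,
        group_common=common,
        group_exclusive=exclusive,
        intersection_counts=inter,
    )


def replicate_correlation(
    nsaf: NSAFMatrix,
    sample_a: str,
    sample_b: str,
    method: Literal["pearson", "spearman"] = "pearson",
    detection: Literal["intersection", "union"] = "intersection",
) -> tuple[float, float]:
    """Correlation of two samples over their shared detected proteins.

    ``detection="intersection"`` (default) uses proteins detected in
    both samples; ``"union"`` keeps proteins detected in either, with
    zeros for the missing side. Returns ``(correlation, p_value)``.
    """
    det = nsaf.detected_mask
    if detection == "intersection":
        mask = det[sample_a] & det[sample_b]
    else:
        mask = det[sample_a] | det[sample_b]
    if int(mask.sum()) < 3:
        raise ValueError("fewer than 3 jointly detected proteins; correlation undefined")
    x = nsaf.values.loc[mask, sample_a]
    y = nsaf.values.loc[mask, sample_b]
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def cluster_samples(
    nsaf: NSAFMatrix,
    annotation: AnnotationSet | None = None,
) -> tuple[np.ndarray, str, list[str]]:
    """Average-linkage Euclidean clustering of samples.

    Optionally restricts to membrane-annotated proteins first. Returns
    ``(linkage_matrix, newick, leaf_order)``; leaf order is the
    deterministic scipy ordering (ties broken by input order).
    """
    values = nsaf.values
    if annotation is not None:
        values, _ = filter_by_annotation(values, annotation, symbols=nsaf.gene_symbols)
    mat = values.T.to_numpy()
    if mat.shape[0] < 2:
        raise ValueError("need at least two samples to cluster")
    link = hierarchy.linkage(pdist(mat, metric="euclidean"), method="average")
    tree = hierarchy.to_tree(link)
    names = list(values.columns)

    def _newick(node) -> str:
        if node.is_leaf():
            return names[node.id]
        left, right = node.get_left(), node.get_right()
        ld = node.dist - left.dist
        rd = node.dist - right.dist
        return f"({_newick(left)}:{ld:.6g},{_newick(right)}:{rd:.6g})"

    newick = _newick(tree) + ";"
    order = [names[i] for i in hierarchy.leaves_list(link)]
    return link, newick, order


def differential_abundance(
    nsaf: NSAFMatrix,
    group_a: str,
    group_b: str,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
    test: Literal["welch", "mannwhitney"] = "welch",
) -> pd.DataFrame:
    """Fold-change + FDR screen of group *a* (tumor) vs group *b* (normal).

    Fold change is the ratio of group means after adding a pseudo-count
    of half the smallest nonzero NSAF in the dataset, which keeps
    tumor-only proteins finite (and large). The test runs on
    log10(NSAF + pseudo); Welch's t by default, Mann-Whitney U as an
    alternative. P-values are Benjamini-Hochberg adjusted; the ``pass``
    column flags proteins with fold change >= ``fc_threshold`` and
    adjusted p < ``fdr_threshold``.
    """
    groups = nsaf.sample_groups
    a_samps = [s for s in nsaf.samples if groups[s] == group_a]
    b_samps = [s for s in nsaf.samples if groups[s] == group_b]
    if not a_samps or not b_samps:
        raise ValueError(f"group {group_a!r} or {group_b!r} absent from the matrix")
    if len(a_samps) < 2 or len(b_samps) < 2:
        raise ValueError("need >=2 samples per group for the test")
    vals = nsaf.values
    nonzero = vals.to_numpy()[vals.to_numpy() > 0]
    pseudo = 0.5 * nonzero.min() if nonzero.size else 1e-12
    a = vals[a_samps].to_numpy() + pseudo
    b = vals[b_samps].to_numpy() + pseudo
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    fc = mean_a / mean_b
    la, lb = np.log10(a), np.log10(b)
    if test == "welch":
        tstat, p = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    elif test == "mannwhitney":
        res = stats.mannwhitneyu(la, lb, axis=1, alternative="two-sided")
        p = res.pvalue
    else:
        raise ValueError(f"unknown test {test!r}")
    p = np.where(np.isnan(p), 1.0, p)
    _, padj, _, _ = multipletests(p, method="fdr_bh")
    out = pd.DataFrame(
        {
            "gene_symbol": nsaf.gene_symbols.values,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fold_change": fc,
            "log2_fc": np.log2(fc),
            "p_raw": p,
            "p_adj": padj,
        },
        index=vals.index,
    )
    out["pass"] = (out["fold_change"] >= fc_threshold) & (out["p_adj"] < fdr_threshold)
    out.attrs["test"] = test
    out.attrs["pseudo_count"] = float(pseudo)
    return out
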