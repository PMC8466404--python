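"""Normal-tissue benchmarking of candidate tumor antigens.

Candidate surface proteins are only useful immunotherapy targets if
they are scarce in healthy organs. This module works on a compendium of
per-tissue median log2 RNA and protein abundances (~32 tissue types):
it converts the log2 medians back to the absolute scale, summarizes
each candidate's normal expression, compares candidates to clinically
tolerated CAR-T reference antigens (MSLN, CEACAM5, ERBB2), computes a
per-tissue specificity score (>2.5 tissue-enriched, >4 tissue-specific),
and correlates the RNA and protein layers per feature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TissueCompendium",
    "reverse_log2",
    "summarize_normal_expression",
    "tissue_specificity_score",
    "rna_protein_correlation",
    "TS_ENRICHED_THRESHOLD",
    "TS_SPECIFIC_THRESHOLD",
]

TS_ENRICHED_THRESHOLD = 2.5
TS_SPECIFIC_THRESHOLD = 4.0


@dataclass
class TissueCompendium:
    """Paired feature-by-tissue log2 abundance layers.

    ``rna_log2`` and ``protein_log2`` share the tissue axis; protein
    rows may be missing (NaN) for features without proteomic coverage.
    ``scale`` records whether values are log2 (the input convention) or
    absolute after :func:`reverse_log2`.
    """

    rna_log2: pd.DataFrame
    protein_log2: pd.DataFrame
    provenance: str = ""
    scale: str = "log2"

    def __post_init__(self) -> None:
        if list(self.rna_log2.columns) != list(self.protein_log2.columns):
            raise ValueError("RNA and protein layers must share the tissue axis")
        if self.rna_log2.columns.has_duplicates:
            raise ValueError("tissue labels must be unique")

    @property
    def tissues(self) -> list[str]:
        return list(self.rna_log2.columns)

    def layer(self, which: Literal["rna", "protein"]) -> pd.DataFrame:
        if which == "rna":
            return self.rna_log2
        if which == "protein":
            return self.protein_log2
        raise ValueError(f"unknown layer {which!r}")


def reverse_log2(comp: TissueCompendium) -> TissueCompendium:
    """Map every log2 value v to 2**v (missing stays missing)."""
    if comp.scale != "log2":
        raise ValueError("compendium is not on the log2 scale")
    return TissueCompendium(
        rna_log2=np.power(2.0, comp.rna_log2),
        protein_log2=np.power(2.0, comp.protein_log2),
        provenance=comp.provenance,
        scale="absolute",
    )


def summarize_normal_expression(
    comp: TissueCompendium,
    candidates: Sequence[str],
    references: Sequence[str] = ("MSLN", "CEACAM5", "ERBB2"),
    statistic: Literal["median", "mean"] = "median",
) -> pd.DataFrame:
    """Cross-tissue normal-expression summary and reference comparison.

    Per candidate and per layer: the median (or mean) absolute-scale
    abundance over tissues, an ascending rank within the candidate set
    (rank 1 = least expressed, feeding the composite ranking), and a
    below-reference flag per reference antigen. Candidates without any
    protein value are flagged and excluded from the protein ranking.
    """
    abs_comp = reverse_log2(comp) if comp.scale == "log2" else comp
    missing_refs = [r for r in references if r not in abs_comp.rna_log2.index]
    if missing_refs:
        raise ValueError(f"reference feature(s) absent from compendium: {missing_refs}")
    agg = "median" if statistic == "median" else "mean"
    out = pd.DataFrame(index=pd.Index(candidates, name="feature"))
    for layer in ("rna", "protein"):
        vals = abs_comp.layer(layer)
        summary = vals.reindex(out.index).agg(agg, axis=1)
        out[f"normal_{layer}"] = summary
        out[f"rank_normal_{layer}"] = summary.rank(method="min", ascending=True)
        for ref in references:
            ref_val = vals.loc[ref].agg(agg)
            out[f"below_{ref}_{layer}"] = summary < ref_val
        out.attrs[f"frac_below_{layer}"] = {
            ref: float(out[f"below_{ref}_{layer}"].mean()) for ref in references
        }
    out.attrs["statistic"] = agg
    return out


def tissue_specificity_score(
    comp: TissueCompendium,
    feature: str,
    layer: Literal["rna", "protein"] = "rna",
) -> pd.Series:
    """Leave-one-tissue-out z-score of a feature across tissues.

    For each tissue t: (x_t - mean(x_others)) / sd(x_others) on the
    log2 layer. A degenerate case where the other tissues are constant
    and x_t equals them scores 0; constant-others with a different x_t
    scores +/-inf (tissue-specific by construction).
    """
    if comp.scale != "log2":
        raise ValueError("TS scores are defined on the log2 layer")
    row = comp.layer(layer).loc[feature].dropna()
    if len(row) < 3:
        raise ValueError("need values in >=3 tissues")
    x = row.to_numpy(dtype=float)
    n = len(x)
    scores = np.empty(n)
    for i in range(n):
        others = np.delete(x, i)
        sd = others.std(ddof=1)
        diff = x[i] - others.mean()
        if sd == 0:
            scores[i] = 0.0 if diff == 0 else np.copysign(np.inf, diff)
        else:
            scores[i] = diff / sd
    out = pd.Series(scores, index=row.index, name=f"ts_score_{layer}")
    out.attrs["formula"] = "(x_t - mean(x_not_t)) / sd(x_not_t) on log2 values"
    return out


def classify_ts(score: float) -> str:
    """Categorize a TS score: none / tissue-enriched (>2.5) / tissue-specific (>4)."""
    if score > TS_SPECIFIC_THRESHOLD:
        return "tissue-specific"
    if score > TS_ENRICHED_THRESHOLD:
        return "tissue-enriched"
    return "none"


def rna_protein_correlation(comp: TissueCompendium, feature: str) -> tuple[float, float]:
    """Spearman correlation of a feature's RNA and protein layers across tissues."""
    rna = comp.rna_log2.loc[feature]
    prot = comp.protein_log2.loc[feature]
    paired = pd.concat([rna, prot], axis=1).dropna()
    if len(paired) < 3:
        raise ValueError("need >=3 tissues with both layers")
    rho, p = stats.spearmanr(paired.iloc[:, 0], paired.iloc[:, 1])
    return float(rho), float(p)
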