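"""Equal-weight composite ranking of candidate surface antigens.

Candidates are scored on four axes — tumor protein abundance, tumor RNA
abundance, normal-tissue protein abundance, and normal-tissue RNA
abundance. Tumor axes are ranked descending (rank 1 = most expressed in
the tumor); normal axes ascending (rank 1 = least expressed in normal
tissue, i.e. safest). The four integer ranks are summed with equal
weights and the sum is re-ranked ascending to give the composite rank.

Ties receive the minimum ("competition") rank on every axis and on the
composite, so tied candidates share a rank and the next distinct value
skips accordingly.
"""

from __future__ import annotations

from typing import Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "rank_axis",
    "composite_rank",
    "build_candidate_table",
    "AXIS_COLUMNS",
    "RANK_COLUMN_ALIASES",
]

#: canonical component-rank column names, in output order
AXIS_COLUMNS = (
    "Proteomic RMS",
    "Transcriptomic RMS",
    "Proteomic Normal",
    "Transcriptomic Normal",
)

#: accepted aliases when reading published-style tables ("Surfaceomic RMS"
#: is the header dialect used for the subtype tables)
RANK_COLUMN_ALIASES: Mapping[str, str] = {"Surfaceomic RMS": "Proteomic RMS"}


def rank_axis(
    values: pd.Series,
    direction: Literal["descending", "ascending"],
    tie_policy: str = "min",
) -> pd.Series:
    """Integer competition ranks for one prioritization axis.

    Parameters
    ----------
    values
        Per-candidate axis values, indexed by candidate identifier.
    direction
        ``"descending"`` ranks the largest value 1 (tumor axes);
        ``"ascending"`` ranks the smallest value 1 (normal axes).
    tie_policy
        Pandas rank method; only ``"min"`` reproduces the published
        tables and is the default.

    Raises
    ------
    ValueError
        If any candidate has a missing value.
    """
    if direction not in ("descending", "ascending"):
        raise ValueError(f"direction must be descending|ascending, got {direction!r}")
    missing = values.index[values.isna()]
    if len(missing):
        raise ValueError(f"missing axis value for candidate(s): {list(missing)}")
    ranks = values.rank(method=tie_policy, ascending=(direction == "ascending"))
    return ranks.astype(int)


def composite_rank(axis_ranks: pd.DataFrame) -> pd.DataFrame:
    """Sum four component rank columns and assign composite ranks.

    ``axis_ranks`` must contain the four columns of :data:`AXIS_COLUMNS`
    (the "Surfaceomic RMS" alias is accepted) holding integer ranks.
    Returns a copy with ``Composite Sum`` and ``Composite Rank``
    appended, sorted by composite rank (stable with respect to input
    order within ties).
    """
    table = axis_ranks.rename(columns=dict(RANK_COLUMN_ALIASES)).copy()
    for col in AXIS_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"missing component rank column {col!r}")
        arr = np.asarray(table[col], dtype=float)
        if not (np.all(np.isfinite(arr)) and np.all(arr == np.floor(arr)) and np.all(arr >= 1)):
            raise ValueError(f"component ranks in {col!r} are not positive integers")
        table[col] = arr.astype(int)
    sums = table[list(AXIS_COLUMNS)].sum(axis=1)
    table["Composite Sum"] = sums.astype(int)
    table["Composite Rank"] = sums.rank(method="min").astype(int)
    return table.sort_values("Composite Rank", kind="stable")


def build_candidate_table(
    tumor_protein: pd.Series,
    tumor_rna: pd.Series,
    normal_protein: pd.Series,
    normal_rna: pd.Series,
    metadata: pd.DataFrame | None = None,
    allow_partial: bool = False,
) -> pd.DataFrame:
    """End-to-end candidate table from the four per-candidate axis values.

    The candidate set is the intersection of the four indices; candidates
    missing from any axis are dropped (the published tables contain only
    fully-ranked candidates) unless ``allow_partial`` is set, in which
    case absent values receive the worst rank on that axis via a +inf /
    -inf sentinel.

    ``metadata`` may carry display columns (``Entry``, ``Gene Names``)
    indexed like the axes; a ``Gene`` column is synthesized from the
    index if absent.
    """
    axes = {
        "Proteomic RMS": (tumor_protein, "descending"),
        "Transcriptomic RMS": (tumor_rna, "descending"),
        "Proteomic Normal": (normal_protein, "ascending"),
        "Transcriptomic Normal": (normal_rna, "ascending"),
    }
    if allow_partial:
        candidates = tumor_protein.index
        for s, _ in axes.values():
            candidates = candidates.union(s.index)
    else:
        candidates = tumor_protein.index
        for s, _ in axes.values():
            candidates = candidates.intersection(s.index)
    candidates = pd.Index(sorted(candidates))
    if len(candidates) == 0:
        cols = ["Gene", *AXIS_COLUMNS, "Composite Sum", "Composite Rank"]
        return pd.DataFrame(columns=cols)

    ranks = pd.DataFrame(index=candidates)
    for name, (series, direction) in axes.items():
        vals = series.reindex(candidates)
        if allow_partial:
            # worst-possible sentinel so absent candidates sink on this axis
            sentinel = -np.inf if direction == "descending" else np.inf
            vals = vals.fillna(sentinel)
        ranks[name] = rank_axis(vals, direction)
    out = composite_rank(ranks)
    out.insert(0, "Gene", out.index)
    if metadata is not None:
        for col in reversed([c for c in ("Entry", "Gene Names") if c in metadata.columns]):
            out.insert(0, col, metadata[col].reindex(out.index))
    return out
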