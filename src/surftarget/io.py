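"""Plain-TSV readers and writers for the pipeline's tabular formats."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from .cytotoxicity import CalceinTraceSet
from .deconvolution import SignatureMatrix
from .normal_tissue import TissueCompendium
from .proteomics import SpectralCountMatrix
from .transcriptomics import ExpressionMatrix

__all__ = [
    "read_groups",
    "write_groups",
    "read_spectral_counts",
    "write_spectral_counts",
    "read_expression",
    "write_expression",
    "read_compendium",
    "write_compendium",
    "read_signature",
    "write_signature",
    "read_traces",
    "write_traces",
]


def read_groups(path) -> dict[str, str]:
    """Two-column TSV ``sample<TAB>group`` -> mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_groups(groups: Mapping[str, str], path) -> None:
    pd.DataFrame({"sample": list(groups), "group": [groups[s] for s in groups]}).to_csv(
        path, sep="\t", index=False
    )


def read_spectral_counts(path, groups_path) -> SpectralCountMatrix:
    """TSV layout: protein_id, gene_symbol, length, <sample columns>."""
    frame = pd.read_csv(path, sep="\t")
    return SpectralCountMatrix.from_frame(frame, read_groups(groups_path))


def write_spectral_counts(sc: SpectralCountMatrix, path, groups_path=None) -> None:
    sc.to_frame().to_csv(path, sep="\t", index=False)
    if groups_path is not None:
        write_groups(sc.sample_groups, groups_path)


def read_expression(path, groups_path=None, unit: str = "counts") -> ExpressionMatrix:
    """TSV layout: gene_id, [length_bp,] <sample columns>."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    lengths = None
    if "length_bp" in frame.columns:
        lengths = frame.pop("length_bp").astype(int)
    groups = read_groups(groups_path) if groups_path else {}
    return ExpressionMatrix(values=frame, unit=unit, feature_lengths=lengths, sample_groups=groups)


def write_expression(expr: ExpressionMatrix, path) -> None:
    out = expr.values.copy()
    if expr.feature_lengths is not None:
        out.insert(0, "length_bp", expr.feature_lengths.astype(int))
    out.rename_axis("gene_id").to_csv(path, sep="\t")


def read_compendium(path) -> TissueCompendium:
    """Long-wide TSV: feature, layer(rna|protein), <tissue columns>."""
    df = pd.read_csv(path, sep="\t")
    rna = df[df["layer"] == "rna"].drop(columns="layer").set_index("feature")
    prot = df[df["layer"] == "protein"].drop(columns="layer").set_index("feature")
    return TissueCompendium(rna_log2=rna, protein_log2=prot.reindex(rna.index))


def write_compendium(comp: TissueCompendium, path) -> None:
    rna = comp.rna_log2.copy()
    rna.insert(0, "layer", "rna")
    prot = comp.protein_log2.copy()
    prot.insert(0, "layer", "protein")
    pd.concat([rna, prot]).rename_axis("feature").to_csv(path, sep="\t")


def read_signature(path) -> SignatureMatrix:
    return SignatureMatrix(values=pd.read_csv(path, sep="\t", index_col=0))


def write_signature(sig: SignatureMatrix, path) -> None:
    sig.values.rename_axis("gene").to_csv(path, sep="\t")


def read_traces(path) -> CalceinTraceSet:
    return CalceinTraceSet(data=pd.read_csv(path, sep="\t"))


def write_traces(traces: CalceinTraceSet, path) -> None:
    traces.data.to_csv(path, sep="\t", index=False)


def write_annotation_gmt(name: str, members, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join([name, "synthetic membrane set", *sorted(members)]) + "\n")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
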