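"""Synthetic data generators for every pipeline input.

Each generator emulates the statistical structure its analysis stage
assumes, with the ground truth attached so forward simulation followed
by the corresponding inverse analysis is the module's main test
surface:

* spectral counts — per-sample multinomial sampling with protein weight
  proportional to (true abundance x length), so length bias is real and
  NSAF is the correct correction; per-sample depths differ.
* RNA-seq counts — negative binomial (Var = mu + alpha mu^2) around
  group means with planted log2 fold changes in the tumor groups; the
  default cohort shape is 66 fusion-negative + 35 fusion-positive
  tumors + 5 normal muscles.
* normal-tissue compendium — paired RNA/protein log2 medians across 32
  tissues with a configurable RNA-protein rank correlation (Gaussian
  copula) and optional designated tissue-specific features.
* immune signature and mixtures — cell-type profiles with exclusive
  markers, equal column sums; mixtures are signature x fractions plus
  an "Other" background profile and truncated-Gaussian noise.
* calcein traces — exponential-decay killing in treated wells,
  triplicate wells, per-donor kill-rate variability.

A single integer seed drives independent sub-streams per output, so
each generated table is reproducible on its own regardless of which
other generators run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cytotoxicity import CalceinTraceSet
from .deconvolution import DEFAULT_CELL_TYPES, SignatureMatrix
from .normal_tissue import TissueCompendium
from .proteomics import AnnotationSet, SpectralCountMatrix
from .transcriptomics import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "simulate_spectral_counts",
    "simulate_rnaseq_counts",
    "simulate_tissue_compendium",
    "simulate_signature",
    "simulate_mixtures",
    "simulate_calcein_traces",
    "membrane_annotation",
]

# stable sub-stream ids so outputs do not depend on generation order
_STREAMS = {
    "universe": 0,
    "spectral": 1,
    "rnaseq": 2,
    "tissue": 3,
    "signature": 4,
    "mixtures": 5,
    "calcein": 6,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],)))


@dataclass
class SimulationConfig:
    """Parameters shared by all generators; defaults mirror the study design.

    ``group_sizes`` is the RNA-seq cohort (66 fusion-negative, 35
    fusion-positive, 5 normal muscle); ``cell_line_groups`` the
    proteomic one (3 fusion-negative + 2 fusion-positive RMS lines, 2
    normal skeletal muscle lines). ``planted_fc`` maps a gene symbol to
    its true log2 fold change in the tumor groups (or to a per-group
    mapping); it drives both the spectral-count and RNA-seq layers.
    ``planted_normal_low`` lists genes forced to near-zero normal-tissue
    abundance, emulating a tumor-restricted antigen.
    """

    seed: int = 0
    n_proteins: int = 200
    n_genes: int = 400
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"fusion_negative": 66, "fusion_positive": 35, "normal": 5}
    )
    cell_line_groups: Mapping[str, int] = field(
        default_factory=lambda: {"fusion_negative": 3, "fusion_positive": 2, "normal": 2}
    )
    control_group: str = "normal"
    frac_membrane: float = 0.3
    planted_fc: Mapping[str, float | Mapping[str, float]] = field(default_factory=dict)
    base_boost: Mapping[str, float] = field(default_factory=dict)
    planted_normal_low: Sequence[str] = field(default_factory=tuple)
    nb_dispersion: float = 0.05
    noise_sd: float = 0.01
    # spectral-count layer
    mean_depth: int = 50_000
    depth_log_sd: float = 0.3
    length_median: float = 400.0
    length_log_sd: float = 0.5
    # normal-tissue layer
    n_tissues: int = 32
    rna_protein_rho: float = 0.8
    ts_features: Mapping[str, str] = field(default_factory=dict)
    # deconvolution layer
    signature_celltypes: Sequence[str] = DEFAULT_CELL_TYPES
    n_signature_genes: int = 500
    # cytotoxicity layer
    calcein_donors: int = 10
    calcein_ratios: Sequence[str] = ("1:10", "1:20")
    calcein_conditions: Sequence[str] = ("control", "treated")
    calcein_kill_rates: Mapping[str, float] = field(
        default_factory=lambda: {"WT": 0.0005, "KO": 0.002}
    )
    calcein_donor_log_sd: float = 0.15
    calcein_noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.n_proteins < 2:
            raise ValueError("n_proteins must be >= 2")
        if self.n_proteins > self.n_genes:
            raise ValueError("n_proteins cannot exceed n_genes (proteins map onto the gene universe)")
        if not self.group_sizes:
            raise ValueError("group_sizes must be non-empty")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if not 0 <= self.frac_membrane <= 1:
            raise ValueError("frac_membrane must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        tumor_groups = set(self.group_sizes) - {self.control_group}
        for feat, fc in self.planted_fc.items():
            if isinstance(fc, Mapping):
                unknown = set(fc) - tumor_groups
                if unknown:
                    raise ValueError(f"planted_fc[{feat!r}] names unknown group(s): {sorted(unknown)}")
        if "control" not in self.calcein_conditions:
            raise ValueError("calcein_conditions must include a 'control' (tumor cells only)")

    # -- shared gene/protein universe ------------------------------------
    def gene_symbols(self) -> list[str]:
        return [f"GENE{i + 1:04d}" for i in range(self.n_genes)]

    def membrane_genes(self) -> list[str]:
        """Deterministic membrane subset of the gene universe.

        Planted candidates are always membrane-annotated (they model
        surface antigens); the remainder is drawn to hit frac_membrane.
        """
        rng = _rng(self.seed, "universe")
        genes = self.gene_symbols()
        planted = [g for g in self.planted_fc if g in set(genes)]
        n_target = int(round(self.frac_membrane * self.n_genes))
        pool = [g for g in genes if g not in set(planted)]
        n_extra = max(0, n_target - len(planted))
        extra = list(rng.choice(pool, size=min(n_extra, len(pool)), replace=False))
        return sorted(set(planted) | set(extra))

    def _planted_lfc(self, feature: str, group: str) -> float:
        fc = self.planted_fc.get(feature)
        if fc is None or group == self.control_group:
            return 0.0
        if isinstance(fc, Mapping):
            return float(fc.get(group, 0.0))
        return float(fc)


def membrane_annotation(config: SimulationConfig) -> AnnotationSet:
    """The simulated plasma-membrane gene set (emulates GO:0005886)."""
    return AnnotationSet(name="GO:0005886 plasma membrane", members=frozenset(config.membrane_genes()))


def _sample_names(groups: Mapping[str, int], prefix: str) -> tuple[list[str], dict[str, str]]:
    names, labels = [], {}
    for g in groups:
        for i in range(groups[g]):
            name = f"{prefix}_{g}_{i + 1}"
            names.append(name)
            labels[name] = g
    return names, labels


def simulate_spectral_counts(config: SimulationConfig) -> SpectralCountMatrix:
    """Multinomial spectral counts with real length bias.

    Protein i in sample s receives counts with probability proportional
    to (true abundance of i in s's group) x (length of i); per-sample
    depths are lognormal around ``mean_depth`` so raw total spectral
    counts differ between samples. Ground truth (lengths, true
    abundances per group, membrane flags) is attached as
    ``result.ground_truth``.
    """
    rng = _rng(config.seed, "spectral")
    n = config.n_proteins
    genes = config.gene_symbols()[:n]
    protein_ids = [f"PROT{i + 1:04d}" for i in range(n)]
    lengths = np.maximum(
        np.round(rng.lognormal(np.log(config.length_median), config.length_log_sd, size=n)), 50
    ).astype(int)
    base = rng.lognormal(0.0, 1.0, size=n)
    for feat, boost in config.base_boost.items():
        if feat in genes:
            base[genes.index(feat)] *= float(boost)
    membrane = set(config.membrane_genes())
    samples, labels = _sample_names(config.cell_line_groups, "cl")
    counts = np.zeros((n, len(samples)), dtype=int)
    truth_abund = {}
    for g in config.cell_line_groups:
        lfc = np.array([config._planted_lfc(genes[i], g) for i in range(n)])
        truth_abund[g] = base * 2.0**lfc
    for j, s in enumerate(samples):
        abund = truth_abund[labels[s]]
        weights = abund * lengths
        probs = weights / weights.sum()
        depth = max(1, int(round(rng.lognormal(np.log(config.mean_depth), config.depth_log_sd))))
        counts[:, j] = rng.multinomial(depth, probs)
    sc = SpectralCountMatrix(
        counts=pd.DataFrame(counts, index=protein_ids, columns=samples),
        lengths=pd.Series(lengths, index=protein_ids),
        gene_symbols=pd.Series(genes, index=protein_ids),
        sample_groups=labels,
    )
    truth = pd.DataFrame(
        {"gene_symbol": genes, "length": lengths, "is_membrane": [g in membrane for g in genes]},
        index=protein_ids,
    )
    for g, ab in truth_abund.items():
        truth[f"abundance_{g}"] = ab
    sc.ground_truth = truth
    return sc


def simulate_rnaseq_counts(config: SimulationConfig) -> ExpressionMatrix:
    """Negative-binomial gene counts with planted tumor fold changes.

    Counts are gamma-Poisson with Var = mu + alpha mu^2 (single alpha =
    ``nb_dispersion``); group means are baseline x 2^planted_lfc, times
    a lognormal per-sample library factor. Gene lengths (bp) are
    attached so RPKM is computable. Ground truth baseline means and
    per-group true means are attached as ``result.ground_truth``.
    """
    rng = _rng(config.seed, "rnaseq")
    genes = config.gene_symbols()
    n = len(genes)
    lengths_bp = np.maximum(
        np.round(rng.lognormal(np.log(2000.0), 0.6, size=n)), 200
    ).astype(int)
    baseline = rng.lognormal(np.log(100.0), 1.2, size=n)
    for feat, boost in config.base_boost.items():
        if feat in genes:
            baseline[genes.index(feat)] *= float(boost)
    samples, labels = _sample_names(config.group_sizes, "s")
    lib = rng.lognormal(0.0, 0.2, size=len(samples))
    counts = np.zeros((n, len(samples)), dtype=int)
    group_means = {}
    for g in config.group_sizes:
        lfc = np.array([config._planted_lfc(genes[i], g) for i in range(n)])
        group_means[g] = baseline * 2.0**lfc
    alpha = config.nb_dispersion
    for j, s in enumerate(samples):
        mu = group_means[labels[s]] * lib[j]
        if alpha < 1e-12:
            counts[:, j] = rng.poisson(mu)
        else:
            lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
            counts[:, j] = rng.poisson(lam)
    expr = ExpressionMatrix(
        values=pd.DataFrame(counts, index=genes, columns=samples),
        unit="counts",
        feature_lengths=pd.Series(lengths_bp, index=genes),
        sample_groups=labels,
    )
    truth = pd.DataFrame({"baseline_mean": baseline, "length_bp": lengths_bp}, index=genes)
    for g, mu in group_means.items():
        truth[f"mean_{g}"] = mu
    expr.ground_truth = truth
    return expr


def simulate_tissue_compendium(config: SimulationConfig) -> TissueCompendium:
    """Paired RNA/protein log2 medians across normal tissues.

    A Gaussian copula couples the two layers at the Pearson level
    2*sin(pi*rho_s/6) so the Spearman correlation targets
    ``rna_protein_rho``. Features named in ``planted_normal_low`` sit
    near the floor of both layers in every tissue; ``ts_features``
    (feature -> tissue) get a one-tissue boost that makes them
    tissue-specific. Reference CAR-T antigens MSLN, CEACAM5 and ERBB2
    are appended with low/intermediate/high normal abundance.
    """
    if config.n_tissues < 2:
        raise ValueError("need >= 2 tissues")
    rng = _rng(config.seed, "tissue")
    tissues = [f"tissue{i + 1:02d}" for i in range(config.n_tissues)]
    features = config.gene_symbols() + ["MSLN", "CEACAM5", "ERBB2"]
    n, t = len(features), config.n_tissues
    rho_s = float(np.clip(config.rna_protein_rho, -1.0, 1.0))
    r = 2.0 * np.sin(np.pi * rho_s / 6.0)
    mu_f = rng.normal(3.0, 1.5, size=n)
    ref_mu = {"MSLN": 1.0, "CEACAM5": 2.5, "ERBB2": 4.5}
    for name, m in ref_mu.items():
        mu_f[features.index(name)] = m
    z1 = rng.normal(size=(n, t))
    z2 = r * z1 + np.sqrt(max(0.0, 1.0 - r * r)) * rng.normal(size=(n, t))
    sd = 1.0
    rna = mu_f[:, None] + sd * z1
    prot = mu_f[:, None] + sd * z2
    rna_df = pd.DataFrame(rna, index=features, columns=tissues)
    prot_df = pd.DataFrame(prot, index=features, columns=tissues)
    low_floor = -6.0
    for feat in config.planted_normal_low:
        if feat in rna_df.index:
            rna_df.loc[feat] = low_floor + 0.1 * rng.normal(size=t)
            prot_df.loc[feat] = low_floor + 0.1 * rng.normal(size=t)
    for feat, tissue in config.ts_features.items():
        if feat in rna_df.index and tissue in tissues:
            rna_df.loc[feat, tissue] += 8.0
            prot_df.loc[feat, tissue] += 8.0
    return TissueCompendium(rna_log2=rna_df, protein_log2=prot_df, provenance="synthetic", scale="log2")


def simulate_signature(config: SimulationConfig) -> tuple[SignatureMatrix, pd.Series]:
    """Immune-cell signature with exclusive markers, plus an Other profile.

    Each cell type receives a block of exclusive high-expression marker
    genes over a shared lognormal background, and every column is
    scaled to the same total. Mirroring how real deconvolution
    signatures pick genes silent in tumor cells, the non-immune "Other"
    background lives on a dedicated block of genes on which every
    immune profile is zero (and vice versa); with equal column sums
    this makes NNLS deconvolution of the forward mixtures recover the
    true fractions exactly in the noise-free case. The second return
    value is the Other profile on the combined gene index.
    """
    rng = _rng(config.seed, "signature")
    celltypes = list(config.signature_celltypes)
    n_genes = config.n_signature_genes
    n_bg = max(10, n_genes // 10)
    genes = [f"SIG{i + 1:04d}" for i in range(n_genes)]
    bg_genes = [f"OTH{i + 1:04d}" for i in range(n_bg)]
    k = len(celltypes)
    base = rng.lognormal(0.0, 0.5, size=(n_genes, k))
    markers_per_type = max(3, n_genes // (4 * k))
    for c in range(k):
        lo = c * markers_per_type
        base[lo : lo + markers_per_type, c] *= 50.0
    target = float(n_genes)
    base = base / base.sum(axis=0) * target
    base = np.vstack([base, np.zeros((n_bg, k))])
    other = rng.lognormal(0.0, 0.3, size=n_bg)
    other = np.concatenate([np.zeros(n_genes), other / other.sum() * target])
    all_genes = genes + bg_genes
    sig = SignatureMatrix(values=pd.DataFrame(base, index=all_genes, columns=celltypes))
    return sig, pd.Series(other, index=all_genes, name="Other")


def simulate_mixtures(
    signature: SignatureMatrix,
    fractions: pd.DataFrame,
    noise_sd: float = 0.0,
    seed: int = 0,
    other_profile: pd.Series | None = None,
) -> ExpressionMatrix:
    """Forward mixtures: signature x fractions^T (+ Other background + noise).

    ``fractions`` is sample x cell-type with entries in [0, 1] and row
    sums <= 1; the remainder 1 - sum(row) is attributed to the Other
    profile when one is given. Gaussian noise (sd = ``noise_sd`` x mean
    signal) is truncated at zero.
    """
    F = fractions.to_numpy(dtype=float)
    if (F < 0).any():
        raise ValueError("fractions must be non-negative")
    if (F > 1).any() or (F.sum(axis=1) > 1 + 1e-9).any():
        raise ValueError("fractions must lie in [0,1] with row sums <= 1")
    missing = [c for c in fractions.columns if c not in signature.values.columns]
    if missing:
        raise ValueError(f"fraction columns not in signature: {missing}")
    S = signature.values[list(fractions.columns)].to_numpy(dtype=float)
    M = S @ F.T
    if other_profile is not None:
        other = other_profile.reindex(signature.values.index).to_numpy(dtype=float)
        M = M + np.outer(other, 1.0 - F.sum(axis=1))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        M = np.maximum(0.0, M + rng.normal(0.0, noise_sd * M.mean(), size=M.shape))
    values = pd.DataFrame(M, index=signature.values.index, columns=list(fractions.index))
    return ExpressionMatrix(values=values, unit="linear")


def simulate_calcein_traces(config: SimulationConfig) -> CalceinTraceSet:
    """Per-well calcein fluorescence traces for the killing assay.

    Control wells hold a constant plateau; treated wells decay as
    v0 * exp(-k t) with the cell-line kill rate scaled per donor and
    per effector ratio (the denser 1:20 ratio kills ~1.5x faster).
    Triplicate wells per condition; multiplicative truncated-Gaussian
    measurement noise. True per-stratum kill rates are attached as
    ``result.ground_truth``.
    """
    rng = _rng(config.seed, "calcein")
    times = np.arange(0, 961, 10)
    v0 = 1000.0
    rows = []
    truth_rows = []
    ratio_scale = {r: 1.0 + 0.5 * i for i, r in enumerate(config.calcein_ratios)}
    for d in range(1, config.calcein_donors + 1):
        donor = f"donor{d:02d}"
        for line, k_base in config.calcein_kill_rates.items():
            donor_factor = rng.lognormal(0.0, config.calcein_donor_log_sd)
            for cond in config.calcein_conditions:
                ratios = config.calcein_ratios if cond != "control" else ("-",)
                for ratio in ratios:
                    k = 0.0 if cond == "control" else k_base * donor_factor * ratio_scale[ratio]
                    truth_rows.append(
                        {"donor": donor, "cell_line": line, "condition": cond, "ratio": ratio, "kill_rate": k}
                    )
                    for rep in range(1, 4):
                        well = f"{donor}_{line}_{cond}_{ratio}_r{rep}"
                        trace = v0 * np.exp(-k * times)
                        if config.calcein_noise_sd > 0:
                            trace = np.maximum(
                                0.0, trace * (1.0 + rng.normal(0.0, config.calcein_noise_sd, size=len(times)))
                            )
                        for t, val in zip(times, trace):
                            rows.append(
                                {
                                    "well_id": well,
                                    "donor": donor,
                                    "cell_line": line,
                                    "condition": cond,
                                    "ratio": ratio,
                                    "time_min": int(t),
                                    "fluorescence": float(val),
                                }
                            )
    traces = CalceinTraceSet(data=pd.DataFrame(rows))
    traces.ground_truth = pd.DataFrame(truth_rows)
    return traces
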