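"""Spectral-count processing: NSAF, filtering, repertoires, clustering, DE."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from surftarget.proteomics import (
    AnnotationSet,
    SpectralCountMatrix,
    cluster_samples,
    compute_nsaf,
    compute_tsc,
    differential_abundance,
    filter_by_annotation,
    repertoire_overlaps,
    replicate_correlation,
)
from surftarget.simulate import SimulationConfig, simulate_spectral_counts

from conftest import make_nsaf


class TestTSC:
    def test_column_sums(self, toy_counts):
        tsc = compute_tsc(toy_counts)
        assert tsc["s1"] == 20 and tsc["s2"] == 10

    def test_all_zero(self):
        sc = SpectralCountMatrix(
            counts=pd.DataFrame({"s1": [0, 0]}, index=["P1", "P2"]),
            lengths=pd.Series([100, 100], index=["P1", "P2"]),
            gene_symbols=pd.Series(["A", "B"], index=["P1", "P2"]),
            sample_groups={"s1": "g"},
        )
        assert (compute_tsc(sc) == 0).all()

    def test_matches_simulated_depth(self):
        cfg = SimulationConfig(seed=5, n_proteins=30, n_genes=30, cell_line_groups={"a": 2}, control_group="x")
        sc = simulate_spectral_counts(cfg)
        # multinomial sampling conserves the per-sample depth exactly
        assert (compute_tsc(sc) > 0).all()


class TestNSAF:
    def test_hand_example(self, toy_counts):
        """SpC 10/L 100 vs SpC 10/L 300 -> 0.75 / 0.25."""
        nsaf = compute_nsaf(toy_counts)
        assert nsaf.values.loc["P1", "s1"] == pytest.approx(0.75, abs=1e-12)
        assert nsaf.values.loc["P2", "s1"] == pytest.approx(0.25, abs=1e-12)

    def test_equal_counts_equal_lengths_symmetric(self):
        sc = SpectralCountMatrix(
            counts=pd.DataFrame({"s": [7, 7]}, index=["P1", "P2"]),
            lengths=pd.Series([200, 200], index=["P1", "P2"]),
            gene_symbols=pd.Series(["A", "B"], index=["P1", "P2"]),
            sample_groups={"s": "g"},
        )
        assert (compute_nsaf(sc).values["s"] == 0.5).all()

    @settings(deadline=None, max_examples=25)
    @given(
        counts=st.lists(st.integers(0, 500), min_size=3, max_size=8),
        lengths=st.lists(st.integers(50, 3000), min_size=8, max_size=8),
    )
    def test_column_sums_one(self, counts, lengths):
        n = len(counts)
        sc = SpectralCountMatrix(
            counts=pd.DataFrame({"s": counts}, index=[f"P{i}" for i in range(n)]),
            lengths=pd.Series(lengths[:n], index=[f"P{i}" for i in range(n)]),
            gene_symbols=pd.Series([f"G{i}" for i in range(n)], index=[f"P{i}" for i in range(n)]),
            sample_groups={"s": "g"},
        )
        nsaf = compute_nsaf(sc)
        total = nsaf.values["s"].sum()
        if any(c > 0 for c in counts):
            assert total == pytest.approx(1.0, abs=1e-9)
        else:
            assert total == 0.0

    def test_scaling_invariance(self, toy_counts):
        doubled = SpectralCountMatrix(
            counts=toy_counts.counts * 2,
            lengths=toy_counts.lengths,
            gene_symbols=toy_counts.gene_symbols,
            sample_groups=dict(toy_counts.sample_groups),
        )
        pd.testing.assert_frame_equal(compute_nsaf(toy_counts).values, compute_nsaf(doubled).values)

    def test_zero_sample_warns_not_raises(self, caplog):
        sc = SpectralCountMatrix(
            counts=pd.DataFrame({"s1": [3, 1], "s2": [0, 0]}, index=["P1", "P2"]),
            lengths=pd.Series([100, 100], index=["P1", "P2"]),
            gene_symbols=pd.Series(["A", "B"], index=["P1", "P2"]),
            sample_groups={"s1": "g", "s2": "g"},
        )
        nsaf = compute_nsaf(sc)
        assert (nsaf.values["s2"] == 0).all()


class TestAnnotationFilter:
    def test_identity_and_empty_overlap(self):
        feats = ["A", "B", "C"]
        ann_all = AnnotationSet("all", frozenset(feats))
        kept, frac = filter_by_annotation(feats, ann_all)
        assert kept == feats and frac == 1.0
        ann_none = AnnotationSet("none", frozenset(["Z"]))
        kept, frac = filter_by_annotation(feats, ann_none)
        assert kept == [] and frac == 0.0

    def test_empty_annotation_rejected(self):
        with pytest.raises(ValueError):
            AnnotationSet("empty", frozenset())

    def test_intersection_composition(self):
        feats = ["A", "B", "C", "D"]
        ann1 = AnnotationSet("1", frozenset(["A", "B", "C"]))
        ann2 = AnnotationSet("2", frozenset(["B", "C", "D"]))
        both = AnnotationSet("12", ann1.members & ann2.members)
        via_both, _ = filter_by_annotation(feats, both)
        via_seq, _ = filter_by_annotation(filter_by_annotation(feats, ann1)[0], ann2)
        assert via_both == via_seq

    def test_simulated_membrane_fraction(self):
        cfg = SimulationConfig(seed=2, n_proteins=300, n_genes=300, frac_membrane=0.3, cell_line_groups={"a": 1}, control_group="x")
        sc = simulate_spectral_counts(cfg)
        from surftarget.simulate import membrane_annotation

        _, frac = filter_by_annotation(list(sc.gene_symbols), membrane_annotation(cfg))
        assert frac == pytest.approx(0.3, abs=0.05)


class TestRepertoires:
    def test_single_group_single_sample(self):
        vals = pd.DataFrame({"s1": [1.0, 0.0, 2.0]}, index=["A", "B", "C"])
        summ = repertoire_overlaps(make_nsaf(vals, {"s1": "g"}))
        assert summ.group_common["g"] == frozenset({"A", "C"})
        assert summ.group_exclusive["g"] == frozenset({"A", "C"})

    def test_identical_groups_no_exclusive(self):
        vals = pd.DataFrame({"s1": [1.0, 1.0], "s2": [2.0, 3.0]}, index=["A", "B"])
        summ = repertoire_overlaps(make_nsaf(vals, {"s1": "g1", "s2": "g2"}))
        assert summ.group_exclusive["g1"] == frozenset()
        assert summ.group_exclusive["g2"] == frozenset()

    def test_three_group_enumeration(self):
        # constructed detection sets: g1={A,B,C}, g2={B,C,D}, g3={C,D,E}
        proteins = ["A", "B", "C", "D", "E"]
        detected = {"g1": {"A", "B", "C"}, "g2": {"B", "C", "D"}, "g3": {"C", "D", "E"}}
        vals = pd.DataFrame(
            {g: [1.0 if p in detected[g] else 0.0 for p in proteins] for g in detected},
            index=proteins,
        )
        summ = repertoire_overlaps(make_nsaf(vals, {g: g for g in detected}))
        assert summ.intersection_counts[frozenset({"g1", "g2", "g3"})] == 1  # {C}
        assert summ.intersection_counts[frozenset({"g1", "g2"})] == 2  # {B,C}
        assert summ.group_exclusive["g1"] == frozenset({"A"})
        assert summ.group_exclusive["g3"] == frozenset({"E"})
        # inclusion-exclusion on the union of the three common sets
        union = len(detected["g1"] | detected["g2"] | detected["g3"])
        ie = (
            sum(summ.intersection_counts[frozenset({g})] for g in detected)
            - summ.intersection_counts[frozenset({"g1", "g2"})]
            - summ.intersection_counts[frozenset({"g1", "g3"})]
            - summ.intersection_counts[frozenset({"g2", "g3"})]
            + summ.intersection_counts[frozenset({"g1", "g2", "g3"})]
        )
        assert ie == union


class TestReplicateCorrelation:
    def test_self_correlation(self):
        vals = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]}, index=list("wxyz"))
        r, p = replicate_correlation(make_nsaf(vals, {"a": "g", "b": "g"}), "a", "b")
        assert r == pytest.approx(1.0)

    def test_anti_ordered_spearman(self):
        vals = pd.DataFrame({"a": [1.0, 2, 3], "b": [3.0, 2, 1]}, index=list("xyz"))
        r, _ = replicate_correlation(make_nsaf(vals, {"a": "g", "b": "g"}), "a", "b", method="spearman")
        assert r == pytest.approx(-1.0)

    def test_too_few_shared(self):
        vals = pd.DataFrame({"a": [1.0, 0, 0], "b": [1.0, 2, 0]}, index=list("xyz"))
        with pytest.raises(ValueError, match="fewer than 3"):
            replicate_correlation(make_nsaf(vals, {"a": "g", "b": "g"}), "a", "b")


class TestClustering:
    def _nsaf_1d(self, xs: dict[str, float]):
        vals = pd.DataFrame({s: [x, 1 - x] for s, x in xs.items()}, index=["P1", "P2"])
        return make_nsaf(vals, {s: "g" for s in xs})

    def test_identical_samples_merge_at_zero(self):
        link, _, _ = cluster_samples(self._nsaf_1d({"a": 0.3, "b": 0.3, "c": 0.9}))
        assert link[0, 2] == pytest.approx(0.0)

    def test_closest_pair_merges_first(self):
        link, newick, _ = cluster_samples(self._nsaf_1d({"a": 0.1, "b": 0.15, "c": 0.9}))
        assert {int(link[0, 0]), int(link[0, 1])} == {0, 1}
        assert "(a:" in newick or "a:" in newick

    def test_average_linkage_heights_match_hand_upgma(self):
        # 1D embedding: pairwise distance = sqrt(2) * |x_i - x_j|
        nsaf = self._nsaf_1d({"A": 0.1, "B": 0.2, "C": 0.5, "D": 0.9})
        link, _, _ = cluster_samples(nsaf)
        root2 = np.sqrt(2.0)
        heights = sorted(link[:, 2])
        # UPGMA by hand: AB at 0.1, (AB)C at mean(0.4,0.3)=0.35, ((AB)C)D at mean(0.8,0.7,0.4)
        assert heights[0] == pytest.approx(0.1 * root2)
        assert heights[1] == pytest.approx(0.35 * root2)
        assert heights[2] == pytest.approx((0.8 + 0.7 + 0.4) / 3 * root2)

    def test_permuted_samples_same_heights(self):
        xs = {"a": 0.1, "b": 0.25, "c": 0.6, "d": 0.8}
        link1, _, _ = cluster_samples(self._nsaf_1d(xs))
        perm = dict(reversed(list(xs.items())))
        link2, _, _ = cluster_samples(self._nsaf_1d(perm))
        assert np.allclose(sorted(link1[:, 2]), sorted(link2[:, 2]))


class TestDifferentialAbundance:
    def test_identical_groups_nothing_flagged(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0.5, 2.0, size=20)
        vals = pd.DataFrame(
            {f"s{i}": base * rng.uniform(0.95, 1.05, size=20) for i in range(6)},
            index=[f"P{i}" for i in range(20)],
        )
        groups = {f"s{i}": ("a" if i < 3 else "b") for i in range(6)}
        res = differential_abundance(make_nsaf(vals, groups), "a", "b")
        assert not res["pass"].any()

    def test_tumor_only_protein_finite_fc(self):
        vals = pd.DataFrame(
            {
                "t1": [0.5, 0.5, 0.6],
                "t2": [0.6, 0.4, 0.5],
                "n1": [0.0, 1.0, 1.1],
                "n2": [0.0, 1.1, 0.9],
            },
            index=["P1", "P2", "P3"],
        )
        groups = {"t1": "t", "t2": "t", "n1": "n", "n2": "n"}
        res = differential_abundance(make_nsaf(vals, groups), "t", "n")
        assert np.isfinite(res.loc["P1", "fold_change"])
        assert res.loc["P1", "fold_change"] > 2

    def test_planted_four_fold_recovered(self):
        cfg = SimulationConfig(
            seed=9,
            n_proteins=120,
            n_genes=120,
            cell_line_groups={"tumor": 3, "normal": 3},
            planted_fc={"GENE0001": 2.0, "GENE0002": 2.0},
            mean_depth=200_000,
            depth_log_sd=0.05,
        )
        sc = simulate_spectral_counts(cfg)
        res = differential_abundance(compute_nsaf(sc), "tumor", "normal")
        flagged = set(res.index[res["pass"]])
        planted_ids = set(res.index[res["gene_symbol"].isin(["GENE0001", "GENE0002"])])
        assert planted_ids <= flagged
        assert len(flagged - planted_ids) <= 2  # at most sporadic false positives

    def test_missing_group_errors(self, toy_counts):
        nsaf = compute_nsaf(toy_counts)
        with pytest.raises(ValueError):
            differential_abundance(nsaf, "tumor", "missing")
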