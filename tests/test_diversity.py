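"""Rarefaction, tree building, generalized UniFrac, PCoA and composition
profiles."""

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode
from skbio.stats.ordination import pcoa as skbio_pcoa
from skbio.stats.distance import DistanceMatrix as SkbioDM

from tissamp16s import diversity as dv
from tissamp16s.otucluster import DistanceMatrix, OTU, OTUTable, build_otu_table

import oracles


class TestRarefaction:
    def test_full_depth_equals_observed_richness(self):
        counts = {"a": 120, "b": 60, "c": 30}
        curve = dv.rarefaction(counts, step=100, resamples=50, seed=0)
        assert curve.depths[-1] == 210
        assert curve.mean_otu_count[-1] == 3.0

    def test_single_otu_constant_curve(self):
        curve = dv.rarefaction({"a": 500}, step=100, resamples=20, seed=0)
        assert np.all(curve.mean_otu_count == 1.0)

    def test_matches_hypergeometric_expectation(self):
        counts = np.array([50, 30, 10, 7, 3])
        resamples = 1000
        curve = dv.rarefaction(counts, step=10, resamples=resamples, seed=1)
        # closed-form expectation at depth 10 vs simulated mean, 3 SE band
        expect = dv.rarefaction_expectation(counts, 10)
        # conservative SE bound for a mean of values in [1, 5]
        se = 5 / np.sqrt(resamples)
        got = curve.mean_otu_count[curve.depths == 10][0]
        assert abs(got - expect) < 3 * se

    def test_curve_non_decreasing(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 100, size=12)
        curve = dv.rarefaction(counts, step=50, resamples=200, seed=3)
        assert np.all(np.diff(curve.mean_otu_count) >= -1e-9)

    def test_total_below_step_raises(self):
        with pytest.raises(ValueError):
            dv.rarefaction({"a": 5}, step=100)


class TestRepresentativeTree:
    def test_two_leaves_midpoint(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, 0.1], [0.1, 0]]))
        tree = dv.tree_from_distance_matrix(dm)
        tips = {t.name: t.length for t in tree.tips()}
        assert tips == {"a": pytest.approx(0.05), "b": pytest.approx(0.05)}

    def test_additive_four_leaf_matrix_recovered(self):
        # additive tree: ((a:0.02,b:0.03):0.04,(c:0.01,d:0.05):0.04)
        names = ["a", "b", "c", "d"]
        d = np.array(
            [
                [0.00, 0.05, 0.11, 0.15],
                [0.05, 0.00, 0.12, 0.16],
                [0.11, 0.12, 0.00, 0.06],
                [0.15, 0.16, 0.06, 0.00],
            ]
        )
        tree = dv.tree_from_distance_matrix(DistanceMatrix(names, d))
        # patristic distances reproduce the additive input
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if i < j:
                    ta = tree.find(a)
                    assert ta.distance(tree.find(b)) == pytest.approx(d[i, j], abs=1e-9)

    def test_branch_lengths_non_negative(self):
        rng = np.random.default_rng(3)
        n = 8
        pts = rng.random((n, 3)) * 0.1
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        tree = dv.tree_from_distance_matrix(
            DistanceMatrix([f"L{i}" for i in range(n)], d)
        )
        for node in tree.traverse():
            if node.length is not None:
                assert node.length >= 0

    def test_fewer_than_two_raises(self):
        with pytest.raises(ValueError):
            dv.build_representative_tree([])


def _random_tree(rng, n_leaves):
    pts = rng.random((n_leaves, 3)) * 0.2
    d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    ids = [f"L{i}" for i in range(n_leaves)]
    return dv.tree_from_distance_matrix(DistanceMatrix(ids, d)), ids


def _random_profile(rng, ids):
    v = rng.random(len(ids))
    v /= v.sum()
    return dict(zip(ids, v))


class TestGeneralizedUnifrac:
    def test_identical_profiles_zero(self):
        rng = np.random.default_rng(4)
        tree, ids = _random_tree(rng, 6)
        p = _random_profile(rng, ids)
        assert dv.generalized_unifrac(tree, p, p, 0.6) == pytest.approx(0.0)

    def test_disjoint_two_leaf_support_is_one(self):
        tree = TreeNode.read(["(a:1.0,b:1.0);"])
        for alpha in (0.0, 0.5, 1.0):
            d = dv.generalized_unifrac(tree, {"a": 1, "b": 0}, {"a": 0, "b": 1}, alpha)
            assert d == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_traversal_oracle(self, seed):
        rng = np.random.default_rng(600 + seed)
        tree, ids = _random_tree(rng, 8)
        p = _random_profile(rng, ids)
        q = _random_profile(rng, ids)
        got = dv.generalized_unifrac(tree, p, q, 0.6)
        expect = oracles.unifrac_oracle(tree, p, q, 0.6)
        assert got == pytest.approx(expect, abs=1e-12)
        assert got == pytest.approx(dv.generalized_unifrac(tree, q, p, 0.6))
        assert 0.0 <= got <= 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_alpha_one_equals_weighted_normalized_form(self, seed):
        """At alpha=1 the weights reduce to b_i(p_i+q_i), i.e. the classic
        weighted-normalized formulation, computed here branch-by-branch."""
        rng = np.random.default_rng(700 + seed)
        tree, ids = _random_tree(rng, 7)
        p = _random_profile(rng, ids)
        q = _random_profile(rng, ids)
        num = den = 0.0
        for node in tree.postorder(include_self=False):
            if node.length is None:
                continue
            tips = {t.name for t in node.tips(include_self=True)}
            pi = sum(p[t] for t in tips)
            qi = sum(q[t] for t in tips)
            num += node.length * abs(pi - qi)
            den += node.length * (pi + qi)
        assert dv.generalized_unifrac(tree, p, q, 1.0) == pytest.approx(num / den)

    def test_unnormalized_input_rejected(self):
        tree = TreeNode.read(["(a:1.0,b:1.0);"])
        with pytest.raises(ValueError):
            dv.generalized_unifrac(tree, {"a": 2.0, "b": 0.0}, {"a": 1, "b": 0}, 0.5)


class TestPCoA:
    def test_three_equidistant_points(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = dv.pcoa(DistanceMatrix(["a", "b", "c"], d))
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])
        coords = res.coordinates.to_numpy()
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.linalg.norm(coords[i] - coords[j]) == pytest.approx(
                    1.0, abs=1e-9
                )

    def test_zero_matrix(self):
        res = dv.pcoa(DistanceMatrix(["a", "b"], np.zeros((2, 2))))
        assert np.allclose(res.eigenvalues, 0, atol=1e-12)
        assert res.coordinates.shape[1] == 0

    def test_euclidean_roundtrip(self):
        rng = np.random.default_rng(5)
        pts = rng.random((5, 3))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        d = d / (d.max() * 2)
        res = dv.pcoa(DistanceMatrix([f"s{i}" for i in range(5)], d))
        coords = res.coordinates.to_numpy()
        rec = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
        assert np.allclose(rec, d, atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_skbio_ordination(self, seed):
        """Cross-check eigenvalues and inter-sample distances against the
        scikit-bio PCoA implementation."""
        rng = np.random.default_rng(800 + seed)
        pts = rng.random((6, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        d = d / (d.max() * 2)
        ids = [f"s{i}" for i in range(6)]
        mine = dv.pcoa(DistanceMatrix(ids, d))
        ref = skbio_pcoa(SkbioDM(d, ids=ids))
        npos = mine.coordinates.shape[1]
        assert np.allclose(
            mine.eigenvalues[:npos], ref.eigvals.to_numpy()[:npos], atol=1e-9
        )
        assert np.allclose(
            np.abs(mine.coordinates.to_numpy()),
            np.abs(ref.samples.to_numpy()[:, :npos]),
            atol=1e-6,
        )

    def test_single_sample_raises(self):
        with pytest.raises(ValueError):
            dv.pcoa(DistanceMatrix(["a"], np.zeros((1, 1))))


def _table(counts: dict[str, dict[str, int]], lineages: dict[str, str]) -> OTUTable:
    otus = []
    per_sample = {}
    lin_map = {}
    for i, (otu_id, per_s) in enumerate(counts.items()):
        members = {f"m_{otu_id}": sum(per_s.values())}
        otu = OTU(otu_id, members, f"m_{otu_id}")
        fam = lineages[otu_id]
        otu.consensus_lineage = {
            r: ((fam, 100.0) if r == "family" else (f"{r}_x", 100.0))
            for r in ("domain", "phylum", "class", "order", "family", "genus")
        }
        if fam == "unclassified":
            otu.consensus_lineage["family"] = ("unclassified", 40.0)
        otus.append(otu)
        per_sample[f"m_{otu_id}"] = per_s
    return build_otu_table(otus, per_sample)


class TestCompositionProfile:
    def test_single_taxon(self):
        t = _table({"OTU1": {"s1": 10}}, {"OTU1": "FamA"})
        prof = dv.composition_profile(t, "family")
        assert prof.proportions.loc["FamA", "s1"] == pytest.approx(1.0)
        assert prof.proportions.loc[dv.OTHER_CATEGORY, "s1"] == 0.0
        assert prof.proportions.loc["unclassified", "s1"] == 0.0

    def test_low_abundance_taxon_pooled(self):
        t = _table(
            {"OTU1": {"s1": 996}, "OTU2": {"s1": 4}},
            {"OTU1": "FamA", "OTU2": "FamB"},
        )
        prof = dv.composition_profile(t, "family")
        assert "FamB" not in prof.proportions.index
        assert prof.proportions.loc[dv.OTHER_CATEGORY, "s1"] == pytest.approx(0.004)

    def test_unclassified_category_not_pooled(self):
        t = _table(
            {"OTU1": {"s1": 998}, "OTU2": {"s1": 2}},
            {"OTU1": "FamA", "OTU2": "unclassified"},
        )
        prof = dv.composition_profile(t, "family")
        assert prof.proportions.loc["unclassified", "s1"] == pytest.approx(0.002)

    def test_sums_to_one_per_sample(self):
        rng = np.random.default_rng(6)
        counts = {
            f"OTU{i}": {f"s{j}": int(rng.integers(0, 400)) for j in range(3)}
            for i in range(12)
        }
        lineages = {f"OTU{i}": f"Fam{i % 5}" for i in range(12)}
        t = _table(counts, lineages)
        prof = dv.composition_profile(t, "family")
        sums = prof.proportions.sum(axis=0)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_unknown_rank_raises(self):
        t = _table({"OTU1": {"s1": 10}}, {"OTU1": "FamA"})
        with pytest.raises(ValueError):
            dv.composition_profile(t, "species")
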