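import math

import dendropy
import numpy as np
import pytest

from classbsurvey.msa import Msa
from classbsurvey.phylo import (
    DistanceMatrix,
    assess_monophyly,
    bootstrap_support,
    distances_from_msa,
    nj_build,
    read_newick,
    root_at_outgroup,
    tree_splits,
    write_newick,
)
from classbsurvey.simulate import sample_tree


def _pendants(tree):
    return {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}


def _additive_matrix(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = [t.label for t in tree.taxon_namespace]
    n = len(taxa)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = pdm.distance(tree.taxon_namespace[i],
                                             tree.taxon_namespace[j])
    return DistanceMatrix(tuple(taxa), m)


def _unrooted_splits(tree):
    t = tree.clone(depth=1)
    t.is_rooted = False
    t.update_bipartitions(suppress_unifurcations=True,
                          collapse_unrooted_basal_bifurcation=True)
    return tree_splits(t)


class TestDistances:
    def test_identical_rows_are_distance_zero(self):
        m = Msa.from_records([("a", "ACDE"), ("b", "ACDE"), ("c", "ACDE")])
        for model in ("p", "poisson"):
            assert np.allclose(distances_from_msa(m, model).values, 0.0)

    def test_p_distance(self):
        m = Msa.from_records([("a", "AAAA"), ("b", "AAAT")])
        assert distances_from_msa(m, "p").values[0, 1] == pytest.approx(0.25)

    def test_poisson_correction_closed_form(self):
        m = Msa.from_records([("a", "AAAA"), ("b", "AAAT")])
        d = distances_from_msa(m, "poisson").values[0, 1]
        assert d == pytest.approx(-math.log(0.75), abs=1e-12)

    def test_saturated_pairs_capped_with_warning(self):
        m = Msa.from_records([("a", "AAAA"), ("b", "TTTT")])
        with pytest.warns(UserWarning, match="saturated"):
            d = distances_from_msa(m, "poisson", max_distance=5.0)
        assert d.values[0, 1] == 5.0


class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        t = nj_build(DistanceMatrix(("A", "B"), np.array([[0.0, 0.7], [0.7, 0.0]])))
        pdm = t.phylogenetic_distance_matrix()
        ta, tb = t.taxon_namespace
        assert pdm.distance(ta, tb) == pytest.approx(0.7)

    def test_three_taxon_closed_form(self):
        d = np.array([[0.0, 0.4, 0.6], [0.4, 0.0, 0.8], [0.6, 0.8, 0.0]])
        t = nj_build(DistanceMatrix(("A", "B", "C"), d))
        p = _pendants(t)
        # vA = (dAB + dAC - dBC) / 2, and cyclically
        assert p["A"] == pytest.approx(0.1, abs=1e-12)
        assert p["B"] == pytest.approx(0.3, abs=1e-12)
        assert p["C"] == pytest.approx(0.5, abs=1e-12)

    def test_negative_branch_lengths_clamped(self):
        d = np.array([[0.0, 0.1, 0.6], [0.1, 0.0, 0.1], [0.6, 0.1, 0.0]])
        t = nj_build(DistanceMatrix(("A", "B", "C"), d))
        assert all(l >= 0 for l in _pendants(t).values())

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("A", "B"), np.array([[0.0, -0.1], [-0.1, 0.0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(("A", "B"), np.array([[0.0, 0.1], [0.3, 0.0]]))

    def test_recovers_additive_topologies(self):
        rng = np.random.default_rng(99)
        for _ in range(25):
            n = int(rng.integers(8, 13))
            gt = sample_tree(n, yule_rate=2.0, seed=int(rng.integers(2**31)))
            rec = nj_build(_additive_matrix(gt))
            assert tree_splits(rec) == _unrooted_splits(gt)

    def test_agrees_with_scikit_bio(self):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sknj

        rng = np.random.default_rng(4)
        ids = list("ABCDEFGH")
        x = rng.random((8, 8))
        m = (x + x.T) / 2
        np.fill_diagonal(m, 0)
        sk = sknj(SkDM(m, ids))
        labels = frozenset(ids)
        ref = min(labels)
        sk_splits = set()
        for nd in sk.non_tips(include_self=False):
            side = frozenset(t.name for t in nd.tips())
            if 2 <= len(side) <= len(labels) - 2:
                sk_splits.add(labels - side if ref in side else side)
        assert sk_splits == tree_splits(nj_build(DistanceMatrix(tuple(ids), m)))


class TestBootstrap:
    def test_zero_variation_split_gets_full_support(self):
        m = Msa.from_records(
            [("A", "ACDE" * 10), ("B", "ACDE" * 10), ("C", "GHIK" * 10), ("D", "GHIK" * 10)]
        )
        t = bootstrap_support(m, n_replicates=100, seed=0)
        sups = [nd.support for nd in t.preorder_node_iter()
                if getattr(nd, "support", None) is not None]
        assert sups == [100.0]

    def test_supports_within_range_and_binary_for_single_replicate(self, survey):
        from classbsurvey.msa import trim_to_core
        from classbsurvey.motifs import default_registry

        aln = trim_to_core(survey.alignment, default_registry())
        t = bootstrap_support(aln, n_replicates=1, seed=1)
        sups = [nd.support for nd in t.preorder_node_iter()
                if getattr(nd, "support", None) is not None]
        assert sups and all(s in (0.0, 100.0) for s in sups)

    def test_three_taxa_warns_and_has_no_supports(self):
        m = Msa.from_records([("A", "ACDE"), ("B", "ACDE"), ("C", "GHIK")])
        with pytest.warns(UserWarning, match="fewer than 4"):
            t = bootstrap_support(m, n_replicates=10, seed=0)
        assert all(getattr(nd, "support", None) is None
                   for nd in t.preorder_node_iter())


class TestRooting:
    def _tree(self):
        t = read_newick("((O1:1,O2:1):0.6,(A:1,(B:1,C:1):0.3):0.2);")
        t.is_rooted = False
        return t

    def test_root_on_separating_edge(self):
        rooted = root_at_outgroup(self._tree(), ["O1", "O2"])
        kids = [sorted(lf.taxon.label for lf in c.leaf_iter())
                for c in rooted.seed_node.child_nodes()]
        assert sorted(kids) == [["A", "B", "C"], ["O1", "O2"]]

    def test_single_leaf_outgroup_roots_on_pendant_edge(self):
        rooted = root_at_outgroup(self._tree(), ["O1"])
        kids = [sorted(lf.taxon.label for lf in c.leaf_iter())
                for c in rooted.seed_node.child_nodes()]
        assert ["O1"] in kids

    def test_interleaved_outgroup_falls_back_with_warning(self):
        t = self._tree()
        with pytest.warns(UserWarning, match="not separated"):
            rooted = root_at_outgroup(t, ["O1", "B"])
        assert rooted.is_rooted

    def test_invalid_outgroup_rejected(self):
        t = self._tree()
        with pytest.raises(ValueError):
            root_at_outgroup(t, [])
        with pytest.raises(ValueError):
            root_at_outgroup(t, ["O1", "O2", "A", "B", "C"])

    def test_rooting_preserves_split_set(self):
        t = self._tree()
        before = tree_splits(t)
        rooted = root_at_outgroup(t, ["O1", "O2"])
        assert _unrooted_splits(rooted) == before


class TestMonophyly:
    def _tree(self, newick="((B1:1,B2:1):1,(F1:1,(F2:1,(N1:1,N2:1):1):1):1);"):
        t = read_newick(newick)
        t.is_rooted = True
        return t

    LABELS = {"B1": "BVMO", "B2": "BVMO", "F1": "FMO", "F2": "FMO",
              "N1": "NMO", "N2": "NMO"}

    def test_complete_clade_is_monophyletic(self):
        res = assess_monophyly(self._tree(), self.LABELS, "BVMO")
        assert res.status == "monophyletic" and res.intruders == ()

    def test_grade_with_nested_complete_family_is_paraphyletic(self):
        res = assess_monophyly(self._tree(), self.LABELS, "FMO")
        assert res.status == "paraphyletic"
        assert set(res.intruders) == {"N1", "N2"}
        assert res.mrca_clade_size == 4

    def test_scattered_intruders_mean_polyphyly(self):
        t = self._tree("((A1:1,B1:1):1,(A2:1,B2:1):1);")
        labels = {"A1": "X", "A2": "X", "B1": "Y", "B2": "Y"}
        assert assess_monophyly(t, labels, "X").status == "polyphyletic"

    def test_invariant_under_child_rotation(self):
        rotated = self._tree("((F1:1,((N2:1,N1:1):1,F2:1):1):1,(B2:1,B1:1):1);")
        for fam in ("BVMO", "FMO", "NMO"):
            assert (assess_monophyly(self._tree(), self.LABELS, fam).status
                    == assess_monophyly(rotated, self.LABELS, fam).status)

    def test_unrooted_tree_rejected(self):
        t = self._tree()
        t.is_rooted = False
        with pytest.raises(ValueError):
            assess_monophyly(t, self.LABELS, "BVMO")

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            assess_monophyly(self._tree(), self.LABELS, "YUCCA")


class TestNewickIO:
    def test_topology_lengths_round_trip(self):
        t = read_newick("((A:1,B:2):0.5,C:3);")
        internal = [nd for nd in t.preorder_node_iter()
                    if not nd.is_leaf() and nd is not t.seed_node]
        assert len(internal) == 1 and internal[0].edge.length == 0.5
        again = read_newick(write_newick(t))
        assert write_newick(again) == write_newick(t)

    def test_internal_label_read_as_support(self):
        t = read_newick("((A,B)95,C);")
        internal = [nd for nd in t.preorder_node_iter()
                    if not nd.is_leaf() and nd is not t.seed_node]
        assert internal[0].support == 95.0

    def test_unbalanced_parentheses_raise(self):
        with pytest.raises(Exception):
            read_newick("((A,B,C);")

    def test_duplicate_leaf_labels_raise(self):
        with pytest.raises(ValueError):
            read_newick("((A,A),B);")
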