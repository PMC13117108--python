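"""p-distances, neighbor joining, bootstrap supports, rooting, Newick I/O."""

import io

import dendropy
import numpy as np
import pytest

from parbid.align import Alignment
from parbid.phylo import (
    DistanceMatrix,
    OutgroupError,
    UndefinedDistanceError,
    bootstrap_support,
    nj_tree,
    p_distance_matrix,
    read_newick,
    root_with_outgroup,
    tree_bipartitions,
    write_newick,
)
from parbid.seqcore import SequenceRecord
from parbid.synth import mutate, random_sequence, simulate_additive_matrix


def aln(rows):
    return Alignment([SequenceRecord(f"t{i}", s, allow_gaps=True)
                      for i, s in enumerate(rows)])


def brute_force_p_distance(a, b):
    """Per-site counting oracle under pairwise deletion."""
    comp = diff = 0
    for x, y in zip(a, b):
        if x in "ACGT" and y in "ACGT":
            comp += 1
            if x != y:
                diff += 1
    return (diff / comp if comp else None), comp


class TestPDistance:
    def test_half_divergent_pair(self):
        dm = p_distance_matrix(aln(["AAAA", "AATT"]))
        assert dm[("t0", "t1")] == pytest.approx(0.5)

    def test_pairwise_deletion_excludes_gapped_sites(self):
        dm = p_distance_matrix(aln(["A-AA", "AAAT"]))
        assert dm.comparable_sites[0, 1] == 3
        assert dm[("t0", "t1")] == pytest.approx(1 / 3)

    def test_identical_rows_zero(self):
        dm = p_distance_matrix(aln(["ACGT", "ACGT"]))
        assert dm[("t0", "t1")] == 0.0

    def test_ambiguity_codes_treated_as_missing(self):
        dm = p_distance_matrix(aln(["ARGT", "AAGT"]))
        assert dm.comparable_sites[0, 1] == 3
        assert dm[("t0", "t1")] == 0.0

    def test_zero_comparable_sites_error_names_pair(self):
        with pytest.raises(UndefinedDistanceError, match="t0.*t1"):
            p_distance_matrix(aln(["A---", "-AAA", "AAAA"]))

    def test_matches_brute_force_on_random_gapped_pairs(self, rng):
        for _ in range(200):
            L = int(rng.integers(10, 60))
            chars = np.array(list("ACGT-N"))
            a = "".join(rng.choice(chars, L, p=[0.22, 0.22, 0.22, 0.22, 0.06, 0.06]))
            b = "".join(rng.choice(chars, L, p=[0.22, 0.22, 0.22, 0.22, 0.06, 0.06]))
            expected, comp = brute_force_p_distance(a, b)
            if expected is None:
                with pytest.raises(UndefinedDistanceError):
                    p_distance_matrix(aln([a, b]))
                continue
            dm = p_distance_matrix(aln([a, b]))
            assert dm[("t0", "t1")] == pytest.approx(expected)
            assert dm.comparable_sites[0, 1] == comp

    def test_symmetry_and_zero_diagonal_enforced(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 0.1], [0.2, 0.0]]),
                           np.ones((2, 2)))
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.1, 0.2], [0.2, 0.0]]),
                           np.ones((2, 2)))

    def test_tsv_export_roundtrip(self, tmp_path):
        dm = p_distance_matrix(aln(["AAAA", "AATT", "TTTT"]))
        p = tmp_path / "d.tsv"
        dm.to_tsv(p)
        lines = p.read_text().splitlines()
        assert lines[0].split("\t") == ["taxon", "t0", "t1", "t2"]
        assert lines[1].split("\t")[2] == "0.500000"


def bipartitions_of(tree):
    return set(tree_bipartitions(tree).keys())


class TestNeighborJoining:
    def test_four_taxon_known_tree_recovered_exactly(self):
        """Additive matrix from ((a:0.1,b:0.2):0.15,(c:0.05,d:0.3)); branch
        lengths and topology recovered exactly."""
        # path lengths through the internal 0.15 edge
        taxa = ["a", "b", "c", "d"]
        D = np.array([
            [0.0, 0.3, 0.3, 0.55],
            [0.3, 0.0, 0.4, 0.65],
            [0.3, 0.4, 0.0, 0.35],
            [0.55, 0.65, 0.35, 0.0],
        ])
        dm = DistanceMatrix(taxa, D, np.full((4, 4), 100))
        tree = nj_tree(dm)
        assert bipartitions_of(tree) == {frozenset({"c", "d"})}
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx(0.1)
        assert lengths["b"] == pytest.approx(0.2)
        assert lengths["c"] == pytest.approx(0.05)
        assert lengths["d"] == pytest.approx(0.3)
        internal = [nd.edge.length for nd in tree.preorder_internal_node_iter()
                    if nd is not tree.seed_node]
        assert internal == [pytest.approx(0.15)]

    def test_three_taxon_closed_form(self):
        # pendant lengths: la = (dab + dac - dbc)/2, etc.
        D = np.array([[0.0, 0.4, 0.6], [0.4, 0.0, 0.8], [0.6, 0.8, 0.0]])
        dm = DistanceMatrix(["a", "b", "c"], D, np.full((3, 3), 100))
        tree = nj_tree(dm)
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx(0.1)
        assert lengths["b"] == pytest.approx(0.3)
        assert lengths["c"] == pytest.approx(0.5)

    def test_duplicate_taxa_join_in_zero_length_cherry(self):
        D = np.array([
            [0.0, 0.0, 0.5, 0.6],
            [0.0, 0.0, 0.5, 0.6],
            [0.5, 0.5, 0.0, 0.3],
            [0.6, 0.6, 0.3, 0.0],
        ])
        dm = DistanceMatrix(["a", "b", "c", "d"], D, np.full((4, 4), 100))
        tree = nj_tree(dm)
        assert frozenset({"c", "d"}) in bipartitions_of(tree) or \
            frozenset({"a", "b"}) in bipartitions_of(tree)
        cherry = tree_bipartitions(tree).get(frozenset({"c", "d"}))
        ab_lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
                      if lf.taxon.label in ("a", "b")}
        assert ab_lengths["a"] == pytest.approx(0.0)
        assert ab_lengths["b"] == pytest.approx(0.0)

    def test_recovers_random_additive_topologies(self, rng):
        """NJ is consistent: exact topology recovery on additive matrices
        from 100 random trees with up to 8 taxa."""
        for _ in range(100):
            n = int(rng.integers(5, 9))
            taxa, D, true_bips = simulate_additive_matrix(n, rng)
            dm = DistanceMatrix(taxa, D, np.full((n, n), 100))
            assert bipartitions_of(nj_tree(dm)) == true_bips

    def test_matches_dendropy_nj_topology(self, rng):
        """Independent cross-check against dendropy's NJ on a random
        (non-additive) matrix."""
        n = 7
        M = rng.uniform(0.05, 0.8, (n, n))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0)
        taxa = [f"t{i}" for i in range(n)]
        dm = DistanceMatrix(taxa, M, np.full((n, n), 100))
        ours = bipartitions_of(nj_tree(dm))
        csv = "," + ",".join(taxa) + "\n" + "\n".join(
            taxa[i] + "," + ",".join(str(x) for x in M[i]) for i in range(n)
        )
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(src=io.StringIO(csv))
        theirs_tree = pdm.nj_tree()
        all_labels = frozenset(taxa)
        anchor = sorted(all_labels)[0]
        theirs = set()
        for nd in theirs_tree.preorder_node_iter():
            if nd is theirs_tree.seed_node or nd.is_leaf():
                continue
            labs = frozenset(l.taxon.label for l in nd.leaf_iter())
            norm = labs if anchor not in labs else all_labels - labs
            if 1 < len(norm) < n - 1:
                theirs.add(norm)
        assert ours == theirs

    def test_fewer_than_three_taxa_rejected(self):
        dm = p_distance_matrix(aln(["AAAA", "AATT"]))
        with pytest.raises(ValueError):
            nj_tree(dm)


class TestBootstrap:
    def make_two_cluster_alignment(self, rng, inter=0.05, intra=0.002, L=2000):
        anc = random_sequence(L, rng)
        c1 = mutate(anc, inter, rng)
        c2 = mutate(anc, inter, rng)
        rows = [mutate(c1, intra, rng) for _ in range(3)] + \
               [mutate(c2, intra, rng) for _ in range(3)]
        return Alignment([SequenceRecord(f"x{i}" if i < 3 else f"y{i-3}", s)
                          for i, s in enumerate(rows)])

    def test_separated_clusters_fully_supported(self, rng):
        alignment = self.make_two_cluster_alignment(rng)
        result = bootstrap_support(alignment, replicates=200, seed=11)
        cluster_bip = frozenset({"y0", "y1", "y2"})
        assert result.support[cluster_bip] == 100.0

    def test_identical_sequences_give_no_support(self, rng):
        seq = random_sequence(300, rng)
        alignment = Alignment([SequenceRecord(f"t{i}", seq) for i in range(5)])
        result = bootstrap_support(alignment, replicates=50, seed=3)
        # every internal branch is length 0; no bipartition deserves support
        assert all(v <= 100.0 for v in result.support.values())
        for nd in result.tree.preorder_internal_node_iter():
            if nd is not result.tree.seed_node:
                assert nd.edge.length == pytest.approx(0.0)

    def test_fixed_seed_reproducible(self, rng):
        alignment = self.make_two_cluster_alignment(rng, L=500)
        r1 = bootstrap_support(alignment, replicates=100, seed=42)
        r2 = bootstrap_support(alignment, replicates=100, seed=42)
        assert r1.support == r2.support

    def test_invariant_under_taxon_permutation(self, rng):
        alignment = self.make_two_cluster_alignment(rng, L=500)
        perm = Alignment(list(reversed(alignment.records)))
        r1 = bootstrap_support(alignment, replicates=100, seed=9)
        r2 = bootstrap_support(perm, replicates=100, seed=9)
        assert r1.support == r2.support

    def test_replicate_count_recorded(self, rng):
        alignment = self.make_two_cluster_alignment(rng, L=400)
        result = bootstrap_support(alignment, replicates=25, seed=1)
        assert result.replicates == 25
        assert all(0.0 <= v <= 100.0 for v in result.support.values())


class TestRooting:
    def five_taxon_tree(self):
        rows = {
            "og1": "AAAATTTTGGGGCCCCAAAATTTT",
            "og2": "AAAATTTTGGGGCCCCAAAATTTA",
            "in1": "TTTTTTTTGGGGCCCCAAAATTTT",
            "in2": "TTTTTTTTGGGGCCCAAAAATTTT",
            "in3": "TTTTTTTTGGGGCCAAAAAATTTT",
        }
        alignment = Alignment([SequenceRecord(k, v) for k, v in rows.items()])
        return nj_tree(p_distance_matrix(alignment))

    def test_two_taxon_outgroup_roots_ingroup_monophyletic(self):
        tree = root_with_outgroup(self.five_taxon_tree(), ["og1", "og2"])
        assert tree.is_rooted
        kids = tree.seed_node.child_nodes()
        sides = [frozenset(l.taxon.label for l in k.leaf_iter()) for k in kids]
        assert frozenset({"og1", "og2"}) in sides
        assert frozenset({"in1", "in2", "in3"}) in sides

    def test_single_taxon_outgroup_roots_on_pendant_edge(self):
        tree = root_with_outgroup(self.five_taxon_tree(), ["og1"])
        sides = [frozenset(l.taxon.label for l in k.leaf_iter())
                 for k in tree.seed_node.child_nodes()]
        assert frozenset({"og1"}) in sides

    def test_absent_outgroup_taxon_errors(self):
        with pytest.raises(OutgroupError, match="absent"):
            root_with_outgroup(self.five_taxon_tree(), ["nope"])

    def test_non_monophyletic_outgroup_errors(self):
        with pytest.raises(OutgroupError, match="monophyletic"):
            root_with_outgroup(self.five_taxon_tree(), ["og1", "in1"])


class TestNewick:
    def test_cherry_roundtrip(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("(a:0.1,b:0.1);\n")
        tree = read_newick(p)
        out = tmp_path / "o.nwk"
        write_newick(tree, out)
        again = read_newick(out)
        labels = sorted(l.taxon.label for l in again.leaf_node_iter())
        assert labels == ["a", "b"]
        assert all(l.edge.length == pytest.approx(0.1)
                   for l in again.leaf_node_iter())

    def test_support_label_preserved(self, tmp_path, rng):
        alignment = TestBootstrap().make_two_cluster_alignment(rng, L=400)
        result = bootstrap_support(alignment, replicates=40, seed=2)
        p = tmp_path / "s.nwk"
        write_newick(result.tree, p)
        again = read_newick(p)
        labels = {nd.label for nd in again.preorder_internal_node_iter()
                  if nd.label is not None}
        expected = {f"{v:g}" for v in result.support.values()}
        assert labels >= expected or expected == set()

    def test_quoted_labels_with_spaces_survive(self, tmp_path):
        p = tmp_path / "q.nwk"
        p.write_text("(('M majus T':0.1,'M guizhouense T':0.2):0.05,b:0.1,c:0.2);\n")
        tree = read_newick(p)
        out = tmp_path / "q2.nwk"
        write_newick(tree, out)
        again = read_newick(out)
        labels = {l.taxon.label for l in again.leaf_node_iter()}
        assert "M majus T" in labels and "M guizhouense T" in labels

    def test_branch_length_precision(self, tmp_path):
        p = tmp_path / "p.nwk"
        p.write_text("(a:0.123456789,b:0.000012345678);\n")
        out = tmp_path / "p2.nwk"
        write_newick(read_newick(p), out)
        lengths = sorted(l.edge.length for l in read_newick(out).leaf_node_iter())
        assert lengths[0] == pytest.approx(0.000012345678, rel=1e-6)
        assert lengths[1] == pytest.approx(0.123456789, rel=1e-6)

    def test_malformed_newick_raises(self, tmp_path):
        p = tmp_path / "bad.nwk"
        p.write_text("((a:0.1,b:0.2;\n")
        with pytest.raises(ValueError, match="malformed"):
            read_newick(p)
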