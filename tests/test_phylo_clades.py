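import dendropy
import numpy as np
import pytest

from rdase_scout import phylo_clades as pc

from oracle_util import (
    additive_distances, alignment_identity_oracle, column_coverage_tally,
    dendropy_splits, random_additive_tree, tree_splits, union_find_groups,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pc.pairwise_identity("MKLVNN", "MKLVNN") == 100.0

    def test_single_substitution(self):
        assert pc.pairwise_identity("AAAAAAAAAA", "AAAAAAAAAC") == \
            pytest.approx(90.0)

    def test_frozen_peptide_pair_matches_enumeration_oracle(self):
        # value computed once with alignment_identity_oracle: score 4.0,
        # two co-optimal alignments, max identity 3/10
        assert pc.pairwise_identity("HEAGAWGHEE", "PAWHEAE") == \
            pytest.approx(30.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_random_short_peptides_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list(AA), size=rng.integers(4, 8)))
        b = "".join(rng.choice(list(AA), size=rng.integers(4, 8)))
        _, expected = alignment_identity_oracle(a, b)
        assert pc.pairwise_identity(a, b) == pytest.approx(expected)

    def test_symmetry(self, rng):
        for _ in range(5):
            a = "".join(rng.choice(list(AA), size=30))
            b = "".join(rng.choice(list(AA), size=25))
            assert pc.pairwise_identity(a, b) == \
                pytest.approx(pc.pairwise_identity(b, a))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pc.pairwise_identity("", "MK")


class TestOrthologGroups:
    def _matrix(self, labels, pairs):
        n = len(labels)
        v = np.full((n, n), 0.0)
        np.fill_diagonal(v, 100.0)
        for (a, b), val in pairs.items():
            i, j = labels.index(a), labels.index(b)
            v[i, j] = v[j, i] = val
        return pc.IdentityMatrix(labels, v)

    def test_single_linkage_chain(self):
        m = self._matrix(["A", "B", "C"],
                         {("A", "B"): 95, ("B", "C"): 92, ("A", "C"): 85})
        groups = pc.ortholog_groups(m, 90)
        assert len(set(groups.assignment.values())) == 1

    def test_all_below_cutoff_are_singletons(self):
        m = self._matrix(["A", "B", "C"],
                         {("A", "B"): 50, ("B", "C"): 60, ("A", "C"): 10})
        groups = pc.ortholog_groups(m, 90)
        assert sorted(groups.assignment.values()) == [0, 1, 2]

    @pytest.mark.parametrize("seed", [7, 8, 9])
    def test_random_matrix_matches_union_find(self, seed):
        rng = np.random.default_rng(seed)
        labels = list("ABCDE")
        v = rng.uniform(0, 100, size=(5, 5))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 100.0)
        m = pc.IdentityMatrix(labels, v)
        assert pc.ortholog_groups(m, 60).assignment == \
            union_find_groups(labels, v, 60)

    def test_cutoff_refinement(self, rng):
        """Raising the cutoff never merges groups; lowering never splits."""
        labels = [f"s{i}" for i in range(8)]
        v = rng.uniform(50, 100, size=(8, 8))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 100.0)
        m = pc.IdentityMatrix(labels, v)
        prev = pc.ortholog_groups(m, 60).assignment
        for cutoff in (70, 80, 90):
            cur = pc.ortholog_groups(m, cutoff).assignment
            for a in labels:
                for b in labels:
                    if cur[a] == cur[b]:  # still together at higher cutoff
                        assert prev[a] == prev[b]
            prev = cur


class TestFilterColumns:
    def test_low_coverage_column_dropped(self):
        msa = pc.Msa(["a", "b", "c"], ["A-", "-A", "-A"])
        out = pc.filter_columns(msa, 0.60)
        assert out.rows == ["-", "A", "A"]

    def test_x_counts_as_ambiguous(self):
        msa = pc.Msa(["a", "b", "c"], ["AX", "AX", "XX"])
        out = pc.filter_columns(msa, 0.60)
        assert out.rows == ["A", "A", "X"]

    @pytest.mark.parametrize("seed", range(3))
    def test_retained_set_matches_independent_tally(self, seed):
        rng = np.random.default_rng(seed)
        rows = ["".join(rng.choice(list(AA + "-X"), size=200))
                for _ in range(10)]
        msa = pc.Msa([f"s{i}" for i in range(10)], rows)
        keep = column_coverage_tally(rows, 0.60)
        out = pc.filter_columns(msa, 0.60)
        assert out.rows == ["".join(r[c] for c in keep) for r in rows]

    def test_idempotent(self, rng):
        rows = ["".join(rng.choice(list(AA + "---X"), size=80))
                for _ in range(6)]
        msa = pc.Msa([f"s{i}" for i in range(6)], rows)
        once = pc.filter_columns(msa)
        twice = pc.filter_columns(once)
        assert once.rows == twice.rows


class TestDistances:
    def test_identical_rows_zero(self):
        msa = pc.Msa(["a", "b"], ["MKLV", "MKLV"])
        assert pc.distance_matrix(msa)[0, 1] == 0.0

    def test_p_distance_counts_comparable_columns(self):
        msa = pc.Msa(["a", "b"], ["AAAAAAAAAA", "CCAAAAAAAA"])
        assert pc.distance_matrix(msa, "p")[0, 1] == pytest.approx(0.2)

    def test_poisson_closed_form(self):
        msa = pc.Msa(["a", "b"], ["AAAAAAAAAA", "CCAAAAAAAA"])
        assert pc.distance_matrix(msa, "poisson")[0, 1] == \
            pytest.approx(-np.log(0.8))

    def test_gap_columns_excluded_from_denominator(self):
        msa = pc.Msa(["a", "b"], ["AA--AAAA", "CAXXAAAA"])
        # comparable columns: 0,1,4,5,6,7 -> one mismatch of six
        assert pc.distance_matrix(msa, "p")[0, 1] == pytest.approx(1 / 6)

    def test_no_comparable_columns_is_error(self):
        msa = pc.Msa(["a", "b"], ["A--", "-AA"])
        with pytest.raises(ValueError, match="'a'.*'b'"):
            pc.distance_matrix(msa)


class TestNeighborJoining:
    def test_two_taxa_split_edge(self):
        tree = pc.nj_tree(np.array([[0.0, 0.4], [0.4, 0.0]]), ["A", "B"])
        pd = pc.patristic_distances(tree)
        assert pd[("A", "B")] == pytest.approx(0.4)
        lengths = [lf.edge.length for lf in tree.leaf_node_iter()]
        assert lengths == pytest.approx([0.2, 0.2])

    def test_three_taxa_closed_form(self):
        d = np.array([[0.0, 0.3, 0.5],
                      [0.3, 0.0, 0.6],
                      [0.5, 0.6, 0.0]])
        tree = pc.nj_tree(d, ["A", "B", "C"])
        lengths = {lf.taxon.label: lf.edge.length
                   for lf in tree.leaf_node_iter()}
        assert lengths["A"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["B"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["C"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    @pytest.mark.parametrize("seed", [3, 4, 5, 6])
    def test_additive_matrix_reconstruction(self, seed):
        rng = np.random.default_rng(seed)
        g, labels = random_additive_tree(rng, int(rng.integers(4, 9)))
        d = additive_distances(g, labels)
        tree = pc.nj_tree(d, labels)
        pd = pc.patristic_distances(tree)
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                key = tuple(sorted((labels[i], labels[j])))
                assert pd[key] == pytest.approx(d[i, j], abs=1e-9)
        assert dendropy_splits(tree, labels) == tree_splits(g, labels)

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 0.1], [0.3, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            pc.nj_tree(d, ["A", "B"])

    def test_cross_check_against_scikit_bio(self):
        """Independent NJ implementation agrees on a tie-free matrix."""
        import io

        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(11)
        g, labels = random_additive_tree(rng, 6)
        d = additive_distances(g, labels)
        ours = pc.nj_tree(d, labels)
        sym = (d + d.T) / 2.0
        np.fill_diagonal(sym, 0.0)
        theirs_newick = str(skbio_nj(DistanceMatrix(sym, labels)))
        theirs = dendropy.Tree.get(data=theirs_newick, schema="newick")
        assert dendropy_splits(ours, labels) == \
            dendropy_splits(theirs, labels)


class TestCladeAssignment:
    def _tree(self):
        nwk = ("((r1:0.1,r2:0.1):0.5,(r3:0.1,(r4:0.1,q1:0.02):0.05):0.5,"
               "q2:0.3);")
        return dendropy.Tree.get(data=nwk, schema="newick")

    def test_query_next_to_reference(self):
        tree = self._tree()
        refs = {"r1": "cladeA", "r2": "cladeA", "r3": "cladeB",
                "r4": "cladeB"}
        assignment, monophyly = pc.assign_clades(tree, refs)
        assert assignment["q1"] == "cladeB"
        assert monophyly == {"cladeA": True, "cladeB": True}

    def test_equidistant_query_is_ambiguous(self):
        nwk = "((r1:0.1,q1:0.1):0.1,r2:0.2,x:1.0);"
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        refs = {"r1": "cladeA", "r2": "cladeB"}
        assignment, _ = pc.assign_clades(tree, refs)
        # q1 is 0.2 from r1 and 0.4 from r2 -> cladeA
        assert assignment["q1"] == "cladeA"
        # x is 1.2 from both references -> tie
        assert assignment["x"] == "ambiguous"

    def test_non_monophyletic_references_warn_but_assign(self, caplog):
        nwk = "((r1:0.1,r3:0.1):0.1,(r2:0.1,q1:0.1):0.1,out:0.5);"
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        refs = {"r1": "cladeA", "r2": "cladeA", "r3": "cladeB",
                "out": "cladeC"}
        with caplog.at_level("WARNING"):
            assignment, monophyly = pc.assign_clades(tree, refs)
        assert monophyly["cladeA"] is False
        assert assignment["q1"] == "cladeA"
        assert any("monophyletic" in r.message for r in caplog.records)

    def test_missing_reference_label_errors(self):
        tree = self._tree()
        with pytest.raises(ValueError, match="nope"):
            pc.assign_clades(tree, {"nope": "cladeA"})


class TestIO:
    def test_newick_round_trip(self, tmp_path):
        nwk = "(A:0.1,B:0.1,(C:0.1,D:0.1):0.05);"
        tree = pc.read_newick(nwk, from_string=True)
        path = tmp_path / "t.nwk"
        pc.write_newick(tree, str(path))
        back = pc.read_newick(str(path))
        assert sorted(lf.taxon.label for lf in back.leaf_node_iter()) == \
            ["A", "B", "C", "D"]
        pd_a, pd_b = pc.patristic_distances(tree), pc.patristic_distances(back)
        for key in pd_a:
            assert pd_b[key] == pytest.approx(pd_a[key], abs=1e-12)

    def test_ragged_fasta_errors(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">a\nMKLV\n>b\nMKL\n")
        with pytest.raises(ValueError, match="'b'"):
            pc.read_aligned_fasta(str(path))

    def test_aligned_fasta_reads_gaps(self, tmp_path):
        path = tmp_path / "ok.fasta"
        path.write_text(">a\nMK-V\n>b\nMKLV\n")
        msa = pc.read_aligned_fasta(str(path))
        assert msa.labels == ["a", "b"] and msa.rows == ["MK-V", "MKLV"]
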