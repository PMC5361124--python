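"""Matrix parsing dialects, NJ reconstruction, ordination geometry."""

import itertools

import numpy as np
import pytest

import mtpop
from mtpop import (
    DistanceMatrix,
    NumericError,
    ParseError,
    additive_matrix_from_tree,
    nearest_and_farthest,
    neighbor_joining,
    ordinate,
    parse_fst_pvalue_table,
    random_additive_tree,
    read_distance_matrix,
    write_fst_pvalue_table,
)
from mtpop.tree_and_ordination import parse_phylip, parse_square_tsv

TOY_TABLE = (
    "# key: 1, A; 2, B\n"
    "Populations\t1\t2\n"
    "1\t*\t0.04000\n"
    "2\t**0.10000**\t*\n"
)


class TestCombinedTableDialect:
    def test_study_matrix_labels_and_values(self, fst_table):
        dm, sm = fst_table
        assert len(dm.labels) == 19
        assert dm.labels[0] == "Xibe"
        assert dm.value("Xibe", "Xinjiang Han") == 0.00276
        assert dm.value("Xibe", "Italians") == 0.14807
        assert sm.value("Xibe", "Guangdong Han") == 0.85586

    def test_toy_table(self):
        dm, sm = parse_fst_pvalue_table(TOY_TABLE)
        assert dm.value("A", "B") == 0.1  # bold markup stripped
        assert sm.value("A", "B") == 0.04

    def test_non_square_rejected(self):
        with pytest.raises(ParseError, match="square"):
            parse_fst_pvalue_table(
                "Populations\t1\t2\n1\t*\t0.1\t0.3\n2\t0.1\t*\n"
            )

    def test_non_numeric_cell_located(self):
        with pytest.raises(ParseError, match="row 2, col 1"):
            parse_fst_pvalue_table(
                "Populations\t1\t2\n1\t*\t0.1\n2\tzap\t*\n"
            )

    def test_roundtrip_reproduces_numeric_cells(self, fst_table):
        dm, sm = fst_table
        dm2, sm2 = parse_fst_pvalue_table(write_fst_pvalue_table(dm, sm))
        assert dm2.labels == dm.labels
        np.testing.assert_array_equal(dm2.values, dm.values)
        np.testing.assert_array_equal(sm2.values, sm.values)

    def test_dialect_equivalence(self, fst_table):
        """The same matrix in square-TSV and PHYLIP dialects parses equal."""
        dm, _ = fst_table
        assert read_distance_matrix(dm.to_square_tsv()).labels == dm.labels
        np.testing.assert_allclose(
            parse_square_tsv(dm.to_square_tsv()).values, dm.values, atol=5e-6
        )
        np.testing.assert_allclose(
            parse_phylip(dm.to_phylip()).values, dm.values, atol=5e-6
        )
        # PHYLIP flattens spaces to underscores; names otherwise verbatim
        assert parse_phylip(dm.to_phylip()).labels == tuple(
            l.replace(" ", "_") for l in dm.labels
        )


class TestQueries:
    def test_study_nearest_and_farthest(self, fst_table):
        dm, _ = fst_table
        (near, nv), (far, fv) = nearest_and_farthest(dm, "Xibe")
        assert (near, nv) == ("Xinjiang Han", 0.00276)
        assert (far, fv) == ("Italians", 0.14807)

    def test_two_label_matrix(self):
        dm = DistanceMatrix(("A", "B"), np.array([[0.0, 0.3], [0.3, 0.0]]))
        assert nearest_and_farthest(dm, "A") == (("B", 0.3), ("B", 0.3))

    def test_tie_break_by_label_order(self):
        values = np.ones((3, 3)) - np.eye(3)
        dm = DistanceMatrix(("C", "A", "B"), values)
        (near, _), (far, _) = nearest_and_farthest(dm, "C")
        assert near == far == "A"

    def test_unknown_focal_rejected(self, fst_table):
        with pytest.raises(mtpop.ValidationError):
            nearest_and_farthest(fst_table[0], "Atlantis")


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = DistanceMatrix(
            ("a", "b", "c"),
            np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]]),
        )
        tree = neighbor_joining(d)
        hub = [n for n in tree.adjacency if not isinstance(n, str)][0]
        assert tree.adjacency["a"][hub] == pytest.approx((3 + 4 - 5) / 2)
        assert tree.adjacency["b"][hub] == pytest.approx((3 + 5 - 4) / 2)
        assert tree.adjacency["c"][hub] == pytest.approx((4 + 5 - 3) / 2)

    def test_five_taxon_additive_recovery(self):
        newick = "((A:1.0,B:2.0):0.5,(C:0.7,D:1.3):0.9,E:2.2);"
        m = additive_matrix_from_tree(newick)
        tree = neighbor_joining(m)
        assert tree.has_split({"A", "B"})
        assert tree.has_split({"C", "D"})
        np.testing.assert_allclose(tree.patristic().values, m.values, atol=1e-9)

    def test_random_additive_recovery(self):
        """Exact topology+length recovery on 100 random 4-8 leaf trees."""
        for s in range(100):
            m = additive_matrix_from_tree(random_additive_tree(4 + s % 5, seed=s))
            tree = neighbor_joining(m)
            np.testing.assert_allclose(tree.patristic().values, m.values, atol=1e-9)

    def test_each_join_minimises_q_criterion(self):
        """At every agglomeration the joined pair attains the minimal
        Q(i,j) = (r-2)d(i,j) - R_i - R_j, checked by exhaustive enumeration
        against an independent step-by-step NJ replay."""
        for n_leaves, seed in [(4, 1), (4, 2), (5, 3), (5, 4)]:
            m = additive_matrix_from_tree(
                random_additive_tree(n_leaves, seed=seed), jitter=0.05, seed=seed
            )
            d = {frozenset(p): m.value(*p) for p in itertools.combinations(m.labels, 2)}
            nodes: list = list(m.labels)
            below = {lab: {lab} for lab in m.labels}
            splits = set()
            nxt = 0
            while len(nodes) > 3:
                r = len(nodes)
                R = {a: sum(d[frozenset((a, b))] for b in nodes if b != a) for a in nodes}
                q_of = {
                    p: (r - 2) * d[frozenset(p)] - R[p[0]] - R[p[1]]
                    for p in itertools.combinations(nodes, 2)
                }
                (a, b), _ = min(q_of.items(), key=lambda kv: kv[1])
                for c in nodes:
                    if c not in (a, b):
                        d[frozenset((nxt, c))] = (
                            d[frozenset((a, c))] + d[frozenset((b, c))] - d[frozenset((a, b))]
                        ) / 2
                below[nxt] = below[a] | below[b]
                if 1 < len(below[nxt]) < n_leaves - 1:
                    splits.add(frozenset(below[nxt]))
                nodes = [c for c in nodes if c not in (a, b)] + [nxt]
                nxt += 1
            expected = {
                frozenset(s if min(m.labels) not in s else set(m.labels) - s)
                for s in splits
            }
            assert neighbor_joining(m).splits() == expected

    def test_topology_invariant_to_label_order(self):
        m = additive_matrix_from_tree(random_additive_tree(7, seed=13))
        perm = [3, 0, 6, 2, 5, 1, 4]
        m2 = DistanceMatrix(
            tuple(m.labels[i] for i in perm), m.values[np.ix_(perm, perm)]
        )
        assert neighbor_joining(m).splits() == neighbor_joining(m2).splits()

    def test_study_matrix_european_split(self, fst_table):
        """The three non-Asian-cluster populations sit on one side of a
        single split, the remaining 16 on the other."""
        tree = neighbor_joining(fst_table[0])
        assert tree.has_split({"Italians", "Estonian", "US_Caucasians"})

    def test_matches_reference_nj_implementation(self, fst_table):
        """Cross-check against scikit-bio's NJ on the non-additive study
        matrix (topologies compared as unrooted split sets)."""
        skbio = pytest.importorskip("skbio")
        dm, _ = fst_table
        ref_tree = skbio.tree.nj(
            skbio.DistanceMatrix(dm.values, ids=list(dm.labels))
        )
        leaves = set(dm.labels)
        ref_splits = set()
        for node in ref_tree.non_tips(include_self=False):
            below = {t.name for t in node.tips()}
            if 1 < len(below) < len(leaves) - 1:
                canon = below if min(leaves) not in below else leaves - below
                ref_splits.add(frozenset(canon))
        assert neighbor_joining(dm).splits() == ref_splits

    def test_fewer_than_three_taxa_rejected(self):
        dm = DistanceMatrix(("A", "B"), np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(NumericError):
            neighbor_joining(dm)

    def test_newick_quotes_spaced_labels(self, fst_table):
        newick = neighbor_joining(fst_table[0]).to_newick()
        assert "'Xinjiang Han'" in newick
        import dendropy

        parsed = dendropy.Tree.get(data=newick, schema="newick")
        assert len(parsed.leaf_nodes()) == 19


class TestOrdination:
    def test_zero_matrix_zero_variance(self):
        dm = DistanceMatrix(tuple("abcd"), np.zeros((4, 4)))
        res = ordinate(dm, k=2)
        np.testing.assert_allclose(res.coordinates, 0.0, atol=1e-12)
        np.testing.assert_allclose(res.explained_fraction, 0.0)

    @pytest.mark.parametrize("method", ["pca", "mds"])
    def test_two_block_matrix_separates_on_axis_one(self, method):
        """Two well-separated clusters: axis 1 splits them with a margin."""
        k = 6
        within, between = 0.01, 1.0
        values = np.full((k, k), between)
        values[:3, :3] = within
        values[3:, 3:] = within
        np.fill_diagonal(values, 0.0)
        res = ordinate(DistanceMatrix(tuple("abcdef"), values), k=2, method=method)
        left, right = res.coordinates[:3, 0], res.coordinates[3:, 0]
        assert max(left) < min(right) or max(right) < min(left)
        assert abs(left.mean() - right.mean()) > 0.5

    @pytest.mark.parametrize("method", ["pca", "mds"])
    def test_axes_centred_and_ordered(self, fst_table, method):
        res = ordinate(fst_table[0], k=3, method=method)
        np.testing.assert_allclose(res.coordinates.mean(axis=0), 0.0, atol=1e-12)
        assert list(res.explained_fraction) == sorted(res.explained_fraction, reverse=True)

    def test_study_matrix_east_asian_cluster(self, fst_table):
        """Xibe/Guangdong Han/Liaoning Han/Yanbian Korean each lie nearer
        their joint centroid than to Italians in the 2-D plane."""
        res = ordinate(fst_table[0], k=2)
        cluster = ["Xibe", "Guangdong Han", "Liaoning Han", "Yanbian Korean"]
        centroid = np.mean([res.coordinate(l) for l in cluster], axis=0)
        italians = res.coordinate("Italians")
        for label in cluster:
            c = res.coordinate(label)
            assert np.linalg.norm(c - centroid) < np.linalg.norm(c - italians)

    def test_too_many_axes_rejected(self, fst_table):
        with pytest.raises(NumericError):
            ordinate(fst_table[0], k=19)
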