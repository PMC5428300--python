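import dendropy
import numpy as np
import pytest

from superbarcode import (
    Msa,
    bootstrap_support,
    collapse_low_support,
    nj_tree,
    read_newick,
    rf_distance,
    write_newick,
)
from superbarcode.divergence import DiffMatrix
from superbarcode.phylogeny import bipartitions
from superbarcode.published import echinacea_diff_matrix


def dm_from_distances(taxa, d):
    """Wrap a plain distance matrix (arbitrary scale) as a DiffMatrix."""
    d = np.asarray(d, dtype=float)
    counts = np.round(d * 1000).astype(np.int64)
    return DiffMatrix(
        taxa=list(taxa),
        counts=counts,
        percents=np.round(d * 100, 2),
        denominator_mode="alignment_length",
        denominators=np.full(d.shape, 1000.0),
    )


def patristic(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    n = len(taxa)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return out, [t.label for t in taxa]


class TestNjTree:
    def test_additive_matrix_recovered_exactly(self):
        # tree ((A:2,B:3):1,(C:4,D:5)) -> additive distances
        d = np.array(
            [
                [0, 5, 7, 8],
                [5, 0, 8, 9],
                [7, 8, 0, 9],
                [8, 9, 9, 0],
            ],
            dtype=float,
        )
        tree = nj_tree(dm_from_distances("ABCD", d))
        assert bipartitions(tree) == {frozenset({"C", "D"})}
        got, labels = patristic(tree)
        assert labels == ["A", "B", "C", "D"]
        np.testing.assert_allclose(got, d, atol=1e-9)

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = nj_tree(dm_from_distances("ABC", d))
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        # a = (dab+dac-dbc)/2 etc.
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(3.0)

    def test_fewer_than_three_taxa_rejected(self):
        d = np.array([[0, 1], [1, 0]], dtype=float)
        with pytest.raises(ValueError):
            nj_tree(dm_from_distances("AB", d))

    def test_published_echinacea_matrix_recovers_sister_species(self):
        tree = nj_tree(echinacea_diff_matrix())
        bps = bipartitions(tree)
        assert frozenset({"paradoxa", "atrorubens"}) in bps
        assert frozenset({"tennesseensis", "laevigata", "speciosa", "purpurea"}) in bps

    def test_negative_branch_estimates_clamped(self):
        # a non-additive matrix that forces a negative NJ branch estimate
        d = np.array(
            [[0, 1, 5, 5], [1, 0, 5, 5], [5, 5, 0, 1], [5, 5, 1, 0]], dtype=float
        )
        d[0, 1] = d[1, 0] = 9.9  # break additivity
        tree = nj_tree(dm_from_distances("ABCD", d))
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length >= 0


class TestRfDistance:
    def test_tree_vs_itself_is_zero(self):
        t = read_newick("((A,B),(C,D));")
        assert rf_distance(t, t) == 0

    def test_alternative_quartet_resolutions_differ_by_two(self):
        a = read_newick("((A,B),(C,D));")
        b = read_newick("((A,C),(B,D));")
        assert rf_distance(a, b) == 2

    def test_caterpillar_vs_balanced_matches_bruteforce_and_dendropy(self):
        cat = "(((((A,B),C),D),E),F);"
        bal = "(((A,B),C),((D,E),F));"
        a, b = read_newick(cat), read_newick(bal)
        brute = len(bipartitions(a) ^ bipartitions(b))
        assert rf_distance(a, b) == brute
        # independent oracle: dendropy's bipartition comparison
        tns = dendropy.TaxonNamespace()
        da = dendropy.Tree.get(data=cat, schema="newick", taxon_namespace=tns)
        db = dendropy.Tree.get(data=bal, schema="newick", taxon_namespace=tns)
        da.encode_bipartitions()
        db.encode_bipartitions()
        expected = dendropy.calculate.treecompare.symmetric_difference(da, db)
        assert rf_distance(a, b) == expected

    def test_leaf_set_mismatch_rejected(self):
        a = read_newick("((A,B),(C,D));")
        b = read_newick("((A,B),(C,E));")
        with pytest.raises(ValueError):
            rf_distance(a, b)


def _diagnostic_alignment(length=1000):
    """4 taxa, one column splitting {t0, t2} from {t1, t3}, rest identical."""
    base = "A" * (length - 1)
    return Msa(
        ["t0", "t1", "t2", "t3"],
        [base + "C", base + "A", base + "C", base + "A"],
    )


class TestBootstrap:
    def test_clades_with_many_diagnostic_columns_get_full_support(self):
        rng = np.random.default_rng(0)
        base = rng.choice(list("ACGT"), size=400)
        rows = []
        for i in range(4):
            row = base.copy()
            block = slice(0, 100) if i < 2 else slice(100, 200)
            row[block] = np.where(row[block] == "A", "C", "A")  # 100 diagnostic cols
            rows.append("".join(row))
        msa = Msa(["a1", "a2", "b1", "b2"], rows)
        tree = bootstrap_support(msa, n_reps=200, seed=1)
        for node in tree.preorder_node_iter():
            if node.label is not None:
                assert int(node.label) >= 99

    def test_single_diagnostic_column_support_near_63_percent(self):
        # the probability a specific column survives column resampling is
        # 1-(1-1/L)^L ~ 0.632; with one informative column the clade support
        # concentrates there
        tree = bootstrap_support(_diagnostic_alignment(), n_reps=600, seed=2)
        sup = {
            frozenset(l.taxon.label for l in n.leaf_iter()): int(n.label)
            for n in tree.preorder_node_iter()
            if n.label is not None
        }
        [(clade, support)] = [
            (c, s) for c, s in sup.items() if c in ({"t0", "t2"}, {"t1", "t3"})
        ]
        assert 55 <= support <= 71

    def test_one_replicate_gives_all_or_nothing_support(self):
        tree = bootstrap_support(_diagnostic_alignment(200), n_reps=1, seed=3)
        sups = [int(n.label) for n in tree.preorder_node_iter() if n.label is not None]
        assert sups and all(s in (0, 100) for s in sups)

    def test_fixed_seed_is_bit_reproducible(self):
        msa = _diagnostic_alignment(300)
        a = write_newick(bootstrap_support(msa, n_reps=50, seed=9))
        b = write_newick(bootstrap_support(msa, n_reps=50, seed=9))
        assert a == b

    def test_three_taxa_returns_tree_without_support(self):
        msa = Msa(["a", "b", "c"], ["ACGT", "ACGA", "ACTT"])
        tree = bootstrap_support(msa, n_reps=10, seed=0)
        assert all(n.label is None for n in tree.preorder_node_iter())


class TestCollapse:
    def _supported_tree(self):
        tree = read_newick("((A,B)80,((C,D)40,E)10,F);")
        return tree

    def test_threshold_zero_is_identity(self):
        t = self._supported_tree()
        assert rf_distance(collapse_low_support(t, 0), t) == 0

    def test_threshold_above_100_gives_star(self):
        t = self._supported_tree()
        collapsed = collapse_low_support(t, 101)
        assert bipartitions(collapsed) == set()

    def test_partial_collapse_keeps_strong_clades(self):
        collapsed = collapse_low_support(self._supported_tree(), 50)
        bps = bipartitions(collapsed)
        assert frozenset({"C", "D"}) not in bps
        assert len(bps) == 1  # only the 80%-supported clade remains

    def test_leaf_set_unchanged(self):
        t = self._supported_tree()
        collapsed = collapse_low_support(t, 101)
        assert {l.taxon.label for l in collapsed.leaf_node_iter()} == set("ABCDEF")
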