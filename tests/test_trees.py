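import dendropy
import numpy as np
import pytest

from barcodegap.distances import DistanceMatrix
from barcodegap.trees import (
    is_monophyletic,
    nj_tree,
    read_newick,
    root_on_outgroup,
    tree_length,
    write_newick,
)


def dm(ids, d):
    return DistanceMatrix(list(ids), np.asarray(d, dtype=float), "K2P")


def leaf_branches(tree):
    return {leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()}


def bipartitions(tree):
    """Non-trivial leaf bipartitions as frozensets of the smaller side."""
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        other = leaves - side
        if len(side) > 1 and len(other) > 1:
            out.add(min(side, other, key=sorted))
    return out


def random_additive_tree(rng, n_leaves):
    """Random binary tree with positive branch lengths and its leaf matrix."""
    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n_leaves)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = [dendropy.Node(taxon=t) for t in taxa]
    pool = list(nodes)
    while len(pool) > 3:
        i, j = sorted(rng.choice(len(pool), size=2, replace=False))
        parent = dendropy.Node()
        for child in (pool[i], pool[j]):
            parent.add_child(child)
            child.edge.length = float(rng.uniform(0.05, 0.3))
        pool = [p for k, p in enumerate(pool) if k not in (i, j)] + [parent]
    for child in pool:
        tree.seed_node.add_child(child)
        child.edge.length = float(rng.uniform(0.05, 0.3))
    tree.is_rooted = False
    pdm = tree.phylogenetic_distance_matrix()
    ids = [t.label for t in taxa]
    d = np.zeros((n_leaves, n_leaves))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i < j:
                d[i, j] = d[j, i] = pdm.distance(a, b)
    return tree, dm(ids, d)


def test_three_taxon_branch_lengths():
    m = dm("ABC", [[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]])
    t = nj_tree(m)
    lengths = leaf_branches(t)
    assert lengths["A"] == pytest.approx(0.05)
    assert lengths["B"] == pytest.approx(0.15)
    assert lengths["C"] == pytest.approx(0.25)


def test_nj_reproduces_additive_matrices():
    rng = np.random.default_rng(5)
    for _ in range(25):
        n = int(rng.integers(5, 13))
        true_tree, m = random_additive_tree(rng, n)
        est = nj_tree(m)
        pdm = est.phylogenetic_distance_matrix()
        for i, a in enumerate(m.ids):
            for j, b in enumerate(m.ids):
                if i < j:
                    ta = est.taxon_namespace.get_taxon(a)
                    tb = est.taxon_namespace.get_taxon(b)
                    assert pdm.distance(ta, tb) == pytest.approx(m.d[i, j], abs=1e-9)
        assert bipartitions(est) == bipartitions(true_tree)


def test_nj_agrees_with_independent_implementation():
    from io import StringIO

    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj as skbio_nj

    rng = np.random.default_rng(17)
    for _ in range(5):
        n = 8
        _, m = random_additive_tree(rng, n)
        est = nj_tree(m)
        sk_tree = skbio_nj(SkbioDM(m.d, ids=m.ids))
        sk_dendro = dendropy.Tree.get(
            data=str(sk_tree), schema="newick", taxon_namespace=est.taxon_namespace
        )
        assert bipartitions(est) == bipartitions(sk_dendro)


def test_nj_star_has_zero_internal_branches():
    d = np.full((4, 4), 0.2)
    np.fill_diagonal(d, 0)
    t = nj_tree(dm("ABCD", d))
    internal = [
        e.length
        for e in t.preorder_edge_iter()
        if e.head_node is not None
        and not e.head_node.is_leaf()
        and e.head_node.parent_node is not None
    ]
    assert all(length == pytest.approx(0.0, abs=1e-12) for length in internal)


def test_nj_rejects_undefined_and_tiny_inputs():
    with pytest.raises(ValueError):
        nj_tree(dm("AB", [[0, 0.1], [0.1, 0]]))
    d = np.array([[0, np.nan, 0.1], [np.nan, 0, 0.1], [0.1, 0.1, 0]])
    with pytest.raises(ValueError, match="undefined"):
        nj_tree(dm("ABC", d))


@pytest.fixture
def five_leaf_tree():
    rng = np.random.default_rng(3)
    _, m = random_additive_tree(rng, 5)
    return nj_tree(m)


def test_rooting_single_leaf_outgroup(five_leaf_tree):
    total = tree_length(five_leaf_tree)
    rooted = root_on_outgroup(five_leaf_tree, ["t0"])
    assert rooted.is_rooted
    children = rooted.seed_node.child_nodes()
    sides = [{l.taxon.label for l in c.leaf_iter()} for c in children]
    assert {"t0"} in sides
    assert {l.taxon.label for l in rooted.leaf_node_iter()} == {
        l.taxon.label for l in five_leaf_tree.leaf_node_iter()
    }
    assert tree_length(rooted) == pytest.approx(total)


def test_rooting_on_outgroup_clade():
    # ((A,B),(C,D)) unrooted: {C,D} is a clade usable as outgroup
    m = dm(
        "ABCD",
        [
            [0, 0.02, 0.2, 0.21],
            [0.02, 0, 0.21, 0.22],
            [0.2, 0.21, 0, 0.03],
            [0.21, 0.22, 0.03, 0],
        ],
    )
    rooted = root_on_outgroup(nj_tree(m), ["C", "D"])
    sides = [
        {l.taxon.label for l in c.leaf_iter()} for c in rooted.seed_node.child_nodes()
    ]
    assert {"C", "D"} in sides


def test_rooting_interleaved_outgroup_errors():
    m = dm(
        "ABCD",
        [
            [0, 0.02, 0.2, 0.21],
            [0.02, 0, 0.21, 0.22],
            [0.2, 0.21, 0, 0.03],
            [0.21, 0.22, 0.03, 0],
        ],
    )
    with pytest.raises(ValueError, match="monophyletic"):
        root_on_outgroup(nj_tree(m), ["A", "C"])


def tree_from_newick(s):
    return dendropy.Tree.get(data=s, schema="newick")


def test_monophyly_cases():
    t = tree_from_newick("((a1:1,(a2:1,x1:1):1):1,(b1:1,b2:1):1);")
    t.is_rooted = True
    labels = {"a1": "Alpha una", "a2": "Alpha una", "x1": None,
              "b1": "Beta dua", "b2": "Beta dua"}
    # unidentified leaf inside the Alpha clade does not break monophyly
    assert is_monophyletic(t, labels, "Alpha una")
    assert is_monophyletic(t, labels, "Beta dua")

    t2 = tree_from_newick("((a1:1,b1:1):1,(a2:1,b2:1):1);")
    t2.is_rooted = True
    labels2 = {"a1": "Alpha una", "a2": "Alpha una", "b1": "Beta dua", "b2": "Beta dua"}
    assert not is_monophyletic(t2, labels2, "Alpha una")
    assert not is_monophyletic(t2, labels2, "Beta dua")


def test_monophyly_singleton_and_missing_species():
    t = tree_from_newick("((a1:1,b1:1):1,c1:1);")
    t.is_rooted = True
    labels = {"a1": "Alpha una", "b1": "Beta dua", "c1": "Gamma tria"}
    assert is_monophyletic(t, labels, "Gamma tria")
    with pytest.raises(ValueError):
        is_monophyletic(t, labels, "Delta quattuor")


def test_monophyly_matches_brute_force_enumeration():
    """Agreement with clade enumeration: monophyletic iff some clade
    contains all target leaves and no identified foreign leaf."""
    rng = np.random.default_rng(11)
    species_pool = ["Alpha una", "Beta dua", "Gamma tria", None]
    for _ in range(30):
        n = int(rng.integers(4, 11))
        _, m = random_additive_tree(rng, n)
        t = nj_tree(m)
        rooted = root_on_outgroup(t, [m.ids[0]])
        labels = {seq_id: species_pool[rng.integers(0, 4)] for seq_id in m.ids}
        clades = []
        for node in rooted.preorder_node_iter():
            clades.append({l.taxon.label for l in node.leaf_iter()})
        for species in {v for v in labels.values() if v}:
            target = {i for i, v in labels.items() if v == species}
            if not target:
                continue
            oracle = any(
                target <= clade
                and all(labels.get(x) in (None, species) for x in clade)
                for clade in clades
            )
            assert is_monophyletic(rooted, labels, species) == oracle


def test_newick_round_trip(tmp_path, five_leaf_tree):
    path = tmp_path / "tree.nwk"
    write_newick(five_leaf_tree, path)
    back = read_newick(path)
    assert {l.taxon.label for l in back.leaf_node_iter()} == {
        l.taxon.label for l in five_leaf_tree.leaf_node_iter()
    }
    assert tree_length(back) == pytest.approx(tree_length(five_leaf_tree))
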