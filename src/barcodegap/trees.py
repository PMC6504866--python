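"""Neighbor-joining trees, outgroup rooting and species monophyly.

The external maximum-likelihood and Bayesian trees a curation study relies
on can be imported as Newick and used anywhere a tree is expected; the
neighbor-joining builder here is the dependency-free fallback for distance
matrices produced in-house, not a claim of equivalence to ML inference.

Trees are dendropy ``Tree`` objects throughout, so Newick round-tripping,
bipartitions and rerooting come from that library; the NJ agglomeration
itself (Saitou & Nei Q-criterion, deterministic ties, non-negative branch
lengths) is implemented here.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import dendropy
import numpy as np

from .distances import DistanceMatrix

__all__ = [
    "nj_tree",
    "root_on_outgroup",
    "is_monophyletic",
    "read_newick",
    "write_newick",
    "tree_length",
]


def _clamp(li: float, lj: float) -> tuple[float, float]:
    """Clamp a negative branch estimate to 0, moving the deficit to the
    sister branch so the pair's path length is preserved."""
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def nj_tree(m: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining.

    Deterministic: Q-criterion ties are broken by the smallest (i, j) index
    pair in the current working order.  Negative branch-length estimates
    are clamped to 0 with the deficit transferred to the sister branch.
    The returned tree is unrooted (trifurcating seed node).
    """
    n = len(m.ids)
    if n < 3:
        raise ValueError("need at least 3 sequences for neighbor joining")
    if np.isnan(m.d).any():
        raise ValueError(
            "distance matrix has undefined entries; impute or drop them first"
        )

    taxa = dendropy.TaxonNamespace(m.ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = [dendropy.Node(taxon=taxa.get_taxon(seq_id)) for seq_id in m.ids]
    d = m.d.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        k = len(active)
        sub = d[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        q = (k - 2) * sub - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        # row-major argmin = smallest (i, j) on ties
        i, j = divmod(int(np.argmin(q)), k)
        if i > j:
            i, j = j, i
        a, b = active[i], active[j]
        li = 0.5 * sub[i, j] + (row_sums[i] - row_sums[j]) / (2 * (k - 2))
        lj = sub[i, j] - li
        li, lj = _clamp(li, lj)

        parent = dendropy.Node()
        parent.add_child(nodes[a])
        parent.add_child(nodes[b])
        nodes[a].edge.length = li
        nodes[b].edge.length = lj
        nodes.append(parent)
        d = np.pad(d, ((0, 1), (0, 1)))
        new = d.shape[0] - 1
        for x in active:
            if x in (a, b):
                continue
            d[new, x] = d[x, new] = 0.5 * (d[a, x] + d[b, x] - d[a, b])
        active = [x for x in active if x not in (a, b)] + [new]

    # join the final three around the seed node (three-point formulas)
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for x, lx in ((a, la), (b, lb), (c, lc)):
        tree.seed_node.add_child(nodes[x])
        nodes[x].edge.length = max(lx, 0.0)
    tree.is_rooted = False
    return tree


def _leaf_names(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def root_on_outgroup(tree: dendropy.Tree, outgroup_ids: Iterable[str]) -> dendropy.Tree:
    """Root a tree on the branch separating the outgroup from everything else.

    The outgroup must be a single leaf or form a clade in the unrooted
    tree; otherwise the offending arrangement is reported.
    """
    outgroup = set(outgroup_ids)
    tree = tree.clone(depth=1)
    all_leaves = _leaf_names(tree)
    missing = outgroup - all_leaves
    if missing:
        raise ValueError(f"outgroup ids not in tree: {sorted(missing)}")
    if outgroup == all_leaves:
        raise ValueError("outgroup cannot be the whole tree")

    tree.encode_bipartitions()
    target = None
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        leafset = {
            leaf.taxon.label for leaf in edge.head_node.leaf_iter()
        }
        if leafset == outgroup or (all_leaves - leafset) == outgroup:
            target = edge
            break
    if target is None:
        raise ValueError(
            f"outgroup is not monophyletic in the unrooted tree: {sorted(outgroup)}"
        )
    length = target.length or 0.0
    tree.reroot_at_edge(target, length1=length / 2.0, length2=length / 2.0)
    tree.is_rooted = True
    return tree


def is_monophyletic(
    tree: dendropy.Tree, labels: Mapping[str, str | None], species: str
) -> bool:
    """Is a species' set of leaves an exclusive clade?

    The smallest clade containing every leaf of the species must contain no
    *identified* leaf of another species; leaves not identified to species
    (``labels[id] is None`` or absent) are transparent and never break
    monophyly.
    """
    target = {
        leaf.taxon.label
        for leaf in tree.leaf_node_iter()
        if labels.get(leaf.taxon.label) == species
    }
    if not target:
        raise ValueError(f"species {species!r} has no leaves in the tree")
    if len(target) == 1:
        return True
    mrca = tree.mrca(taxa=[tree.taxon_namespace.get_taxon(t) for t in target])
    for leaf in mrca.leaf_iter():
        name = leaf.taxon.label
        sp = labels.get(name)
        if sp is not None and sp != species:
            return False
    return True


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def tree_length(tree: dendropy.Tree) -> float:
    return sum(e.length or 0.0 for e in tree.preorder_edge_iter())
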