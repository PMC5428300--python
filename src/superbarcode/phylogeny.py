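"""Distance trees with bootstrap support for species delimitation.

Trees are built by canonical neighbor-joining (NJ) on uncorrected
p-distances — at the 0.1–0.6% divergence typical of congeneric plastomes,
p-distances are effectively additive and NJ recovers the generating
topology.  Branch support comes from the column bootstrap: alignment columns
are resampled with replacement, the difference matrix and NJ tree are
rebuilt, and the support of each internal edge of the full-data tree is the
percentage of replicates containing the same bipartition.

Trees are :class:`dendropy.Tree` objects; bootstrap supports are stored as
internal-node labels (integer percents), which is also how they appear in
the Newick output.
"""

from __future__ import annotations

import logging
from typing import Sequence

import dendropy
import numpy as np

from .alignment import Msa
from .divergence import DiffMatrix, _pair_diff_masks, pairwise_difference_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "nj_tree",
    "bootstrap_support",
    "collapse_low_support",
    "rf_distance",
    "bipartitions",
    "read_newick",
    "write_newick",
]


# --------------------------------------------------------------------------
# Neighbor joining
# --------------------------------------------------------------------------

def _nj_topology(d: np.ndarray) -> list:
    """Run NJ on a distance matrix; return a nested (child, length) structure.

    Returns the children of the unrooted seed node as a list of
    ``(subtree, branch_length)`` where a subtree is either a leaf index or a
    list of two such pairs.  Ties in the Q criterion are broken by the lowest
    (i, j) index pair; negative branch-length estimates are clamped to 0.
    """
    d = np.array(d, dtype=float)
    n = d.shape[0]
    nodes: list = list(range(n))  # leaf index or [(sub, len), (sub, len)]
    active = list(range(n))

    def clamp(x: float) -> float:
        if x < 0:
            logger.debug("negative NJ branch length %.3g clamped to 0", x)
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (i, j) among minima
        qmin = q.min()
        ii, jj = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))[0]
        if ii > jj:
            ii, jj = jj, ii
        a, b = active[ii], active[jj]
        dij = sub[ii, jj]
        la = clamp(0.5 * dij + (r[ii] - r[jj]) / (2 * (m - 2)))
        lb = clamp(dij - (0.5 * dij + (r[ii] - r[jj]) / (2 * (m - 2))))
        new = [(nodes[a], la), (nodes[b], lb)]
        # distances from the new node to every other active node
        dnew = 0.5 * (d[a, active] + d[b, active] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        k = d.shape[0] - 1
        d[k, active] = dnew
        d[active, k] = dnew
        d[k, k] = 0.0
        nodes.append(new)
        active = [x for x in active if x not in (a, b)] + [k]

    if len(active) == 3:
        a, b, c = active
        dab, dac, dbc = d[a, b], d[a, c], d[b, c]
        la = clamp(0.5 * (dab + dac - dbc))
        lb = clamp(0.5 * (dab + dbc - dac))
        lc = clamp(0.5 * (dac + dbc - dab))
        return [(nodes[a], la), (nodes[b], lb), (nodes[c], lc)]
    if len(active) == 2:
        a, b = active
        return [(nodes[a], clamp(d[a, b])), (nodes[b], 0.0)]
    return [(nodes[active[0]], 0.0)]


def _build_dendropy(
    children: list, taxa: Sequence[str], tns: dendropy.TaxonNamespace
) -> dendropy.Tree:
    tree = dendropy.Tree(taxon_namespace=tns)

    def attach(parent: dendropy.Node, sub, length: float) -> None:
        node = dendropy.Node()
        node.edge.length = length
        if isinstance(sub, int):
            node.taxon = tns.get_taxon(taxa[sub])
        else:
            for child, clen in sub:
                attach(node, child, clen)
        parent.add_child(node)

    for sub, length in children:
        attach(tree.seed_node, sub, length)
    tree.is_rooted = False
    return tree


def nj_tree(
    dm: DiffMatrix, taxon_namespace: dendropy.TaxonNamespace | None = None
) -> dendropy.Tree:
    """Canonical neighbor-joining tree from a pairwise difference matrix.

    Distances are the matrix's unrounded p-distances (fractions of sites).
    Deterministic: ties in the join criterion go to the lowest taxon-index
    pair.  Needs at least 3 taxa.
    """
    if len(dm.taxa) < 3:
        raise ValueError("nj_tree needs at least 3 taxa")
    d = dm.distances()
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    tns = taxon_namespace or dendropy.TaxonNamespace(dm.taxa)
    children = _nj_topology(d)
    return _build_dendropy(children, dm.taxa, tns)


# --------------------------------------------------------------------------
# Bipartitions & Robinson–Foulds
# --------------------------------------------------------------------------

def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as canonical leaf-label sets.

    Each internal edge splits the leaves in two; the side *not* containing
    the lexicographically smallest label is the canonical representation.
    """
    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    ref = labels[0]
    all_set = frozenset(labels)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if ref in side:
            side = all_set - side
        if 1 < len(side) < len(labels) - 1:
            out.add(side)
    return out


def rf_distance(a: dendropy.Tree, b: dendropy.Tree) -> int:
    """Robinson–Foulds symmetric difference of internal bipartitions."""
    la = {leaf.taxon.label for leaf in a.leaf_node_iter()}
    lb = {leaf.taxon.label for leaf in b.leaf_node_iter()}
    if la != lb:
        raise ValueError(f"leaf sets differ: {sorted(la ^ lb)}")
    return len(bipartitions(a) ^ bipartitions(b))


# --------------------------------------------------------------------------
# Bootstrap
# --------------------------------------------------------------------------

def bootstrap_support(
    msa: Msa,
    n_reps: int = 1000,
    seed: int = 0,
    mode: str = "alignment_length",
) -> dendropy.Tree:
    """NJ tree with column-bootstrap support values.

    Columns are resampled with replacement ``n_reps`` times; each replicate's
    NJ tree contributes to the support (percent of replicates) of every
    internal edge of the full-data tree.  Supports are stored as internal
    node labels.  With fewer than 4 taxa there are no internal edges and the
    tree is returned without supports.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    full_dm = pairwise_difference_matrix(msa, mode=mode)
    tree = nj_tree(full_dm)
    if msa.n_taxa < 4:
        return tree

    # per-pair difference indicators over columns: a replicate's count matrix
    # is a weighted column sum, with multinomial resampling weights
    diff, _comp = _pair_diff_masks(msa)
    diff = diff.astype(np.float64)
    L = msa.length
    n = msa.n_taxa
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    rng = np.random.default_rng(seed)

    occurrences: dict[frozenset[str], int] = {bp: 0 for bp in bipartitions(tree)}
    tns = dendropy.TaxonNamespace(msa.taxa)
    for _ in range(n_reps):
        w = rng.multinomial(L, np.full(L, 1.0 / L))
        counts = diff @ w
        d = np.zeros((n, n))
        for p, (i, j) in enumerate(pairs):
            d[i, j] = d[j, i] = counts[p] / L
        rep_tree = _build_dendropy(_nj_topology(d), msa.taxa, tns)
        for bp in bipartitions(rep_tree):
            if bp in occurrences:
                occurrences[bp] += 1

    labels = sorted(msa.taxa)
    ref = labels[0]
    all_set = frozenset(labels)
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if ref in side:
            side = all_set - side
        if 1 < len(side) < len(labels) - 1:
            pct = int(round(100.0 * occurrences[side] / n_reps))
            node.label = str(pct)
    return tree


def collapse_low_support(tree: dendropy.Tree, threshold: float) -> dendropy.Tree:
    """Contract internal edges with support below ``threshold`` (percent).

    Nodes without a numeric support label are left untouched; the leaf set is
    unchanged.  Collapsing at threshold 0 is the identity; a threshold above
    100 yields the star tree (for a fully labelled tree).
    """
    out = tree.clone(depth=1)
    to_collapse = []
    for node in out.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        if node.label is None:
            continue
        try:
            support = float(node.label)
        except ValueError:
            continue
        if support < threshold:
            to_collapse.append(node.edge)
    for edge in to_collapse:
        edge.collapse()
    return out


# --------------------------------------------------------------------------
# Newick I/O
# --------------------------------------------------------------------------

def read_newick(source: str) -> dendropy.Tree:
    """Read a Newick tree from a string or a file path."""
    import os

    if os.path.exists(source):
        return dendropy.Tree.get(path=source, schema="newick")
    return dendropy.Tree.get(data=source, schema="newick")


def write_newick(tree: dendropy.Tree, path: str | None = None) -> str:
    """Serialize with supports as internal-node labels, 6 significant digits."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".6g",
    ).strip()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s + "\n")
    return s
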