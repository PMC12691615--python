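"""Distance-based phylogenetics on concatenated core genes.

Trees are :class:`dendropy.Tree` objects throughout.  Alignments are thin
numpy-backed containers (one row per taxon, nucleotides coded 0..3, missing
data coded 4).  Tree building is neighbor joining on Jukes-Cantor distances;
tree comparison is the Robinson-Foulds bipartition distance normalised to a
0-100 scale, after pruning both trees to their shared leaf set.

The hot path used by the gene-tree resampling machinery bypasses dendropy:
``nj_bipartitions`` runs NJ on a distance matrix and returns the set of
non-trivial bipartitions directly as integer bitmasks over a fixed taxon
order, so that tens of thousands of replicate trees can be compared cheaply.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

NUC = "ACGT"
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _c in enumerate(NUC):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i

#: distance assigned to saturated pairs (observed divergence >= 0.75)
D_MAX = 5.0


def encode_seq(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8 codes (A,C,G,T -> 0..3, other -> 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_seq(codes: np.ndarray) -> str:
    out = np.full(codes.shape, ord("N"), dtype=np.uint8)
    for i, c in enumerate(NUC):
        out[codes == i] = ord(c)
    return out.tobytes().decode("ascii")


@dataclass
class Alignment:
    """A multiple sequence alignment with equal-length rows.

    Parameters
    ----------
    taxa : ordered taxon labels, unique.
    data : int8 array of shape (n_taxa, length); 0..3 = ACGT, 4 = gap/N.
    gene_id : identifier of the source gene family (optional).
    """

    taxa: list[str]
    data: np.ndarray
    gene_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.taxa):
            raise ValueError("data must be (n_taxa, length)")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")

    @property
    def length(self) -> int:
        return self.data.shape[1]

    def sequence(self, taxon: str) -> str:
        return decode_seq(self.data[self.taxa.index(taxon)])

    def subset(self, taxa: list[str]) -> "Alignment":
        idx = [self.taxa.index(t) for t in taxa]
        return Alignment(list(taxa), self.data[idx], self.gene_id)

    @classmethod
    def from_strings(cls, pairs, gene_id: str = "") -> "Alignment":
        taxa = [t for t, _ in pairs]
        data = np.stack([encode_seq(s) for _, s in pairs])
        return cls(taxa, data, gene_id)

    def to_fasta(self, handle) -> None:
        for t, row in zip(self.taxa, self.data):
            handle.write(f">{t}\n{decode_seq(row)}\n")


def concatenate_alignments(alns: list[Alignment]) -> Alignment:
    """Row-wise concatenation of alignments over an identical taxon set.

    Taxon order follows the first alignment; later alignments may list taxa
    in any order but must contain exactly the same set.
    """
    if not alns:
        raise ValueError("no alignments to concatenate")
    taxa = list(alns[0].taxa)
    ref = set(taxa)
    blocks = [alns[0].data]
    for a in alns[1:]:
        if set(a.taxa) != ref:
            raise ValueError("taxon sets differ between alignments")
        idx = [a.taxa.index(t) for t in taxa]
        blocks.append(a.data[idx])
    return Alignment(taxa, np.concatenate(blocks, axis=1))


# ---------------------------------------------------------------------------
# pairwise distances
# ---------------------------------------------------------------------------

def pairwise_diff_counts(aln: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair counts of differing and comparable (both non-missing) sites.

    Returns two symmetric (n, n) integer matrices; the diagonal is zero /
    the sequence's non-missing length.
    """
    X = aln.data
    n = X.shape[0]
    ok = X < 4
    diffs = np.zeros((n, n), dtype=np.int64)
    comp = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = ok[i] & ok[i + 1:]
        ne = (X[i] != X[i + 1:]) & both
        diffs[i, i + 1:] = ne.sum(axis=1)
        comp[i, i + 1:] = both.sum(axis=1)
    diffs += diffs.T
    comp += comp.T
    np.fill_diagonal(comp, ok.sum(axis=1))
    return diffs, comp


def jc69_from_p(p: np.ndarray) -> np.ndarray:
    """Jukes-Cantor distance from observed proportion of differing sites.

    Saturated entries (p >= 0.75) are capped at :data:`D_MAX`.
    """
    p = np.asarray(p, dtype=float)
    d = np.full(p.shape, D_MAX, dtype=float)
    ok = p < 0.75
    with np.errstate(divide="ignore"):
        d[ok] = -0.75 * np.log1p(-4.0 * p[ok] / 3.0)
    return d


def jc69_distances(aln: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """JC69 distance matrix for an alignment, with pairwise deletion.

    Returns ``(D, saturated)`` where ``saturated`` marks capped entries.
    Pairs with zero comparable sites are also capped and flagged.
    """
    if len(aln.taxa) < 2:
        raise ValueError("need at least two sequences")
    diffs, comp = pairwise_diff_counts(aln)
    with np.errstate(invalid="ignore"):
        p = np.where(comp > 0, diffs / np.maximum(comp, 1), 1.0)
    np.fill_diagonal(p, 0.0)
    D = jc69_from_p(p)
    np.fill_diagonal(D, 0.0)
    saturated = (p >= 0.75) | ((comp == 0) & ~np.eye(len(aln.taxa), dtype=bool))
    return D, saturated


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def _nj_topology(D: np.ndarray):
    """Core NJ agglomeration.

    Returns ``(children, lengths, root_children)`` where ``children`` maps an
    internal node id to its two joined child ids, ``lengths`` maps a node id
    to its pendant branch length, and ``root_children`` are the final three
    (or two) nodes joined into the unrooted "root".  Leaf ids are 0..n-1;
    internal ids count upward from n.  Ties in the Q matrix are broken by the
    smallest (i, j) index pair, so the result is deterministic in the input
    order of the matrix.
    """
    D = np.array(D, dtype=float)
    n = D.shape[0]
    active = list(range(n))
    ids = list(range(n))
    children: dict[int, tuple[int, int]] = {}
    lengths: dict[int, float] = {}
    next_id = n
    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # smallest (i, j) among minima: flatten index order is row-major,
        # argmin already returns the first occurrence
        k = int(np.argmin(Q))
        i, j = divmod(k, m)
        if i > j:
            i, j = j, i
        a, b = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        # clamp negative pendant lengths, moving the deficit to the sister
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li = max(li, 0.0)
        lj = max(lj, 0.0)
        u = next_id
        next_id += 1
        children[u] = (a, b)
        lengths[a] = li
        lengths[b] = lj
        # Studier-Keppler update for the new node's distances
        D = np.pad(D, ((0, 1), (0, 1)))
        D[u, :u] = 0.5 * (D[a, :u] + D[b, :u] - dij)
        D[:u, u] = D[u, :u]
        active = [x for x in active if x not in (a, b)] + [u]
    if len(active) == 2:
        a, b = active
        lengths[a] = D[a, b] / 2.0
        lengths[b] = D[a, b] / 2.0
        root_children = (a, b)
    else:
        root_children = tuple(active)
    return children, lengths, root_children


def neighbor_joining(D: np.ndarray, labels: list[str]) -> dendropy.Tree:
    """Neighbor joining (Saitou-Nei with Studier-Keppler branch lengths).

    ``D`` must be a symmetric matrix over at least three taxa.  Negative
    branch lengths are clamped to zero with the deficit moved to the sister
    branch of the same join.  The returned tree is unrooted (trifurcating
    seed node) with leaf labels taken from ``labels``.
    """
    D = np.asarray(D, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be square and symmetric")
    if D.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if len(labels) != D.shape[0]:
        raise ValueError("label count does not match matrix size")
    children, lengths, root_children = _nj_topology(D)

    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)

    def build(nid: int) -> dendropy.Node:
        node = dendropy.Node()
        if nid < len(labels):
            node.taxon = taxa.get_taxon(labels[nid])
        else:
            for c in children[nid]:
                node.add_child(build(c))
        node.edge.length = float(lengths.get(nid, 0.0))
        return node

    for c in root_children:
        tree.seed_node.add_child(build(c))
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# bipartitions and Robinson-Foulds
# ---------------------------------------------------------------------------

def _canonical(mask: int, full: int) -> int:
    other = full ^ mask
    return mask if mask < other else other


def nj_bipartitions(D: np.ndarray) -> frozenset[int]:
    """Run NJ and return the tree's non-trivial bipartitions as bitmasks.

    Taxon ``i`` corresponds to bit ``i``; each bipartition is represented by
    the lexicographically smaller of the two complementary leaf sets.  This
    is the fast path for resampling loops: no tree object is built.
    """
    n = D.shape[0]
    children, _, root_children = _nj_topology(D)
    full = (1 << n) - 1
    masks: dict[int, int] = {i: 1 << i for i in range(n)}
    out = set()
    order = sorted(children)  # internal ids are created in increasing order
    for u in order:
        a, b = children[u]
        masks[u] = masks[a] | masks[b]
    for u in order:
        m = masks[u]
        pc = bin(m).count("1")
        if 2 <= pc <= n - 2:
            out.add(_canonical(m, full))
    return frozenset(out)


def tree_bipartitions(tree: dendropy.Tree, taxon_order: list[str]) -> frozenset[int]:
    """Non-trivial bipartitions of a tree as bitmasks over ``taxon_order``."""
    index = {t: i for i, t in enumerate(taxon_order)}
    n = len(taxon_order)
    full = (1 << n) - 1
    out = set()
    masks: dict[int, int] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            masks[id(node)] = 1 << index[node.taxon.label]
        else:
            m = 0
            for c in node.child_nodes():
                m |= masks[id(c)]
            masks[id(node)] = m
            pc = bin(m).count("1")
            if node.parent_node is not None and 2 <= pc <= n - 2:
                out.add(_canonical(m, full))
    return frozenset(out)


def rf_from_bipartitions(b1: frozenset[int], b2: frozenset[int]) -> float:
    """Normalised RF on a 0-100 scale from two bipartition sets.

    The denominator is the total number of non-trivial internal edges of the
    two trees (2(n-3) when both are fully resolved), so 100 remains
    attainable for multifurcating trees.  Two star trees are at distance 0.
    """
    denom = len(b1) + len(b2)
    if denom == 0:
        return 0.0
    return 100.0 * len(b1 ^ b2) / denom


def normalized_rf(t1: dendropy.Tree, t2: dendropy.Tree) -> float:
    """Robinson-Foulds topological distance between two trees, scaled 0-100.

    Trees are first pruned to their shared leaf set (at least four shared
    leaves required); 0 means identical topologies, 100 means no shared
    non-trivial bipartition.
    """
    l1 = {lf.taxon.label for lf in t1.leaf_node_iter()}
    l2 = {lf.taxon.label for lf in t2.leaf_node_iter()}
    shared = sorted(l1 & l2)
    if len(shared) < 4:
        raise ValueError("fewer than 4 shared leaves between trees")

    def restricted(t: dendropy.Tree, leaves: set[str]) -> dendropy.Tree:
        if {lf.taxon.label for lf in t.leaf_node_iter()} == leaves:
            return t
        tt = t.clone(depth=1)
        tt.retain_taxa_with_labels(sorted(leaves))
        return tt

    sset = set(shared)
    b1 = tree_bipartitions(restricted(t1, sset), shared)
    b2 = tree_bipartitions(restricted(t2, sset), shared)
    return rf_from_bipartitions(b1, b2)


# ---------------------------------------------------------------------------
# Newick / VCV helpers
# ---------------------------------------------------------------------------

def read_newick(source: str) -> dendropy.Tree:
    """Read a Newick tree from a string or a file path."""
    if "(" in source:
        return dendropy.Tree.get(data=source, schema="newick")
    return dendropy.Tree.get(path=source, schema="newick")


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def tree_vcv(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Brownian-motion covariance matrix of a tree's tips.

    Entry (i, j) is the root-to-MRCA path length shared by tips i and j;
    the diagonal holds root-to-tip depths.
    """
    tree = tree.clone(depth=1)
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    leaves = sorted(tree.leaf_node_iter(), key=lambda n: n.taxon.label)
    taxa = [n.taxon.label for n in leaves]
    n = len(taxa)
    # accumulate shared depth clade-by-clade: for each internal node, every
    # pair of tips whose MRCA is that node shares its root distance
    idx = {id(n): i for i, n in enumerate(leaves)}
    C = np.zeros((n, n))
    below: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = [idx[id(node)]]
            C[idx[id(node)], idx[id(node)]] = node.root_distance
        else:
            kids = [below[id(c)] for c in node.child_nodes()]
            depth = node.root_distance or 0.0
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for i in kids[a]:
                        C[i, kids[b]] = depth
                        C[kids[b], i] = depth
            below[id(node)] = [i for k in kids for i in k]
    return taxa, C
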