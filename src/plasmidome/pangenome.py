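"""Gene-family presence/absence, gene-content ordination, and enrichment.

Gene families are single-linkage clusters of CDS sequences (two genes are
linked when their global identity is at least 90% over at least 80% of the
shorter sequence; edit distances from edlib, candidate pairs prefiltered by
shared 16-mers).  Presence/absence matrices feed a Jaccard distance matrix
and classical metric multidimensional scaling (PCoA, cmdscale-style double
centering).  Functional-category enrichment on a replicon type against a
background gene pool uses Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform


# ---------------------------------------------------------------------------
# gene family clustering
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, a):
        p = self.parent
        while p[a] != a:
            p[a] = p[p[a]]
            a = p[a]
        return a

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def pair_identity(a: str, b: str) -> float:
    """Global (NW) identity of two sequences: 1 - editdist / longer length."""
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def cluster_gene_families(
    genes: dict[str, str],
    min_identity: float = 0.9,
    min_coverage: float = 0.8,
    probe_k: int = 16,
) -> dict[str, str]:
    """Single-linkage clustering of CDS sequences into gene families.

    Two genes are linked iff the shorter is at least ``min_coverage`` of
    the longer (length compatibility) and their global identity is at least
    ``min_identity``.  Families are connected components of the link graph;
    the family id is the lexicographically smallest member id, so output is
    stable under input order.  Candidate pairs are prefiltered by a shared
    ``probe_k``-mer (exact linkage is still verified by alignment), which
    keeps the all-vs-all step near-linear for diverged inputs.
    """
    if not genes:
        return {}
    ids = sorted(genes)
    uf = _UnionFind(ids)
    # inverted index over probe k-mers (sampled every probe_k/2 positions)
    index: dict[str, list[str]] = {}
    step = max(probe_k // 2, 1)
    for gid in ids:
        s = genes[gid]
        for i in range(0, max(len(s) - probe_k + 1, 1), step):
            index.setdefault(s[i:i + probe_k], []).append(gid)
    seen: set[tuple[str, str]] = set()
    for bucket in index.values():
        if len(bucket) < 2:
            continue
        for i in range(len(bucket)):
            for j in range(i + 1, len(bucket)):
                a, b = bucket[i], bucket[j]
                if a == b:
                    continue
                key = (a, b) if a < b else (b, a)
                if key in seen or uf.find(a) == uf.find(b):
                    continue
                seen.add(key)
                sa, sb = genes[a], genes[b]
                if min(len(sa), len(sb)) < min_coverage * max(len(sa), len(sb)):
                    continue
                if pair_identity(sa, sb) >= min_identity:
                    uf.union(a, b)
    comp: dict[str, list[str]] = {}
    for gid in ids:
        comp.setdefault(uf.find(gid), []).append(gid)
    out = {}
    for members in comp.values():
        fam = min(members)
        for gid in members:
            out[gid] = fam
    return out


def presence_absence(
    gene_table: pd.DataFrame,
    family_col: str = "family",
    unit_col: str = "strain",
) -> pd.DataFrame:
    """Binary unit x family matrix from a long gene table.

    ``gene_table`` needs one row per gene copy with at least the unit
    (strain or replicon) and family columns; empty families cannot occur by
    construction.
    """
    m = pd.crosstab(gene_table[unit_col], gene_table[family_col])
    return (m > 0).astype(np.int8)


# ---------------------------------------------------------------------------
# core genes and overlaps
# ---------------------------------------------------------------------------

def core_genes(m: pd.DataFrame, members: list[str]) -> list[str]:
    """Families present in every listed member row of the matrix."""
    if not list(members):
        raise ValueError("empty member set")
    sub = m.loc[list(members)]
    return sorted(sub.columns[(sub > 0).all(axis=0)])


def core_overlap(core_a, core_b) -> float:
    """Shared fraction of two core gene sets: |A n B| / min(|A|, |B|).

    The smaller core is the denominator so that a subset relationship
    scores 1.0; pass sets or lists of family ids.
    """
    a, b = set(core_a), set(core_b)
    if not a or not b:
        raise ValueError("core sets must be non-empty")
    return len(a & b) / min(len(a), len(b))


def jaccard_distance_matrix(m: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Jaccard distance (1 - |i n j| / |i u j|) between binary rows.

    All-zero rows are flagged with distance 1 to every other row (0 to
    themselves).
    """
    X = (m.values > 0)
    n = X.shape[0]
    inter = X.astype(np.int32) @ X.astype(np.int32).T
    sizes = X.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        D = 1.0 - np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    empty = sizes == 0
    D[empty, :] = 1.0
    D[:, empty] = 1.0
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=m.index, columns=m.index)


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    """Classical MDS (PCoA) of a distance matrix.

    ``coordinates`` holds one row per sample over the retained positive
    axes; ``eigenvalues`` lists all eigenvalues in descending order
    (negative ones are reported but excluded from the coordinates);
    ``proportion_explained`` is relative to the sum of positive eigenvalues.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(d: pd.DataFrame, m_axes: int = 2) -> OrdinationResult:
    """Principal coordinate analysis (cmdscale): double-center -D^2/2,
    eigendecompose, scale eigenvectors by sqrt(eigenvalue)."""
    D = np.asarray(d, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = 1e-9 * max(abs(vals[0]), 1.0)
    pos = vals > tol
    k = min(m_axes, int(pos.sum()))
    coords = vecs[:, :k] * np.sqrt(vals[:k])
    index = d.index if isinstance(d, pd.DataFrame) else pd.RangeIndex(n)
    cols = [f"axis{i + 1}" for i in range(k)]
    prop = np.where(pos, vals, 0.0) / max(vals[pos].sum(), np.finfo(float).tiny)
    return OrdinationResult(pd.DataFrame(coords, index=index, columns=cols),
                            vals, prop)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def fishers_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test (probability ordering) on a 2x2 table.

    Returns (odds ratio, p).  Tables with a zero margin give p = 1.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return float(odds), float(p)


def category_enrichment(
    gene_categories: pd.Series,
    focal_genes: list[str],
    min_genes: int = 5,
) -> pd.DataFrame:
    """Per-category Fisher enrichment of a focal gene set vs the background.

    ``gene_categories`` maps every background gene id to its functional
    category; ``focal_genes`` is the subset of interest (e.g. all genes on
    one plasmid type).  Categories with fewer than ``min_genes`` background
    genes are skipped.
    """
    focal = set(focal_genes)
    cats = gene_categories
    rows = []
    for cat in sorted(cats.unique()):
        in_cat = cats == cat
        if int(in_cat.sum()) < min_genes:
            continue
        a = int((in_cat & cats.index.isin(focal)).sum())
        b = int(in_cat.sum()) - a
        c = len(focal & set(cats.index)) - a
        d = len(cats) - a - b - c
        odds, p = fishers_exact_2x2([[a, b], [c, d]])
        rows.append((cat, a, b, c, d, odds, p))
    return pd.DataFrame(rows, columns=[
        "category", "focal_in", "background_in", "focal_out", "background_out",
        "odds_ratio", "p_value"])
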