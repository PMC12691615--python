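"""FracMinHash sketching and similarity-network plasmid typing.

Replicon sequences are reduced to FracMinHash sketches: every canonical
k-mer (the lexicographic minimum of a k-mer and its reverse complement) is
hashed to 64 bits and kept iff its hash falls below ``2**64 / scaled``, so a
sketch retains roughly a 1/scaled fraction of distinct k-mers.  The Jaccard
index of two sketches estimates the Jaccard similarity of the underlying
k-mer sets.  Plasmid types are the connected components of the similarity
network thresholded at a minimum Jaccard index; subtypes are re-thresholded
components within a type at a stricter cutoff.

The hash is splitmix64 applied to the 2-bit packed canonical k-mer (with a
fixed XOR seed), chosen so sketches are reproducible across runs and
platforms; it is not sourmash-compatible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

_HASH_SEED = np.uint64(0x9E2021CAFE5EED42)

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
          "XI", "XII", "XIII", "XIV", "XV", "XVI", "XVII", "XVIII", "XIX", "XX"]


def _roman(i: int) -> str:
    return _ROMAN[i] if i < len(_ROMAN) else f"T{i + 1}"


@dataclass
class Sketch:
    """FracMinHash signature of a sequence."""

    k: int
    scaled: int
    hashes: frozenset = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.hashes)


def _splitmix64(x: np.ndarray) -> np.ndarray:
    x = x ^ _HASH_SEED
    x = (x + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = x
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


_ENC = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _ENC[ord(_c)] = _i
    _ENC[ord(_c.lower())] = _i


def canonical_kmers(seq: str, k: int) -> np.ndarray:
    """Distinct canonical k-mers of ``seq`` as 2-bit packed uint64 values.

    k-mers containing any character outside {A, C, G, T} are skipped whole.
    With the encoding A=0 < C=1 < G=2 < T=3, numeric order on packed values
    equals lexicographic order on strings, so the canonical form is the
    numeric minimum of a k-mer and its reverse complement.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > 31:
        raise ValueError("k must be <= 31 to fit 2k bits in uint64")
    codes = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    valid = codes >= 0
    u = codes.astype(np.uint64)
    rc = (np.uint64(3) - u[::-1]) % np.uint64(4)  # reverse complement codes
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    ok = np.ones(n, dtype=bool)
    for i in range(k):
        fwd = (fwd << np.uint64(2)) | u[i:i + n]
        rev = (rev << np.uint64(2)) | rc[i:i + n]
        ok &= valid[i:i + n]
    rev = rev[::-1]  # rev[j] is now the reverse complement of fwd[j]
    canon = np.minimum(fwd, rev)[ok]
    return np.unique(canon)


def sketch_replicon(seq: str, k: int = 31, scaled: int = 10000) -> Sketch:
    """FracMinHash sketch of a replicon sequence.

    Keeps the hashes of canonical k-mers that fall below ``2**64 / scaled``.
    Sequences shorter than k (or containing only ambiguous characters)
    yield an empty sketch.
    """
    if scaled < 1:
        raise ValueError("scaled must be >= 1")
    kmers = canonical_kmers(seq, k)
    if kmers.size == 0:
        return Sketch(k, scaled, frozenset())
    h = _splitmix64(kmers)
    cutoff = np.uint64(2**64 // scaled - 1) if scaled > 1 else np.uint64(0xFFFFFFFFFFFFFFFF)
    kept = h[h <= cutoff] if scaled > 1 else h
    return Sketch(k, scaled, frozenset(int(x) for x in kept))


def jaccard_index(a: Sketch, b: Sketch) -> float:
    """|A n B| / |A u B| of two sketches; 0.0 when both are empty."""
    if a.k != b.k or a.scaled != b.scaled:
        raise ValueError("sketches have mismatched k or scaled")
    union = a.hashes | b.hashes
    if not union:
        return 0.0
    return len(a.hashes & b.hashes) / len(union)


def similarity_matrix(sketches: dict[str, Sketch]) -> pd.DataFrame:
    """All-vs-all Jaccard index matrix (symmetric, diagonal 1 when non-empty)."""
    ids = sorted(sketches)
    n = len(ids)
    M = np.zeros((n, n))
    for i in range(n):
        M[i, i] = 1.0 if len(sketches[ids[i]]) else 0.0
        for j in range(i + 1, n):
            ji = jaccard_index(sketches[ids[i]], sketches[ids[j]])
            M[i, j] = M[j, i] = ji
    return pd.DataFrame(M, index=ids, columns=ids)


def build_type_network(m: pd.DataFrame, min_ji: float = 0.1) -> nx.Graph:
    """Weighted undirected similarity network thresholded at ``min_ji``.

    Nodes are all replicons; an edge (i, j) is present iff JI(i, j) >= min_ji
    (inclusive threshold), weighted by the Jaccard index.
    """
    if not np.allclose(m.values, m.values.T):
        raise ValueError("similarity matrix must be symmetric")
    g = nx.Graph()
    g.add_nodes_from(m.index)
    ids = list(m.index)
    vals = m.values
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if vals[i, j] >= min_ji:
                g.add_edge(ids[i], ids[j], weight=float(vals[i, j]))
    return g


def _ordered_components(members_iter) -> list[list[str]]:
    comps = [sorted(c) for c in members_iter]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


@dataclass
class PlasmidTypeAssignment:
    """Replicon -> (type, subtype) labels from the similarity network.

    Types are connected components labelled I, II, III, ... by descending
    member count (ties broken by smallest member id); single-node components
    are labelled ``singleton``.
    """

    types: dict[str, str]
    subtypes: dict[str, str] = field(default_factory=dict)

    def type_members(self, type_id: str) -> list[str]:
        return sorted(r for r, t in self.types.items() if t == type_id)

    @property
    def type_sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for t in self.types.values():
            out[t] = out.get(t, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [(r, t, self.subtypes.get(r, "")) for r, t in sorted(self.types.items())]
        return pd.DataFrame(rows, columns=["replicon", "type", "subtype"])


def assign_types(graph: nx.Graph) -> PlasmidTypeAssignment:
    """Label the network's connected components as plasmid types."""
    comps = _ordered_components(nx.connected_components(graph))
    types: dict[str, str] = {}
    ti = 0
    for comp in comps:
        if len(comp) == 1:
            label = "singleton"
        else:
            label = _roman(ti)
            ti += 1
        for r in comp:
            types[r] = label
    return PlasmidTypeAssignment(types)


def assign_subtypes(
    members: list[str],
    m: pd.DataFrame,
    subtype_ji: float = 0.5,
    min_ji: float = 0.1,
) -> dict[str, str]:
    """Subtype labels within one type by re-thresholding at ``subtype_ji``.

    Components at the stricter cutoff are labelled a, b, c, ... by
    descending size (ties by smallest member id).
    """
    if subtype_ji <= min_ji:
        raise ValueError("subtype_ji must exceed min_ji")
    sub = m.loc[members, members]
    g = build_type_network(sub, min_ji=subtype_ji)
    out: dict[str, str] = {}
    for i, comp in enumerate(_ordered_components(nx.connected_components(g))):
        label = chr(ord("a") + i) if i < 26 else f"sub{i + 1}"
        for r in comp:
            out[r] = label
    return out


def type_plasmids(
    sequences: dict[str, str],
    k: int = 31,
    scaled: int = 10000,
    min_ji: float = 0.1,
    subtype_ji: float = 0.5,
) -> tuple[PlasmidTypeAssignment, pd.DataFrame, nx.Graph]:
    """Sketch, network, and type/subtype assignment in one call."""
    sketches = {rid: sketch_replicon(s, k=k, scaled=scaled)
                for rid, s in sequences.items()}
    m = similarity_matrix(sketches)
    g = build_type_network(m, min_ji=min_ji)
    assignment = assign_types(g)
    for t in sorted(set(assignment.types.values())):
        if t == "singleton":
            for r in assignment.type_members(t):
                assignment.subtypes[r] = "a"
            continue
        assignment.subtypes.update(
            assign_subtypes(assignment.type_members(t), m, subtype_ji, min_ji))
    return assignment, m, g
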