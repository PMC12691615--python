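"""Gene-tree-resampling inference of plasmid transmission mode.

The central idea: genes that are co-inherited vertically share one
genealogy up to recombination and estimation noise, so the topological
distance between trees built from two random subsets of a replicon's core
genes has a characteristic distribution.  Because the chromosome is
necessarily vertically transmitted, the distribution of GRF distances
between two random sets of *chromosomal* genes is a null for what
"vertically co-inherited" looks like under recombination and tree
uncertainty.  A plasmid whose genes, compared against chromosomal genes,
produce GRF distances above the null's 95th percentile has an evolutionary
history decoupled from the chromosome - the signature of horizontal
transmission.

Each replicate draws gene subsamples (disjoint within a replicate),
concatenates each set, builds a neighbor-joining tree on JC69 distances,
and records the normalised Robinson-Foulds distance (0-100) between the
two trees.  Per-gene pairwise difference counts are precomputed once, so a
replicate costs one matrix sum and two small NJ runs.  Replicate r of a
run with master seed s uses the substream SeedSequence((s, r)), so results
for the first n replicates do not depend on n_reps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .phylo import Alignment, jc69_from_p, nj_bipartitions, rf_from_bipartitions


@dataclass
class GRFDistribution:
    """Resampled GRF values with their provenance."""

    values: np.ndarray
    n_genes: int
    n_reps: int
    seed: int
    comparison: tuple[str, str] = ("", "")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and (self.values.min() < 0 or self.values.max() > 100):
            raise ValueError("GRF values must lie in [0, 100]")


@dataclass
class TransmissionCall:
    replicon: str
    mean: float
    sd: float
    median: float
    fraction_above: float
    threshold: float
    call: str  # "vertical-like" | "decoupled"


def _prepare(alns: list[Alignment], taxa: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-gene pairwise difference/comparable counts over fixed taxa."""
    n = len(taxa)
    G = len(alns)
    diffs = np.empty((G, n, n), dtype=np.int32)
    comp = np.empty((G, n, n), dtype=np.int32)
    for g, aln in enumerate(alns):
        idx = [aln.taxa.index(t) for t in taxa]
        X = aln.data[idx]
        ok = X < 4
        for i in range(n):
            both = ok[i] & ok
            ne = (X[i] != X) & both
            diffs[g, i] = ne.sum(axis=1)
            comp[g, i] = both.sum(axis=1)
    return diffs, comp


def _tree_bits(diffs, comp, gene_idx):
    """Bipartitions of the NJ tree for a concatenation of the given genes."""
    d = diffs[gene_idx].sum(axis=0)
    c = comp[gene_idx].sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(c > 0, d / np.maximum(c, 1), 1.0)
    np.fill_diagonal(p, 0.0)
    D = jc69_from_p(p)
    np.fill_diagonal(D, 0.0)
    return nj_bipartitions(D)


def _rep_rng(seed: int, rep: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=(seed, rep)))


def _effective_n_genes(available: int, n_genes: int, need_two: bool, label: str) -> int:
    need = 2 * n_genes if need_two else n_genes
    if available < 2 * (2 if need_two else 1):
        raise ValueError(f"fewer than two usable core genes for {label}")
    if available < need:
        n_eff = available // 2 if need_two else available
        warnings.warn(
            f"{label}: core of {available} genes too small for n_genes="
            f"{n_genes}; reduced to {n_eff}", stacklevel=3)
        return n_eff
    return n_genes


def within_replicon_grf(
    core_alns: list[Alignment],
    n_genes: int = 100,
    n_reps: int = 1000,
    seed: int = 0,
    replicon: str = "",
) -> GRFDistribution:
    """GRF distribution between trees of two disjoint core-gene subsamples.

    Per replicate: draw two disjoint uniform subsamples of ``n_genes`` core
    genes, concatenate each, build an NJ tree on JC69 distances, and record
    the normalised RF distance between the two trees.  ``n_genes`` is
    reduced (with a warning) to half the core when the core is smaller than
    2 x n_genes, mirroring the use of smaller subsamples on small-core
    elements.
    """
    taxa = sorted(core_alns[0].taxa) if core_alns else []
    if core_alns and any(set(a.taxa) != set(taxa) for a in core_alns):
        raise ValueError("core alignments must share one taxon set")
    G = len(core_alns)
    n_eff = _effective_n_genes(G, n_genes, True, replicon or "replicon")
    diffs, comp = _prepare(core_alns, taxa)
    vals = np.empty(n_reps)
    for r in range(n_reps):
        rng = _rep_rng(seed, r)
        pick = rng.choice(G, size=2 * n_eff, replace=False)
        b1 = _tree_bits(diffs, comp, pick[:n_eff])
        b2 = _tree_bits(diffs, comp, pick[n_eff:])
        vals[r] = rf_from_bipartitions(b1, b2)
    return GRFDistribution(vals, n_eff, n_reps, seed, (replicon, replicon))


def cross_replicon_grf(
    plasmid_alns: list[Alignment],
    chromosome_alns: list[Alignment],
    n_genes: int = 100,
    n_reps: int = 1000,
    seed: int = 0,
    comparison: tuple[str, str] = ("plasmid", "chromosome"),
) -> GRFDistribution:
    """GRF distribution between one plasmid-core and one chromosome-core
    subsample per replicate, over the strains shared by both replicons."""
    shared = sorted(set(plasmid_alns[0].taxa) & set(chromosome_alns[0].taxa))
    if len(shared) < 4:
        raise ValueError("fewer than 4 shared strains between replicons")
    Gp, Gc = len(plasmid_alns), len(chromosome_alns)
    np_eff = _effective_n_genes(Gp, n_genes, False, comparison[0])
    nc_eff = _effective_n_genes(Gc, n_genes, False, comparison[1])
    dp, cp = _prepare(plasmid_alns, shared)
    dc, cc = _prepare(chromosome_alns, shared)
    vals = np.empty(n_reps)
    for r in range(n_reps):
        rng = _rep_rng(seed, r)
        b1 = _tree_bits(dp, cp, rng.choice(Gp, size=np_eff, replace=False))
        b2 = _tree_bits(dc, cc, rng.choice(Gc, size=nc_eff, replace=False))
        vals[r] = rf_from_bipartitions(b1, b2)
    return GRFDistribution(vals, min(np_eff, nc_eff), n_reps, seed, comparison)


def null_threshold(chrom_within: GRFDistribution, pct: float = 95.0) -> float:
    """Empirical percentile (linear interpolation) of the within-chromosome
    null distribution; the classification cutoff for decoupled histories."""
    if chrom_within.values.size == 0:
        raise ValueError("empty null distribution")
    return float(np.percentile(chrom_within.values, pct))


def classify_transmission(cross: GRFDistribution, threshold: float) -> TransmissionCall:
    """Call a replicon decoupled iff the median of its cross-replicon GRF
    distribution exceeds the null threshold; vertical-like otherwise."""
    if cross.values.size == 0:
        raise ValueError("empty distribution")
    v = cross.values
    med = float(np.median(v))
    return TransmissionCall(
        replicon=cross.comparison[0],
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)) if v.size > 1 else 0.0,
        median=med,
        fraction_above=float((v >= threshold).mean()),
        threshold=float(threshold),
        call="decoupled" if med > threshold else "vertical-like",
    )


def summarize_distribution(d: GRFDistribution) -> dict:
    """Mean, sample sd, min, max, and the fraction of replicates at the
    maximum attainable distance of 100."""
    v = d.values
    if v.size == 0:
        raise ValueError("empty distribution")
    return {
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        "min": float(v.min()),
        "max": float(v.max()),
        "fraction_at_max": float((np.abs(v - 100.0) < 1e-9).mean()),
    }
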