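"""Synthetic multipartite-genome populations with known transmission truth.

The generator emulates a natural population of nodule-isolate *Rhizobium*:
each strain carries one chromosome plus several plasmids; plasmid classes
differ in size, core-gene count, horizontal-transfer rate, within-element
recombination, and accessory gene turnover; one HGT-rich class carries
symbiosis marker genes and large insertion blocks that make its size
distribution bimodal.  Every stochastic step is driven by a single master
seed, and all events (transfers, losses, gene gains) are logged so that
downstream inference can be scored against truth.

Model outline
-------------
* The chromosome genealogy is a Kingman coalescent (time in coalescent
  units; while k lineages remain the waiting time is Exp(k(k-1)/2)).
* Plasmid transfer is whole-element replacement: conjugation events are a
  Poisson process on the cell genealogy (rate = hgt_rate x total branch
  length); at an event the recipient cell's plasmid lineage jumps to a
  donor cell lineage chosen uniformly among lineages alive at that time.
  The plasmid genealogy is obtained by sweeping these jumps from the tips
  toward the root.  Loss events prune whole clades of carriers.
* Sequences evolve under JC69 from uniform-random root sequences; each
  gene is independent.  Within-element homologous recombination gives each
  core gene its own genealogy (the element tree perturbed by gene-level
  transfer events at the element's recombination rate).
* Gene content: core families are present in every carrier; accessory
  families switch on/off along branches as a two-state Markov process
  (gain/loss rates); an insertion block is a linked set of families gained
  and lost as a single unit.
* Tip traits follow Brownian motion with Pagel-lambda-scaled covariance,
  plus an optional fixed effect keyed to the focal plasmid's insertion-block
  backbone, and a two-level environment label whose frequency is biased by
  that same backbone.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .phylo import Alignment, decode_seq, tree_vcv, write_newick

FUNCTIONAL_CATEGORIES = ["C", "E", "G", "J", "K", "L", "M", "T", "replication", "transfer"]
SYM_CATEGORY = "symbiosis"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class InsertionBlock:
    """A linked set of gene families gained/lost as one unit.

    ``prob`` is the stationary carrier frequency of the block,
    ``switch_rate`` the total switching intensity (gain rate = prob x
    switch_rate, loss rate = (1 - prob) x switch_rate), ``n_genes`` the
    number of linked families.
    """

    prob: float = 0.5
    n_genes: int = 40
    switch_rate: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prob <= 1.0:
            raise ValueError("block probability must be in [0, 1]")
        if self.n_genes < 1 or self.switch_rate < 0:
            raise ValueError("invalid insertion block")


@dataclass
class PlasmidClassSpec:
    """Transmission and gene-content regime of one plasmid class."""

    name: str
    hgt_rate: float = 0.0          # whole-plasmid transfers / lineage / unit time
    hgt_model: str = "length"      # "length": Poisson on total branch length;
                                   # "pairwise": rate per pair of coexisting
                                   # lineages (conjugation-like, concentrates
                                   # transfers toward the present)
    loss_rate: float = 0.0         # clade losses / lineage / unit time
    gain_rate: float = 0.3         # accessory family gains
    lose_rate: float = 0.3         # accessory family losses
    recomb_rate: float = 0.5       # within-element gene-level transfers
    n_core: int = 200
    n_accessory: int = 30
    insertion_block: InsertionBlock | None = None
    backbone_divergence: float = 0.0   # extra fixed divergence between block backbones
    carries_sym_markers: bool = False
    expected_mode: str | None = None   # "vertical-like" | "decoupled"; None = derive

    def __post_init__(self) -> None:
        for r in (self.hgt_rate, self.loss_rate, self.gain_rate, self.lose_rate,
                  self.recomb_rate):
            if r < 0:
                raise ValueError("rates must be >= 0")
        if self.n_core < 1:
            raise ValueError("n_core must be >= 1")
        if self.hgt_model not in ("length", "pairwise"):
            raise ValueError("hgt_model must be 'length' or 'pairwise'")

    @property
    def expected_call(self) -> str:
        if self.expected_mode is not None:
            return self.expected_mode
        return "decoupled" if self.hgt_rate > 0 else "vertical-like"


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic population."""

    n_strains: int = 62
    plasmid_classes: list[PlasmidClassSpec] = field(default_factory=lambda: default_plasmid_classes())
    mu: float = 0.01               # expected substitutions / site / coalescent unit
    gene_length: int = 300
    n_core_chromosome: int = 400
    n_accessory_chromosome: int = 40
    chrom_recomb_rate: float = 0.5
    spacer_fraction: float = 0.15  # intergenic fraction of each replicon
    trait_lambda: float = 0.1      # phylogenetic signal of the baseline trait
    trait_sigma2: float = 1.0
    clade_effect: float = 5.0      # trait shift keyed to the focal plasmid backbone
    treatment_bias: float = 0.3    # |P(C) - 0.5| keyed to the same backbone
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 3:
            raise ValueError("n_strains must be >= 3")
        if self.gene_length < 1:
            raise ValueError("gene_length must be >= 1")
        if self.mu < 0 or self.trait_sigma2 < 0:
            raise ValueError("rates must be >= 0")
        if not 0 <= self.trait_lambda <= 1:
            raise ValueError("trait_lambda must be in [0, 1]")


def default_plasmid_classes() -> list[PlasmidClassSpec]:
    """Four coexisting plasmid classes mirroring a multipartite *Rhizobium*
    population: two vertically co-inherited elements (II, III; III with low
    internal recombination), one horizontally mobile large element with a
    bimodal size distribution (I), and a small HGT-rich symbiosis element
    (pSym) with a tiny core and its own insertion block."""
    return [
        PlasmidClassSpec("I", hgt_rate=1.0, recomb_rate=0.5, n_core=220,
                         n_accessory=40,
                         insertion_block=InsertionBlock(prob=0.5, n_genes=70),
                         expected_mode="decoupled"),
        PlasmidClassSpec("II", hgt_rate=0.0, recomb_rate=0.5, n_core=200,
                         n_accessory=30, expected_mode="vertical-like"),
        PlasmidClassSpec("III", hgt_rate=0.0, recomb_rate=0.1, n_core=210,
                         n_accessory=30, expected_mode="vertical-like"),
        PlasmidClassSpec("pSym", hgt_rate=1.5, hgt_model="pairwise",
                         loss_rate=0.05, recomb_rate=1.5,
                         n_core=20, n_accessory=40,
                         gain_rate=0.5, lose_rate=0.2,
                         insertion_block=InsertionBlock(prob=0.5, n_genes=25,
                                                        switch_rate=3.0),
                         backbone_divergence=0.04,
                         carries_sym_markers=True, expected_mode="decoupled"),
    ]


@dataclass
class Event:
    time: float
    kind: str                      # HGT | loss | gain | block_gain | block_loss
    donor: str | None
    recipient: str | None
    replicon: str
    effective: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class EventLog:
    events: list[Event] = field(default_factory=list)

    def count(self, kind: str) -> int:
        return sum(1 for e in self.events if e.kind == kind)

    def extend(self, other: "EventLog") -> None:
        self.events.extend(other.events)


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# chromosome genealogy
# ---------------------------------------------------------------------------

def simulate_coalescent_tree(n_tips: int, seed, labels: list[str] | None = None) -> dendropy.Tree:
    """Kingman coalescent genealogy for ``n_tips`` lineages.

    Time is in coalescent units: while k lineages remain the waiting time to
    the next coalescence is exponential with rate k(k-1)/2 and the merging
    pair is uniform.  The returned tree is ultrametric and binary.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = _rng(seed)
    if labels is None:
        labels = [f"s{i + 1:02d}" for i in range(n_tips)]
    taxa = dendropy.TaxonNamespace(labels)
    nodes = []
    for lab in labels:
        nd = dendropy.Node()
        nd.taxon = taxa.get_taxon(lab)
        nd.age = 0.0
        nodes.append(nd)
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        parent = dendropy.Node()
        parent.age = t
        a, b = nodes[i], nodes[j]
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = t - a.age
        b.edge.length = t - b.age
        nodes = [nd for idx, nd in enumerate(nodes) if idx not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=nodes[0])
    tree.is_rooted = True
    return tree


def _node_ages(tree: dendropy.Tree) -> dict:
    """Ages (tip = 0) for an ultrametric tree; keyed by node id."""
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    height = max(lf.root_distance for lf in tree.leaf_node_iter())
    return {id(nd): height - nd.root_distance for nd in tree}


# ---------------------------------------------------------------------------
# plasmid genealogy: whole-element transfer + loss on the cell genealogy
# ---------------------------------------------------------------------------

def overlay_plasmid_transfers(
    chrom_tree: dendropy.Tree,
    spec: PlasmidClassSpec,
    seed,
) -> tuple[dendropy.Tree | None, EventLog]:
    """Derive a plasmid genealogy from the cell (chromosome) genealogy.

    Transfer events form a Poisson process with intensity ``spec.hgt_rate``
    per unit branch length on the cell genealogy; each event re-attaches the
    recipient cell lineage's plasmid ancestry to a contemporaneous donor
    lineage chosen uniformly.  Loss events (intensity ``spec.loss_rate``)
    remove the plasmid from the whole descendant clade.  Returns the plasmid
    tree over carrier strains (None if fewer than two carriers remain) and
    the event log; an event is flagged ineffective when it did not move any
    surviving plasmid lineage.
    """
    rng = _rng(seed)
    ages = _node_ages(chrom_tree)
    # edges as (head node, head age, tail age); the root has no edge
    edges = []
    for nd in chrom_tree.preorder_node_iter():
        if nd.parent_node is not None:
            edges.append((nd, ages[id(nd)], ages[id(nd.parent_node)]))
    elens = np.array([t - h for _, h, t in edges])
    total_len = float(elens.sum())

    log = EventLog()

    def sample_points(rate: float) -> list[tuple[int, float]]:
        n = rng.poisson(rate * total_len)
        pts = []
        for _ in range(n):
            e = int(rng.choice(len(edges), p=elens / total_len))
            h, t = edges[e][1], edges[e][2]
            pts.append((e, float(h + rng.uniform() * (t - h))))
        return pts

    def tipset(node) -> list[str]:
        return [lf.taxon.label for lf in node.leaf_iter()]

    # losses prune clades
    lost: set[str] = set()
    for e, t in sample_points(spec.loss_rate):
        clade = tipset(edges[e][0])
        log.events.append(Event(t, "loss", None, _edge_label(edges[e][0]), spec.name,
                                effective=not set(clade) <= lost))
        lost |= set(clade)
    all_tips = [lf.taxon.label for lf in chrom_tree.leaf_node_iter()]
    carriers = [t for t in all_tips if t not in lost]
    if len(carriers) < 2:
        return None, log

    if spec.hgt_model == "pairwise":
        # conjugation-like: intensity hgt_rate x k(k-1)/2 while k lineages
        # coexist, so transfers concentrate where the population is dense
        # (toward the present) and tend to move single strains, not clades
        cuts = sorted({0.0} | {ages[id(nd)]
                               for nd in chrom_tree.preorder_internal_node_iter()})
        transfers = []
        for t0, t1 in zip(cuts, cuts[1:]):
            alive = [i for i, (_, h, tt) in enumerate(edges)
                     if h <= t0 + 1e-15 and tt >= t1 - 1e-15]
            k = len(alive)
            if k < 2:
                continue
            lam = spec.hgt_rate * 0.5 * k * (k - 1) * (t1 - t0)
            for _ in range(rng.poisson(lam)):
                transfers.append((int(rng.choice(alive)),
                                  float(rng.uniform(t0, t1))))
        transfers.sort(key=lambda p: p[1])
    else:
        transfers = sorted(sample_points(spec.hgt_rate), key=lambda p: p[1])

    # sweep tips -> root; each active plasmid lineage sits on one cell edge
    class _PNode:
        __slots__ = ("children", "age", "label")

        def __init__(self, age, label=None, children=()):
            self.age = age
            self.label = label
            self.children = list(children)

    occupant: dict[int, _PNode] = {}
    for nd, h, t in edges:
        if nd.is_leaf() and nd.taxon.label in carriers:
            occupant[id(nd)] = _PNode(0.0, nd.taxon.label)

    def alive_edges(t: float) -> list[int]:
        return [i for i, (_, h, tt) in enumerate(edges) if h < t <= tt]

    # event queue: cell coalescences and transfer events, in age order
    cell_events = [(ages[id(nd)], 0, nd) for nd in chrom_tree.preorder_internal_node_iter()]
    xfer_events = [(t, 1, e) for e, t in transfers]
    queue = sorted(cell_events + xfer_events, key=lambda q: (q[0], q[1]))

    for t, kind, payload in queue:
        if kind == 0:  # cell coalescence: child edges merge into parent edge
            nd = payload
            occ = [occupant.pop(id(c)) for c in nd.child_nodes() if id(c) in occupant]
            if len(occ) == 2:
                occupant[id(nd)] = _PNode(t, children=occ)
            elif len(occ) == 1:
                occupant[id(nd)] = occ[0]
        else:  # transfer: recipient edge's plasmid jumps to a donor edge
            e = payload
            recip = edges[e][0]
            alive = [i for i in alive_edges(t) if i != e]
            if not alive:
                log.events.append(Event(t, "HGT", None, _edge_label(recip),
                                        spec.name, effective=False))
                continue
            d = int(rng.choice(alive))
            donor = edges[d][0]
            moved = occupant.pop(id(recip), None)
            log.events.append(Event(t, "HGT", _edge_label(donor), _edge_label(recip),
                                    spec.name, effective=moved is not None))
            if moved is None:
                continue
            if id(donor) in occupant:
                occupant[id(donor)] = _PNode(t, children=[occupant[id(donor)], moved])
            else:
                occupant[id(donor)] = moved

    roots = list(occupant.values())
    # any lineages left unmerged at the cell root coalesce there
    root_age = max(ages.values())
    while len(roots) > 1:
        a = roots.pop()
        roots[-1] = _PNode(root_age, children=[roots[-1], a])
    proot = roots[0]

    taxa = dendropy.TaxonNamespace(sorted(carriers))
    tree = dendropy.Tree(taxon_namespace=taxa)

    def build(p: _PNode) -> dendropy.Node:
        nd = dendropy.Node()
        if p.label is not None:
            nd.taxon = taxa.get_taxon(p.label)
        for c in p.children:
            cn = build(c)
            cn.edge.length = p.age - c.age
            nd.add_child(cn)
        return nd

    root = build(proot)
    tree.seed_node = root
    tree.is_rooted = True
    return tree, log


def _edge_label(node) -> str:
    if node.is_leaf():
        return node.taxon.label
    return "|".join(sorted(lf.taxon.label for lf in node.leaf_iter()))


# ---------------------------------------------------------------------------
# sequence evolution (JC69)
# ---------------------------------------------------------------------------

def _evolve_one(tree: dendropy.Tree, length: int, mu: float, rng) -> dict[str, np.ndarray]:
    root_seq = rng.integers(0, 4, size=length, dtype=np.int8)
    seqs = {}
    state = {id(tree.seed_node): root_seq}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            cur = root_seq
        else:
            parent = state[id(nd.parent_node)]
            b = (nd.edge.length or 0.0) * mu
            p_diff = 0.75 * (1.0 - np.exp(-4.0 * b / 3.0))
            cur = parent.copy()
            hit = rng.random(length) < p_diff
            k = int(hit.sum())
            if k:
                cur[hit] = (parent[hit] + rng.integers(1, 4, size=k)) % 4
            state[id(nd)] = cur
        state[id(nd)] = cur
        if nd.is_leaf():
            seqs[nd.taxon.label] = cur
    return seqs


def evolve_gene_alignments(
    tree: dendropy.Tree,
    n_genes: int,
    gene_length: int,
    mu: float,
    seed,
    prefix: str = "g",
) -> list[Alignment]:
    """Evolve ``n_genes`` independent genes under JC69 along ``tree``.

    Each gene starts from a uniform-random root sequence; the per-branch
    substitution probability is the JC69 closed form 3/4(1 - exp(-4 mu b/3)).
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    rng = _rng(seed)
    taxa = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    out = []
    for g in range(n_genes):
        seqs = _evolve_one(tree, gene_length, mu, rng)
        data = np.stack([seqs[t] for t in taxa])
        out.append(Alignment(list(taxa), data, gene_id=f"{prefix}{g + 1:04d}"))
    return out


def evolve_core_genes(
    tree: dendropy.Tree,
    n_genes: int,
    gene_length: int,
    mu: float,
    recomb_rate: float,
    seed,
    prefix: str = "g",
) -> tuple[list[Alignment], list[dendropy.Tree]]:
    """Core genes with within-element homologous recombination.

    Each gene's genealogy is the element tree perturbed by gene-level
    transfer events at ``recomb_rate`` (same whole-lineage re-attachment
    process as plasmid transfer, applied per gene); the gene then evolves
    under JC69 on its own genealogy.
    """
    rng = _rng(seed)
    taxa = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    alns, gtrees = [], []
    dummy = PlasmidClassSpec("recomb", hgt_rate=recomb_rate)
    for g in range(n_genes):
        if recomb_rate > 0:
            gt, _ = overlay_plasmid_transfers(tree, dummy, rng)
        else:
            gt = tree
        seqs = _evolve_one(gt, gene_length, mu, rng)
        data = np.stack([seqs[t] for t in taxa])
        alns.append(Alignment(list(taxa), data, gene_id=f"{prefix}{g + 1:04d}"))
        gtrees.append(gt)
    return alns, gtrees


# ---------------------------------------------------------------------------
# gene content
# ---------------------------------------------------------------------------

def _evolve_binary(tree, root_state, gain, lose, rng, log, kinds, replicon):
    """Two-state Markov jump process along the tree; returns tip states."""
    ages = _node_ages(tree)
    states = {id(tree.seed_node): root_state}
    tips = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            s = states[id(nd.parent_node)]
            t0, t1 = ages[id(nd.parent_node)], ages[id(nd)]
            t = t0
            while True:
                rate = gain if s == 0 else lose
                if rate <= 0:
                    break
                t -= rng.exponential(1.0 / rate)
                if t <= t1:
                    break
                s = 1 - s
                log.events.append(Event(t, kinds[s], None, _edge_label(nd), replicon))
            states[id(nd)] = s
        if nd.is_leaf():
            tips[nd.taxon.label] = states[id(nd)]
    return tips


def simulate_gene_content(
    tree: dendropy.Tree,
    spec: PlasmidClassSpec,
    n_core: int | None = None,
    seed=None,
    block_tips: list[str] | None = None,
) -> tuple[pd.DataFrame, EventLog]:
    """Binary gene-family presence/absence for one replicon class.

    Core families are present in every carrier.  Accessory families evolve
    as independent two-state Markov processes (rates ``gain_rate`` /
    ``lose_rate``) with the root drawn from the stationary frequency.  The
    insertion block, if any, is a single linked unit whose families are
    gained and lost together.
    """
    rng = _rng(seed)
    n_core = spec.n_core if n_core is None else n_core
    log = EventLog()
    taxa = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    cols = {}
    for i in range(n_core):
        cols[f"{spec.name}_core{i + 1:04d}"] = {t: 1 for t in taxa}
    g, l = spec.gain_rate, spec.lose_rate
    stat = g / (g + l) if g + l > 0 else 0.0
    for i in range(spec.n_accessory):
        root = int(rng.random() < stat)
        tips = _evolve_binary(tree, root, g, l, rng, log, ("loss", "gain"), spec.name)
        cols[f"{spec.name}_acc{i + 1:04d}"] = tips
    if spec.insertion_block is not None:
        blk = spec.insertion_block
        if block_tips is not None:
            # block fixed to one ancestral element lineage (no turnover)
            tips = {t: int(t in set(block_tips)) for t in taxa}
        else:
            root = int(rng.random() < blk.prob)
            gain = blk.switch_rate * blk.prob
            lose = blk.switch_rate * (1.0 - blk.prob)
            tips = _evolve_binary(tree, root, gain, lose, rng, log,
                                  ("block_loss", "block_gain"), spec.name)
        for i in range(blk.n_genes):
            cols[f"{spec.name}_blk{i + 1:04d}"] = dict(tips)
    df = pd.DataFrame(cols, index=taxa).astype(np.int8)
    df = df.loc[:, (df > 0).any(axis=0)]   # no empty families
    return df, log


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def simulate_trait(
    tree: dendropy.Tree,
    lam: float,
    sigma2: float,
    seed,
    mean: float = 0.0,
) -> pd.Series:
    """Tip trait values under Brownian motion with Pagel-lambda covariance.

    Values are multivariate normal with covariance sigma2 * V(lambda), where
    V(lambda) is the tree's shared-path matrix with off-diagonal entries
    multiplied by lambda.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    rng = _rng(seed)
    taxa, C = tree_vcv(tree)
    V = C * lam
    np.fill_diagonal(V, np.diag(C))
    V = sigma2 * V
    if sigma2 == 0:
        vals = np.full(len(taxa), mean)
    else:
        L = np.linalg.cholesky(V + 1e-12 * np.eye(len(taxa)))
        vals = mean + L @ rng.standard_normal(len(taxa))
    return pd.Series(vals, index=taxa)


# ---------------------------------------------------------------------------
# whole-population assembly
# ---------------------------------------------------------------------------

@dataclass
class RepliconData:
    """One replicon class across its carrier strains."""

    name: str
    tree: dendropy.Tree | None
    carriers: list[str]
    content: pd.DataFrame                  # carriers x families, binary
    alignments: dict[str, Alignment]       # family -> alignment over carriers
    gene_trees: dict[str, dendropy.Tree]   # core family -> genealogy
    categories: dict[str, str]             # family -> functional category
    spacer: Alignment | None
    events: EventLog


@dataclass
class TransmissionTruth:
    hgt_counts: dict[str, int]
    expected: dict[str, str]


@dataclass
class Population:
    config: SimulationConfig
    strains: list[str]
    chrom_tree: dendropy.Tree
    replicons: dict[str, RepliconData]     # "chromosome" + class names
    traits: pd.DataFrame                   # strain, treatment, biomass, chlorophyll
    truth: TransmissionTruth
    backbone_group: dict[str, int]         # strain -> focal-plasmid backbone (block state)

    def replicon_sequence(self, strain: str, replicon: str) -> str:
        """Concatenated gene + spacer sequence of one strain's replicon."""
        rd = self.replicons[replicon]
        if strain not in rd.carriers:
            raise KeyError(f"{strain} does not carry {replicon}")
        parts = []
        row = rd.content.loc[strain]
        for fam in rd.content.columns:
            if row[fam]:
                aln = rd.alignments[fam]
                parts.append(aln.data[aln.taxa.index(strain)])
        if rd.spacer is not None:
            parts.append(rd.spacer.data[rd.spacer.taxa.index(strain)])
        return decode_seq(np.concatenate(parts))


def _assign_categories(families: list[str], sym: bool, rng) -> dict[str, str]:
    cats = {}
    for f in families:
        cats[f] = FUNCTIONAL_CATEGORIES[int(rng.integers(len(FUNCTIONAL_CATEGORIES)))]
    if sym:
        core = [f for f in families if "_core" in f]
        for f in core[: max(6, len(core) // 3)]:
            cats[f] = SYM_CATEGORY
    return cats


def backbone_split(tree: dendropy.Tree) -> list[str]:
    """Tips of one side of the element genealogy's root split.

    Used for anciently diverged backbone lineages: the returned side is the
    one *not* containing the lexicographically smallest tip label, so the
    choice is deterministic for a given tree.
    """
    kids = tree.seed_node.child_nodes()
    if len(kids) < 2:
        return []
    sides = [sorted(lf.taxon.label for lf in k.leaf_iter()) for k in kids]
    sides.sort(key=lambda s: s[0])
    return [t for side in sides[1:] for t in side]


def _build_replicon(name, tree, spec, mu, gene_length, recomb_rate, rng,
                    spacer_fraction: float = 0.15) -> RepliconData:
    # with ancient backbone divergence the insertion block marks one side of
    # the element tree's root split instead of switching along branches
    block_tips = None
    if spec.backbone_divergence > 0 and spec.insertion_block is not None:
        block_tips = backbone_split(tree)
    content, events = simulate_gene_content(tree, spec, seed=rng,
                                            block_tips=block_tips)
    carriers = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    core_fams = [f for f in content.columns if "_core" in f]
    other_fams = [f for f in content.columns if "_core" not in f]
    core_alns, gene_trees = evolve_core_genes(
        tree, len(core_fams), gene_length, mu, recomb_rate, rng)
    # anciently diverged backbones: block carriers pick up extra fixed
    # substitutions in the core, emulating deeply split element lineages
    # (lower within-type ANI) that coexist in one population via transfer
    blk_cols = [c for c in content.columns if "_blk" in c]
    if spec.backbone_divergence > 0 and blk_cols:
        with_block = [s for s in content.index if content.loc[s, blk_cols[0]]]
        for aln in core_alns:
            rows = [aln.taxa.index(s) for s in with_block]
            if not rows or len(rows) == len(aln.taxa):
                continue
            sites = np.flatnonzero(rng.random(aln.data.shape[1]) < spec.backbone_divergence)
            if sites.size:
                shift = rng.integers(1, 4, size=sites.size).astype(np.int8)
                aln.data[np.ix_(rows, sites)] = (aln.data[np.ix_(rows, sites)] + shift) % 4
    alns = {}
    gtrees = {}
    for fam, aln, gt in zip(core_fams, core_alns, gene_trees):
        aln.gene_id = fam
        alns[fam] = aln
        gtrees[fam] = gt
    for fam, aln in zip(other_fams, evolve_gene_alignments(
            tree, len(other_fams), gene_length, mu, rng)):
        aln.gene_id = fam
        alns[fam] = aln
    genic = len(core_fams) * gene_length
    spacer_len = int(round(spacer_fraction / (1.0 - spacer_fraction) * genic))
    spacer = evolve_gene_alignments(tree, 1, max(spacer_len, 50), mu, rng,
                                    prefix=f"{name}_spacer")[0]
    cats = _assign_categories(list(content.columns), spec.carries_sym_markers, rng)
    return RepliconData(name, tree, carriers, content, alns, gtrees, cats, spacer, events)


def simulate_population(config: SimulationConfig) -> Population:
    """Run the full generator; every output is a pure function of the config."""
    ss = np.random.SeedSequence(config.seed)
    keys = ss.spawn(8)
    rng_tree = np.random.default_rng(keys[0])
    chrom = simulate_coalescent_tree(config.n_strains, rng_tree)
    strains = sorted(lf.taxon.label for lf in chrom.leaf_node_iter())

    replicons: dict[str, RepliconData] = {}
    chrom_spec = PlasmidClassSpec(
        "chromosome", n_core=config.n_core_chromosome,
        n_accessory=config.n_accessory_chromosome,
        recomb_rate=config.chrom_recomb_rate, expected_mode="vertical-like")
    rng_chrom = np.random.default_rng(keys[1])
    replicons["chromosome"] = _build_replicon(
        "chromosome", chrom, chrom_spec, config.mu, config.gene_length,
        config.chrom_recomb_rate, rng_chrom, config.spacer_fraction)

    truth_counts: dict[str, int] = {}
    truth_expected: dict[str, str] = {}
    rng_plasmids = np.random.default_rng(keys[2])
    for spec in config.plasmid_classes:
        ptree, plog = overlay_plasmid_transfers(chrom, spec, rng_plasmids)
        if ptree is None:
            continue
        rd = _build_replicon(spec.name, ptree, spec, config.mu,
                             config.gene_length, spec.recomb_rate, rng_plasmids,
                             config.spacer_fraction)
        rd.events.extend(plog)
        replicons[spec.name] = rd
        truth_counts[spec.name] = sum(
            1 for e in plog.events if e.kind == "HGT" and e.effective)
        truth_expected[spec.name] = spec.expected_call

    # focal plasmid backbone: insertion-block state of the sym-marker class
    focal = next((s.name for s in config.plasmid_classes
                  if s.carries_sym_markers and s.name in replicons), None)
    backbone: dict[str, int] = {}
    if focal is not None:
        rd = replicons[focal]
        blk = [c for c in rd.content.columns if "_blk" in c]
        if blk:
            backbone = {s: int(rd.content.loc[s, blk[0]]) for s in rd.carriers}

    rng_traits = np.random.default_rng(keys[3])
    base = simulate_trait(chrom, config.trait_lambda, config.trait_sigma2, rng_traits)
    chl = simulate_trait(chrom, config.trait_lambda, config.trait_sigma2, rng_traits)
    effect = pd.Series({s: config.clade_effect * backbone.get(s, 0) for s in strains})
    biomass = base + effect
    chlorophyll = chl + 0.5 * config.clade_effect * pd.Series(
        {s: backbone.get(s, 0) for s in strains})
    p_control = pd.Series(
        {s: 0.5 + (config.treatment_bias if backbone.get(s, 0) == 0
                   else -config.treatment_bias) for s in strains})
    treatment = ["C" if rng_traits.random() < p_control[s] else "N" for s in strains]
    traits = pd.DataFrame({
        "strain": strains,
        "treatment": treatment,
        "biomass": biomass[strains].to_numpy(),
        "chlorophyll": chlorophyll[strains].to_numpy(),
    })

    return Population(
        config=config, strains=strains, chrom_tree=chrom, replicons=replicons,
        traits=traits, truth=TransmissionTruth(truth_counts, truth_expected),
        backbone_group=backbone)


# ---------------------------------------------------------------------------
# on-disk emission
# ---------------------------------------------------------------------------

def emit_population(pop: Population, outdir: str) -> dict:
    """Write the population to plain-text files and return the manifest.

    Layout: per-strain multi-record genome FASTA (one record per replicon,
    record id ``strain:replicon``; the chromosome is the largest record,
    plasmids are named p1, p2, ... by descending length within the strain),
    a CDS FASTA plus gene-to-replicon TSV, a strain metadata TSV, and a
    truth JSON with trees (Newick), the event log, and expected calls.
    """
    os.makedirs(outdir, exist_ok=True)
    gdir = os.path.join(outdir, "genomes")
    os.makedirs(gdir, exist_ok=True)

    # per-strain replicon naming by descending sequence length
    replicon_names: dict[tuple[str, str], str] = {}   # (strain, class) -> name
    seqs: dict[tuple[str, str], str] = {}
    for strain in pop.strains:
        entries = []
        for cname, rd in pop.replicons.items():
            if strain in rd.carriers:
                s = pop.replicon_sequence(strain, cname)
                entries.append((cname, s))
        entries.sort(key=lambda e: (-len(e[1]), e[0]))
        pi = 0
        for cname, s in entries:
            if cname == "chromosome":
                name = "chromosome"
            else:
                pi += 1
                name = f"p{pi}"
            replicon_names[(strain, cname)] = name
            seqs[(strain, cname)] = s

    genome_files = []
    for strain in pop.strains:
        path = os.path.join(gdir, f"{strain}.fasta")
        with open(path, "w") as fh:
            ordered = sorted(
                ((cls, nm) for (st, cls), nm in replicon_names.items() if st == strain),
                key=lambda cn: (cn[1] != "chromosome", cn[1]))
            for cls, nm in ordered:
                fh.write(f">{strain}:{nm}\n{seqs[(strain, cls)]}\n")
        genome_files.append(path)

    genes_path = os.path.join(outdir, "genes.tsv")
    cds_path = os.path.join(outdir, "cds.fasta")
    with open(genes_path, "w") as gh, open(cds_path, "w") as ch:
        gh.write("gene_id\tstrain\treplicon\tfamily\tcategory\n")
        for cname, rd in pop.replicons.items():
            for strain in rd.carriers:
                rep = replicon_names[(strain, cname)]
                row = rd.content.loc[strain]
                for fam in rd.content.columns:
                    if not row[fam]:
                        continue
                    gid = f"{strain}|{rep}|{fam}"
                    gh.write(f"{gid}\t{strain}\t{rep}\t{fam}\t{rd.categories[fam]}\n")
                    aln = rd.alignments[fam]
                    ch.write(f">{gid}\n{decode_seq(aln.data[aln.taxa.index(strain)])}\n")

    meta_path = os.path.join(outdir, "metadata.tsv")
    pop.traits.to_csv(meta_path, sep="\t", index=False)

    truth = {
        "seed": pop.config.seed,
        "chromosome_tree": write_newick(pop.chrom_tree),
        "replicon_trees": {n: write_newick(r.tree) for n, r in pop.replicons.items()
                           if r.tree is not None},
        "carriers": {n: r.carriers for n, r in pop.replicons.items()},
        "replicon_names": {f"{s}:{replicon_names[(s, c)]}": c
                           for (s, c) in replicon_names},
        "spacer_length": {n: (r.spacer.length if r.spacer is not None else 0)
                          for n, r in pop.replicons.items()},
        "events": {n: [e.to_dict() for e in r.events.events]
                   for n, r in pop.replicons.items()},
        "transmission": {"hgt_counts": pop.truth.hgt_counts,
                         "expected": pop.truth.expected},
        "backbone_group": pop.backbone_group,
    }
    truth_path = os.path.join(outdir, "truth.json")
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=1)

    manifest = {
        "genomes": [os.path.basename(p) for p in genome_files],
        "genes": os.path.basename(genes_path),
        "cds": os.path.basename(cds_path),
        "metadata": os.path.basename(meta_path),
        "truth": os.path.basename(truth_path),
        "n_strains": len(pop.strains),
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
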