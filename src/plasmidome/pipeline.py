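"""End-to-end orchestration: simulate -> type -> pangenome -> trees ->
transmission -> popgen -> traits.

Each stage reads its inputs from files under the run directory and writes
plain-text outputs (TSV/JSON/Newick/FASTA), so a run is resumable: with
``resume=True`` a stage whose outputs already exist is skipped.  A manifest
records, per executed stage, the outputs, wall time, and seed.  The same
config and seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import os
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from . import kmer_typing, pangenome, popgen, simulate, traits, transmission
from .phylo import Alignment, concatenate_alignments, encode_seq, jc69_distances, \
    neighbor_joining, read_newick, write_newick

STAGES = ["simulate", "type", "pangenome", "trees", "transmission", "popgen", "traits"]


@dataclass
class RunConfig:
    """Parameters for one pipeline run.

    Sketching/typing defaults follow the standard plasmid-typing settings
    (k = 31, scaled = 10000, minimum Jaccard index 0.1); resampling defaults
    are 100 genes per subsample over 1000 replicates with a 95th-percentile
    null cutoff.  ``sim`` holds overrides for the synthetic population
    (ignored when ``input_dir`` points at existing data).
    """

    outdir: str = "run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    input_dir: str | None = None     # existing population dir; None = simulate
    # typing
    k: int = 31
    scaled: int = 10000
    min_ji: float = 0.1
    subtype_ji: float = 0.5
    # transmission
    n_genes: int = 100
    n_reps: int = 1000
    percentile: float = 95.0
    # popgen
    window: int = 10000
    step: int = 1000
    # simulator overrides (field name -> value on SimulationConfig)
    sim: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        if not (0 <= self.min_ji <= 1 and self.min_ji < self.subtype_ji <= 1):
            raise ValueError("need 0 <= min_ji < subtype_ji <= 1")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def population_dir(self) -> str:
        return self.input_dir or os.path.join(self.outdir, "population")


# ---------------------------------------------------------------------------
# shared loaders
# ---------------------------------------------------------------------------

def load_replicon_sequences(population_dir: str) -> dict[str, str]:
    """All replicon records (id ``strain:replicon``) from genomes/*.fasta."""
    gdir = os.path.join(population_dir, "genomes")
    out: dict[str, str] = {}
    for fn in sorted(os.listdir(gdir)):
        if not fn.endswith((".fasta", ".fa", ".fna")):
            continue
        for rec in SeqIO.parse(os.path.join(gdir, fn), "fasta"):
            if rec.id in out:
                raise ValueError(f"duplicate replicon id {rec.id}")
            out[rec.id] = str(rec.seq).upper()
    return out


def load_genes(population_dir: str) -> tuple[pd.DataFrame, dict[str, str]]:
    genes = pd.read_csv(os.path.join(population_dir, "genes.tsv"), sep="\t")
    cds = {rec.id: str(rec.seq).upper()
           for rec in SeqIO.parse(os.path.join(population_dir, "cds.fasta"), "fasta")}
    return genes, cds


def group_core_alignments(
    genes: pd.DataFrame,
    cds: dict[str, str],
    members: list[str],
) -> list[Alignment]:
    """Per-family alignments of the core of a replicon group.

    ``members`` are replicon ids (``strain:replicon``).  A family is core
    when present in every member, single copy.  Simulated gene sequences
    are generated aligned (equal length within a family); for real data an
    external per-family aligner would be slotted in here.
    """
    sub = genes[genes.apply(lambda r: f"{r['strain']}:{r['replicon']}" in set(members),
                            axis=1)]
    n_members = len(set(members))
    fam_ok = []
    for fam, grp in sub.groupby("family"):
        units = grp["strain"] + ":" + grp["replicon"]
        if units.nunique() == n_members and len(grp) == n_members:
            fam_ok.append((fam, grp))
    alns = []
    for fam, grp in fam_ok:
        pairs = [(row["strain"], cds[row["gene_id"]])
                 for _, row in grp.sort_values("strain").iterrows()]
        lengths = {len(s) for _, s in pairs}
        if len(lengths) != 1:
            continue  # would need alignment; out of scope for the simulator path
        alns.append(Alignment.from_strings(pairs, gene_id=fam))
    return alns


def _write_tsv(df: pd.DataFrame, path: str, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _sim_config(cfg: RunConfig) -> simulate.SimulationConfig:
    sim = dict(cfg.sim)
    classes = sim.get("plasmid_classes")
    if classes is not None:
        specs = []
        for c in classes:
            if isinstance(c, simulate.PlasmidClassSpec):
                specs.append(c)
            else:
                c = dict(c)
                blk = c.get("insertion_block")
                if isinstance(blk, dict):
                    c["insertion_block"] = simulate.InsertionBlock(**blk)
                specs.append(simulate.PlasmidClassSpec(**c))
        sim["plasmid_classes"] = specs
    return simulate.SimulationConfig(seed=cfg.seed, **sim)


def stage_simulate(cfg: RunConfig) -> list[str]:
    sim_cfg = _sim_config(cfg)
    pop = simulate.simulate_population(sim_cfg)
    manifest = simulate.emit_population(pop, cfg.population_dir)
    return [os.path.join(cfg.population_dir, "manifest.json")] + [
        os.path.join(cfg.population_dir, "genomes", g) for g in manifest["genomes"]]


def stage_type(cfg: RunConfig) -> list[str]:
    seqs = load_replicon_sequences(cfg.population_dir)
    plasmids = {rid: s for rid, s in seqs.items() if not rid.endswith(":chromosome")}
    assignment, m, g = kmer_typing.type_plasmids(
        plasmids, k=cfg.k, scaled=cfg.scaled,
        min_ji=cfg.min_ji, subtype_ji=cfg.subtype_ji)
    tdir = os.path.join(cfg.outdir, "typing")
    os.makedirs(tdir, exist_ok=True)
    outs = []
    p = os.path.join(tdir, "similarity.tsv")
    m.to_csv(p, sep="\t", float_format="%.6g")
    outs.append(p)
    edges = pd.DataFrame(
        [(u, v, d["weight"]) for u, v, d in g.edges(data=True)],
        columns=["source", "target", "weight"]).sort_values(["source", "target"])
    p = os.path.join(tdir, "edges.tsv")
    _write_tsv(edges, p)
    outs.append(p)
    p = os.path.join(tdir, "types.tsv")
    _write_tsv(assignment.to_frame(), p)
    outs.append(p)
    return outs


def _load_types(cfg: RunConfig) -> pd.DataFrame:
    return pd.read_csv(os.path.join(cfg.outdir, "typing", "types.tsv"), sep="\t")


def _type_groups(cfg: RunConfig, include_chromosome: bool = True) -> dict[str, list[str]]:
    """Replicon-id members per non-singleton type (plus the chromosome)."""
    types = _load_types(cfg)
    groups: dict[str, list[str]] = {}
    for t, grp in types.groupby("type"):
        if t != "singleton":
            groups[str(t)] = sorted(grp["replicon"])
    if include_chromosome:
        seqs = load_replicon_sequences(cfg.population_dir)
        groups["chromosome"] = sorted(r for r in seqs if r.endswith(":chromosome"))
    return groups


def stage_pangenome(cfg: RunConfig) -> list[str]:
    genes, cds = load_genes(cfg.population_dir)
    fam_map = pangenome.cluster_gene_families(cds)
    genes = genes.copy()
    genes["family"] = genes["gene_id"].map(fam_map)
    pdir = os.path.join(cfg.outdir, "pangenome")
    os.makedirs(pdir, exist_ok=True)
    outs = []
    p = os.path.join(pdir, "families.tsv")
    _write_tsv(genes[["gene_id", "strain", "replicon", "family", "category"]], p)
    outs.append(p)

    genes["unit"] = genes["strain"] + ":" + genes["replicon"]
    pa = pangenome.presence_absence(genes, unit_col="unit")
    p = os.path.join(pdir, "presence_absence.tsv")
    pa.to_csv(p, sep="\t")
    outs.append(p)

    # ordination of plasmid replicons by gene content
    plasmid_rows = [r for r in pa.index if not r.endswith(":chromosome")]
    d = pangenome.jaccard_distance_matrix(pa.loc[plasmid_rows])
    ord_res = pangenome.pcoa(d, m_axes=2)
    coords = ord_res.coordinates.copy()
    types = _load_types(cfg).set_index("replicon")
    coords["type"] = [types["type"].get(r, "NA") for r in coords.index]
    p = os.path.join(pdir, "ordination.tsv")
    coords.to_csv(p, sep="\t")
    outs.append(p)
    with open(os.path.join(pdir, "eigenvalues.json"), "w") as fh:
        json.dump({"eigenvalues": ord_res.eigenvalues.tolist(),
                   "proportion_explained": ord_res.proportion_explained.tolist()},
                  fh, indent=1)
    outs.append(os.path.join(pdir, "eigenvalues.json"))

    # pairwise core-gene overlap between types
    groups = _type_groups(cfg, include_chromosome=False)
    cores = {t: pangenome.core_genes(pa, mem) for t, mem in groups.items()
             if set(mem) <= set(pa.index)}
    rows = []
    names = sorted(cores)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if cores[a] and cores[b]:
                rows.append((a, b, len(cores[a]), len(cores[b]),
                             pangenome.core_overlap(cores[a], cores[b])))
    p = os.path.join(pdir, "core_overlap.tsv")
    _write_tsv(pd.DataFrame(rows, columns=["type_a", "type_b", "core_a", "core_b",
                                           "overlap"]), p)
    outs.append(p)

    # functional enrichment per type against the extrachromosomal background
    plasmid_genes = genes[~genes["replicon"].eq("chromosome")]
    cats = plasmid_genes.set_index("gene_id")["category"]
    enr = []
    for t, mem in groups.items():
        focal = plasmid_genes[plasmid_genes["unit"].isin(mem)]["gene_id"].tolist()
        e = pangenome.category_enrichment(cats, focal)
        e.insert(0, "type", t)
        enr.append(e)
    p = os.path.join(pdir, "enrichment.tsv")
    _write_tsv(pd.concat(enr, ignore_index=True) if enr else pd.DataFrame(), p)
    outs.append(p)
    return outs


def stage_trees(cfg: RunConfig) -> list[str]:
    genes, cds = load_genes(cfg.population_dir)
    groups = _type_groups(cfg)
    tdir = os.path.join(cfg.outdir, "trees")
    os.makedirs(tdir, exist_ok=True)
    outs = []
    for name, members in sorted(groups.items()):
        alns = group_core_alignments(genes, cds, members)
        if len(alns) < 1 or len(alns[0].taxa) < 3:
            continue
        concat = concatenate_alignments(alns)
        D, _ = jc69_distances(concat)
        tree = neighbor_joining(D, concat.taxa)
        p = os.path.join(tdir, f"{name}.nwk")
        with open(p, "w") as fh:
            fh.write(write_newick(tree) + "\n")
        outs.append(p)
        info = pd.DataFrame({"family": [a.gene_id for a in alns],
                             "length": [a.length for a in alns]})
        p2 = os.path.join(tdir, f"{name}.core_families.tsv")
        _write_tsv(info, p2)
        outs.append(p2)
    return outs


def stage_transmission(cfg: RunConfig) -> list[str]:
    genes, cds = load_genes(cfg.population_dir)
    groups = _type_groups(cfg)
    if "chromosome" not in groups:
        raise RuntimeError("transmission stage requires chromosome records")
    core = {name: group_core_alignments(genes, cds, mem)
            for name, mem in groups.items()}
    core = {n: a for n, a in core.items() if len(a) >= 4}
    xdir = os.path.join(cfg.outdir, "transmission")
    os.makedirs(xdir, exist_ok=True)

    dists: dict[tuple[str, str], transmission.GRFDistribution] = {}
    for name, alns in sorted(core.items()):
        dists[(name, name)] = transmission.within_replicon_grf(
            alns, n_genes=cfg.n_genes, n_reps=cfg.n_reps, seed=cfg.seed,
            replicon=name)
    thr = transmission.null_threshold(dists[("chromosome", "chromosome")],
                                      cfg.percentile)
    calls = []
    for name, alns in sorted(core.items()):
        if name == "chromosome":
            continue
        cross = transmission.cross_replicon_grf(
            alns, core["chromosome"], n_genes=cfg.n_genes, n_reps=cfg.n_reps,
            seed=cfg.seed, comparison=(name, "chromosome"))
        dists[(name, "chromosome")] = cross
        calls.append(transmission.classify_transmission(cross, thr))

    outs = []
    rows = []
    for (a, b), d in sorted(dists.items()):
        for i, v in enumerate(d.values):
            rows.append((a, b, i, v))
    p = os.path.join(xdir, "distributions.tsv")
    _write_tsv(pd.DataFrame(rows, columns=["replicon", "against", "replicate",
                                           "grf"]), p)
    outs.append(p)
    srows = []
    for (a, b), d in sorted(dists.items()):
        s = transmission.summarize_distribution(d)
        srows.append((a, b, d.n_genes, d.n_reps, s["mean"], s["sd"], s["min"],
                      s["max"], s["fraction_at_max"]))
    p = os.path.join(xdir, "summary.tsv")
    _write_tsv(pd.DataFrame(srows, columns=[
        "replicon", "against", "n_genes", "n_reps", "mean", "sd", "min", "max",
        "fraction_at_max"]), p)
    outs.append(p)
    p = os.path.join(xdir, "calls.tsv")
    _write_tsv(pd.DataFrame([dataclasses.asdict(c) for c in calls]), p)
    outs.append(p)
    with open(os.path.join(xdir, "null_threshold.json"), "w") as fh:
        json.dump({"percentile": cfg.percentile, "threshold": thr}, fh, indent=1)
    outs.append(os.path.join(xdir, "null_threshold.json"))
    return outs


def stage_popgen(cfg: RunConfig) -> list[str]:
    genes, cds = load_genes(cfg.population_dir)
    seqs = load_replicon_sequences(cfg.population_dir)
    groups = _type_groups(cfg)
    types = _load_types(cfg)
    pdir = os.path.join(cfg.outdir, "popgen")
    os.makedirs(pdir, exist_ok=True)
    outs = []
    rows = []
    concat_by_type: dict[str, Alignment] = {}
    for name, members in sorted(groups.items()):
        alns = group_core_alignments(genes, cds, members)
        if not alns or len(alns[0].taxa) < 2:
            continue
        concat = concatenate_alignments(alns)
        concat_by_type[name] = concat
        sizes = [len(seqs[m]) for m in members]
        rows.append(popgen.replicon_summary(name, sizes, concat, len(alns)))
    p = os.path.join(pdir, "summary.tsv")
    _write_tsv(pd.DataFrame(rows), p)
    outs.append(p)

    # sliding-window differentiation between the two largest subtypes of the
    # focal (sym-carrying, smallest-core) plasmid type: use the type whose
    # members have the fewest core genes among non-chromosome groups
    focal = None
    plasmid_rows = [r for r in rows if r["type"] != "chromosome"]
    if plasmid_rows:
        focal = min(plasmid_rows, key=lambda r: r["core_genes"])["type"]
    wrote_fst = False
    if focal is not None and focal in concat_by_type:
        sub = types[types["type"] == focal].set_index("replicon")["subtype"]
        strain_sub = {r.split(":")[0]: s for r, s in sub.items()}
        counts = pd.Series(strain_sub).value_counts()
        if len(counts) >= 2 and (counts.iloc[1] >= 2):
            top = list(counts.index[:2])
            concat = concat_by_type[focal]
            pops = {t: strain_sub[t] for t in concat.taxa
                    if strain_sub.get(t) in top}
            keep = [t for t in concat.taxa if t in pops]
            sub_aln = concat.subset(keep)
            track = popgen.sliding_window_fst(sub_aln, pops, cfg.window, cfg.step)
            bed = track.to_bed(focal)
            bed.insert(1, "groups", "|".join(top))
            p = os.path.join(pdir, "fst_windows.tsv")
            _write_tsv(bed, p)
            outs.append(p)
            wrote_fst = True
    if not wrote_fst:
        warnings.warn("no suitable subtype pair for sliding-window F_ST")
    return outs


def stage_traits(cfg: RunConfig) -> list[str]:
    meta = pd.read_csv(os.path.join(cfg.population_dir, "metadata.tsv"), sep="\t")
    types = _load_types(cfg)
    tdir = os.path.join(cfg.outdir, "traits")
    os.makedirs(tdir, exist_ok=True)
    outs = []
    trait_cols = [c for c in meta.columns if c not in ("strain", "treatment")]
    rows = []
    tree_dir = os.path.join(cfg.outdir, "trees")
    for fn in sorted(os.listdir(tree_dir)):
        if not fn.endswith(".nwk"):
            continue
        name = fn[:-4]
        tree = read_newick(os.path.join(tree_dir, fn))
        try:
            tree.reroot_at_midpoint(update_bipartitions=False)
        except (AssertionError, ValueError):
            pass
        for col in trait_cols:
            trait = meta.set_index("strain")[col]
            try:
                fit = traits.pagel_lambda_fit(tree, trait)
            except ValueError:
                continue
            rows.append((name, col, fit.lambda_hat, fit.sigma2_hat,
                         fit.log_likelihood, fit.p_value, fit.n_tips))
    p = os.path.join(tdir, "phylogenetic_signal.tsv")
    _write_tsv(pd.DataFrame(rows, columns=[
        "replicon", "trait", "lambda", "sigma2", "logL", "p_lrt", "n_tips"]), p)
    outs.append(p)

    results = {}
    for t in sorted(set(types["type"])):
        if t == "singleton":
            continue
        sub = types[types["type"] == t].set_index("replicon")["subtype"]
        strain_sub = {r.split(":")[0]: s for r, s in sub.items()}
        table, dropped = traits.subtype_treatment_table(strain_sub, meta)
        if table.empty or table.shape[0] < 2 or table.shape[1] < 2:
            continue
        p2 = os.path.join(tdir, f"contingency_{t}.tsv")
        table.to_csv(p2, sep="\t")
        outs.append(p2)
        try:
            x2, df, pval = traits.chisq_independence(table)
        except ValueError:
            continue
        results[t] = {"X2": x2, "df": df, "p": pval, "n_dropped": len(dropped)}
    p = os.path.join(tdir, "subtype_treatment_tests.json")
    with open(p, "w") as fh:
        json.dump(results, fh, indent=1)
    outs.append(p)
    return outs


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "type": stage_type,
    "pangenome": stage_pangenome,
    "trees": stage_trees,
    "transmission": stage_transmission,
    "popgen": stage_popgen,
    "traits": stage_traits,
}

_STAGE_SENTINELS = {
    "simulate": ("population", "manifest.json"),
    "type": ("typing", "types.tsv"),
    "pangenome": ("pangenome", "presence_absence.tsv"),
    "trees": ("trees", "chromosome.nwk"),
    "transmission": ("transmission", "calls.tsv"),
    "popgen": ("popgen", "summary.tsv"),
    "traits": ("traits", "phylogenetic_signal.tsv"),
}


def run_pipeline(cfg: RunConfig, resume: bool = False) -> dict:
    """Run the configured stages in dependency order; returns the manifest."""
    os.makedirs(cfg.outdir, exist_ok=True)
    with open(os.path.join(cfg.outdir, "config.yaml"), "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh)
    manifest: dict = {"seed": cfg.seed, "stages": {}}
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        if stage == "simulate" and cfg.input_dir is not None:
            continue
        sub, sentinel = _STAGE_SENTINELS[stage]
        base = cfg.population_dir if stage == "simulate" else os.path.join(cfg.outdir, sub)
        if resume and os.path.exists(os.path.join(base, sentinel)):
            manifest["stages"][stage] = {"skipped": True}
            continue
        t0 = time.time()
        outputs = _STAGE_FUNCS[stage](cfg)
        manifest["stages"][stage] = {
            "outputs": [os.path.relpath(p, cfg.outdir) for p in outputs],
            "wall_time_s": round(time.time() - t0, 3),
            "seed": cfg.seed,
        }
    with open(os.path.join(cfg.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------

def validate_inputs(population_dir: str) -> list[str]:
    """Schema and consistency checks on a population directory.

    Returns an itemised list of problems (empty = clean); report-only,
    nothing raises.
    """
    problems: list[str] = []
    gdir = os.path.join(population_dir, "genomes")
    seen_ids: set[str] = set()
    fasta_strains: set[str] = set()
    if not os.path.isdir(gdir):
        problems.append(f"missing genomes directory: {gdir}")
    else:
        for fn in sorted(os.listdir(gdir)):
            if not fn.endswith((".fasta", ".fa", ".fna")):
                continue
            for rec in SeqIO.parse(os.path.join(gdir, fn), "fasta"):
                if rec.id in seen_ids:
                    problems.append(f"fatal: duplicate replicon id {rec.id}")
                seen_ids.add(rec.id)
                if ":" not in rec.id:
                    problems.append(f"replicon id {rec.id} is not strain:replicon")
                else:
                    fasta_strains.add(rec.id.split(":")[0])
                s = str(rec.seq)
                bad = set(s.upper()) - set("ACGTN")
                if bad:
                    problems.append(
                        f"{rec.id}: non-nucleotide characters {sorted(bad)}")
                elif s != s.upper():
                    problems.append(
                        f"note: {rec.id} contains lowercase bases (normalised on load)")
    meta_path = os.path.join(population_dir, "metadata.tsv")
    if not os.path.exists(meta_path):
        problems.append(f"missing metadata: {meta_path}")
    else:
        meta = pd.read_csv(meta_path, sep="\t")
        for col in ("strain", "treatment"):
            if col not in meta.columns:
                problems.append(f"metadata missing column {col}")
        if "strain" in meta.columns:
            for s in meta["strain"]:
                if fasta_strains and s not in fasta_strains:
                    problems.append(f"strain {s} in metadata but has no genome FASTA")
            for s in sorted(fasta_strains - set(meta.get("strain", []))):
                problems.append(f"strain {s} has a genome but no metadata row")
    genes_path = os.path.join(population_dir, "genes.tsv")
    if os.path.exists(genes_path):
        genes = pd.read_csv(genes_path, sep="\t")
        need = {"gene_id", "strain", "replicon", "family"}
        missing = need - set(genes.columns)
        if missing:
            problems.append(f"genes.tsv missing columns {sorted(missing)}")
    return problems
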