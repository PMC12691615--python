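"""Synthetic population generator: genealogies, transfer overlay, sequence
evolution, gene content, traits, and on-disk emission."""

import json
import os

import numpy as np
import pandas as pd
import pytest

from plasmidome import (
    InsertionBlock,
    PlasmidClassSpec,
    SimulationConfig,
    emit_population,
    evolve_gene_alignments,
    normalized_rf,
    overlay_plasmid_transfers,
    simulate_coalescent_tree,
    simulate_gene_content,
    simulate_population,
    simulate_trait,
    write_newick,
)
from plasmidome.phylo import tree_vcv


def tip_depths(tree):
    tree.calc_node_root_distances()
    return np.array([lf.root_distance for lf in tree.leaf_node_iter()])


class TestCoalescent:
    def test_ultrametric(self):
        for n in (3, 10, 25):
            d = tip_depths(simulate_coalescent_tree(n, n))
            assert np.allclose(d, d[0], atol=1e-9)

    def test_deterministic_newick(self):
        assert write_newick(simulate_coalescent_tree(9, 5)) == \
            write_newick(simulate_coalescent_tree(9, 5))

    def test_rejects_single_tip(self):
        with pytest.raises(ValueError):
            simulate_coalescent_tree(1, 0)

    def test_two_tip_height_matches_kingman_expectation(self):
        # E[T2] = 1 in coalescent units; 10000 replicates, +/- 3 SE
        rng = np.random.default_rng(0)
        h = np.array([tip_depths(simulate_coalescent_tree(2, rng))[0]
                      for _ in range(10000)])
        se = h.std(ddof=1) / np.sqrt(h.size)
        assert abs(h.mean() - 1.0) < 3 * se

    def test_height_matches_2_1_minus_1_over_n(self):
        # E[height] = 2(1 - 1/n); Monte-Carlo at n=6
        rng = np.random.default_rng(1)
        h = np.array([tip_depths(simulate_coalescent_tree(6, rng))[0]
                      for _ in range(3000)])
        se = h.std(ddof=1) / np.sqrt(h.size)
        assert abs(h.mean() - 2 * (1 - 1 / 6)) < 3 * se


class TestOverlay:
    def test_zero_rates_preserve_tree_exactly(self, tree20):
        spec = PlasmidClassSpec("p", hgt_rate=0.0, loss_rate=0.0)
        ptree, log = overlay_plasmid_transfers(tree20, spec, 1)
        assert len(log.events) == 0
        assert normalized_rf(tree20, ptree) == 0.0
        # branch lengths preserved: identical patristic distances
        pdm_a = tree20.phylogenetic_distance_matrix()
        pdm_b = ptree.phylogenetic_distance_matrix()
        ta = {t.label: t for t in tree20.taxon_namespace}
        tb = {t.label: t for t in ptree.taxon_namespace}
        for x in list(ta)[:5]:
            for y in list(ta)[:5]:
                if x < y:
                    assert pdm_a.distance(ta[x], ta[y]) == pytest.approx(
                        pdm_b.distance(tb[x], tb[y]), abs=1e-9)

    def test_zero_hgt_empty_transfer_log(self, tree20):
        spec = PlasmidClassSpec("p", hgt_rate=0.0, loss_rate=0.3)
        _, log = overlay_plasmid_transfers(tree20, spec, 2)
        assert log.count("HGT") == 0

    def test_event_count_matches_poisson_mean(self):
        # 200 seeds at rate 5: realized mean within 5% of rate x tree length
        tree = simulate_coalescent_tree(30, 3)
        total = sum(e.length for e in tree.preorder_edge_iter()
                    if e.length is not None)
        spec = PlasmidClassSpec("p", hgt_rate=5.0)
        counts = [overlay_plasmid_transfers(tree, spec, s)[1].count("HGT")
                  for s in range(200)]
        assert np.mean(counts) == pytest.approx(5.0 * total, rel=0.05)

    def test_plasmid_tree_stays_ultrametric_under_transfers(self, tree20):
        spec = PlasmidClassSpec("p", hgt_rate=3.0, loss_rate=0.1)
        ptree, _ = overlay_plasmid_transfers(tree20, spec, 11)
        d = tip_depths(ptree)
        assert np.allclose(d, d[0], atol=1e-9)

    def test_losses_prune_carriers(self, tree20):
        spec = PlasmidClassSpec("p", hgt_rate=0.0, loss_rate=1.0)
        ptree, log = overlay_plasmid_transfers(tree20, spec, 4)
        n_lost = 20 - (len(ptree.leaf_nodes()) if ptree is not None else 0)
        assert log.count("loss") >= 1
        assert n_lost >= 1

    def test_pairwise_model_runs_and_transfers(self, tree20):
        spec = PlasmidClassSpec("p", hgt_rate=1.0, hgt_model="pairwise")
        ptree, log = overlay_plasmid_transfers(tree20, spec, 8)
        assert log.count("HGT") > 0
        assert np.allclose(tip_depths(ptree), tip_depths(ptree)[0], atol=1e-9)


class TestSequenceEvolution:
    def test_zero_rate_keeps_root_sequence(self, tree20):
        a = evolve_gene_alignments(tree20, 1, 200, 0.0, 3)[0]
        assert (a.data == a.data[0]).all()

    def test_deterministic(self, tree20):
        a = evolve_gene_alignments(tree20, 2, 100, 0.02, 9)
        b = evolve_gene_alignments(tree20, 2, 100, 0.02, 9)
        assert np.array_equal(a[1].data, b[1].data)

    def test_divergence_matches_jc69_closed_form(self):
        # two tips at path distance d: P(diff) = (3/4)(1 - e^(-4 mu d / 3))
        import dendropy
        tns = dendropy.TaxonNamespace(["a", "b"])
        tree = dendropy.Tree.get(data="(a:0.4,b:0.4);", schema="newick",
                                 taxon_namespace=tns)
        mu, L = 0.5, 40000
        a = evolve_gene_alignments(tree, 1, L, mu, 13)[0]
        p_obs = (a.data[0] != a.data[1]).mean()
        p_exp = 0.75 * (1 - np.exp(-4 * mu * 0.8 / 3))
        se = np.sqrt(p_exp * (1 - p_exp) / L)
        assert abs(p_obs - p_exp) < 3 * se


class TestGeneContent:
    def test_zero_turnover_identical_content(self, tree20):
        spec = PlasmidClassSpec("p", gain_rate=0.0, lose_rate=0.0, n_core=5,
                                n_accessory=6)
        df, log = simulate_gene_content(tree20, spec, seed=1)
        assert (df.nunique(axis=0) == 1).all()
        assert len(log.events) == 0

    def test_occupancy_near_stationary_frequency(self):
        # long branches: per-family tip occupancy ~ gain / (gain + lose)
        tree = simulate_coalescent_tree(40, 17)
        spec = PlasmidClassSpec("p", gain_rate=0.6, lose_rate=0.3, n_core=1,
                                n_accessory=400)
        df, _ = simulate_gene_content(tree, spec, seed=5)
        occ = df[[c for c in df.columns if "_acc" in c]].to_numpy().mean(axis=0)
        se = occ.std(ddof=1) / np.sqrt(occ.size)
        assert abs(occ.mean() - 0.6 / 0.9) < 3 * se

    def test_block_families_fully_linked(self, tree20):
        spec = PlasmidClassSpec("p", n_core=3, n_accessory=0,
                                insertion_block=InsertionBlock(prob=0.5, n_genes=6))
        df, _ = simulate_gene_content(tree20, spec, seed=21)
        blk = df[[c for c in df.columns if "_blk" in c]]
        assert (blk.nunique(axis=1) == 1).all()

    def test_block_makes_row_sums_bimodal(self, tree20):
        # with no accessory noise, row sums take exactly two values
        # separated by the block gene count (when both states are realized)
        spec = PlasmidClassSpec("p", n_core=10, n_accessory=0,
                                insertion_block=InsertionBlock(prob=0.5, n_genes=7))
        for seed in range(6):
            df, _ = simulate_gene_content(tree20, spec, seed=seed)
            sums = set(df.sum(axis=1))
            assert sums <= {10, 17}
            if len(sums) == 2:
                return
        pytest.fail("block never polymorphic over 6 seeds")

    def test_fixed_block_tips_mark_exact_clade(self, tree20):
        tips = sorted(lf.taxon.label for lf in tree20.leaf_node_iter())[:8]
        spec = PlasmidClassSpec("p", n_core=2, n_accessory=0,
                                insertion_block=InsertionBlock(n_genes=3))
        df, _ = simulate_gene_content(tree20, spec, seed=0, block_tips=tips)
        blk = df[[c for c in df.columns if "_blk" in c][0]]
        assert set(blk[blk == 1].index) == set(tips)


class TestTraitSimulation:
    def test_lambda_out_of_range_rejected(self, tree20):
        with pytest.raises(ValueError):
            simulate_trait(tree20, 1.5, 1.0, 0)

    def test_zero_variance_constant(self, tree20):
        tr = simulate_trait(tree20, 0.5, 0.0, 0, mean=2.5)
        assert (tr == 2.5).all()

    def test_empirical_covariance_matches_specified(self):
        # 500 replicates on a 6-tip tree vs sigma2 * V(lambda=1)
        tree = simulate_coalescent_tree(6, 23)
        taxa, C = tree_vcv(tree)
        draws = np.stack([simulate_trait(tree, 1.0, 2.0, s)[taxa].to_numpy()
                          for s in range(500)])
        emp = np.cov(draws.T)
        scale = np.abs(2.0 * C).max()
        assert np.abs(emp - 2.0 * C).max() < 0.25 * scale

    def test_lambda_zero_tips_uncorrelated(self):
        tree = simulate_coalescent_tree(6, 29)
        taxa, _ = tree_vcv(tree)
        draws = np.stack([simulate_trait(tree, 0.0, 1.0, 700 + s)[taxa].to_numpy()
                          for s in range(500)])
        emp = np.corrcoef(draws.T)
        off = emp[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.2


class TestPopulationAndEmission:
    def test_population_deterministic(self):
        cfg = SimulationConfig(n_strains=8, seed=3, n_core_chromosome=10,
                               n_accessory_chromosome=2,
                               plasmid_classes=[PlasmidClassSpec("P", n_core=8)])
        a, b = simulate_population(cfg), simulate_population(cfg)
        assert write_newick(a.chrom_tree) == write_newick(b.chrom_tree)
        pd.testing.assert_frame_equal(a.traits, b.traits)
        assert a.replicon_sequence("s01", "P") == b.replicon_sequence("s01", "P")

    def test_emit_round_trip(self, tmp_path):
        cfg = SimulationConfig(n_strains=10, seed=5, n_core_chromosome=12,
                               n_accessory_chromosome=3,
                               plasmid_classes=[PlasmidClassSpec(
                                   "P", n_core=8, n_accessory=4)])
        pop = simulate_population(cfg)
        manifest = emit_population(pop, str(tmp_path))
        assert len(manifest["genomes"]) == 10

        genes = pd.read_csv(tmp_path / "genes.tsv", sep="\t")
        truth = json.loads((tmp_path / "truth.json").read_text())
        # gene-family matrix reconstructed from files equals the in-memory one
        sub = genes[genes["family"].str.startswith("P_")]
        mat = pd.crosstab(sub["strain"], sub["family"])
        rd = pop.replicons["P"]
        assert mat.shape == rd.content.shape
        assert (mat.sort_index(axis=1).to_numpy() ==
                rd.content.sort_index(axis=1).to_numpy()).all()

        # FASTA record length = genes present x gene length + spacer
        from Bio import SeqIO
        recs = {r.id: len(r.seq) for r in SeqIO.parse(
            tmp_path / "genomes" / "s01.fasta", "fasta")}
        psym_rec = next(k for k, v in truth["replicon_names"].items()
                        if v == "P" and k.startswith("s01:"))
        n_genes = int(rd.content.loc["s01"].sum())
        expected = n_genes * cfg.gene_length + truth["spacer_length"]["P"]
        assert recs[psym_rec] == expected


def test_simulation_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(n_strains=2)
    with pytest.raises(ValueError):
        SimulationConfig(gene_length=0)
    with pytest.raises(ValueError):
        PlasmidClassSpec("x", hgt_rate=-1)
    with pytest.raises(ValueError):
        PlasmidClassSpec("x", hgt_model="bogus")
    with pytest.raises(ValueError):
        InsertionBlock(prob=1.5)
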