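"""FracMinHash sketches, Jaccard networks, and plasmid type assignment."""

import numpy as np
import pandas as pd
import pytest

from plasmidome import (
    InsertionBlock,
    PlasmidClassSpec,
    SimulationConfig,
    Sketch,
    assign_subtypes,
    assign_types,
    build_type_network,
    jaccard_index,
    similarity_matrix,
    simulate_population,
    sketch_replicon,
    type_plasmids,
)
from plasmidome.kmer_typing import canonical_kmers

from conftest import rand_dna

RC = str.maketrans("ACGT", "TGCA")


def revcomp(s):
    return s.translate(RC)[::-1]


def brute_canonical(seq, k=31):
    out = set()
    for i in range(len(seq) - k + 1):
        km = seq[i:i + k]
        if set(km) <= set("ACGT"):
            out.add(min(km, revcomp(km)))
    return out


class TestSketching:
    def test_short_sequence_empty_sketch(self):
        assert len(sketch_replicon("ACGT" * 5, k=31)) == 0

    def test_reverse_complement_invariance(self):
        s = rand_dna(500, np.random.default_rng(0))
        assert sketch_replicon(s, scaled=1).hashes == \
            sketch_replicon(revcomp(s), scaled=1).hashes

    def test_scaled_one_counts_match_brute_force_enumeration(self):
        rng = np.random.default_rng(1)
        for n in (50, 100, 400):
            s = rand_dna(n, rng)
            assert len(sketch_replicon(s, scaled=1)) == len(brute_canonical(s))

    def test_n_containing_kmers_skipped(self):
        s = rand_dna(100, np.random.default_rng(2))
        with_n = s[:40] + "N" + s[41:]
        expect = brute_canonical(with_n)
        assert len(sketch_replicon(with_n, scaled=1)) == len(expect)

    def test_sketch_is_subset_of_full_hash_set(self):
        s = rand_dna(5000, np.random.default_rng(3))
        full = sketch_replicon(s, scaled=1).hashes
        sub = sketch_replicon(s, scaled=10).hashes
        assert sub <= full
        assert 0 < len(sub) < len(full)

    def test_sketch_jaccard_tracks_exact_jaccard(self):
        # known-overlap 50-kb pairs at scaled=100, +/- 0.05
        rng = np.random.default_rng(4)
        a = rand_dna(50000, rng)
        b = a[:30000] + rand_dna(20000, rng)
        ka, kb = brute_canonical(a), brute_canonical(b)
        exact = len(ka & kb) / len(ka | kb)
        est = jaccard_index(sketch_replicon(a, scaled=100),
                            sketch_replicon(b, scaled=100))
        assert abs(est - exact) <= 0.05


class TestJaccard:
    def test_identical_sketches_one(self):
        s = Sketch(31, 10, frozenset({1, 2, 3}))
        assert jaccard_index(s, s) == 1.0

    def test_disjoint_zero(self):
        a = Sketch(31, 10, frozenset({1, 2}))
        b = Sketch(31, 10, frozenset({3, 4}))
        assert jaccard_index(a, b) == 0.0

    def test_half_overlap(self):
        a = Sketch(31, 10, frozenset({1, 2, 3}))
        b = Sketch(31, 10, frozenset({2, 3, 4}))
        assert jaccard_index(a, b) == 0.5

    def test_both_empty_zero(self):
        assert jaccard_index(Sketch(31, 10), Sketch(31, 10)) == 0.0

    def test_mismatched_parameters_rejected(self):
        with pytest.raises(ValueError, match="mismatched"):
            jaccard_index(Sketch(31, 10), Sketch(21, 10))


def sim_matrix(ids, pairs):
    m = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for a, b, v in pairs:
        m.loc[a, b] = m.loc[b, a] = v
    return m


class TestNetworkAndTypes:
    def test_no_edges_below_threshold(self):
        m = sim_matrix(list("ABCD"), [("A", "B", 0.09)])
        g = build_type_network(m, min_ji=0.1)
        assert g.number_of_edges() == 0

    def test_threshold_inclusive(self):
        m = sim_matrix(list("AB"), [("A", "B", 0.1)])
        assert build_type_network(m, min_ji=0.1).has_edge("A", "B")

    def test_two_pairs_two_components(self):
        m = sim_matrix(list("ABCD"), [("A", "B", 0.5), ("C", "D", 0.5)])
        asg = assign_types(build_type_network(m))
        assert asg.type_sizes == {"I": 2, "II": 2}

    def test_chain_closure_single_component(self):
        m = sim_matrix(list("ABC"), [("A", "B", 0.3), ("B", "C", 0.3)])
        asg = assign_types(build_type_network(m))
        assert len(set(asg.types.values())) == 1

    def test_isolated_nodes_are_singletons(self):
        m = sim_matrix(list("ABC"), [])
        asg = assign_types(build_type_network(m))
        assert set(asg.types.values()) == {"singleton"}

    def test_labels_ordered_by_descending_size(self):
        m = sim_matrix(list("ABCDE"),
                       [("C", "D", 0.5), ("C", "E", 0.5), ("A", "B", 0.5)])
        asg = assign_types(build_type_network(m))
        assert asg.types["C"] == "I"      # size-3 component
        assert asg.types["A"] == "II"

    def test_assignment_invariant_to_input_order(self):
        rng = np.random.default_rng(6)
        ids = [f"r{i}" for i in range(10)]
        m = pd.DataFrame(np.eye(10), index=ids, columns=ids)
        for i in range(10):
            for j in range(i + 1, 10):
                v = float(rng.random() < 0.2) * rng.uniform(0.1, 0.9)
                m.iloc[i, j] = m.iloc[j, i] = v
        perm = list(rng.permutation(ids))
        a1 = assign_types(build_type_network(m))
        a2 = assign_types(build_type_network(m.loc[perm, perm]))
        assert a1.types == a2.types

    def test_raising_threshold_never_merges_components(self):
        rng = np.random.default_rng(7)
        ids = [f"r{i}" for i in range(12)]
        m = pd.DataFrame(np.eye(12), index=ids, columns=ids)
        for i in range(12):
            for j in range(i + 1, 12):
                v = rng.uniform(0, 0.6)
                m.iloc[i, j] = m.iloc[j, i] = v
        lo = assign_types(build_type_network(m, min_ji=0.2))
        hi = assign_types(build_type_network(m, min_ji=0.4))
        # refinement: replicons sharing a type at the higher cutoff must
        # share one at the lower cutoff
        for a in ids:
            for b in ids:
                if hi.types[a] == hi.types[b] and hi.types[a] != "singleton":
                    assert lo.types[a] == lo.types[b]


class TestSubtypes:
    def test_invalid_thresholds_rejected(self):
        m = sim_matrix(list("AB"), [("A", "B", 0.9)])
        with pytest.raises(ValueError):
            assign_subtypes(["A", "B"], m, subtype_ji=0.1, min_ji=0.1)

    def test_uniform_high_similarity_single_subtype(self):
        m = sim_matrix(list("ABC"),
                       [("A", "B", 0.95), ("B", "C", 0.95), ("A", "C", 0.95)])
        subs = assign_subtypes(list("ABC"), m)
        assert set(subs.values()) == {"a"}

    def test_singleton_type_one_subtype(self):
        m = sim_matrix(["A"], [])
        assert assign_subtypes(["A"], m) == {"A": "a"}


class TestTruthRecovery:
    def test_four_class_population_recovers_four_types(self, small_population):
        pop = small_population
        seqs = {}
        truth = {}
        for cname, rd in pop.replicons.items():
            if cname == "chromosome":
                continue
            for s in rd.carriers:
                rid = f"{s}:{cname}"
                seqs[rid] = pop.replicon_sequence(s, cname)
                truth[rid] = cname
        asg, m, _ = type_plasmids(seqs, scaled=30, min_ji=0.1)
        non_singleton = {t for t in asg.types.values() if t != "singleton"}
        assert len(non_singleton) == 4
        # detected types partition exactly along true classes
        for t in non_singleton:
            classes = {truth[r] for r in asg.type_members(t)}
            assert len(classes) == 1

    def test_two_backbone_class_recovers_two_subtypes(self):
        # one plasmid class with two anciently diverged insertion-block
        # backbones; re-thresholding at 0.5 must recover the block truth
        matched = 0
        usable = 0
        for seed in (1, 2, 4, 8, 9, 10):
            cfg = SimulationConfig(
                n_strains=14, mu=0.003, seed=seed,
                n_core_chromosome=30, n_accessory_chromosome=0,
                plasmid_classes=[PlasmidClassSpec(
                    "P", hgt_rate=0.0, recomb_rate=0.0, n_core=40,
                    n_accessory=0, gain_rate=0, lose_rate=0,
                    insertion_block=InsertionBlock(prob=0.5, n_genes=30),
                    backbone_divergence=0.03)])
            pop = simulate_population(cfg)
            rd = pop.replicons["P"]
            blk = [c for c in rd.content.columns if "_blk" in c][0]
            truth = {s: int(rd.content.loc[s, blk]) for s in rd.carriers}
            if min(sum(truth.values()), len(truth) - sum(truth.values())) < 4:
                continue
            usable += 1
            seqs = {f"{s}:p1": pop.replicon_sequence(s, "P")
                    for s in rd.carriers}
            asg, _, _ = type_plasmids(seqs, scaled=20, min_ji=0.1,
                                      subtype_ji=0.5)
            groups = {}
            for r in asg.types:
                groups.setdefault(asg.subtypes[r], set()).add(r.split(":")[0])
            want = [frozenset(s for s in truth if truth[s] == v)
                    for v in (0, 1)]
            if sorted(map(frozenset, groups.values())) == sorted(want):
                matched += 1
        assert usable >= 4
        assert matched == usable
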