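# Methods

This note documents the models behind `plasmidome`, the defaults and their
units, the numerical choices, and what the synthetic-population tests do
and do not demonstrate about real data.

## The inference problem

Given closed multi-replicon assemblies from a bacterial population, the
package asks two linked questions: (i) how do the extrachromosomal
replicons partition into types, and (ii) which types are co-transmitted
with the chromosome (vertical) versus exchanged between lineages
(horizontal)? The transmission question is answered by comparing gene-tree
discordance *within* and *between* replicons against a chromosomal null,
never by asserting an absolute clock or rate.

## Plasmid typing by FracMinHash networks

Each replicon sequence is reduced to the set of 64-bit hashes of its
canonical k-mers (lexicographic minimum of k-mer and reverse complement;
k-mers containing non-ACGT characters are skipped whole) that fall below
2⁶⁴/`scaled`. The hash is splitmix64 applied to the 2-bit-packed k-mer
with a fixed XOR seed, so sketches are bit-reproducible across platforms;
they are not interchangeable with other tools' signatures. The Jaccard
index of two sketches is an unbiased estimator of the k-mer-set Jaccard
similarity with error ~1/√(sketch size).

Types are connected components of the similarity graph with edges where
JI ≥ `min_ji`; the threshold is **inclusive** (the field's convention
states the cutoff both as "> 0.1" and as "a minimum of 0.1"; we fix the
inclusive reading and expose the parameter). Components are labelled
I, II, III, … by descending size, ties broken by lexicographically
smallest member; single nodes are `singleton`. Subtypes re-threshold
within a type at `subtype_ji` (default 0.5) and are labelled a, b, c, …
How subtypes should be delimited from a k-mer network is genuinely open;
re-thresholding is one defensible, monotone choice (raising a threshold
can only refine, never merge, components).

Defaults k = 31, scaled = 10 000 suit megabase-scale natural replicons.
The synthetic replicons are ~100× smaller than real plasmids, so the
pipeline examples and the acceptance run use scaled = 100, keeping a few
hundred hashes per sketch and JI error below ~0.05.

## Synthetic populations

The generator produces the one thing real data never provide: known
transmission truth. Time is in coalescent units throughout; all rates are
per unit coalescent time.

* **Chromosome genealogy**: Kingman coalescent (waiting time Exp(k(k−1)/2)
  while k lineages remain), ultrametric, binary.
* **Whole-plasmid transfer**: conjugation events are placed on the *cell*
  genealogy; at an event, the recipient lineage's plasmid ancestry jumps
  to a contemporaneous donor chosen uniformly. The plasmid genealogy is
  reconstructed by sweeping these jumps tip-to-root (two plasmid lineages
  on one cell edge coalesce on contact). Two placement models:
  - `length` (default): a Poisson process with intensity `hgt_rate` per
    unit branch length — the natural null, and the model under which the
    realised event count is Poisson(rate × tree length).
  - `pairwise`: intensity `hgt_rate`·k(k−1)/2 while k lineages coexist,
    i.e. a constant rate per pair of contemporaneous cells. Because most
    branch *length* in a coalescent tree lies on few deep edges, the
    `length` model mostly moves whole clades together and leaves plasmid
    backbones aligned with chromosomal clades; the `pairwise` model
    concentrates transfers toward the present and scatters single strains
    across backbones — the pattern actually observed for symbiosis
    plasmids. The default symbiosis-element class uses `pairwise` at rate
    1.5 per pair, calibrated so its plasmid–chromosome gene-tree
    discordance approaches saturation (cross-replicon GRF mean ≳ 95),
    matching the near-maximal discordance reported for natural pSyms.
  - Losses prune whole clades at `loss_rate` per unit branch length.
* **Sequences**: JC69 from uniform-random root sequences, μ expected
  substitutions/site/unit time (default 0.01, giving ~2 % typical pairwise
  core divergence, ANI ≈ 98). Genes are `gene_length` = 300 bp by default
  (a desk-scale stand-in for conserved core-gene alignment blocks; tests
  that need more per-gene signal use 450–600 bp and say so below).
  Within-element homologous recombination gives each core gene its own
  genealogy: the element tree perturbed by gene-level transfer events at
  `recomb_rate` (same overlay machinery, applied per gene).
* **Gene content**: core families present in every carrier; accessory
  families evolve as independent two-state Markov processes (`gain_rate`,
  `lose_rate`; root at stationarity), so occupancy converges to
  gain/(gain+lose). An insertion block is a linked set of families gained
  and lost as one unit — the mechanism behind bimodal plasmid-size
  distributions.
* **Ancient backbones**: for the symbiosis class, the insertion block is
  instead fixed to one side of the element tree's root split, and block
  carriers receive extra fixed substitutions in the core at
  `backbone_divergence` (default 0.04). This emulates two anciently
  diverged element backbones coexisting in one population via transfer:
  it depresses the type's ANI by ~4 points relative to other replicons,
  makes reconstructed element trees split by backbone, and drives
  between-subtype F_ST toward 1.
* **Traits and environment**: a baseline trait follows Brownian motion on
  the chromosome tree with Pagel's λ = 0.1 and σ² = 1 (partner quality in
  the emulated system is plasmid-encoded; the chromosome carries little
  signal), plus a fixed effect of `clade_effect` = 5 for strains whose
  focal element carries the backbone block (the observed subtype–quality
  correspondence is strong, and this makes the backbone the dominant
  variance component). The two-level environment label (C/N) is Bernoulli
  with P(C) = 0.5 ± `treatment_bias` (default 0.3) keyed to the same
  backbone.
* **Determinism**: one master seed; per-component streams are spawned
  through `numpy` `SeedSequence` in a fixed order, so every output is a
  pure function of the configuration.
* **Emission**: per-strain multi-record FASTA (`strain:replicon`; the
  chromosome is the largest record, plasmids p1, p2, … by descending
  length), CDS FASTA + gene table TSV, metadata TSV, and a truth JSON
  (Newick trees, event log, expected transmission calls). 15 % of each
  replicon is a neutral spacer so sketches contain non-genic signal.

What the generator does **not** emulate: indels and rearrangements (genes
are generated aligned), rate heterogeneity across sites or lineages,
intragenic recombination breakpoints, annotation noise, paralogy, or
assembly error. Passing truth-recovery tests therefore demonstrates the
statistical machinery, not robustness to real-world annotation/alignment
artefacts.

## Trees and tree distance

Distance trees are deliberate: neighbor joining (Studier–Keppler) on JC69
distances is deterministic, fast enough for tens of thousands of
resampled trees, and sufficient for topology-level GRF statistics; it
replaces likelihood tree search, which this package does not attempt.
Numerical choices: JC69 distances use pairwise deletion and are capped at
d = 5.0 when the observed difference proportion reaches 3/4 (saturation,
flagged); NJ ties in the Q matrix resolve to the smallest index pair;
negative pendant branch lengths are clamped to zero with the deficit
moved to the sister branch. The resampling hot path runs NJ straight to
bipartition bitsets without building tree objects; a test asserts the two
routes agree exactly.

The GRF distance is the Robinson–Foulds bipartition distance normalised
by the total non-trivial internal edge count of the two trees (2(n−3) for
two binary trees) and scaled to 0–100; trees are first pruned to their
shared leaf set (≥ 4 leaves required). Using actual edge counts keeps 100
attainable for multifurcating inputs. Exact numeric parity with any
particular published GRF variant is not claimed — only scale-compatible
behaviour (0 = identical, 100 = no shared bipartition).

## Transmission inference

Per replicate, two disjoint subsamples of `n_genes` core genes are drawn
(disjointness avoids trivially shared signal and is toggleable), each
concatenated, a tree built, and the GRF recorded; `n_reps` (default 1000)
replicates form the distribution. When a core holds fewer than
2·`n_genes` families, `n_genes` drops to ⌊core/2⌋ with a warning —
mirroring the use of 10-gene subsamples on small-core symbiosis elements.
Replicate r of master seed s uses substream SeedSequence((s, r)), so
extending `n_reps` preserves earlier replicates. The null threshold is
the 95th percentile (linear interpolation) of the within-chromosome
distribution; a replicon is `decoupled` iff the median of its
cross-replicon distribution exceeds it. The fraction of values above the
threshold is also reported for users who prefer stricter rules. Gene
subsampling is joint over the shared strain set (per-strain independent
subsampling would break the one-tree-per-set construction).

## Pangenome, popgen, and trait statistics

* Families: single-linkage at ≥ 90 % global identity (edlib NW edit
  distance over the longer length) with ≥ 80 % length compatibility;
  candidate pairs are prefiltered by shared 16-mers and verified against
  one representative per existing cluster in a bucket — near-linear in
  practice and exact on inputs whose families are well inside the margins
  (the generator's are, at ≤ ~5 % within-family divergence). Family ids
  are the smallest member id, so output is input-order stable.
* Core overlap between two core sets is |A∩B|/min(|A|,|B|) (subset ⇒ 1);
  the denominator is configurable.
* PCoA is classical cmdscale: double-centre −½JD²J, eigendecompose,
  scale eigenvectors by √eigenvalue; negative eigenvalues are reported
  but excluded from coordinates (no Cailliez correction). Cross-checked
  against scikit-bio's implementation in tests.
* Fisher's exact test is two-sided by probability ordering (scipy).
  Exact p-values are discrete and conservative; tests assert type-I error
  ≤ nominal rather than strict uniformity, which no exact test attains.
* π is the mean over unordered pairs of per-site differences with
  pairwise deletion (gap/N columns cost only the pairs they touch);
  ANI = 100(1−π̄) over comparable positions. Hudson's F_ST = 1 − H_w/H_b
  (groups averaged for H_w) is undefined (NaN) when H_b = 0. Windows are
  0-based half-open at fixed step (defaults 10 kb / 1 kb, exposed); a
  trailing partial window is kept only when strictly longer than half a
  window; windows without segregating sites are flagged missing.
* Pagel's λ: covariance σ²C(λ) with off-diagonal shared-path entries
  scaled by λ ∈ [0, 1] (upper bound fixed at 1); μ by GLS and σ² by ML
  are profiled analytically, leaving a 1-D bounded Brent search (endpoint
  candidates checked; a test pins the optimizer to a 10⁻⁴ grid oracle).
  The λ = 0 test is a likelihood-ratio test on χ²₁ — the same convention
  as the standard R implementation, against which the fit agrees to 4+
  decimals on shared data. Note the LRT is conservative at the λ = 0
  boundary (empirically ~0.5 % rejections at α = 0.05 on 20–100-tip
  trees; ~90 % of null LR statistics are exactly 0), a property of the
  estimator, not of this implementation.
* χ² independence tests are Pearson without continuity correction;
  zero-margin rows/columns are dropped with a warning first.

## Pipeline and problem sizes

Stages communicate through plain-text files under the run directory and
are individually resumable; identical config + seed gives byte-identical
outputs. The test suite and the acceptance script run everything at desk
scale, chosen as: populations of 25–62 strains; cores of 100–400 genes of
300–600 bp; 60–300 resampling replicates per GRF distribution (medians
and 95th percentiles are stable well below the 1000-replicate default);
typing at scaled = 20–100 for the short synthetic replicons. The trait
contrast (λ on the focal element tree vs the chromosome tree) is asserted
only on populations where the backbone split materialises (both groups
≥ 5 carriers) — it is a property of that scenario, not of every random
draw.

## Known limitations

* Distance-based trees understate support for short internal edges; GRF
  distributions therefore have a nonzero noise floor that the
  chromosomal null absorbs by construction, but absolute GRF values are
  not comparable across very different core sizes or gene lengths.
* The whole-plasmid replacement model ignores partial transfers and
  homologous recombination tracts between replicons.
* The family clusterer is a desk-scale stand-in for a full ortholog
  caller: no paralog splitting, no synteny, protein-level identity not
  considered.
* Real-data CDS inputs of unequal length within a family would need an
  external per-family aligner before tree building; the pipeline skips
  such families and says so, since the generator emits aligned genes.
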