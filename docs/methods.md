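# Methods

`gcpsr` implements multi-locus species delimitation by genealogical
concordance (GCPSR): species limits are placed where clades are recovered
monophyletic, with strong support, consistently across several independent
gene genealogies. The package covers the analysis layer of that workflow —
marker assessment, the initial clade-hypothesis tree, the concordance
scoring, and haplotype summaries — together with a simulator that generates
data with the statistical structure the analysis assumes, so every stage can
be exercised end to end without external data.

## Alignments, concatenation and trimming

Alignments are rectangular character blocks over `A C G T`, IUPAC ambiguity
codes, the gap `-` and the missing symbol `?`. Two conventions matter
throughout:

* `?` is the only "missing" symbol. It is introduced by concatenation (a
  strain unsequenced at a locus receives a `?` run spanning that locus) and
  removed by `trim_missing_columns`, which drops every column containing a
  `?` in any row.
* `-` is data, not missing data. Gap columns survive trimming because the
  haplotype stage treats the gap as a fifth character state.

Rows are upper-cased on input and `U` is mapped to `T` (the marker panel
mixes rDNA and protein-coding loci). Partition coordinates are 0-based
half-open internally and 1-based inclusive in the RAxML-style partition file
written alongside the supermatrix. `trim_missing_columns` returns a small
result record rather than a bare alignment so that the degenerate
all-columns-removed case can be flagged as metadata instead of an exception.

## Marker variability and the barcode gap

Per locus we report the number of sequences, unique sequences (exact string
equality, gaps and `?` significant), aligned length, distinct site patterns
(columns as tuples over all taxa; every symbol distinguishes), and
parsimony-informative sites (columns with at least two unambiguous bases
each present in at least two taxa; gaps, `?` and ambiguity codes are not
states). Pattern counting and PIC counting follow the conventions of the
likelihood and parsimony tools usually used for these tables; the choice
affects only table reproduction, not downstream logic.

p-distances are uncorrected mismatch proportions with pairwise deletion:
a site enters a pair's comparison only when both rows hold an unambiguous
base. Pairs with no comparable site are stored as undefined (NaN) and
excluded from summaries rather than imputed. The barcode-gap summary
partitions all defined pairs into within-clade and between-clade sets under
a clade hypothesis and reports mean/min/max/count for each; *overlap* is the
closed-interval test `within_max >= between_min`, because the assessment of
a marker is categorical (gap present or not).

## The initial tree: observed-distance neighbor joining

The clade hypothesis is seeded by neighbor joining on the concatenated
supermatrix using an "observed distance" in which gap sites are retained:
gap-versus-base counts as a difference, gap-versus-gap as a match, and only
`?` (plus unresolvable ambiguity codes) is skipped pairwise. This mirrors
the distance-with-gap-sites option of the alignment viewers commonly used
for such first-pass trees; the exact gap semantics of those GUIs are
undocumented, so this rule is recorded here as the package's definition.

NJ is the standard Saitou–Nei agglomeration. Determinism: Q-matrix ties are
broken by the first minimal (i, j) pair in the current matrix order, with
merged nodes appended at the end. Negative limb lengths are clamped to zero
with the deficit moved to the sibling edge so leaf-to-leaf path lengths are
preserved; raw values are logged at DEBUG. For additive inputs the algorithm
is exact (verified against a least-squares topology search and an
independent agglomeration trace in the tests).

Bootstrap support resamples columns with replacement, recomputes the
observed-distance NJ tree per replicate, and annotates each internal edge of
the reference tree with the percentage of replicates containing the same
bipartition — support is reported on the reference tree, not on a consensus
of replicates. Implementation note: with per-pair difference/validity
indicator matrices precomputed, all replicate distance matrices are obtained
by one matrix product per batch against the resampled column multiplicities,
so the cost is dominated by the NJ agglomerations. One root seed spawns
per-replicate substreams, making results independent of batch size.
Replicates producing an undefined pair are discarded; more than 10%
discarded aborts the run. Midpoint rooting locates the midpoint of the tree
diameter itself (falling back to an existing node when the midpoint lands on
one) and carries edge supports across the rerooting by bipartition identity.

## Concordance scoring

Gene trees enter as newick with internal-node labels read as supports; the
scale is auto-detected (any value above 1 means percent, otherwise
posterior) and can be overridden per tree. Splits are canonicalised as the
leaf set not containing the lexicographically smallest leaf, which makes
them comparable across rootings; monophyly on unrooted trees is split
membership, with singletons and complements of singletons monophyletic by
convention. Strict consensus intersects the canonical split sets and
rebuilds the tree from the surviving (necessarily nested) clusters.

The acceptance rule for a clade at a locus is: recovered as a distinct group
in the parsimony strict consensus (no support threshold — strict consensus
trees carry none) *and* support strictly greater than 80% in each of the NJ,
ML and Bayesian trees. Posteriors are compared as PP × 100 against the same
threshold, i.e. PP > 0.80, because a single phrase governs all three
methods. Strains absent from a locus are dropped from the clade for that
locus's evaluation (a marker sequenced for only part of the strains can
still be scored); a clade reduced below two members is "not evaluable"
there. Verdicts: *concordant* (black dot) — passes every evaluable locus;
*partial* (grey dot) — passes at least two but not all; *discordant*
otherwise. Candidate clades are proposed from the midpoint-rooted initial
tree tip-ward to root-ward (ascending node height); all candidates are
emitted and the concordance grid decides, since the tip-to-root sweep has no
natural stopping rule — nested passing candidates are left to the analyst.

## Haplotypes

On a `?`-free alignment, strains with identical rows share a haplotype; the
gap is a distinguishing fifth state and IUPAC codes are distinguishing as
well (exact-sequence semantics). Ids are assigned by first occurrence, as
the original numbering of any given study is not reconstructible; a member
table is produced instead. By default the pipeline haplotypes the
concatenation of the three loci sequenced for every strain (MCM7 + RPB1 +
TSR1 in the default panel), excluding the incompletely sequenced markers,
after trimming all missing-data columns. Summaries: variable sites,
singleton count, haplotypes per clade (a haplotype spanning clades would
contradict the hypothesis and is flagged), and a haplotype × region
cross-tab with region-exclusivity calls.

## The simulator

`simulate_species_scenario` draws a composite ultrametric genealogy: four
in-complex clades radiate at `between_clade_depth` (0.03 substitutions/site
by default) from a common point — a star-like backbone, matching the poor
backbone resolution such complexes show — and one distant clade attaches at
`outgroup_depth` (0.15). Within each clade a random-join (Yule-topology)
subtree of depth `within_clade_depth` (0.002) is drawn with uniform node
heights scaled to that fixed depth. Sequences evolve site-independently
under K80 (transition/transversion ratio κ = 2) with discrete-gamma rate
heterogeneity (shape 0.5, 8 equal-probability categories whose mean rates
are renormalised to average one). Branch lengths are expected
substitutions/site, so configured depths translate directly into p-distance
magnitudes. Locus lengths default to 513/603/610/738/607 bp; whole-locus
dropout removes an exact rounded count of strains per locus (22% for the
ITS-like first locus, 5.6% for the RPB2-like fourth), modelling missingness
as absence from the locus so that concatenation reintroduces it as `?`
padding. Clade sizes default to 25/40/4/6/15 (totalling 90 strains, with the
second clade largest and two small clades, consistent with the haplotype
structure such surveys report). Regions are sampled per strain from
clade-specific weight tables whose defaults encode the qualitative pattern
of the motivating system: two worldwide clades, one single-region clade, one
subtropical clade, one strictly European distant species.

What the simulator deliberately does not model: incomplete lineage sorting
(gene trees share the species-tree topology), indel evolution (alignments
are generated aligned), base-composition bias (K80 is symmetric), and
intragenomic marker heterogeneity. Passing the recovery tests therefore
shows the pipeline machinery is correct under clean, concordant signal of
realistic magnitude — not that real data of this difficulty will always
yield black dots.

`method_tree_suite` provides the concordance stage's inputs: NJ trees are
computed by the real NJ + bootstrap machinery on the simulated alignments,
while MP-strict/ML/BI trees are stand-ins derived from the true genealogy
(topology only, support 100%, posterior 1.0 respectively). Distortions
reproduce documented failure modes: collapsing a named clade to a polytomy
at one locus (the clade stops being monophyletic there), or forcing one
support value (e.g. an ML bootstrap of 51%), which must surface as exactly
one exception cell in the grid.

## Recovery experiment

`recovery_trial` runs the whole pipeline on one simulated data set: generate
→ concatenate → observed-distance NJ with bootstrap → midpoint root →
propose candidates → build the method suite → score concordance. A run
counts as a recovery when every true clade appears among the proposed
candidates and every true clade is fully concordant. Nested within-clade
candidates passing as well do not contradict the partition (well-supported
nodes internal to a species are expected) and are not counted against
recovery. The experiment sizes used by the tests and the acceptance script
are 20 seeds, 200 bootstrap replicates on the concatenated tree and 100 per
locus — chosen as the package's standard validation workload; fewer
replicates than the conventional 1000 only add support noise, so they make
the >80% criterion harder, not easier. The pipeline's user-facing default
remains 1000 replicates.

Reported p-distance magnitudes from the simulation are summarised over the
four in-complex clades, excluding the distant species: the barcode-gap
question concerns the complex itself, and the 0.15-deep outgroup would
otherwise dominate the between-clade mean with pairs that no one would
consult a secondary barcode to separate.

## Numerical and degenerate-input choices

* Distance matrices must be symmetric and non-negative; undefined entries
  abort NJ but merely reduce barcode-gap summaries.
* Bootstrap supports are percentages of kept replicates.
* `strict_consensus` requires identical leaf sets; `parse_newick` rejects
  duplicate leaves and reports parse errors with the underlying reader's
  position information.
* All stochastic components accept a single integer seed and spawn named
  substreams from it; identical seeds give byte-identical FASTA, newick and
  JSON outputs.
* Clamped NJ branch lengths keep path-length additivity on additive inputs
  to 1e-9.

## Known limitations

* The concordance stage consumes externally inferred MP/ML/BI trees; the
  package does not implement parsimony, likelihood or Bayesian tree search.
* Observed-distance semantics of legacy GUI tools are reproduced by a
  documented convention, so trees from those tools may differ in
  tie-breaking and gap treatment; topology-level agreement is the realistic
  expectation.
* Haplotype numbering is input-order based and will not match any published
  numbering; compare partitions, not labels.
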