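# Methods

`barcode-gauge` evaluates candidate DNA-barcode loci for a congeneric group of
plants. Its stages mirror the standard locus-screening workflow: sequence QC,
multiple alignment, Kimura 2-parameter (K2P) distances, inter/intraspecific
divergence parameters, barcoding-gap analysis, signed-rank comparison of loci,
leave-one-out identification, neighbor-joining monophyly assessment, and
detection of species-diagnostic sequence features. A synthetic-genus
generator provides ground truth so every stage can be exercised without any
sequence downloads.

## Quality control (`dataset_io`)

Records are rejected when the ungapped sequence is shorter than `min_len`
(default 100 bp), carries more than `max_ambiguous` ambiguous symbols
(default 1; any non-ACGT, non-gap IUPAC code counts — the stricter reading of
"more than one N"), or belongs to an undetermined taxon (species name
containing a `sp.`, `spp.`, `aff.` or `cf.` token, case-insensitively).

The congener screen mirrors a BLAST cross-check with the in-repo global
aligner: a record passes if its best identity AND query coverage
(aligned-query-length / query-length) against some conspecific record both
reach 0.90. Sole representatives of a species pass vacuously. Because
removing a record can orphan its conspecifics, the screen is iterated to a
fixed point; this makes the filter idempotent, at the cost that a mutually
dissimilar conspecific pair is removed entirely rather than one member being
kept arbitrarily. BLAST-style identity/coverage values would differ slightly
(local vs global alignment); the thresholds are exposed as parameters.

GC content is computed per record over unambiguous bases only (ambiguous
symbols leave both numerator and denominator), then averaged over records.

## Alignment (`align`)

Pairwise global and local alignments use affine gap scoring, default
+1/−1 match/mismatch and −5/−1 gap open/extend (a gap of length L costs
open + (L−1)·extend). These approximate ClustalW-era DNA defaults; the exact
values matter little at congeneric divergences and are configurable. The
engine is Bio.Align.PairwiseAligner; among co-optimal alignments its first
traceback is reported, which is deterministic for fixed inputs. Scores,
identities and coverages — the quantities the rest of the pipeline consumes —
are invariant across co-optimal tracebacks.

The progressive multiple alignment builds a neighbor-joining guide tree on
pairwise (1 − identity) distances and merges profiles in guide-tree
postorder. Profile–profile merging is an affine-gap dynamic program over
column count profiles (expected pairwise residue score between columns; gaps
and ambiguity codes score 0), vectorised along anti-diagonals. Output row
order equals input order; all-gap columns are dropped. No iterative
refinement or sequence weighting is attempted — at within-genus divergences
(≲ 11%) progressive alignment is essentially exact.

Variable sites are columns with ≥ 2 distinct unambiguous bases; gaps and
ambiguity codes are not states. Indels are counted as events: maximal gap
runs, identical (start, end) column intervals counted once however many rows
share them. A per-column alternative (`count_gap_columns`) is provided
because published indel counts are sometimes column-based.

## Distances (`distances`)

K2P distances use pairwise deletion: a column contributes to a pair only if
both rows carry an unambiguous base. With transition proportion P (A↔G, C↔T)
and transversion proportion Q over the L compared sites,

    d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q).

Saturated pairs (either logarithm argument ≤ 0) and pairs with L = 0 are
flagged undefined (NaN), excluded from all downstream means, and never
coerced to 0. Complete deletion is available by pre-filtering columns, but
pairwise deletion is the default, as in the common MEGA configuration for
this analysis. The overall mean distance is the mean over defined unordered
pairs; it is used for ranking loci, not for reproducing values computed under
other substitution models.

## Divergence parameters and gap analysis (`divergence`)

Six parameters summarise a locus (all substitutions/site, mean ± SD, SD with
the n−1 denominator and 0 for a single value):

* **all intraspecific distance** — over all conspecific pairs;
* **theta (θ)** — per-species mean conspecific distance, averaged across
  species with ≥ 2 accessions;
* **coalescent depth** — per-species maximum conspecific distance, averaged
  across species;
* **all interspecific distance** — over all heterospecific pairs;
* **theta prime (θ′)** — per-species mean distance from its members to all
  congeners, averaged across species;
* **minimum interspecific distance** — per-species smallest distance to any
  heterospecific member, averaged across species.

θ′ and the minimum interspecific distance are defined per species and then
averaged, the convention of the barcoding-gap literature; single-accession
species contribute only to the interspecific parameters.

The barcoding-gap profile histograms conspecific and heterospecific distances
(default bin width 0.005, the scale of published gap histograms) and reports
an overlap statistic: the fraction of intraspecific distances at or above the
5th percentile of the interspecific distribution. A clean gap gives ~0;
coincident distributions give ~0.95.

Locus pairs are compared with a paired Wilcoxon signed-rank test. Distances
are paired by unordered accession-id pairs present and defined in both loci;
pairs with < 4 shared accession pairs are flagged underpowered. Zero
differences are dropped and ties midranked. The two-sided p-value is exact
for n ≤ 25 — computed by dynamic programming over the rank-sum distribution,
identical to enumerating all 2^n sign patterns — and a normal approximation
with continuity and tie correction otherwise. The reported direction comes
from the sign of the median difference (rank-sum comparison on a zero
median). W statistics from other software may not be comparable because
pairing schemes vary; direction and significance are the meaningful surface.

## Identification (`identify`)

Leave-one-out, per locus. *Nearest distance*: the query takes the species of
its minimum-K2P reference. *Top hit* (BLAST1-style): the species of the
best-scoring local alignment, computed with the in-repo Smith–Waterman
engine — deterministic, no external executable, no E-values or heuristic
seeding. A tie on the optimum succeeds only if all tied references agree at
the scored level, making results independent of record order. Queries whose
species has no second representative cannot be matched correctly and are
excluded from the species-level denominator (they still count at genus
level); this choice shifts percentages and is therefore stated prominently.

## Features (`features`)

Coordinates are 1-based inclusive on the ungapped sequence (the "171–177 bp"
convention); the BED writer converts to 0-based half-open.

* Homopolymers: maximal single-base runs ≥ 6 bp by default.
* Tandem repeats: maximal perfect arrays of a primitive unit of 3–10 bp with
  ≥ 2 full copies and total length ≥ 12 bp; homopolymer arrays and arrays
  whose primitive period is below the unit minimum are excluded. Only
  perfect repeats are sought; the diagnostic insertions this tool targets are
  perfect.
* Inversions: the reverse complement of the query is locally aligned against
  a reference; the aligned block is trimmed to its maximal high-identity core
  (largest-sum contiguous column range scoring +1 per match and
  −id/(1−id) per non-match, so a segment is positive only above the identity
  threshold, default 0.98). A hit must span ≥ 50 query residues and beat the
  forward-strand alignment of the same segment. Found segments are masked and
  the scan repeated, so multiple inversions can be reported. The trimming
  step replaces a windowed scan: it is exact, needs no stride parameter, and
  snaps coordinates to the inverted segment even when chance matches would
  let the raw local alignment extend past its edges.
* Diagnostic columns: alignment columns where the states (base or gap) of the
  target species are disjoint from all other accessions' states.

## Trees and monophyly (`phylo`)

Saitou–Nei neighbor joining with deterministic lowest-index tie-breaking;
negative branch estimates are clamped to 0 with the deficit moved to the
sibling (raw values kept in a debug field). Undefined distances are imputed
as 1.1 × the maximum defined distance when they are ≤ 5 % of the entries
(keeping saturated pairs peripheral), otherwise the run fails loudly. The
tree is stored rooted at the final three-lineage junction (a trifurcation)
and treated as unrooted by downstream code.

A species is monophyletic when some edge bipartition isolates exactly its
accessions. Misplaced accessions are counted by greedy intruder removal:
repeatedly delete the accession whose removal makes the most species
monophyletic (ties broken alphabetically) until all species are. This counts
a single accession grafted into a foreign clade once — the natural reading of
"accessions in the incorrect taxonomic category" — whereas a per-species
largest-pure-clade count would charge the same graft to both species
involved.

Newick output writes branch lengths at full float precision and quotes labels
containing whitespace or punctuation; the package's own reader round-trips it
byte-identically.

## Synthetic data (`synthetic`)

The generator emulates a congeneric barcoding study. The species tree is a
star-like radiation: each of S species sits on its own stem off the root,
stems jittered lognormally (σ = 0.1) and normalised so the mean heterospecific
tip-to-tip path is exactly `target_inter`; accessions hang off their species
node at depth `target_intra`/2, so conspecific pairs sit at exactly
`target_intra`. This matches the design condition that between-species
divergences concentrate at the target; it deliberately omits deep
phylogenetic structure, so passing tests say nothing about taxa whose
interspecific divergences span orders of magnitude.

Sequences evolve by the exact K2P transition-probability matrix applied per
site per branch (transition/transversion rate ratio κ, default 2, a typical
plant-spacer value), rather than by sampling substitution-event counts:
multiple hits are handled exactly and the expected estimated distance between
two tips equals their path length by construction. The root sequence is
drawn i.i.d. with the target GC. Indels are Poisson events (default 0.05
events/site/unit branch length) with geometric lengths (mean 3 bp, a typical
spacer value; neither rate is identified by published tables, so both are
stated here once and exposed as parameters).

Two presets name the regimes of the study's two best loci: a GC-rich short
nuclear spacer (`ITS2`: 220 bp, GC 0.66, conspecific 0.006, heterospecific
0.035) and an AT-rich chloroplast spacer (`psbA-trnH`: 287 bp, GC 0.25,
0.048/0.107) — one gap-rich, one gap-poor regime.

Planted features are injected after evolution, all accessions of the carrier
species receiving the feature near a common anchor position. Insertion sites
are chosen so feature boundaries are sharp: flanking bases cannot extend a
run or repeat array, and for inversions no gap-free extension of the
reverse-complement match can reach a positive alignment score. The planted
inversion replaces the carrier's window with the reverse complement of a
designated non-carrier accession's window, so its identity against that
reference is exactly 1.0. Truth coordinates are recorded on the final
sequences, which is what makes exact-coordinate recovery a testable claim.

What the generator does **not** emulate: rate variation across sites and
lineages, alignment-hostile microsatellite churn, imperfect repeats,
contamination/mislabeled vouchers, and non-star species trees. Identification
efficiencies near 100 % on synthetic data therefore demonstrate correctness
of the pipeline, not expected field performance.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run simulations at 10 species × 5
accessions × 500 bp (parameter recovery and efficiency, 5 seeds), 6 × 3 × 300
bp (gap-overlap behaviour, 5 seeds per ratio), and 4 × 2 × 300 bp (100
feature-planting and 100 feature-free replicates). These sizes give stable
averages — the recovery tolerance (25 % relative) is dominated by the Poisson
noise of ~7 substitutions per species stem, which the 5-seed mean reduces to
a few percent — while keeping a full run to a few minutes on one CPU.

## Reproducing the original study's numbers

The packaged accession table (`barcode_gauge/data/uncaria_accessions.tsv`)
defines the datasets: 257 GenBank accessions over ITS2 (77 accessions, 14
species), rbcL (63/15), psbA–trnH (49/10), ITS (58/14) and matK (10/7).
`barcode-gauge accessions --locus L` emits the per-locus download lists; no
network code exists in the tested core. With the sequences fetched to FASTA,
`barcode-gauge run --config cfg.json` produces the per-locus summary,
divergence, gap-histogram, efficiency, signed-rank and monophyly tables in
the layout of the published ones. Expect sensitivity to the alignment
engine, the BLAST emulation, the tie policy, and the singleton-denominator
convention; distance-model differences (K2P here, composite-likelihood in
some published figures) shift absolute overall means but not locus rankings.

## Known limitations

* The signed-rank pairing scheme (shared accession pairs) is one of several
  defensible choices; published W+/W− values computed under another pairing
  are not comparable.
* The congener QC screen uses global-alignment identity, not BLAST identity;
  records near the 0.90 thresholds may be classified differently.
* The progressive aligner has no iterative refinement; at divergences well
  beyond the congeneric range its alignments (and hence distances) degrade.
* Monophyly counting is a greedy heuristic for the minimum-removal problem;
  it is exact in the common case of isolated grafts but may overcount on
  pathologically interleaved trees.
* At short locus lengths distances are coarse: on a 220 bp spacer a
  conspecific distance of 0.006 corresponds to ~1 substitution, so
  identification efficiency and gap overlap fluctuate strongly between
  replicates even when the divergence targets are met. The
  `truth_report` rule of thumb (gap ratio ≥ 5 ⇒ expected 100 % efficiency)
  assumes enough sites for the ratio to be resolved; the shipped recovery
  checks use 500 bp for exactly this reason.
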