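# barcode-gauge

Evaluation of candidate DNA-barcode loci for congeneric plants.

DNA barcoding assigns specimens to species from a short standardized DNA
region. Whether a locus works for a given genus hinges on a few quantitative
properties: interspecific divergence must exceed intraspecific variation (a
"barcoding gap"), leave-one-out identification must be accurate, species
should come out monophyletic on a distance tree, and ideally the locus offers
species-diagnostic characters (insertions, repeats, inversions). This package
implements that entire screening pipeline for datasets like the *Uncaria*
(Gouteng) candidate-barcode study — five loci (ITS2, rbcL, psbA–trnH, ITS,
matK) across a genus of medicinal plants whose adulterants are hard to tell
apart morphologically — and ships the study's 257-accession GenBank table as
a packaged fixture.

## What it computes

Genetic distances use the Kimura 2-parameter model with pairwise deletion:
with transition proportion *P* (A↔G, C↔T) and transversion proportion *Q*
over the compared sites,

    d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)

From the per-locus distance matrix it derives the six standard divergence
parameters (all-intra, θ, coalescent depth, all-inter, θ′, minimum
interspecific distance, each mean ± SD), barcoding-gap histograms with an
overlap statistic, exact Wilcoxon signed-rank comparisons between loci,
leave-one-out identification efficiency by the nearest-distance and local-
alignment top-hit (BLAST1-style) methods, Saitou–Nei neighbor-joining trees
with a per-species monophyly report, and diagnostic features (homopolymer
runs, perfect tandem repeats, reverse-complement inversions, diagnostic
alignment columns).

A synthetic-genus simulator (`barcode_gauge.synthetic`) generates congeneric
datasets with known truth — target conspecific/heterospecific K2P distances,
GC content, indels, planted diagnostic features — so the full pipeline is
testable end to end without downloading a single sequence. See
`docs/methods.md` for models, conventions and limitations.

## Worked example

```python
import barcode_gauge as bg
from barcode_gauge import synthetic as syn
from barcode_gauge.divergence import divergence_parameters, barcoding_gap

cfg = syn.SimulationConfig(n_species=6, accessions_per_species=3,
                           root_length=500, gc_target=0.66,
                           target_intra=0.006, target_inter=0.035, seed=11)
sim = syn.simulate_dataset(cfg)

msa = bg.progressive_msa(sim.dataset)
dm = bg.distance_matrix(msa, sim.dataset.species)

div = divergence_parameters(dm)
print("all-intra:", div.all_intra)
print("all-inter:", div.all_inter)
print("gap overlap:", round(barcoding_gap(dm).overlap, 3))
print("nearest-distance efficiency:",
      bg.efficiency(sim.dataset, "nearest_distance", "species", dm=dm), "%")

tree = bg.nj_tree(dm)
report, misplaced = bg.monophyly_report(tree)
print("misplaced accessions:", misplaced, "/", len(dm.ids))
```

Output:

```
all-intra: 0.0063 ± 0.0036
all-inter: 0.0310 ± 0.0062
gap overlap: 0.0
nearest-distance efficiency: 100.0 %
misplaced accessions: 0 / 18
```

The simulated genus was built with conspecific K2P distance 0.006 and
heterospecific distance 0.035; the recovered all-intra/all-inter means land on
those targets, the intra and inter distance distributions do not overlap
(overlap 0 = clean barcoding gap), every accession is re-identified to the
correct species when left out, and all species are monophyletic on the NJ
tree.

The same stages run from the shell:

```bash
barcode-gauge simulate --preset psbA-trnH --seed 1 --out sim/
barcode-gauge qc --fasta sim/sequences.fasta --meta sim/metadata.tsv \
    --locus psbA-trnH --out qc/
barcode-gauge identify --fasta sim/sequences.fasta --meta sim/metadata.tsv \
    --locus psbA-trnH --method nearest --level species
barcode-gauge run --config cfg.json    # full multi-locus report bundle
```

## The packaged study table

`bg.load_study_metadata()` returns the accession table of the *Uncaria*
study: 257 accessions — ITS2 77 (14 species), rbcL 63 (15), psbA–trnH 49
(10), ITS 58 (14), matK 10 (7). `barcode-gauge accessions --locus ITS2`
prints the download list for a locus; the tested core contains no network
code. Once sequences are fetched into per-locus FASTA files,
`barcode-gauge run` reproduces the study's analysis tables (lengths and GC,
divergence parameters, gap histograms, signed-rank locus rankings,
identification efficiencies, NJ monophyly); `docs/methods.md` discusses which
published values should reproduce exactly and which are sensitive to
alignment and tie-policy choices.

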