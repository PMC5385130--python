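# paircomp

Comparative genomics of closely related prokaryote genome pairs: average
nucleotide identity (ANI), two-way average amino acid identity (AAI),
shared/unique gene inventories, and fragment-recruitment discrimination with
identity-threshold calibration — exercised end-to-end on synthetic diverged
genome pairs with known ground truth.

The package is aimed at the situation where two genomes of the same lineage
are recovered from different environments (say, a metagenome-assembled genome
and a complete reference) and one wants to (a) quantify their relatedness,
(b) partition their gene content into shared and unique sets, and (c) find an
alignment-identity cutoff at which metagenome reads can be attributed to one
genome or the other with a controlled spurious-mapping rate.

## What it computes

For genomes A and B with gene models:

* **ANI** — mean percent identity over reciprocal best-hit gene pairs with
  ≥70% identity and ≥70% coverage of the shorter gene. ~95% is the
  conventional species boundary.
* **AAI (two-way)** — the protein analogue over proteins ≥100 aa; the mean of
  the two directional means. ~65–75% spans the genus boundary.
* **Percent shared genes** — 100 × 2n / (nA + nB), with n the number of
  two-way AAI pairs and nA, nB the proteins ≥100 aa in each genome.
* **Homolog inventories** — directional shared/unique partitions at e-value
  ≤10⁻⁵ and identity ≥30%, with optional COG-category summaries.
* **Threshold sweep** — both genomes cut into non-overlapping 150 bp
  fragments, each genome's fragments mapped against the other genome over
  identity thresholds 70–100%; the selected cutoff is the smallest threshold
  holding spurious cross-mapping ≤1% in both directions.
* **Read recruitment** — single best hit per read against the joint
  reference at the selected threshold; per-genome counts and the A:B ratio.

All alignments come from a seed-and-extend local aligner (exact k-mer seeds,
affine-gap Smith–Waterman extension, BLAST-style gap-inclusive identity)
checked in the test suite against a full dynamic-programming oracle.

A first-class synthetic-data module generates the inputs: gene-dense ancestor
genomes; descendant pairs with programmed pairwise divergence (exact rate
inversion, ts/tv bias, site-scale rate heterogeneity, intergenic indels,
per-lineage gene loss) plus a ground-truth record of ortholog pairs and
per-gene identities; and labeled read mixtures. See `docs/methods.md` for the
model and its assumptions.

## Worked example

```bash
# simulate a 100 kb pair at 23.1% site divergence (expected ANI ~77%) with
# 15% per-lineage gene loss, plus a 4:1 read mixture
paircomp simulate --out-dir demo --length 100000 --divergence 0.231 \
    --gene-loss 0.15 --n-reads 10000 --weight-a 4 --weight-b 1 --seed 1

# pair statistics
paircomp ani --genome-a demo/A --genome-b demo/B
paircomp aai --genome-a demo/A --genome-b demo/B

# threshold calibration and read discrimination
paircomp sweep --genome-a demo/A --genome-b demo/B --out-dir demo/sweep
paircomp recruit --genome-a demo/A --genome-b demo/B \
    --reads demo/reads.fna --threshold 96 --out-dir demo/recruit
```

Output for seed 1:

```
wrote pair (programmed ANI 76.9%) to demo
ANI A->B: 78.49%  B->A: 78.49%  (n=69)
AAI two-way: 59.35%  (n=75 pairs; 86/89 proteins >= 100 aa)
selected threshold: 97%
mapped: {'A': 7978, 'B': 2022}  unmapped: 0  ratio A:B = 3.9455984174085064
```

Reading this: the pair was programmed to 23.1% site divergence, and measured
ANI lands within ~2 points of 100×(1−d) (local alignment trims diverged ends,
which nudges identity up; see the methods note). The sweep finds that a 97%
identity cutoff holds spurious cross-mapping below 1% in both directions,
and recruiting the mixed reads at a 96% cutoff recovers the programmed 4:1
mixture as a 3.95 ratio.

`paircomp report` runs the whole comparison (ANI, AAI, shared genes,
inventories, link table, optional COG summary) and writes a JSON report plus
TSVs; every output file records the tool version and a hash of the run
configuration, and every run is byte-reproducible for a fixed seed.

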