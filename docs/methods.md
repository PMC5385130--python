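# Methods

`paircomp` re-creates, on synthetic data with known ground truth, the
comparative-genomics computations used to characterize a pair of closely
related prokaryote genomes from different environments: best-hit homology
between gene sets, average nucleotide identity (ANI), two-way average amino
acid identity (AAI), shared/unique gene inventories, and a
fragment-recruitment procedure that calibrates an identity threshold able to
discriminate reads belonging to one genome from the other.

## The synthetic genome-pair model

### Ancestor

A single-contig ancestor is generated with dense protein-coding structure:
gene lengths are gamma-distributed (shape 4) around `gene_length_mean`
(default 900 bp), rounded to whole codons with a 300 bp floor so every
protein is at least 100 aa; genes are placed non-overlapping with the
intergenic remainder split uniformly; ~50% of genes sit on the minus strand;
each gene is an ATG followed by random non-stop codons drawn at the target GC
(default 0.60, coding density default 0.90 — the characteristics of the
gene-dense thermophile genomes this emulates). Stop codons are slightly
AT-rich, so rejection nudges realized GC up by ~0.3 points; the generator
guarantees realized GC within ±2 points of target at ≥50 kb.

### Divergence

Two descendants are derived independently. The target statistic is the
**pairwise** aligned-site divergence `d` (so expected ANI ≈ 100·(1−d)). Since
both lineages can substitute the same site — and sometimes to the same base —
a naive per-lineage rate of d/2 understates the coincidence correction by
~0.02 at d = 0.231. The per-lineage rate p is instead solved exactly from

    2p − (1 + c)·p² = d,    c = (R² + ½) / (R + 1)²

where R is the transition/transversion ratio (default 2) and c the
probability that two independent substitutions of the same site pick the same
target base. Calibration tests confirm the realized mean aligned-site
mismatch is within ±0.005 of d up to d = 0.231.

**Rate heterogeneity.** Real genome pairs at ~77% ANI show homolog identities
spanning roughly 70–100%: substitution rates vary along the genome (conserved
domains and genes, fast-evolving regions). The generator models this with
discrete rate classes assigned to 150 bp windows of the ancestor — shared by
both lineages, since conservation is a property of the site. Default classes
(multiplier, weight): (0.15, 0.04), (0.70, 0.26), (1.00, 0.44), (1.30, 0.20),
(1.90, 0.06), rescaled so the weighted mean multiplier is exactly 1. Windows
are allocated to classes by stratified (largest-remainder) counts and
shuffled, which removes class-sampling variance; each class rate is inverted
exactly for its own pairwise divergence m·d, so the genome-wide expectation
stays exactly d by linearity. Without this feature (``rate_classes=None``)
every fragment's identity concentrates near 100(1−d) and the recruitment
sweep has no conserved tail to calibrate against — unrealistically easy
discrimination. Very large d with the default fast class can make m·d
infeasible (the quadratic has no root); validation raises and homogeneous
classes can be passed instead.

Coding substitutions never create stop codons (the target base is redrawn
among the remaining alternatives), so descendant proteins stay stop-free and
the TruthRecord's per-gene protein identities are meaningful.
`nonsyn_fraction` forces that fraction of coding substitutions to change the
amino acid (falling back to any non-stop change at sites with no
amino-acid-changing alternative, e.g. some fourfold-degenerate positions).
This can only *lower* AAI relative to the codon-random baseline: with
substitution sites placed uniformly, the nonsynonymous fraction cannot drop
below its natural ~⅔, because only about a third of coding sites admit a
synonymous change. Raising AAI toward ANI would require codon-position-biased
substitution placement (purifying selection), which is out of scope; AAI
tests are therefore truth-relative (against the generator's realized protein
identities), not target-relative.

**Indels** (default 10⁻⁴ per site, lengths 1–10 bp) are placed in intergenic
regions only, keeping gene models frame-intact; coding frameshifts are real
but rarely fixed, and excluding them keeps the protein ground truth exact.
**Gene loss** removes each gene (sequence and model) per lineage with the
given probability, so the expected directional shared-gene fraction is
1 − loss of the other lineage.

### Reads

Reads of fixed length (default 150 bp — a typical short-read length) are
drawn from uniformly random positions and strands of genomes chosen in
proportion to mixture weights; a reserved `background` component yields
i.i.d. random sequence. Substitution errors are uniform per base (default
0.5% — a free choice, as no error model is prescribed for the real data).
Provenance labels are retained for truth-based tests. Real-read features not
modeled: quality-correlated errors, indel errors, coverage bias, paired ends.
Passing tests therefore demonstrate correctness of the *procedures*, not
robustness to every real-data artifact.

## Alignment engine

Seed-and-extend local alignment. Exact k-mer seeds (k = 11 nucleotide, 4
protein; ambiguity characters never seed) locate candidates; extension is
affine-gap Smith–Waterman (Gotoh) over the full subject when it is ≤5 kb —
so for gene-scale comparisons the optimal local score is returned whenever a
seed exists — and over windows around clustered seed diagonals for
genome-scale subjects. Scoring defaults are the community-standard +1/−2
with gap open −5 / extend −2 (nucleotide) and BLOSUM62 with −11/−1
(protein); the first gap position pays the open penalty.

Percent identity is gap-inclusive — 100 × matches / alignment columns,
counting gap columns — the convention of the BLAST-family tools emulated
here, stated once and applied everywhere. A consequence worth knowing: local
alignment trims mismatch-dense ends, so measured identity sits slightly
*above* the true site identity of the full homologous span (≈ +0.1 at 5%
divergence, ≈ +0.9 at 20%). This is a property of the convention, not of the
implementation; alignment-based ANI in the wild shares it.

`best_hits` keeps the single highest-scoring subject per query passing the
filters, with deterministic tie-breaks (score, then identity, then alignment
length, then lexicographic subject id). Two pruning layers keep all-pairs
searches fast without affecting results: an ungapped best-diagonal-segment
screen (a candidate whose seed diagonals cannot approach the minimum useful
score is skipped), and — when an e-value bound is among the filters — an
exact score cutoff derived by inverting the e-value formula, since E is
monotone in score for fixed query and database size.

E-values use the Karlin–Altschul form E = K·m·n·exp(−λ·score) with published
*ungapped* constants applied to gapped scores (nucleotide +1/−2: λ = 1.33,
K = 0.621; BLOSUM62: λ = 0.3176, K = 0.134; other match/mismatch schemes
solve λ numerically with K ≈ 0.35). This is a coarse approximation — E is
used only as a 10⁻⁵-scale filter, where monotonicity in score is what
matters, not absolute accuracy.

## Pair statistics

* **ANI**: reciprocal best-hit gene pairs at ≥70% identity with ≥70%
  coverage of the shorter gene; per-direction ANI is the unweighted mean of
  pair identities (length-weighting is not applied; the per-gene convention
  of the emulated tools), and the A→B direction is the headline value. No
  qualifying pairs yields an explicit undefined (NaN) result, never 0.
* **AAI**: proteins ≥100 aa; reciprocal best-hit pairs filtered at e-value
  ≤10⁻⁵ and identity ≥30%; two-way AAI is the mean of the two directional
  means, and the pair count n feeds the shared-genes formula.
* **Percent shared genes** (two-way): 100 × 2n / (nA + nB) with nA, nB the
  counts of proteins ≥100 aa.
* **Homolog inventories** are directional and one-sided: a gene is shared if
  it has *any* qualifying hit (e-value ≤10⁻⁵, identity ≥30%) in the other
  genome — deliberately looser than the reciprocal pairing, which is why the
  directional shared fraction (~85% under default study conditions) exceeds
  the two-way percentage.
* **COG summaries** consume an external gene→category table and report
  per-category relative abundance among annotated genes per inventory set,
  with unannotated genes counted separately.
* **Metagenome profiles** report the fraction of genome genes with a
  qualifying hit (identity ≥70%, e-value ≤10⁻⁵) in a metagenome gene set;
  normalization per metagenome gene is available behind a flag since the
  emulated "relative frequency" is ambiguous. Per-genome-gene is the default.

## Fragment recruitment and threshold calibration

Genomes are cut into non-overlapping 150 bp fragments (trailing remainders
discarded). For the sweep, each genome's fragments are mapped against the
*other genome alone* — with a joint reference every fragment would take its
exact self-hit and spurious mapping would be identically zero, which cannot
reproduce a ~1% operating point — and the cross-mapping frequency is the
fraction of fragments with a hit at identity ≥ T, for T = 70..100 in 1%
steps. A hit requires ≥80% of the fragment aligned (the coverage floor
prevents short high-identity slivers from counting as mapped). The selected
threshold is the smallest T holding cross-mapping at or below the spurious
bound (default 1%) in both directions. Under default study conditions
(d = 0.231) the curve passes ~1% near 96% and selection lands at 97–98,
driven by the conserved rate class.

Read recruitment (the discrimination step) maps each read against the joint
two-genome reference — single best hit across both strands, deterministic
tie-breaks — at the selected threshold, and reports per-genome counts and
the A:B ratio (an infinite sentinel when B recruits nothing; an explicit
empty result when nothing maps). Mapping uses the same seeded engine plus an
ungapped diagonal screen tied to the identity/coverage floor, so random
reads cost almost nothing to reject.

## Problem sizes and numerical choices

Default study conditions: 100 kb genomes (~90 genes), d = 0.231 (the ANI
scale of the motivating genome pair), 15% per-lineage gene loss, 10,000-read
mixtures. Tests use 15–50 kb genomes for unit-scale checks and 100 kb for
acceptance-scale recovery; the divergence calibration uses 10 replicates at
50 kb. These sizes are the package's chosen desk scale: large enough that
binomial noise on ANI (< 0.2 points) and on mixture fractions is well inside
the asserted tolerances.

Degenerate inputs are defined, not silent: zero qualifying ANI/AAI pairs →
NaN with n = 0; empty read set → empty result; identical genomes in the
sweep → threshold-selection error carrying the curve; zero denominator in
the shared-genes formula → error.

## Known limitations

* The generator has no rearrangements, horizontal transfer, paralog
  families, or coding indels; ortholog truth is therefore exact but easier
  than real data.
* The ungapped Karlin–Altschul constants overstate gapped-alignment
  significance somewhat; e-value filters here are coarse by design.
* Identity conventions differ subtly across real tools (gap-inclusive or
  not, global-over-read or local); results at the 1-point scale depend on
  the convention, which is fixed and documented here.
* The seeded aligner's optimality guarantee holds when a seed k-mer exists;
  homologous pairs much shorter than ~100 nt at >10% divergence can fall
  outside it (they are also below any of the statistics' filters).
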