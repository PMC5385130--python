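"""Synthetic prokaryote genome pairs with known divergence, gene loss and reads.

The generator emulates a pair of gene-dense microbial genomes descended from a
common ancestor: an ancestor genome is built with non-overlapping, stop-free
protein-coding genes covering a programmable fraction of the sequence, and two
descendant lineages are derived by placing independent substitutions (with a
transition/transversion bias and an optional forced-nonsynonymous fraction),
small intergenic indels, and per-lineage gene deletions.  Every emitted pair
carries a :class:`TruthRecord` — the ortholog pairing and per-gene realized
identities — so downstream homology, ANI/AAI and fragment-recruitment code can
be tested against known ground truth without downloading anything.

Read simulation draws fixed-length fragments from a weighted mixture of
genomes (plus an optional random-sequence "background" component) with a
uniform per-base substitution error, retaining per-read provenance labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

__all__ = [
    "AncestorSpec",
    "DivergenceSpec",
    "ReadMixSpec",
    "Gene",
    "Genome",
    "TruthRecord",
    "Read",
    "ReadSet",
    "generate_ancestor",
    "diverge_pair",
    "simulate_reads",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# transition partner per base index (A<->G, C<->T)
_TRANSITION = np.array([2, 3, 0, 1], dtype=np.int8)
# the two transversion partners per base index
_TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]], dtype=np.int8)

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Standard-code translation of an in-frame coding sequence."""
    return str(Seq(seq).translate())


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Gene:
    """A CDS gene model on a contig; 0-based half-open coordinates."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str  # '+' or '-'

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Genome:
    """A genome: named contigs plus CDS gene models."""

    genome_id: str
    contigs: dict[str, str]
    genes: list[Gene] = field(default_factory=list)

    @property
    def length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def gene_seq(self, gene: Gene) -> str:
        """Coding-orientation nucleotide sequence of a gene."""
        s = self.contigs[gene.contig][gene.start : gene.end]
        return reverse_complement(s) if gene.strand == "-" else s

    def gene_protein(self, gene: Gene) -> str:
        return translate(self.gene_seq(gene))

    def gene_seqs(self) -> dict[str, str]:
        return {g.gene_id: self.gene_seq(g) for g in self.genes}

    def proteins(self) -> dict[str, str]:
        return {g.gene_id: self.gene_protein(g) for g in self.genes}

    def gc_content(self) -> float:
        gc = tot = 0
        for s in self.contigs.values():
            gc += s.count("G") + s.count("C")
            tot += len(s)
        return gc / tot if tot else math.nan


def _require(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"{fieldname}: {msg}")


@dataclass(frozen=True)
class AncestorSpec:
    """Parameters of the ancestral genome.

    Defaults mirror a gene-dense thermophile genome: ~90% coding, GC ~0.60.
    """

    genome_length: int = 100_000
    gene_length_mean: int = 900
    gene_density: float = 0.90
    gc_content: float = 0.60
    seed: int = 0

    def validate(self) -> None:
        _require(self.genome_length >= 10_000, "genome_length", "must be >= 10000 bp")
        _require(
            self.gene_length_mean >= 300 and self.gene_length_mean % 3 == 0,
            "gene_length_mean",
            "must be a multiple of 3, >= 300",
        )
        _require(0 < self.gene_density <= 0.95, "gene_density", "must be in (0, 0.95]")
        _require(0 <= self.gc_content <= 1, "gc_content", "must be in [0, 1]")


# Site-scale rate heterogeneity: (multiplier, weight) classes assigned to
# 150 bp windows of the ancestor, shared by both lineages.  Emulates
# within-genome conservation structure (domains, motifs, fast/slow genes):
# a strongly conserved minority fraction plus a faster tail, producing the
# broad homolog-identity spread real genome pairs show.  Weighted mean
# multiplier is normalized to exactly 1, so the genome-wide expected
# divergence stays at site_divergence.
DEFAULT_RATE_CLASSES: tuple[tuple[float, float], ...] = (
    (0.15, 0.04),
    (0.70, 0.26),
    (1.00, 0.44),
    (1.30, 0.20),
    (1.90, 0.06),
)


@dataclass(frozen=True)
class DivergenceSpec:
    """Parameters of the two-lineage divergence process.

    ``site_divergence`` is the expected pairwise substitution fraction per
    aligned site between the two descendants; within each rate class the
    per-lineage rate is solved so the pairwise expectation is exact
    (both-lineages-hit-same-site coincidences are accounted for, see
    :func:`lineage_substitution_prob`), and the class multipliers average to
    one, so the genome-wide expectation is exact too.  Set ``rate_classes``
    to None for a homogeneous clock.
    """

    site_divergence: float = 0.10
    ts_tv_ratio: float = 2.0
    indel_rate: float = 1e-4
    indel_max_len: int = 10
    gene_loss_fraction: float = 0.0
    nonsyn_fraction: float = 0.0
    rate_classes: tuple[tuple[float, float], ...] | None = DEFAULT_RATE_CLASSES
    rate_window_bp: int = 150
    seed: int = 0

    def validate(self) -> None:
        _require(0 <= self.site_divergence <= 0.5, "site_divergence", "must be in [0, 0.5]")
        _require(self.ts_tv_ratio > 0, "ts_tv_ratio", "must be > 0")
        _require(self.indel_rate >= 0, "indel_rate", "must be >= 0")
        _require(self.indel_max_len >= 1, "indel_max_len", "must be >= 1")
        _require(0 <= self.gene_loss_fraction <= 1, "gene_loss_fraction", "must be in [0, 1]")
        _require(0 <= self.nonsyn_fraction <= 1, "nonsyn_fraction", "must be in [0, 1]")
        _require(self.rate_window_bp >= 1, "rate_window_bp", "must be >= 1")
        if self.rate_classes is not None:
            _require(
                all(m > 0 and w >= 0 for m, w in self.rate_classes)
                and sum(w for _, w in self.rate_classes) > 0,
                "rate_classes",
                "multipliers must be > 0 and weights >= 0 with positive sum",
            )

    def normalized_rate_classes(self) -> tuple[tuple[float, float], ...]:
        """Rate classes rescaled to weight sum 1 and mean multiplier exactly 1."""
        classes = self.rate_classes or ((1.0, 1.0),)
        wsum = sum(w for _, w in classes)
        classes = tuple((m, w / wsum) for m, w in classes)
        mean = sum(m * w for m, w in classes)
        return tuple((m / mean, w) for m, w in classes)


@dataclass(frozen=True)
class ReadMixSpec:
    """A metagenome-like read mixture drawn from several genomes.

    ``weights`` maps genome ids to sampling weights; the reserved key
    ``"background"`` adds i.i.d. random-sequence reads at ``background_gc``.
    The default error rate (0.5% substitutions per base) is a free choice in
    the absence of a stated error model for real reads.
    """

    n_reads: int = 10_000
    read_length: int = 150
    weights: dict[str, float] = field(default_factory=dict)
    read_error_rate: float = 0.005
    background_gc: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        _require(self.n_reads >= 0, "n_reads", "must be >= 0")
        _require(self.read_length >= 1, "read_length", "must be >= 1")
        _require(bool(self.weights), "weights", "must be non-empty")
        _require(all(w >= 0 for w in self.weights.values()), "weights", "must be >= 0")
        _require(sum(self.weights.values()) > 0, "weights", "must sum to > 0")
        _require(0 <= self.read_error_rate < 1, "read_error_rate", "must be in [0, 1)")


@dataclass
class TruthRecord:
    """Ground truth for an emitted genome pair."""

    programmed_ani: float
    programmed_shared_fraction_a: float
    programmed_shared_fraction_b: float
    ortholog_pairs: list[tuple[str, str]]
    per_gene_identity: dict[tuple[str, str], float]
    per_gene_protein_identity: dict[tuple[str, str], float]
    realized_site_divergence: float

    def mean_gene_identity(self) -> float:
        return float(np.mean(list(self.per_gene_identity.values())))

    def mean_protein_identity(self) -> float:
        return float(np.mean(list(self.per_gene_protein_identity.values())))


@dataclass
class Read:
    read_id: str
    seq: str
    source: str  # genome id or "background"


@dataclass
class ReadSet:
    reads: list[Read]

    def __len__(self) -> int:
        return len(self.reads)

    def sequences(self) -> dict[str, str]:
        return {r.read_id: r.seq for r in self.reads}

    def labels(self) -> dict[str, str]:
        return {r.read_id: r.source for r in self.reads}


# ---------------------------------------------------------------------------
# ancestor generation
# ---------------------------------------------------------------------------


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.int8)


def _indices_to_str(idx: np.ndarray) -> str:
    return _BASES[idx].tobytes().decode("ascii")


def _str_to_indices(seq: str) -> np.ndarray:
    arr = _BASE_INDEX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        raise ValueError("sequence contains non-ACGT characters")
    return arr.astype(np.int8)


def _random_orf(rng: np.random.Generator, length: int, gc: float) -> str:
    """A stop-free reading frame: ATG followed by random non-stop codons."""
    n_codons = length // 3
    out = ["ATG"]
    # draw in bulk, reject stops, redraw the few rejected codons
    need = n_codons - 1
    codons: list[str] = []
    while len(codons) < need:
        block = _indices_to_str(_random_bases(rng, 3 * (need - len(codons)), gc))
        for i in range(0, len(block), 3):
            c = block[i : i + 3]
            if c not in STOP_CODONS:
                codons.append(c)
    out.extend(codons[:need])
    return "".join(out)


def generate_ancestor(spec: AncestorSpec, genome_id: str = "ancestor") -> Genome:
    """Generate a single-contig ancestor genome with dense, stop-free CDS genes.

    Gene lengths are gamma-distributed around ``gene_length_mean`` (rounded to
    codons, floor 300 bp so every protein is >= 100 aa), strands are drawn
    ~50/50, and the intergenic remainder is split uniformly between genes.
    Deterministic for a fixed seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    L = spec.genome_length
    coding_target = int(spec.gene_density * L)

    lengths: list[int] = []
    total = 0
    shape = 4.0
    while total < coding_target:
        raw = rng.gamma(shape, spec.gene_length_mean / shape)
        gl = max(300, 3 * int(round(raw / 3)))
        if total + gl > coding_target:
            gl = max(300, 3 * ((coding_target - total) // 3))
            if total + gl > coding_target:
                break
        lengths.append(gl)
        total += gl
    n_genes = len(lengths)
    if n_genes == 0:
        raise ValueError("gene_density: too low to place a single gene")

    intergenic_total = L - total
    gaps = rng.multinomial(intergenic_total, np.full(n_genes + 1, 1.0 / (n_genes + 1)))

    contig_name = f"{genome_id}_c1"
    parts: list[str] = []
    genes: list[Gene] = []
    pos = 0
    for i, gl in enumerate(lengths):
        gap = int(gaps[i])
        if gap:
            parts.append(_indices_to_str(_random_bases(rng, gap, spec.gc_content)))
            pos += gap
        orf = _random_orf(rng, gl, spec.gc_content)
        strand = "+" if rng.random() < 0.5 else "-"
        parts.append(reverse_complement(orf) if strand == "-" else orf)
        genes.append(Gene(f"g{i + 1:05d}", contig_name, pos, pos + gl, strand))
        pos += gl
    tail = int(gaps[n_genes])
    if tail:
        parts.append(_indices_to_str(_random_bases(rng, tail, spec.gc_content)))
        pos += tail

    return Genome(genome_id, {contig_name: "".join(parts)}, genes)


# ---------------------------------------------------------------------------
# divergence
# ---------------------------------------------------------------------------


def lineage_substitution_prob(site_divergence: float, ts_tv_ratio: float) -> float:
    """Per-lineage substitution probability giving exact pairwise divergence.

    With each lineage substituting a site independently with probability p, the
    site differs between lineages with probability 2p(1-p) + p^2(1-c), where c
    is the probability two independent substitutions pick the same target base
    under the ts/tv bias: c = (R^2 + 1/2) / (R+1)^2 for ratio R.  Solving
    2p - (1+c)p^2 = d gives p.
    """
    d = site_divergence
    if d == 0:
        return 0.0
    R = ts_tv_ratio
    c = (R * R + 0.5) / (R + 1) ** 2
    disc = 1 - (1 + c) * d
    if disc < 0:
        raise ValueError(f"site_divergence: {d} not reachable with ts_tv_ratio {R}")
    return (1 - math.sqrt(disc)) / (1 + c)


def _draw_targets(rng: np.random.Generator, orig: np.ndarray, kappa: float) -> np.ndarray:
    """Substituted base per site under the ts/tv bias (vectorized)."""
    n = orig.size
    is_ts = rng.random(n) < kappa / (kappa + 1)
    tv_pick = rng.integers(0, 2, size=n)
    targets = np.where(
        is_ts, _TRANSITION[orig], _TRANSVERSIONS[orig, tv_pick]
    ).astype(np.int8)
    return targets


def _mutate_intergenic(
    rng: np.random.Generator, seq: str, p_site: np.ndarray, spec: DivergenceSpec
) -> str:
    if not seq:
        return seq
    arr = _str_to_indices(seq)
    mask = rng.random(arr.size) < p_site
    if mask.any():
        arr = arr.copy()
        arr[mask] = _draw_targets(rng, arr[mask], spec.ts_tv_ratio)
    out = _indices_to_str(arr)
    n_indels = rng.binomial(arr.size, spec.indel_rate)
    if n_indels:
        positions = np.sort(rng.integers(0, len(out) + 1, size=n_indels))[::-1]
        for pos in positions:
            length = int(rng.integers(1, spec.indel_max_len + 1))
            if rng.random() < 0.5:  # deletion
                out = out[: int(pos)] + out[int(pos) + length :]
            else:  # insertion of random sequence at background GC 0.5
                ins = _indices_to_str(rng.integers(0, 4, size=length).astype(np.int8))
                out = out[: int(pos)] + ins + out[int(pos) :]
    return out


_AA_CACHE: dict[str, str] = {}


def _aa(codon: str) -> str:
    aa = _AA_CACHE.get(codon)
    if aa is None:
        aa = str(Seq(codon).translate())
        _AA_CACHE[codon] = aa
    return aa


def _mutate_coding(
    rng: np.random.Generator, seq: str, p_site: np.ndarray, spec: DivergenceSpec
) -> str:
    """Substitute within a coding sequence, never creating a stop codon.

    Each substituted site keeps its substituted status: if the drawn target
    makes a stop (or a synonymous change where a nonsynonymous one was forced),
    the target base is redrawn among the remaining alternatives.  A forced
    nonsynonymous change falls back to any non-stop change when the site admits
    no amino-acid-changing alternative (e.g. fourfold-degenerate third
    positions).
    """
    arr = _str_to_indices(seq)
    n = arr.size
    mask = rng.random(n) < p_site
    if not mask.any():
        return seq
    arr = arr.copy()
    sites = np.flatnonzero(mask)
    targets = _draw_targets(rng, arr[sites], spec.ts_tv_ratio)
    force_nonsyn = rng.random(sites.size) < spec.nonsyn_fraction

    chars = list(seq)
    for site, target, force in zip(sites, targets, force_nonsyn):
        site = int(site)
        c0 = 3 * (site // 3)
        old_codon = "".join(chars[c0 : c0 + 3])
        pos_in_codon = site - c0
        old_aa = _aa(old_codon)

        def codon_with(base_idx: int) -> str:
            return (
                old_codon[:pos_in_codon]
                + chr(_BASES[base_idx])
                + old_codon[pos_in_codon + 1 :]
            )

        orig_base = _BASE_INDEX[ord(seq[site])]
        alternatives = [int(target)] + [
            b for b in range(4) if b != int(target) and b != int(orig_base)
        ]
        chosen = None
        if force:
            for b in alternatives:
                cdn = codon_with(b)
                if cdn not in STOP_CODONS and _aa(cdn) != old_aa:
                    chosen = b
                    break
        if chosen is None:
            for b in alternatives:
                if codon_with(b) not in STOP_CODONS:
                    chosen = b
                    break
        if chosen is None:  # cannot happen: every codon has a non-stop neighbour
            continue
        new_codon = codon_with(chosen)
        chars[c0] = new_codon[0]
        chars[c0 + 1] = new_codon[1]
        chars[c0 + 2] = new_codon[2]
    return "".join(chars)


def _column_identity(a: str, b: str) -> float:
    """Percent identity of two equal-length aligned strings."""
    xa = np.frombuffer(a.encode(), dtype=np.uint8)
    xb = np.frombuffer(b.encode(), dtype=np.uint8)
    return 100.0 * float((xa == xb).mean())


def _site_rate_array(
    spec: DivergenceSpec, genome_length: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-site per-lineage substitution probability, shared by both lineages.

    Rate-class multipliers are assigned to fixed windows by stratified
    allocation (class counts proportional to weights, placement shuffled), and
    each class rate is solved exactly for its pairwise divergence m*d.
    """
    classes = spec.normalized_rate_classes()
    d = spec.site_divergence
    p_class = np.array(
        [lineage_substitution_prob(m * d, spec.ts_tv_ratio) for m, _ in classes]
    )
    n_windows = (genome_length + spec.rate_window_bp - 1) // spec.rate_window_bp
    weights = np.array([w for _, w in classes])
    counts = np.floor(weights * n_windows).astype(int)
    remainder = n_windows - counts.sum()
    if remainder > 0:  # largest-remainder allocation
        frac = weights * n_windows - np.floor(weights * n_windows)
        for i in np.argsort(-frac)[:remainder]:
            counts[i] += 1
    assignment = np.repeat(np.arange(len(classes)), counts)
    rng.shuffle(assignment)
    per_window = p_class[assignment]
    return np.repeat(per_window, spec.rate_window_bp)[:genome_length]


def _derive_lineage(
    ancestor: Genome,
    spec: DivergenceSpec,
    p_site: np.ndarray,
    rng: np.random.Generator,
    genome_id: str,
) -> tuple[Genome, dict[str, str], set[str]]:
    """One descendant: returns (genome, coding seqs by gene id, lost gene ids)."""
    (contig_name, anc_seq), = ancestor.contigs.items()
    lost = {
        g.gene_id for g in ancestor.genes if rng.random() < spec.gene_loss_fraction
    }

    parts: list[str] = []
    genes: list[Gene] = []
    coding: dict[str, str] = {}
    new_contig = f"{genome_id}_c1"
    pos = 0
    prev_end = 0
    for g in ancestor.genes:
        inter = _mutate_intergenic(
            rng, anc_seq[prev_end : g.start], p_site[prev_end : g.start], spec
        )
        parts.append(inter)
        pos += len(inter)
        prev_end = g.end
        if g.gene_id in lost:
            continue
        rates = p_site[g.start : g.end]
        if g.strand == "-":  # rates follow genome sites into coding orientation
            rates = rates[::-1]
        cds = _mutate_coding(rng, ancestor.gene_seq(g), rates, spec)
        coding[g.gene_id] = cds
        parts.append(reverse_complement(cds) if g.strand == "-" else cds)
        genes.append(Gene(g.gene_id, new_contig, pos, pos + len(cds), g.strand))
        pos += len(cds)
    tail = _mutate_intergenic(rng, anc_seq[prev_end:], p_site[prev_end:], spec)
    parts.append(tail)
    return Genome(genome_id, {new_contig: "".join(parts)}, genes), coding, lost


def diverge_pair(
    ancestor: Genome,
    spec: DivergenceSpec,
    ids: tuple[str, str] = ("A", "B"),
) -> tuple[Genome, Genome, TruthRecord]:
    """Derive two descendant genomes plus ground truth from an ancestor.

    Substitutions are placed i.i.d. per site independently on each lineage at
    the rate that makes the expected pairwise aligned-site divergence equal
    ``spec.site_divergence``; genes are deleted per lineage with probability
    ``gene_loss_fraction``; indels fall in intergenic regions so gene models
    stay frame-intact.
    """
    spec.validate()
    if not ancestor.genes:
        raise ValueError("ancestor must have at least one gene")
    ss = np.random.SeedSequence(spec.seed)
    rng_a, rng_b, rng_rates = (np.random.default_rng(s) for s in ss.spawn(3))
    p_site = _site_rate_array(spec, ancestor.length, rng_rates)

    genome_a, coding_a, _ = _derive_lineage(ancestor, spec, p_site, rng_a, ids[0])
    genome_b, coding_b, _ = _derive_lineage(ancestor, spec, p_site, rng_b, ids[1])

    ortholog_pairs: list[tuple[str, str]] = []
    per_gene_identity: dict[tuple[str, str], float] = {}
    per_gene_protein_identity: dict[tuple[str, str], float] = {}
    mismatch = 0
    columns = 0
    for g in ancestor.genes:
        gid = g.gene_id
        if gid in coding_a and gid in coding_b:
            pair = (gid, gid)
            ortholog_pairs.append(pair)
            ca, cb = coding_a[gid], coding_b[gid]
            per_gene_identity[pair] = _column_identity(ca, cb)
            per_gene_protein_identity[pair] = _column_identity(
                translate(ca), translate(cb)
            )
            xa = np.frombuffer(ca.encode(), dtype=np.uint8)
            xb = np.frombuffer(cb.encode(), dtype=np.uint8)
            mismatch += int((xa != xb).sum())
            columns += xa.size

    truth = TruthRecord(
        programmed_ani=100.0 * (1 - spec.site_divergence),
        programmed_shared_fraction_a=1 - spec.gene_loss_fraction,
        programmed_shared_fraction_b=1 - spec.gene_loss_fraction,
        ortholog_pairs=ortholog_pairs,
        per_gene_identity=per_gene_identity,
        per_gene_protein_identity=per_gene_protein_identity,
        realized_site_divergence=(mismatch / columns) if columns else math.nan,
    )
    return genome_a, genome_b, truth


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def simulate_reads(genomes: list[Genome], spec: ReadMixSpec) -> ReadSet:
    """Draw a read mixture from genomes (plus optional background) with errors.

    Reads start at uniformly random positions on a contig chosen with
    probability proportional to contig length within the chosen genome; strand
    is random; substitution errors are uniform at ``read_error_rate``.
    """
    spec.validate()
    by_id = {g.genome_id: g for g in genomes}
    for key in spec.weights:
        if key != "background" and key not in by_id:
            raise ValueError(f"weights: unknown genome id {key!r}")
    rng = np.random.default_rng(spec.seed)

    names = sorted(spec.weights)
    w = np.array([spec.weights[k] for k in names], dtype=float)
    w = w / w.sum()
    for name in names:
        if name == "background" or spec.weights[name] == 0:
            continue
        shortest = min(len(s) for s in by_id[name].contigs.values())
        if spec.read_length > shortest:
            raise ValueError(
                f"read_length {spec.read_length} exceeds shortest contig "
                f"({shortest} bp) of genome {name!r}"
            )

    choices = rng.choice(len(names), size=spec.n_reads, p=w)
    reads: list[Read] = []
    for i, ci in enumerate(choices):
        src = names[int(ci)]
        if src == "background":
            idx = _random_bases(rng, spec.read_length, spec.background_gc)
            seq = _indices_to_str(idx)
        else:
            genome = by_id[src]
            contigs = list(genome.contigs.items())
            lens = np.array([len(s) for _, s in contigs], dtype=float)
            cname, cseq = contigs[int(rng.choice(len(contigs), p=lens / lens.sum()))]
            start = int(rng.integers(0, len(cseq) - spec.read_length + 1))
            seq = cseq[start : start + spec.read_length]
            if rng.random() < 0.5:
                seq = reverse_complement(seq)
            if spec.read_error_rate > 0:
                arr = _str_to_indices(seq)
                mask = rng.random(arr.size) < spec.read_error_rate
                if mask.any():
                    shift = rng.integers(1, 4, size=int(mask.sum()))
                    arr[mask] = (arr[mask] + shift) % 4
                    seq = _indices_to_str(arr)
        reads.append(Read(f"r{i + 1:06d}", seq, src))
    return ReadSet(reads)
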