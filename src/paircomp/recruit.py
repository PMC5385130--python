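"""Fragment recruitment: tiling, threshold sweep, cutoff selection, ratios.

The lineage-discrimination procedure: each genome is cut into non-overlapping
fixed-length fragments; fragments of one genome are mapped against the other
genome alone over an identity-threshold sweep (70..100%) to find the smallest
threshold holding spurious cross-mapping at or below a target frequency; reads
are then recruited against the joint reference at that threshold (single best
hit per read) and the per-genome mapped-read counts and their ratio reported.

Mapping is seed-and-extend against both strands of every reference contig: a
k-mer index proposes diagonal clusters, a cheap ungapped diagonal screen
discards clusters that cannot reach the identity/coverage floor, and the
survivors are scored with windowed affine-gap Smith-Waterman.  A hit qualifies
when its gap-inclusive identity meets the threshold and at least 80% of the
read is aligned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .align import (
    AlignmentHit,
    ScoringScheme,
    _kmers,
    _make_aligner,
    _hit_from_alignment,
)
from .simulate import Genome, ReadSet, reverse_complement

__all__ = [
    "FragmentSet",
    "SweepCurve",
    "RecruitmentResult",
    "ReadAssignment",
    "GenomeIndex",
    "ThresholdNotFoundError",
    "fragment_genome",
    "recruit",
    "threshold_sweep",
    "select_threshold",
    "discrimination_ratio",
    "DEFAULT_MIN_READ_COVERAGE",
]

DEFAULT_MIN_READ_COVERAGE = 0.8


@dataclass
class FragmentSet:
    """Non-overlapping tiling of a genome into L-bp fragments."""

    source_genome_id: str
    length: int
    fragments: list[tuple[str, int, str]]  # (contig, offset, sequence)

    def __len__(self) -> int:
        return len(self.fragments)

    def as_reads(self) -> dict[str, str]:
        return {
            f"{self.source_genome_id}:{contig}:{off}": seq
            for contig, off, seq in self.fragments
        }


def fragment_genome(genome: Genome, length: int = 150) -> FragmentSet:
    """Tile each contig from position 0; trailing remainder < L is discarded."""
    if length < 50:
        raise ValueError("fragment length must be >= 50 bp")
    frags = []
    for contig, seq in genome.contigs.items():
        for off in range(0, len(seq) - length + 1, length):
            frags.append((contig, off, seq[off : off + length]))
    return FragmentSet(genome.genome_id, length, frags)


# ---------------------------------------------------------------------------
# reference index / read mapping
# ---------------------------------------------------------------------------


def _max_diagonal_score(
    q: np.ndarray, window: np.ndarray, match: int, mismatch: int
) -> float:
    """Best contiguous ungapped segment score of q on one diagonal of window."""
    n = min(q.size, window.size)
    s = np.where(q[:n] == window[:n], float(match), float(mismatch))
    c = np.cumsum(s)
    running_min = np.minimum.accumulate(np.concatenate(([0.0], c[:-1])))
    return float((c - running_min).max())


class GenomeIndex:
    """Both-strand k-mer index over one or more reference genomes."""

    def __init__(self, references: list[Genome], k: int = 11):
        self.k = k
        self.entries: list[tuple[str, str, str, str, dict[str, list[int]]]] = []
        # (ref_id, contig, strand, strand_seq, kmer_index)
        for genome in references:
            for contig, seq in genome.contigs.items():
                rc = reverse_complement(seq)
                self.entries.append(
                    (genome.genome_id, contig, "+", seq, _kmers(seq, k))
                )
                self.entries.append(
                    (genome.genome_id, contig, "-", rc, _kmers(rc, k))
                )

    def map_query(
        self,
        seq: str,
        scheme: ScoringScheme,
        min_identity: float,
        min_coverage: float = DEFAULT_MIN_READ_COVERAGE,
        read_id: str = "read",
    ) -> tuple[str, AlignmentHit] | None:
        """Best qualifying hit of one read across all references, or None.

        The ungapped diagonal screen skips the DP extension for seed clusters
        whose best on-diagonal segment score falls short of the lowest score a
        qualifying hit could have (minus a gap allowance).
        """
        k = self.k
        qlen = len(seq)
        if qlen < k:
            return None
        aligner = _make_aligner(scheme)
        qarr = np.frombuffer(seq.encode(), dtype=np.uint8)
        # lowest possible score of a hit at the identity/coverage floor
        min_cols = min_coverage * qlen
        frac = min_identity / 100.0
        needed = min_cols * (frac * scheme.match + (1 - frac) * scheme.mismatch)
        screen = needed - 12.0  # gap allowance
        slack = 20 + qlen // 8
        band = max(16, qlen // 8)

        best: tuple[tuple, str, AlignmentHit] | None = None
        qkmers = [
            (i, seq[i : i + k])
            for i in range(qlen - k + 1)
        ]
        for ref_id, contig, strand, sseq, skmers in self.entries:
            diags: dict[int, int] = {}
            for i, kmer in qkmers:
                positions = skmers.get(kmer)
                if not positions:
                    continue
                for j in positions:
                    diags[j - i] = max(diags.get(j - i, -1), j)
            if not diags:
                continue
            # cluster nearby diagonals
            sorted_diags = sorted(diags)
            clusters: list[list[int]] = [[sorted_diags[0]]]
            for d in sorted_diags[1:]:
                if d - clusters[-1][-1] <= band:
                    clusters[-1].append(d)
                else:
                    clusters.append([d])
            sarr = np.frombuffer(sseq.encode(), dtype=np.uint8)
            for cluster in clusters:
                passed = False
                for d in cluster:
                    lo = max(0, d)
                    w = sarr[lo : lo + qlen]
                    qoff = lo - d
                    if qoff >= qlen:
                        continue
                    score = _max_diagonal_score(
                        qarr[qoff:], w, scheme.match, scheme.mismatch
                    )
                    if score >= screen:
                        passed = True
                        break
                if not passed:
                    continue
                lo = max(0, min(cluster) - slack)
                hi = min(len(sseq), max(cluster) + qlen + slack)
                window = sseq[lo:hi]
                alignments = aligner.align(window, seq)
                if alignments.score <= 0:
                    continue
                hit = _hit_from_alignment(
                    alignments[0], seq, window, read_id, contig, lo, len(sseq)
                )
                hit.subject_strand = strand
                if strand == "-":
                    n = len(sseq)
                    hit.subject_start, hit.subject_end = (
                        n - hit.subject_end,
                        n - hit.subject_start,
                    )
                if (
                    hit.percent_identity < min_identity
                    or hit.query_coverage < min_coverage
                ):
                    continue
                key = (
                    -hit.score,
                    -hit.percent_identity,
                    -hit.alignment_length,
                    ref_id,
                    contig,
                    strand,
                    hit.subject_start,
                )
                if best is None or key < best[0]:
                    best = (key, ref_id, hit)
        if best is None:
            return None
        return best[1], best[2]


# ---------------------------------------------------------------------------
# recruitment
# ---------------------------------------------------------------------------


@dataclass
class ReadAssignment:
    read_id: str
    reference: str | None
    hit: AlignmentHit | None


def recruit(
    reads: dict[str, str],
    references: list[Genome],
    min_similarity: float = 75.0,
    scheme: ScoringScheme | None = None,
    min_read_coverage: float = DEFAULT_MIN_READ_COVERAGE,
    index: GenomeIndex | None = None,
) -> list[ReadAssignment]:
    """Single best hit per read across all references (both strands).

    A read maps when its best local alignment reaches ``min_similarity``
    percent identity with at least ``min_read_coverage`` of the read aligned;
    otherwise it is unmapped.  Ties break deterministically (score, identity,
    length, then reference/contig/strand/position order).
    """
    if not references:
        raise ValueError("at least one reference genome is required")
    scheme = scheme or ScoringScheme.nucleotide()
    index = index or GenomeIndex(references, scheme.seed_k)
    out: list[ReadAssignment] = []
    for rid, seq in reads.items():
        found = index.map_query(
            seq, scheme, min_similarity, min_read_coverage, read_id=rid
        )
        if found is None:
            out.append(ReadAssignment(rid, None, None))
        else:
            out.append(ReadAssignment(rid, found[0], found[1]))
    return out


# ---------------------------------------------------------------------------
# threshold sweep and selection
# ---------------------------------------------------------------------------


@dataclass
class SweepCurve:
    """Cross- and self-mapping frequency as a function of identity threshold."""

    thresholds: list[int]
    cross_map_freq: dict[tuple[str, str], dict[int, float]]
    self_map_freq: dict[str, dict[int, float]]
    n_fragments: dict[str, int] = field(default_factory=dict)

    def directions(self) -> list[tuple[str, str]]:
        return list(self.cross_map_freq)


def _freq_curve(
    identities: list[float | None], thresholds: list[int]
) -> dict[int, float]:
    vals = np.array([i for i in identities if i is not None], dtype=float)
    n = len(identities)
    if n == 0:
        return {t: 0.0 for t in thresholds}
    return {t: float((vals >= t).sum()) / n for t in thresholds}


def threshold_sweep(
    genome_a: Genome,
    genome_b: Genome,
    length: int = 150,
    thresholds: range | list[int] = range(70, 101),
    scheme: ScoringScheme | None = None,
    min_read_coverage: float = DEFAULT_MIN_READ_COVERAGE,
) -> SweepCurve:
    """Map each genome's fragments against the other genome alone.

    cross_map_freq[(src, tgt)][T] is the fraction of src fragments with a
    qualifying hit in tgt at identity >= T; self_map_freq maps fragments back
    to their source genome.  Cross-mapping against the other genome alone (not
    a joint reference) is what makes "spurious" non-degenerate: with a joint
    reference every fragment would take its exact self-hit.
    """
    scheme = scheme or ScoringScheme.nucleotide()
    thresholds = list(thresholds)
    floor = float(min(thresholds))
    curve = SweepCurve(thresholds, {}, {}, {})
    for src, tgt in ((genome_a, genome_b), (genome_b, genome_a)):
        frags = fragment_genome(src, length)
        curve.n_fragments[src.genome_id] = len(frags)
        idx_tgt = GenomeIndex([tgt], scheme.seed_k)
        idx_self = GenomeIndex([src], scheme.seed_k)
        cross_ids: list[float | None] = []
        self_ids: list[float | None] = []
        for contig, off, seq in frags.fragments:
            m = idx_tgt.map_query(seq, scheme, floor, min_read_coverage)
            cross_ids.append(m[1].percent_identity if m else None)
            s = idx_self.map_query(seq, scheme, floor, min_read_coverage)
            self_ids.append(s[1].percent_identity if s else None)
        curve.cross_map_freq[(src.genome_id, tgt.genome_id)] = _freq_curve(
            cross_ids, thresholds
        )
        curve.self_map_freq[src.genome_id] = _freq_curve(self_ids, thresholds)
    return curve


class ThresholdNotFoundError(ValueError):
    """No threshold in the sweep satisfies the spurious-mapping bound."""

    def __init__(self, max_spurious: float, curve: SweepCurve):
        self.curve = curve
        self.max_spurious = max_spurious
        super().__init__(
            f"no threshold holds cross-mapping <= {max_spurious:g} in both "
            f"directions (range {min(curve.thresholds)}..{max(curve.thresholds)})"
        )


def select_threshold(curve: SweepCurve, max_spurious: float = 0.01) -> int:
    """Smallest threshold with cross-mapping <= max_spurious both ways."""
    directions = curve.directions()
    for t in sorted(curve.thresholds):
        if all(curve.cross_map_freq[d][t] <= max_spurious for d in directions):
            return t
    raise ThresholdNotFoundError(max_spurious, curve)


# ---------------------------------------------------------------------------
# discrimination
# ---------------------------------------------------------------------------


@dataclass
class RecruitmentResult:
    """Per-genome mapped-read counts at a threshold, plus the A:B ratio."""

    counts: dict[str, int]
    unmapped: int
    threshold_used: float
    genome_a: str
    genome_b: str

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + self.unmapped

    @property
    def ratio_ab(self) -> float | None:
        """count_A / count_B; inf when B recruits nothing; None when both 0."""
        a = self.counts.get(self.genome_a, 0)
        b = self.counts.get(self.genome_b, 0)
        if b > 0:
            return a / b
        return math.inf if a > 0 else None


def discrimination_ratio(
    reads: dict[str, str] | ReadSet,
    genome_a: Genome,
    genome_b: Genome,
    threshold: float = 96.0,
    scheme: ScoringScheme | None = None,
) -> tuple[RecruitmentResult, list[ReadAssignment]]:
    """Recruit reads against the joint (A + B) reference at one threshold."""
    if isinstance(reads, ReadSet):
        reads = reads.sequences()
    assignments = recruit(
        reads, [genome_a, genome_b], min_similarity=threshold, scheme=scheme
    )
    counts = {genome_a.genome_id: 0, genome_b.genome_id: 0}
    unmapped = 0
    for asg in assignments:
        if asg.reference is None:
            unmapped += 1
        else:
            counts[asg.reference] = counts.get(asg.reference, 0) + 1
    return (
        RecruitmentResult(
            counts,
            unmapped,
            threshold,
            genome_a.genome_id,
            genome_b.genome_id,
        ),
        assignments,
    )
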