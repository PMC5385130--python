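"""Seeded local alignment, directional best hits, reciprocal best hits.

The aligner is seed-and-extend: exact k-mer seeds locate candidate regions,
and each candidate is scored with an affine-gap Smith-Waterman extension
(Bio.Align.PairwiseAligner in local mode).  For short subjects the extension
window is the whole sequence, so the returned score is the optimal local
alignment score whenever any seed exists; for genome-scale subjects the
extension is confined to windows around clustered seed diagonals.

Identity is gap-inclusive: percent_identity = 100 * matches / alignment
columns (columns counting gap positions), the convention of the BLAST-family
tools this engine emulates.  Ambiguity characters (N/X) never count as
matches and never seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.optimize import brentq

__all__ = [
    "ScoringScheme",
    "AlignmentHit",
    "HitFilters",
    "HomologyMap",
    "ReciprocalPairSet",
    "align_pair",
    "estimate_evalue",
    "best_hits",
    "reciprocal_best_hits",
    "SubjectIndex",
]

_NT_ALPHABET = set("ACGTN")
_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBZX*")
_AMBIGUOUS = set("NX")

# subject longer than this gets windowed extension instead of full DP
_FULL_DP_LIMIT = 5_000


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring parameters plus Karlin-Altschul constants.

    Gap convention: the first position of a gap scores ``gap_open``, each
    further position ``gap_extend`` (both <= 0).  ``ka_lambda``/``ka_k`` are
    ungapped Karlin-Altschul constants applied to gapped scores — a documented
    approximation; E-values here serve as coarse filters, and monotonicity in
    score is what matters.
    """

    mode: str = "nucleotide"  # "nucleotide" | "protein"
    match: int = 1
    mismatch: int = -2
    matrix: str = "BLOSUM62"
    gap_open: int = -5
    gap_extend: int = -2
    seed_k: int = 11
    min_score: float = 16.0
    ka_lambda: float = 1.33
    ka_k: float = 0.621

    def validate(self) -> None:
        if self.mode not in ("nucleotide", "protein"):
            raise ValueError(f"mode: unknown mode {self.mode!r}")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        min_k = 4 if self.mode == "nucleotide" else 3
        if self.seed_k < min_k:
            raise ValueError(f"seed_k: must be >= {min_k} for {self.mode}")

    @classmethod
    def nucleotide(cls, match: int = 1, mismatch: int = -2, **kw) -> "ScoringScheme":
        scheme = cls(mode="nucleotide", match=match, mismatch=mismatch, **kw)
        if (match, mismatch) != (1, -2):
            lam = ungapped_lambda(match, mismatch)
            scheme = replace(scheme, ka_lambda=lam, ka_k=0.35)
        scheme.validate()
        return scheme

    @classmethod
    def protein(cls, **kw) -> "ScoringScheme":
        defaults = dict(
            mode="protein",
            gap_open=-11,
            gap_extend=-1,
            seed_k=4,
            min_score=25.0,
            ka_lambda=0.3176,
            ka_k=0.134,
        )
        defaults.update(kw)
        scheme = cls(**defaults)
        scheme.validate()
        return scheme

    def alphabet(self) -> set[str]:
        return _NT_ALPHABET if self.mode == "nucleotide" else _AA_ALPHABET


def ungapped_lambda(match: int, mismatch: int, p_match: float = 0.25) -> float:
    """Solve sum_i p_i p_j exp(lambda s_ij) = 1 for a match/mismatch scheme."""
    if match <= 0 or mismatch >= 0:
        raise ValueError("need match > 0 and mismatch < 0")

    def f(lam: float) -> float:
        return (
            p_match * math.exp(lam * match)
            + (1 - p_match) * math.exp(lam * mismatch)
            - 1.0
        )

    return float(brentq(f, 1e-6, 10.0))


@lru_cache(maxsize=8)
def _nt_matrix(match: int, mismatch: int):
    m = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for a in "ACGT":
        for b in "ACGT":
            m[a, b] = match if a == b else mismatch
    for a in "ACGTN":
        m[a, "N"] = mismatch
        m["N", a] = mismatch
    return m


@lru_cache(maxsize=8)
def _make_aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(mode="local")
    if scheme.mode == "nucleotide":
        aligner.substitution_matrix = _nt_matrix(scheme.match, scheme.mismatch)
    else:
        aligner.substitution_matrix = substitution_matrices.load(scheme.matrix)
    aligner.open_gap_score = scheme.gap_open
    aligner.extend_gap_score = scheme.gap_extend
    return aligner


@dataclass
class AlignmentHit:
    """A scored local alignment between a query and a subject sequence."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int  # columns, gap positions included
    matches: int
    mismatches: int
    gap_opens: int
    gap_columns: int
    query_start: int  # 0-based half-open on the query
    query_end: int
    subject_start: int  # 0-based half-open on the subject strand aligned
    subject_end: int
    query_coverage: float
    subject_coverage: float
    score: float
    evalue: float = math.inf
    subject_strand: str = "+"

    def sort_key(self) -> tuple:
        """Descending preference: score, identity, length; then stable id."""
        return (
            -self.score,
            -self.percent_identity,
            -self.alignment_length,
            self.subject_id,
        )


@dataclass(frozen=True)
class HitFilters:
    """Hit acceptance filters recorded on every HomologyMap."""

    min_identity: float = 0.0  # percent
    max_evalue: float = math.inf
    min_coverage: float = 0.0  # fraction
    coverage_of: str = "shorter"  # "shorter" | "query" | "subject"

    def passes(self, hit: AlignmentHit, query_len: int, subject_len: int) -> bool:
        if hit.percent_identity < self.min_identity:
            return False
        if hit.evalue > self.max_evalue:
            return False
        if self.min_coverage > 0:
            if self.coverage_of == "query":
                cov = hit.query_coverage
            elif self.coverage_of == "subject":
                cov = hit.subject_coverage
            else:
                cov = (
                    hit.query_coverage
                    if query_len <= subject_len
                    else hit.subject_coverage
                )
            if cov < self.min_coverage:
                return False
        return True


@dataclass
class HomologyMap:
    """Directional best hits from one gene set to another."""

    direction: tuple[str, str]
    best_hit: dict[str, AlignmentHit]
    filters: HitFilters


@dataclass
class ReciprocalPairSet:
    """Mutual best-hit pairs between two gene sets."""

    genomes: tuple[str, str]
    pairs: list[tuple[str, str, AlignmentHit, AlignmentHit]]

    def __len__(self) -> int:
        return len(self.pairs)

    def id_pairs(self) -> list[tuple[str, str]]:
        return [(a, b) for a, b, _, _ in self.pairs]


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------


def _kmers(seq: str, k: int, ambiguous: str = "N") -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if ambiguous not in kmer:
            out.setdefault(kmer, []).append(i)
    return out


def _seed_windows(
    query: str, subject_kmers: dict[str, list[int]], k: int, subject_len: int,
    ambiguous: str = "N",
) -> list[tuple[int, int]]:
    """Cluster seed diagonals into subject extension windows."""
    diags: list[int] = []
    spans: list[tuple[int, int]] = []
    for i in range(len(query) - k + 1):
        kmer = query[i : i + k]
        if kmer in subject_kmers and ambiguous not in kmer:
            for j in subject_kmers[kmer]:
                diags.append(j - i)
                spans.append((j, j + k))
    if not diags:
        return []
    order = np.argsort(diags)
    qlen = len(query)
    band = max(32, qlen // 4)
    windows: list[tuple[int, int]] = []
    cur_diag = None
    lo = hi = 0
    for idx in order:
        d = diags[idx]
        s0, s1 = spans[idx]
        if cur_diag is None or d - cur_diag > band:
            if cur_diag is not None:
                windows.append((lo, hi))
            cur_diag = d
            lo, hi = s0, s1
        else:
            cur_diag = d
            lo, hi = min(lo, s0), max(hi, s1)
    windows.append((lo, hi))
    pad = qlen + band
    merged: list[tuple[int, int]] = []
    for lo, hi in sorted(windows):
        lo = max(0, lo - pad)
        hi = min(subject_len, hi + pad)
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


# ---------------------------------------------------------------------------
# extension and hit construction
# ---------------------------------------------------------------------------


def _hit_from_alignment(
    aln, query: str, subject: str, query_id: str, subject_id: str, offset: int,
    full_subject_len: int, ambiguous: str = "N",
) -> AlignmentHit:
    counts = aln.counts()
    t_blocks, q_blocks = aln.aligned  # target == subject-window here
    matches = int(counts.identities)
    mismatches = int(counts.mismatches)
    # never credit ambiguity self-matches (N==N nucleotide, X==X protein)
    if ambiguous in subject or ambiguous in query:
        bad = 0
        for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
            sub = subject[ts:te]
            q = query[qs:qe]
            for cs, cq in zip(sub, q):
                if cs == cq and cs == ambiguous:
                    bad += 1
        matches -= bad
        mismatches += bad
    gap_cols = int(counts.internal_gaps)
    gap_opens = int(
        counts.open_internal_insertions + counts.open_internal_deletions
    )
    length = matches + mismatches + gap_cols
    qs, qe = int(q_blocks[0][0]), int(q_blocks[-1][1])
    ss, se = int(t_blocks[0][0]) + offset, int(t_blocks[-1][1]) + offset
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        percent_identity=100.0 * matches / length if length else 0.0,
        alignment_length=length,
        matches=matches,
        mismatches=mismatches,
        gap_opens=gap_opens,
        gap_columns=gap_cols,
        query_start=qs,
        query_end=qe,
        subject_start=ss,
        subject_end=se,
        query_coverage=(qe - qs) / len(query) if query else 0.0,
        subject_coverage=(se - ss) / full_subject_len if full_subject_len else 0.0,
        score=float(aln.score),
    )


def _check_alphabet(seq: str, scheme: ScoringScheme, what: str) -> None:
    if not seq:
        raise ValueError(f"{what}: empty sequence")
    extra = set(seq) - scheme.alphabet()
    if extra:
        raise ValueError(
            f"{what}: characters {sorted(extra)} not in the {scheme.mode} alphabet"
        )


def align_pair(
    query: str,
    subject: str,
    scheme: ScoringScheme | None = None,
    query_id: str = "query",
    subject_id: str = "subject",
    _subject_kmers: dict[str, list[int]] | None = None,
) -> AlignmentHit | None:
    """Best seeded local alignment of query against subject, or None.

    Returns None when no exact k-mer seed is shared or the best extension
    scores below ``scheme.min_score``.  For subjects up to a few kb the
    extension covers the whole subject, so the score is the optimal local
    alignment score whenever a seed exists.
    """
    scheme = scheme or ScoringScheme.nucleotide()
    _check_alphabet(query, scheme, "query")
    _check_alphabet(subject, scheme, "subject")

    k = scheme.seed_k
    ambiguous = "N" if scheme.mode == "nucleotide" else "X"
    if len(query) < k or len(subject) < k:
        return None
    subject_kmers = (
        _subject_kmers
        if _subject_kmers is not None
        else _kmers(subject, k, ambiguous)
    )
    if len(subject) <= _FULL_DP_LIMIT:
        has_seed = any(
            query[i : i + k] in subject_kmers for i in range(len(query) - k + 1)
        )
        windows = [(0, len(subject))] if has_seed else []
    else:
        windows = _seed_windows(query, subject_kmers, k, len(subject), ambiguous)
    if not windows:
        return None

    aligner = _make_aligner(scheme)
    best: AlignmentHit | None = None
    for lo, hi in windows:
        window = subject[lo:hi]
        alignments = aligner.align(window, query)
        if alignments.score <= 0:
            continue
        hit = _hit_from_alignment(
            alignments[0], query, window, query_id, subject_id, lo, len(subject),
            ambiguous="N" if scheme.mode == "nucleotide" else "X",
        )
        if best is None or hit.sort_key() < best.sort_key():
            best = hit
    if best is None or best.score < scheme.min_score:
        return None
    best.evalue = estimate_evalue(best.score, len(query), len(subject), scheme)
    return best


def estimate_evalue(
    score: float, query_len: int, db_len: int, scheme: ScoringScheme
) -> float:
    """Karlin-Altschul expectation E = K * m * n * exp(-lambda * score)."""
    if score <= 0:
        raise ValueError("score must be > 0")
    return scheme.ka_k * query_len * db_len * math.exp(-scheme.ka_lambda * score)


# ---------------------------------------------------------------------------
# best hits
# ---------------------------------------------------------------------------


@lru_cache(maxsize=8)
def _score_lut(scheme: ScoringScheme) -> np.ndarray:
    """256x256 per-character substitution scores (ambiguity always negative)."""
    lut = np.full((256, 256), float(min(scheme.mismatch, -1)), dtype=np.float32)
    if scheme.mode == "nucleotide":
        for a in b"ACGT":
            for b in b"ACGT":
                lut[a, b] = scheme.match if a == b else scheme.mismatch
    else:
        m = substitution_matrices.load(scheme.matrix)
        for a in m.alphabet:
            for b in m.alphabet:
                lut[ord(a), ord(b)] = m[a, b]
        for a in m.alphabet:  # X never rewards
            lut[ord("X"), ord(a)] = min(lut[ord("X"), ord(a)], -1)
            lut[ord(a), ord("X")] = min(lut[ord(a), ord("X")], -1)
    return lut


def max_diagonal_segment_score(
    q: np.ndarray, s: np.ndarray, lut: np.ndarray
) -> float:
    """Best contiguous ungapped segment score of q vs s along one diagonal."""
    n = min(q.size, s.size)
    if n == 0:
        return 0.0
    scores = lut[q[:n], s[:n]].astype(np.float64)
    c = np.cumsum(scores)
    running_min = np.minimum.accumulate(np.concatenate(([0.0], c[:-1])))
    return float((c - running_min).max())


class SubjectIndex:
    """k-mer index over a subject gene set for candidate prefiltering."""

    def __init__(self, subjects: dict[str, str], k: int, ambiguous: str = "N"):
        self.k = k
        self.ambiguous = ambiguous
        self.subjects = subjects
        self.per_subject: dict[str, dict[str, list[int]]] = {}
        self.arrays: dict[str, np.ndarray] = {
            sid: np.frombuffer(seq.encode(), dtype=np.uint8)
            for sid, seq in subjects.items()
        }
        self.kmer_map: dict[str, list[tuple[str, int]]] = {}
        for sid, seq in subjects.items():
            km = _kmers(seq, k, ambiguous)
            self.per_subject[sid] = km
            for kmer, positions in km.items():
                bucket = self.kmer_map.setdefault(kmer, [])
                for j in positions:
                    bucket.append((sid, j))

    def seed_diagonals(self, query: str) -> dict[str, set[int]]:
        """Per candidate subject, the set of seed diagonals shared with query."""
        k = self.k
        out: dict[str, set[int]] = {}
        for i in range(len(query) - k + 1):
            bucket = self.kmer_map.get(query[i : i + k])
            if not bucket:
                continue
            for sid, j in bucket:
                out.setdefault(sid, set()).add(j - i)
        return out

    def candidates(self, query: str) -> set[str]:
        return set(self.seed_diagonals(query))

    def screen_score(self, query_arr: np.ndarray, sid: str, diagonals: set[int],
                     lut: np.ndarray) -> float:
        """Best ungapped segment score over the shared-seed diagonals."""
        sarr = self.arrays[sid]
        best = 0.0
        for d in diagonals:
            lo = max(0, d)
            qoff = lo - d
            if qoff >= query_arr.size:
                continue
            score = max_diagonal_segment_score(
                query_arr[qoff:], sarr[lo:], lut
            )
            if score > best:
                best = score
        return best


def best_hits(
    queries: dict[str, str],
    subjects: dict[str, str],
    scheme: ScoringScheme | None = None,
    filters: HitFilters | None = None,
    direction: tuple[str, str] = ("A", "B"),
    index: SubjectIndex | None = None,
) -> HomologyMap:
    """Single best subject per query, after filters; deterministic tie-break.

    Ties on score break by higher identity, then longer alignment, then
    lexicographically smallest subject id.  E-values use the total subject-set
    length as the database size.
    """
    if not queries or not subjects:
        raise ValueError("gene sets must be non-empty")
    scheme = scheme or ScoringScheme.nucleotide()
    filters = filters or HitFilters()
    index = index or SubjectIndex(
        subjects, scheme.seed_k, "N" if scheme.mode == "nucleotide" else "X"
    )
    db_len = sum(len(s) for s in subjects.values())

    aligner = _make_aligner(scheme)
    lut = _score_lut(scheme)
    best: dict[str, AlignmentHit] = {}
    for qid, qseq in queries.items():
        # the e-value bound is monotone in score, so it is an exact score cut
        # for this query; candidates below it can never pass the filters
        score_cut = scheme.min_score
        if math.isfinite(filters.max_evalue):
            s_ev = (
                math.log(scheme.ka_k * len(qseq) * db_len / filters.max_evalue)
                / scheme.ka_lambda
            )
            score_cut = max(score_cut, s_ev - 1e-9)
        # an ungapped seed-diagonal segment far below the cut cannot back a
        # qualifying gapped hit (heuristic margin for gap-joined segments)
        screen_floor = max(scheme.min_score - 4, 0.35 * score_cut)
        # screen seed diagonals (cheap, ungapped), score-only DP the survivors,
        # then extract alignments in score order until no remaining candidate
        # can beat the best passing hit
        qarr = np.frombuffer(qseq.encode(), dtype=np.uint8)
        scored: list[tuple[float, str]] = []
        for sid, diagonals in sorted(index.seed_diagonals(qseq).items()):
            if index.screen_score(qarr, sid, diagonals, lut) < screen_floor:
                continue
            if len(subjects[sid]) > _FULL_DP_LIMIT:
                hit = align_pair(
                    qseq, subjects[sid], scheme, query_id=qid, subject_id=sid,
                    _subject_kmers=index.per_subject[sid],
                )
                score = hit.score if hit else 0.0
            else:
                score = float(aligner.score(subjects[sid], qseq))
            if score >= score_cut:
                scored.append((-score, sid))
        scored.sort()
        top: AlignmentHit | None = None
        for neg_score, sid in scored:
            if top is not None and -neg_score < top.score:
                break
            hit = align_pair(
                qseq,
                subjects[sid],
                scheme,
                query_id=qid,
                subject_id=sid,
                _subject_kmers=index.per_subject[sid],
            )
            if hit is None:
                continue
            hit.evalue = estimate_evalue(hit.score, len(qseq), db_len, scheme)
            if not filters.passes(hit, len(qseq), len(subjects[sid])):
                continue
            if top is None or hit.sort_key() < top.sort_key():
                top = hit
        if top is not None:
            best[qid] = top
    return HomologyMap(direction=direction, best_hit=best, filters=filters)


def reciprocal_best_hits(
    map_ab: HomologyMap, map_ba: HomologyMap
) -> ReciprocalPairSet:
    """Pairs (a, b) where b is a's best hit and a is b's best hit.

    Output order follows map_ab's query order (coordinate order when the
    caller supplies coordinate-sorted genes), so link tables are stable.
    """
    if map_ab.direction != (map_ba.direction[1], map_ba.direction[0]):
        raise ValueError(
            f"direction mismatch: {map_ab.direction} vs {map_ba.direction}"
        )
    pairs = []
    for a, hit_ab in map_ab.best_hit.items():
        b = hit_ab.subject_id
        hit_ba = map_ba.best_hit.get(b)
        if hit_ba is not None and hit_ba.subject_id == a:
            pairs.append((a, b, hit_ab, hit_ba))
    return ReciprocalPairSet(genomes=map_ab.direction, pairs=pairs)
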