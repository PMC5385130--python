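"""Independent full dynamic-programming local-alignment oracle for tests.

A from-scratch Gotoh affine-gap Smith-Waterman over the complete DP matrix
(no seeding, no windows, no pruning), used to cross-check the package's
seed-and-extend aligner.  Gap convention matches the package's declared one:
the first position of a gap costs ``gap_open``, each further position
``gap_extend``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1e18


@njit(cache=True)
def _gotoh_local(a: np.ndarray, b: np.ndarray, lut: np.ndarray,
                 gap_open: float, gap_extend: float) -> float:
    n, m = a.size, b.size
    h_prev = np.zeros(m + 1)
    f_prev = np.full(m + 1, NEG)
    best = 0.0
    for i in range(1, n + 1):
        h_cur = np.zeros(m + 1)
        f_cur = np.empty(m + 1)
        f_cur[0] = NEG
        e = NEG
        for j in range(1, m + 1):
            e = max(h_cur[j - 1] + gap_open, e + gap_extend)
            f_cur[j] = max(h_prev[j] + gap_open, f_prev[j] + gap_extend)
            diag = h_prev[j - 1] + lut[a[i - 1], b[j - 1]]
            h = max(0.0, diag, e, f_cur[j])
            h_cur[j] = h
            if h > best:
                best = h
        h_prev = h_cur
        f_prev = f_cur
    return best


def _as_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def nucleotide_lut(match: float = 1.0, mismatch: float = -2.0) -> np.ndarray:
    lut = np.full((256, 256), mismatch)
    for c in b"ACGT":
        lut[c, c] = match
    for c in b"ACGTN":  # N never matches anything, including itself
        lut[c, ord("N")] = mismatch
        lut[ord("N"), c] = mismatch
    return lut


def blosum62_lut() -> np.ndarray:
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("BLOSUM62")
    lut = np.full((256, 256), -4.0)
    for x in m.alphabet:
        for y in m.alphabet:
            lut[ord(x), ord(y)] = m[x, y]
    return lut


def optimal_local_score(query: str, subject: str, lut: np.ndarray,
                        gap_open: float, gap_extend: float) -> float:
    """Optimal affine-gap local alignment score over the full DP matrix."""
    return float(
        _gotoh_local(_as_bytes(query), _as_bytes(subject), lut, gap_open, gap_extend)
    )


def all_pairs_best(queries: dict[str, str], subjects: dict[str, str],
                   lut: np.ndarray, gap_open: float, gap_extend: float,
                   min_score: float) -> dict[str, tuple[float, list[str]]]:
    """Per query: (best score, all subjects attaining it), ignoring sub-min hits."""
    out: dict[str, tuple[float, list[str]]] = {}
    for qid, q in queries.items():
        best = 0.0
        holders: list[str] = []
        for sid, s in subjects.items():
            sc = optimal_local_score(q, s, lut, gap_open, gap_extend)
            if sc < min_score:
                continue
            if sc > best:
                best, holders = sc, [sid]
            elif sc == best:
                holders.append(sid)
        if holders:
            out[qid] = (best, holders)
    return out
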