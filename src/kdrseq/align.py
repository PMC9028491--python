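"""Deterministic affine-gap pairwise alignment of amplicon sequences.

Two modes are provided:

``semiglobal``
    The query must be aligned end to end while the reference may overhang
    freely on either side ("glocal" alignment).  This is the mode used to
    place a consensus amplicon inside its reference region.
``global``
    Both sequences are aligned end to end (Needleman-Wunsch with affine
    gaps).  Used to reconcile clone reads of unequal length before voting.

Scoring is affine: a gap of length ``L`` costs ``gap_open + (L-1) *
gap_extend`` (both negative).  IUPAC ambiguity codes are honoured on both
sequences: two letters whose base sets intersect score as a match.

The dynamic program is a standard three-state Gotoh recursion, filled
row-by-row with numpy (the within-row gap state is computed with a running
prefix maximum).  Tie-breaking during traceback is fixed and documented:
diagonal continuation is preferred over gaps, and a gap in the query is
preferred over a gap in the reference, which yields one canonical optimal
alignment for any input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from Bio.Data.IUPACData import ambiguous_dna_values

#: Score used as "minus infinity"; large enough to dominate, small enough
#: never to overflow int32 when summed with real scores.
_NEG = np.int32(-(2**20))

# 4-bit encoding: A=1, C=2, G=4, T=8; ambiguity codes are unions.
_BASE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
IUPAC_BITS: dict[str, int] = {
    letter: sum(_BASE_BITS[b] for b in bases)
    for letter, bases in ambiguous_dna_values.items()
    if letter != "X"
}
IUPAC_BITS["U"] = _BASE_BITS["T"]

_ENCODE = np.zeros(256, dtype=np.uint8)
for _letter, _bits in IUPAC_BITS.items():
    _ENCODE[ord(_letter)] = _bits
    _ENCODE[ord(_letter.lower())] = _bits


def encode_bases(seq: str) -> np.ndarray:
    """Encode a nucleotide string into 4-bit IUPAC masks.

    Raises ``ValueError`` on characters that are not IUPAC nucleotide
    codes (gap symbols included).
    """
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    masks = _ENCODE[arr]
    if np.any(masks == 0):
        bad = seq[int(np.argmin(masks > 0))]
        raise ValueError(f"non-nucleotide character {bad!r} in sequence")
    return masks


@dataclass(frozen=True)
class Scoring:
    """Alignment scores: match/mismatch per column, affine gap costs.

    ``gap_open`` is the cost of a length-1 gap; each further gapped base
    adds ``gap_extend``.
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2


@dataclass
class PairwiseAlignment:
    """One canonical optimal alignment.

    ``aligned_ref``/``aligned_query`` use ``-`` for gaps and, in
    semiglobal mode, cover only the aligned reference window
    ``[ref_start, ref_end)``; reference overhangs are not represented.
    """

    aligned_ref: str
    aligned_query: str
    score: int
    ref_start: int
    ref_end: int

    @property
    def n_columns(self) -> int:
        return len(self.aligned_ref)

    def identity(self) -> float:
        """Fraction of columns where both letters are compatible bases."""
        if not self.aligned_ref:
            return 0.0
        matches = 0
        for r, q in zip(self.aligned_ref, self.aligned_query):
            if r != "-" and q != "-" and (IUPAC_BITS[r] & IUPAC_BITS[q]):
                matches += 1
        return matches / self.n_columns


def _fill(ref_bits: np.ndarray, query_bits: np.ndarray, sc: Scoring, semiglobal: bool):
    n, m = len(query_bits), len(ref_bits)
    go, ge = np.int32(sc.gap_open), np.int32(sc.gap_extend)
    mt, mm = np.int32(sc.match), np.int32(sc.mismatch)

    M = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    Ix = np.full((n + 1, m + 1), _NEG, dtype=np.int32)  # gap in ref, consumes query
    Iy = np.full((n + 1, m + 1), _NEG, dtype=np.int32)  # gap in query, consumes ref

    if semiglobal:
        M[0, :] = 0  # alignment may start at any reference offset for free
    else:
        M[0, 0] = 0
        if m:
            Iy[0, 1:] = go + ge * np.arange(m, dtype=np.int32)
    if n:
        Ix[1:, 0] = go + ge * np.arange(n, dtype=np.int32)

    js = np.arange(1, m + 1, dtype=np.int32)
    for i in range(1, n + 1):
        compat = (ref_bits & query_bits[i - 1]) > 0
        sub = np.where(compat, mt, mm).astype(np.int32)
        prev_best = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = prev_best[:-1] + sub
        Ix[i, 1:] = np.maximum(M[i - 1, 1:] + go, Ix[i - 1, 1:] + ge)
        # Iy[i, j] = max_{k<j} M[i, k] + go + ge*(j-1-k), via prefix max.
        a = M[i, :-1] + go - ge * js
        Iy[i, 1:] = np.maximum.accumulate(a) + ge * js
    return M, Ix, Iy


def _traceback(ref, query, M, Ix, Iy, sc, semiglobal):
    n, m = len(query), len(ref)
    go, ge = sc.gap_open, sc.gap_extend

    if semiglobal:
        # End column: prefer the match state, then the rightmost column.
        end_vals = np.maximum(M[n], Ix[n])
        j = int(np.argmax(end_vals[::-1]))
        j = m - j
        score = int(end_vals[j])
        state = "M" if M[n, j] == score else "Ix"
    else:
        score = int(max(M[n, m], Ix[n, m], Iy[n, m]))
        for state in ("M", "Ix", "Iy"):
            if {"M": M, "Ix": Ix, "Iy": Iy}[state][n, m] == score:
                break
        j = m

    cols_r: list[str] = []
    cols_q: list[str] = []
    i = n
    ref_end = j
    while i > 0 or (not semiglobal and j > 0):
        if state == "M":
            if i == 0:
                break
            cols_r.append(ref[j - 1])
            cols_q.append(query[i - 1])
            bits_ok = IUPAC_BITS[ref[j - 1]] & IUPAC_BITS[query[i - 1]]
            sub = sc.match if bits_ok else sc.mismatch
            want = M[i, j] - sub
            i -= 1
            j -= 1
            if i == 0 and (semiglobal or j == 0):
                break
            # predecessor preference: diagonal, then gap-in-query, then gap-in-ref
            if M[i, j] == want:
                state = "M"
            elif Iy[i, j] == want:
                state = "Iy"
            else:
                state = "Ix"
        elif state == "Ix":
            cols_r.append("-")
            cols_q.append(query[i - 1])
            if j == 0:
                prev_from_m = i == 1
            else:
                prev_from_m = M[i - 1, j] + go == Ix[i, j]
            i -= 1
            state = "M" if prev_from_m else "Ix"
            if i == 0:
                break
        else:  # Iy
            cols_r.append(ref[j - 1])
            cols_q.append("-")
            prev_from_m = M[i, j - 1] + go == Iy[i, j]
            j -= 1
            state = "M" if prev_from_m else "Iy"
            if i == 0 and j == 0:
                break

    ref_start = j
    return PairwiseAlignment(
        aligned_ref="".join(reversed(cols_r)),
        aligned_query="".join(reversed(cols_q)),
        score=score,
        ref_start=ref_start,
        ref_end=ref_end,
    )


def pairwise_align(
    ref: str,
    query: str,
    scoring: Scoring | None = None,
    mode: str = "semiglobal",
) -> PairwiseAlignment:
    """Align ``query`` against ``ref`` and return one canonical optimum.

    Parameters
    ----------
    ref, query:
        Uppercase nucleotide strings; IUPAC ambiguity codes allowed.
    scoring:
        Affine scoring scheme (defaults to match +2 / mismatch -3 /
        gap open -5 / gap extend -2).
    mode:
        ``"semiglobal"`` (free reference end gaps) or ``"global"``.
    """
    if mode not in ("semiglobal", "global"):
        raise ValueError(f"unknown alignment mode {mode!r}")
    if not query:
        raise ValueError("query sequence is empty")
    if not ref:
        raise ValueError("reference sequence is empty")
    sc = scoring or Scoring()
    semiglobal = mode == "semiglobal"
    rb = encode_bases(ref)
    qb = encode_bases(query)
    M, Ix, Iy = _fill(rb, qb, sc, semiglobal)
    return _traceback(ref, query, M, Ix, Iy, sc, semiglobal)
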