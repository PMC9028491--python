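"""In-silico PCR and clone consensus.

:func:`extract_amplicon` locates a primer pair on either strand of a
clone read (ungapped matching with a per-primer mismatch tolerance,
IUPAC-degeneracy aware on both sides), orients the hit to the forward
strand of the gene and trims the primers.  :func:`consensus_from_clones`
arbitrates the 2-3 sequenced clones of one mosquito into a single
consensus: strict per-position majority, with ties emitted as the IUPAC
code covering the tied bases and recorded as discordant.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from Bio.Seq import Seq

from kdrseq.align import IUPAC_BITS, Scoring, encode_bases, pairwise_align
from kdrseq.reference import PrimerPair

#: bitmask (A=1, C=2, G=4, T=8) -> IUPAC letter
BITS_TO_IUPAC = {bits: letter for letter, bits in IUPAC_BITS.items() if letter != "U"}


class AmbiguousAmpliconError(ValueError):
    """Several equally good primer placements; no silent choice is made."""


@dataclass(frozen=True)
class AmpliconHit:
    """One primer-delimited amplicon found in a clone read.

    ``start``/``end`` delimit the primer-trimmed insert on the *oriented*
    read (forward-gene orientation); ``insert`` is that subsequence.
    """

    record_id: str | None
    region: str | None
    strand: str
    start: int
    end: int
    mismatches_fwd: int
    mismatches_rev: int
    insert: str

    @property
    def total_mismatches(self) -> int:
        return self.mismatches_fwd + self.mismatches_rev


def _scan(seq_bits: np.ndarray, primer_bits: np.ndarray) -> np.ndarray:
    """Mismatch count of an ungapped primer placement at every offset."""
    m = len(primer_bits)
    if len(seq_bits) < m:
        return np.zeros(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(seq_bits, m)
    return np.count_nonzero((windows & primer_bits) == 0, axis=1)


def extract_amplicon(
    sequence: str,
    pair: PrimerPair,
    max_mismatch: int = 2,
    *,
    record_id: str | None = None,
    region: str | None = None,
) -> AmpliconHit | None:
    """Search both strands for the primer pair and return the best hit.

    The unique placement with the fewest total mismatches wins; equally
    good distinct placements raise :class:`AmbiguousAmpliconError`; if
    either primer is absent within tolerance the function returns
    ``None``.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    seq = sequence.upper()
    fwd_bits = encode_bases(pair.seq_fwd)
    site_bits = encode_bases(pair.site_rev_forward_strand)

    candidates: list[tuple[int, str, int, int, int, int, str]] = []
    for strand, oriented in (("+", seq), ("-", str(Seq(seq).reverse_complement()))):
        bits = encode_bases(oriented)
        mm_f = _scan(bits, fwd_bits)
        mm_r = _scan(bits, site_bits)
        f_offsets = np.flatnonzero(mm_f <= max_mismatch)
        r_offsets = np.flatnonzero(mm_r <= max_mismatch)
        for f in f_offsets:
            insert_start = int(f) + len(pair.seq_fwd)
            for r in r_offsets:
                if int(r) < insert_start:
                    continue
                total = int(mm_f[f]) + int(mm_r[r])
                candidates.append(
                    (
                        total,
                        strand,
                        insert_start,
                        int(r),
                        int(mm_f[f]),
                        int(mm_r[r]),
                        oriented,
                    )
                )
    if not candidates:
        return None
    best = min(c[0] for c in candidates)
    top = [c for c in candidates if c[0] == best]
    if len(top) > 1:
        raise AmbiguousAmpliconError(
            f"{len(top)} equally good primer placements (total mismatches {best})"
        )
    _, strand, start, end, mmf, mmr, oriented = top[0]
    return AmpliconHit(
        record_id=record_id,
        region=region,
        strand=strand,
        start=start,
        end=end,
        mismatches_fwd=mmf,
        mismatches_rev=mmr,
        insert=oriented[start:end],
    )


@dataclass(frozen=True)
class ConsensusResult:
    """Consensus of the clone amplicons of one individual and region."""

    individual_id: str | None
    region: str | None
    sequence: str
    n_clones: int
    discordant_positions: tuple[int, ...]

    def with_ids(self, individual_id: str, region: str) -> "ConsensusResult":
        return replace(self, individual_id=individual_id, region=region)


def _vote_column(column: Sequence[str]) -> tuple[str, bool]:
    """Majority vote over one column of bases/gaps.

    Returns ``(symbol, discordant)``; ``symbol`` is ``-`` when gaps hold a
    strict majority, the winning base on a strict base majority, and the
    IUPAC union of the top-tied bases otherwise.
    """
    counts: dict[str, int] = {}
    for b in column:
        counts[b] = counts.get(b, 0) + 1
    discordant = len(counts) > 1
    gap_count = counts.pop("-", 0)
    if not counts:
        return "-", discordant
    top = max(counts.values())
    if gap_count > sum(counts.values()):
        return "-", discordant
    winners = sorted(b for b, c in counts.items() if c == top)
    if len(winners) == 1 and top > sum(counts.values()) - top:
        return winners[0], discordant
    bits = 0
    for b in winners:
        bits |= IUPAC_BITS[b]
    return BITS_TO_IUPAC[bits], True


def _align_clones(clones: list[str], scoring: Scoring) -> list[str]:
    """Star-align unequal-length clones against the longest clone.

    Returns gapped rows of equal length (anchor columns plus insertion
    columns keyed to the anchor position they follow).
    """
    anchor_idx = max(range(len(clones)), key=lambda i: len(clones[i]))
    anchor = clones[anchor_idx]
    # per clone: map anchor position -> base, and insertions after position
    rows: list[tuple[dict[int, str], dict[int, list[str]]]] = []
    for clone in clones:
        if clone == anchor:
            rows.append(({i: b for i, b in enumerate(anchor)}, {}))
            continue
        aln = pairwise_align(anchor, clone, scoring, mode="global")
        bases: dict[int, str] = {}
        inserts: dict[int, list[str]] = {}
        apos = -1  # last consumed anchor position
        for a, q in zip(aln.aligned_ref, aln.aligned_query):
            if a == "-":
                inserts.setdefault(apos, []).append(q)
            else:
                apos += 1
                bases[apos] = q
        rows.append((bases, inserts))

    n = len(clones)
    max_ins = {
        p: max(len(r[1].get(p, [])) for r in rows)
        for p in set().union(*(r[1] for r in rows))
    }
    columns: list[list[str]] = []
    keys: list[tuple[int, int]] = []
    for p in range(-1, len(anchor)):
        if p >= 0:
            columns.append([r[0].get(p, "-") for r in rows])
            keys.append((p, 0))
        for k in range(max_ins.get(p, 0)):
            col = []
            for bases, inserts in rows:
                ins = inserts.get(p, [])
                col.append(ins[k] if k < len(ins) else "-")
            columns.append(col)
            keys.append((p, k + 1))
    return ["".join(col[i] for col in columns) for i in range(n)]


def consensus_from_clones(
    clone_amplicons: Sequence[str],
    policy: str = "majority",
    scoring: Scoring | None = None,
) -> ConsensusResult:
    """Arbitrate clone amplicons of one individual into a consensus.

    ``policy="majority"`` (default) votes per position; ties become IUPAC
    ambiguity codes and are listed in ``discordant_positions`` (offsets on
    the consensus).  ``policy="first"`` returns the first clone verbatim
    but still reports discordance against the remaining clones.  Clones
    of unequal length are mutually aligned before voting; a strict gap
    majority deletes the column.
    """
    clones = [c.upper() for c in clone_amplicons]
    if not clones:
        raise ValueError("at least one clone amplicon is required")
    if policy not in ("majority", "first"):
        raise ValueError(f"unknown consensus policy {policy!r}")

    if len(set(map(len, clones))) == 1:
        rows = clones
    else:
        rows = _align_clones(clones, scoring or Scoring())

    out: list[str] = []
    discordant: list[int] = []
    first_row = rows[0]
    for col_idx in range(len(rows[0])):
        column = [r[col_idx] for r in rows]
        symbol, disc = _vote_column(column)
        if policy == "first":
            symbol = first_row[col_idx]
            if symbol == "-":
                continue
            if disc:
                discordant.append(len(out))
            out.append(symbol)
            continue
        if symbol == "-":
            continue
        if disc:
            discordant.append(len(out))
        out.append(symbol)

    return ConsensusResult(
        individual_id=None,
        region=None,
        sequence="".join(out),
        n_clones=len(clones),
        discordant_positions=tuple(discordant),
    )
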