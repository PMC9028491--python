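"""Codon-aware amino-acid substitution calling against the gene model.

Each consensus amplicon is aligned semi-globally to its reference region
(the primer-trimmed insert, introns included), the alignment is projected
onto the model's codon map, every fully covered in-frame codon is
translated, and residues that differ from the reference yield
:class:`AaCall` records classified against the kdr catalogue.

IUPAC ambiguity codes in the consensus (clone discordance) are expanded:
a codon whose expansions translate to more than one residue is classified
``ambiguous`` and never counted as a mutant.  Codons touched by gaps,
insertions, or lying downstream of a frameshifting (non multiple-of-3)
coding gap are reported as uncovered rather than called.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

from kdrseq.align import IUPAC_BITS, PairwiseAlignment, Scoring, pairwise_align
from kdrseq.reference import GeneModel, KdrSite, catalog_site, translate_codon

CLASS_VALIDATED = "validated_kdr"
CLASS_WATCH = "watch"
CLASS_OTHER = "other"
CLASS_AMBIGUOUS = "ambiguous"

_BITS_TO_BASES = {
    letter: [b for b in "ACGT" if IUPAC_BITS[b] & IUPAC_BITS[letter]]
    for letter in IUPAC_BITS
}


def expand_codon(codon: str) -> list[str]:
    """All unambiguous codons covered by an IUPAC-coded triplet."""
    return [
        "".join(bases)
        for bases in itertools.product(*(_BITS_TO_BASES[b] for b in codon))
    ]


def translate_ambiguous(codon: str) -> frozenset[str]:
    """Set of residues (incl. ``*``) reachable from an ambiguous codon."""
    return frozenset(translate_codon(c) for c in expand_codon(codon))


@dataclass(frozen=True)
class AaCall:
    """One amino-acid substitution call in one individual.

    ``alt_residue`` is a single letter, or a ``/``-joined sorted set for
    ambiguous calls.  ``label`` follows the field convention
    wild-type + position + mutant (e.g. ``V1016G``).
    """

    individual_id: str | None
    region: str
    protein_position: int
    ref_residue: str
    alt_residue: str
    ref_codon: str
    obs_codon: str
    classification: str

    @property
    def label(self) -> str:
        return f"{self.ref_residue}{self.protein_position}{self.alt_residue}"


@dataclass
class RegionAlignment:
    """A consensus amplicon placed on its reference region insert."""

    region: str
    alignment: PairwiseAlignment
    identity: float
    unalignable: bool

    @property
    def score(self) -> int:
        return self.alignment.score


@dataclass
class CallSet:
    """Calls plus coverage bookkeeping for one individual and region."""

    individual_id: str | None
    region: str
    calls: tuple[AaCall, ...]
    covered_positions: frozenset[int]
    uncovered_positions: tuple[int, ...]
    frameshift: bool


def align_to_reference(
    consensus: str,
    model: GeneModel,
    region: str,
    scoring: Scoring | None = None,
    identity_floor: float = 0.8,
) -> RegionAlignment:
    """Semi-global alignment of a consensus onto a region's insert.

    Alignments whose identity falls below ``identity_floor`` are flagged
    ``unalignable``; the individual is then excluded from that region's
    calls (off-target amplicon guard).
    """
    if not consensus:
        raise ValueError("consensus sequence is empty")
    ref = model.insert_sequence(region)
    aln = pairwise_align(ref, consensus, scoring, mode="semiglobal")
    identity = aln.identity()
    return RegionAlignment(
        region=region,
        alignment=aln,
        identity=identity,
        unalignable=identity < identity_floor,
    )


def _project(alignment: PairwiseAlignment):
    """Map reference-insert positions to query bases and list gap runs.

    Returns ``(qbase, insertions)`` where ``qbase[ref_local_pos]`` is the
    aligned query base or ``None`` for a deletion, and ``insertions`` maps
    a reference position to the number of query bases inserted
    immediately before it.
    """
    qbase: dict[int, str | None] = {}
    insertions: dict[int, int] = {}
    ref_pos = alignment.ref_start
    for r, q in zip(alignment.aligned_ref, alignment.aligned_query):
        if r == "-":
            insertions[ref_pos] = insertions.get(ref_pos, 0) + 1
        else:
            qbase[ref_pos] = None if q == "-" else q
            ref_pos += 1
    return qbase, insertions


def call_substitutions(
    region_alignment: RegionAlignment,
    model: GeneModel,
    catalog: Sequence[KdrSite],
    individual_id: str | None = None,
) -> CallSet:
    """Translate covered codons and emit substitution calls.

    Precondition: the alignment passed the identity floor (``ValueError``
    otherwise).  A coding gap whose exonic length is not a multiple of 3
    marks the individual's amplicon as frameshifted: every codon from the
    gap onward is uncovered and flagged for review.
    """
    if region_alignment.unalignable:
        raise ValueError("alignment below the identity floor; no calls possible")
    region = model.region(region_alignment.region)
    ins_start, _ = model.insert_interval(region.name)
    qbase, insertions = _project(region_alignment.alignment)

    # locate the earliest frameshifting coding gap (reference-local pos)
    frameshift_from: int | None = None

    # deletions: runs of reference positions aligned to '-'
    run: list[int] = []
    sorted_positions = sorted(qbase)
    for p in sorted_positions + [None]:
        if p is not None and qbase[p] is None:
            run.append(p)
            continue
        if run:
            exonic = sum(1 for rp in run if model.is_exonic(ins_start + rp))
            if exonic % 3 != 0:
                start = run[0]
                if frameshift_from is None or start < frameshift_from:
                    frameshift_from = start
            run = []

    # insertions: coding when they interrupt two exonic reference bases
    # that are genomically adjacent (i.e. inside one exon)
    for p, length in insertions.items():
        g_after = ins_start + p
        g_before = g_after - 1
        if model.is_exonic(g_after) and model.is_exonic(g_before):
            if length % 3 != 0:
                if frameshift_from is None or p < frameshift_from:
                    frameshift_from = p

    calls: list[AaCall] = []
    covered: set[int] = set()
    uncovered: list[int] = []
    for pos in range(region.protein_span[0], region.protein_span[1] + 1):
        intervals, ref_codon = model.codon_for_position(pos)
        locals_: list[int] = []
        for s, e in intervals:
            locals_.extend(range(s - ins_start, e - ins_start))
        bases = [qbase.get(lp) for lp in locals_]
        ok = all(b is not None for b in bases)
        if ok and frameshift_from is not None:
            ok = max(locals_) < frameshift_from
        if ok:
            # an insertion strictly inside an exonic run of the codon
            # breaks the frame of the observed triplet
            for s, e in intervals:
                for g in range(s + 1, e):
                    if insertions.get(g - ins_start, 0):
                        ok = False
        if not ok:
            uncovered.append(pos)
            continue
        covered.add(pos)
        obs_codon = "".join(bases)  # type: ignore[arg-type]
        if obs_codon == ref_codon:
            continue
        residues = translate_ambiguous(obs_codon)
        ref_residue = model.residue_at(pos)
        if residues == {ref_residue}:
            continue  # synonymous
        site = catalog_site(catalog, pos)
        if len(residues) > 1:
            alt = "/".join(sorted(residues))
            classification = CLASS_AMBIGUOUS
        else:
            (alt,) = residues
            if site is not None and alt in site.known_mutants:
                classification = CLASS_VALIDATED if site.validated else CLASS_WATCH
            else:
                classification = CLASS_OTHER
        calls.append(
            AaCall(
                individual_id=individual_id,
                region=region.name,
                protein_position=pos,
                ref_residue=ref_residue,
                alt_residue=alt,
                ref_codon=ref_codon,
                obs_codon=obs_codon,
                classification=classification,
            )
        )
    return CallSet(
        individual_id=individual_id,
        region=region.name,
        calls=tuple(calls),
        covered_positions=frozenset(covered),
        uncovered_positions=tuple(uncovered),
        frameshift=frameshift_from is not None,
    )
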