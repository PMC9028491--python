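"""Reference gene model for the vgsc amplicons and the kdr-site catalogue.

A :class:`GeneModel` couples a genomic reference sequence with its exon
structure, the protein numbering of the encoded codons, and the two
amplified regions (DII-S6 and DIII-S6 for the bundled model), each
delimited by a PCR primer pair.  Coordinates are 0-based half-open on the
forward strand; protein positions are 1-based and follow the reference
translation, so that the canonical kdr sites carry their field names
(S989P, V1016G, T1520I, F1534C/L).

The kdr-site catalogue lists, per protein position, the wild-type residue,
the known mutant residues and whether the substitution is validated as a
resistance allele; non-validated "watch" sites (F1020S, E1553G) are
included so that calls at them are classified separately.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: codon -> amino acid (stop codons excluded; translated as ``*`` below)
CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)

#: amino acid -> sorted tuple of codons under the standard genetic code
CODONS_BY_AA: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    CODONS_BY_AA.setdefault(_aa, ())
    CODONS_BY_AA[_aa] = CODONS_BY_AA[_aa] + (_codon,)

AMINO_ACIDS = frozenset(CODONS_BY_AA)


def translate_codon(codon: str) -> str:
    """Translate an unambiguous codon; stop codons give ``*``."""
    return CODON_TO_AA.get(codon, "*" if codon in _STANDARD_TABLE.stop_codons else "X")


class GeneModelError(ValueError):
    """Base class for gene-model validation failures."""


class MissingSequenceError(GeneModelError):
    """The annotation references a sequence id absent from the FASTA."""


class ExonLayoutError(GeneModelError):
    """Exons overlap, are unsorted, or fall outside the sequence."""


class FrameError(GeneModelError):
    """Exonic length or a region's protein span is inconsistent with frame."""


class InternalStopError(GeneModelError):
    """The concatenated exonic sequence translates with an internal stop."""


class PrimerSiteError(GeneModelError):
    """A region's primer pair is absent or not unique in the reference."""


class UnmappedPositionError(GeneModelError):
    """A protein position is not covered by the model's codon map."""


@dataclass(frozen=True)
class PrimerPair:
    """A PCR primer pair, both given 5'->3' as synthesized.

    The reverse primer anneals to the forward strand, so its binding site
    on the forward strand is its reverse complement.
    """

    name_fwd: str
    name_rev: str
    seq_fwd: str
    seq_rev: str

    def __post_init__(self):
        for label, seq in (("forward", self.seq_fwd), ("reverse", self.seq_rev)):
            if len(seq) < 15:
                raise ValueError(f"{label} primer shorter than 15 nt: {seq!r}")
            if set(seq) - set("ACGT"):
                raise ValueError(f"{label} primer has non-ACGT characters: {seq!r}")

    @property
    def site_rev_forward_strand(self) -> str:
        """Reverse-primer binding site as it reads on the forward strand."""
        return str(Seq(self.seq_rev).reverse_complement())


@dataclass(frozen=True)
class RegionDef:
    """An amplified region: a primer pair plus the fully sequenced codons."""

    name: str
    primers: PrimerPair
    protein_span: tuple[int, int]  # inclusive 1-based protein positions

    def __post_init__(self):
        a, b = self.protein_span
        if a > b:
            raise ValueError(f"empty protein span for region {self.name!r}")

    def contains(self, protein_position: int) -> bool:
        return self.protein_span[0] <= protein_position <= self.protein_span[1]


@dataclass(frozen=True)
class KdrSite:
    """One catalogued vgsc site with its known amino-acid replacements."""

    protein_position: int
    wild_type: str
    known_mutants: frozenset[str]
    domain: str
    validated: bool

    def __post_init__(self):
        if self.wild_type in self.known_mutants:
            raise ValueError(
                f"site {self.protein_position}: wild type listed as mutant"
            )


@dataclass(frozen=True)
class GeneModel:
    """Reference sequence + exon structure + amplified regions.

    Invariants are checked on construction: exons sorted, disjoint and in
    bounds; exonic length a multiple of three; translation free of
    internal stops; each region's primers present exactly once on the
    forward strand and its protein span fully mapped between them.
    """

    reference_id: str
    sequence: str
    exons: tuple[tuple[int, int], ...]
    coding_start_protein_position: int
    regions: tuple[RegionDef, ...]

    def __post_init__(self):
        seq = self.sequence
        if set(seq) - set("ACGT"):
            raise GeneModelError("reference sequence must be uppercase A/C/G/T")
        prev_end = 0
        for start, end in self.exons:
            if not (0 <= start < end <= len(seq)):
                raise ExonLayoutError(f"exon ({start}, {end}) out of bounds")
            if start < prev_end:
                raise ExonLayoutError(f"exon ({start}, {end}) overlaps or is unsorted")
            prev_end = end
        if self.exonic_length % 3 != 0:
            raise FrameError(
                f"exonic length {self.exonic_length} is not a multiple of 3"
            )
        if "*" in self.protein_sequence:
            raise InternalStopError("exonic sequence translates with a stop codon")
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise GeneModelError("duplicate region names")
        for region in self.regions:
            lo, hi = self._insert_span(region)
            for p in range(region.protein_span[0], region.protein_span[1] + 1):
                intervals, _ = self.codon_for_position(p)
                for s, e in intervals:
                    if s < lo or e > hi:
                        raise FrameError(
                            f"region {region.name!r}: codon {p} extends outside "
                            "the primer-delimited insert"
                        )

    # -- codon map ---------------------------------------------------------

    @cached_property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @cached_property
    def exonic_sequence(self) -> str:
        return "".join(self.sequence[s:e] for s, e in self.exons)

    @cached_property
    def protein_sequence(self) -> str:
        return str(Seq(self.exonic_sequence).translate())

    @property
    def protein_positions(self) -> range:
        start = self.coding_start_protein_position
        return range(start, start + self.exonic_length // 3)

    @cached_property
    def _exon_starts(self) -> list[int]:
        return [s for s, _ in self.exons]

    @cached_property
    def _exon_offsets(self) -> list[int]:
        # cumulative exonic length before each exon
        offsets = [0]
        for s, e in self.exons:
            offsets.append(offsets[-1] + (e - s))
        return offsets

    def is_exonic(self, genomic_position: int) -> bool:
        i = bisect.bisect_right(self._exon_starts, genomic_position) - 1
        if i < 0:
            return False
        s, e = self.exons[i]
        return s <= genomic_position < e

    def _exonic_offset_to_genomic(self, offset: int) -> int:
        i = bisect.bisect_right(self._exon_offsets, offset) - 1
        s, e = self.exons[i]
        return s + (offset - self._exon_offsets[i])

    def residue_at(self, protein_position: int) -> str:
        if protein_position not in self.protein_positions:
            raise UnmappedPositionError(f"protein position {protein_position} unmapped")
        return self.protein_sequence[
            protein_position - self.coding_start_protein_position
        ]

    def codon_for_position(
        self, protein_position: int
    ) -> tuple[tuple[tuple[int, int], ...], str]:
        """Genomic intervals (1-3 of them, 3 bases total) and the triplet.

        Codons split by an intron return one interval per exonic segment,
        in exon order.
        """
        if protein_position not in self.protein_positions:
            raise UnmappedPositionError(f"protein position {protein_position} unmapped")
        off = (protein_position - self.coding_start_protein_position) * 3
        genomic = [self._exonic_offset_to_genomic(off + k) for k in range(3)]
        intervals: list[list[int]] = []
        for g in genomic:
            if intervals and intervals[-1][1] == g:
                intervals[-1][1] = g + 1
            else:
                intervals.append([g, g + 1])
        triplet = "".join(self.sequence[g] for g in genomic)
        return tuple((s, e) for s, e in intervals), triplet

    # -- amplified regions -------------------------------------------------

    def region(self, name: str) -> RegionDef:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(f"no region named {name!r}")

    def region_for_position(self, protein_position: int) -> RegionDef | None:
        for r in self.regions:
            if r.contains(protein_position):
                return r
        return None

    def _find_unique(self, needle: str, what: str) -> int:
        first = self.sequence.find(needle)
        if first < 0:
            raise PrimerSiteError(f"{what} not found in reference")
        if self.sequence.find(needle, first + 1) >= 0:
            raise PrimerSiteError(f"{what} occurs more than once in reference")
        return first

    @cached_property
    def _amplicon_intervals(self) -> dict[str, tuple[int, int]]:
        out = {}
        for region in self.regions:
            p = region.primers
            fwd = self._find_unique(p.seq_fwd, f"forward primer for {region.name!r}")
            site = p.site_rev_forward_strand
            rev = self._find_unique(site, f"reverse primer site for {region.name!r}")
            if rev < fwd + len(p.seq_fwd):
                raise PrimerSiteError(
                    f"region {region.name!r}: reverse primer site precedes forward"
                )
            out[region.name] = (fwd, rev + len(site))
        return out

    def amplicon_interval(self, region_name: str) -> tuple[int, int]:
        """Genomic interval of the full PCR product, primers included."""
        return self._amplicon_intervals[region_name]

    def insert_interval(self, region_name: str) -> tuple[int, int]:
        """Genomic interval of the primer-trimmed insert."""
        region = self.region(region_name)
        start, end = self.amplicon_interval(region_name)
        return (
            start + len(region.primers.seq_fwd),
            end - len(region.primers.seq_rev),
        )

    def _insert_span(self, region: RegionDef) -> tuple[int, int]:
        return self.insert_interval(region.name)

    def amplicon_sequence(self, region_name: str) -> str:
        s, e = self.amplicon_interval(region_name)
        return self.sequence[s:e]

    def insert_sequence(self, region_name: str) -> str:
        s, e = self.insert_interval(region_name)
        return self.sequence[s:e]

    # -- serialization -----------------------------------------------------

    def annotation_dict(self) -> dict:
        return {
            "reference_id": self.reference_id,
            "exons": [list(iv) for iv in self.exons],
            "coding_start_protein_position": self.coding_start_protein_position,
            "regions": [
                {
                    "name": r.name,
                    "primers": {
                        "name_fwd": r.primers.name_fwd,
                        "name_rev": r.primers.name_rev,
                        "seq_fwd": r.primers.seq_fwd,
                        "seq_rev": r.primers.seq_rev,
                    },
                    "protein_span": list(r.protein_span),
                }
                for r in self.regions
            ],
        }


def load_gene_model(sequence_file: str | Path, annotation) -> GeneModel:
    """Build a validated :class:`GeneModel` from a FASTA and an annotation.

    ``annotation`` may be a dict or a path to a JSON document with keys
    ``reference_id``, ``exons``, ``coding_start_protein_position`` and
    ``regions`` (each region: ``name``, ``primers``, ``protein_span``).
    """
    if not isinstance(annotation, dict):
        annotation = json.loads(Path(annotation).read_text())
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(sequence_file), "fasta")}
    ref_id = annotation["reference_id"]
    if ref_id not in records:
        raise MissingSequenceError(
            f"sequence id {ref_id!r} not present in {sequence_file}"
        )
    regions = tuple(
        RegionDef(
            name=r["name"],
            primers=PrimerPair(**r["primers"]),
            protein_span=tuple(r["protein_span"]),
        )
        for r in annotation["regions"]
    )
    return GeneModel(
        reference_id=ref_id,
        sequence=records[ref_id],
        exons=tuple(tuple(iv) for iv in annotation["exons"]),
        coding_start_protein_position=int(annotation["coding_start_protein_position"]),
        regions=regions,
    )


# -- kdr catalogue ---------------------------------------------------------

_DEFAULT_CATALOG = (
    KdrSite(989, "S", frozenset("P"), "DII-S6", True),
    KdrSite(1016, "V", frozenset("G"), "DII-S6", True),
    KdrSite(1020, "F", frozenset("S"), "DII-S6", False),
    KdrSite(1520, "T", frozenset("I"), "DIII-S6", True),
    KdrSite(1534, "F", frozenset("CL"), "DIII-S6", True),
    KdrSite(1553, "E", frozenset("G"), "DIII-S6", False),
)


def kdr_catalog() -> tuple[KdrSite, ...]:
    """The default catalogue of kdr and watch sites.

    Validated resistance alleles: S989P, V1016G, T1520I, F1534C and
    F1534L.  Watch sites with unclear resistance association: F1020S,
    E1553G.
    """
    return _DEFAULT_CATALOG


def load_kdr_catalog(path: str | Path) -> tuple[KdrSite, ...]:
    """Load a catalogue from JSON (a list of KdrSite-shaped objects)."""
    entries = json.loads(Path(path).read_text())
    sites = tuple(
        KdrSite(
            protein_position=int(e["protein_position"]),
            wild_type=e["wild_type"],
            known_mutants=frozenset(e["known_mutants"]),
            domain=e["domain"],
            validated=bool(e["validated"]),
        )
        for e in entries
    )
    positions = [s.protein_position for s in sites]
    if len(set(positions)) != len(positions):
        raise ValueError("duplicate protein positions in kdr catalogue")
    return sites


def catalog_site(
    catalog: Sequence[KdrSite], protein_position: int
) -> KdrSite | None:
    for site in catalog:
        if site.protein_position == protein_position:
            return site
    return None


def validate_catalog(model: GeneModel, catalog: Iterable[KdrSite]) -> None:
    """Check catalogue consistency against a gene model.

    Every site must fall inside its declared domain's protein span and
    the model's residue there must equal the catalogued wild type.
    """
    seen = set()
    for site in catalog:
        if site.protein_position in seen:
            raise ValueError(f"duplicate catalogue position {site.protein_position}")
        seen.add(site.protein_position)
        region = model.region(site.domain)
        if not region.contains(site.protein_position):
            raise ValueError(
                f"site {site.protein_position} outside {site.domain} span"
            )
        residue = model.residue_at(site.protein_position)
        if residue != site.wild_type:
            raise ValueError(
                f"site {site.protein_position}: model residue {residue} != "
                f"catalogue wild type {site.wild_type}"
            )
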