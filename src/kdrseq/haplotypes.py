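"""Combination haplotypes over the four canonical kdr positions.

An individual's haplotype is the residue tuple at vgsc positions
(989, 1016, 1520, 1534), defaulting to wild type (S, V, T, F) where no
substitution was called.  Eleven recurrent combinations carry the fixed
survey labels H1-H11; anything else receives a stable novel label
``N{k}:<mutations>`` in first-seen order.

The three single-mutant labels are assigned in position order
(H2 = S989P, H3 = V1016G, H4 = F1534C).  This ordering is a package
convention, configurable through a naming map, and is emitted with every
run so downstream consumers never have to guess it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from kdrseq.calling import CLASS_AMBIGUOUS, AaCall

CANONICAL_POSITIONS: tuple[int, int, int, int] = (989, 1016, 1520, 1534)
WILD_ALLELES: tuple[str, str, str, str] = ("S", "V", "T", "F")

#: fixed labels for the recurrent combinations (tuple -> label)
STANDARD_NAMES: dict[tuple[str, str, str, str], str] = {
    ("S", "V", "T", "F"): "H1",  # wild type
    ("P", "V", "T", "F"): "H2",  # S989P
    ("S", "G", "T", "F"): "H3",  # V1016G
    ("S", "V", "T", "C"): "H4",  # F1534C
    ("P", "G", "T", "F"): "H5",  # S989P/V1016G
    ("P", "V", "T", "C"): "H6",  # S989P/F1534C
    ("S", "G", "T", "C"): "H7",  # V1016G/F1534C
    ("S", "V", "I", "C"): "H8",  # T1520I/F1534C
    ("P", "G", "T", "C"): "H9",  # S989P/V1016G/F1534C
    ("P", "G", "T", "L"): "H10",  # S989P/V1016G/F1534L
    ("P", "G", "I", "C"): "H11",  # S989P/V1016G/T1520I/F1534C
}


def mutation_string(alleles: Sequence[str]) -> str:
    """Human-readable mutation list, e.g. ``S989P/V1016G`` (wild: ``wt``)."""
    parts = [
        f"{wild}{pos}{allele}"
        for pos, wild, allele in zip(CANONICAL_POSITIONS, WILD_ALLELES, alleles)
        if allele != wild
    ]
    return "/".join(parts) if parts else "wt"


@dataclass(frozen=True)
class Haplotype:
    """Allele tuple at the canonical positions plus its label."""

    alleles: tuple[str, str, str, str]
    label: str
    n_mutant_sites: int
    complete: bool = True
    reason: str = ""

    @property
    def mutations(self) -> str:
        return mutation_string(self.alleles)


class HaplotypeNamer:
    """Stable tuple -> label mapping, extensible with novel labels.

    Novel tuples are labelled ``N1:<mutations>``, ``N2:...`` in first-seen
    order, which keeps labels reproducible for a fixed input order.  The
    full map can be dumped as JSON alongside every run.
    """

    def __init__(self, names: dict[tuple[str, str, str, str], str] | None = None):
        self._names = dict(STANDARD_NAMES if names is None else names)
        labels = list(self._names.values())
        if len(set(labels)) != len(labels):
            raise ValueError("haplotype naming map is not injective")
        self._n_novel = sum(1 for v in self._names.values() if v.startswith("N"))

    @classmethod
    def from_json(cls, path: str | Path) -> "HaplotypeNamer":
        raw = json.loads(Path(path).read_text())
        return cls({tuple(key): value for key, value in raw.items()})

    def label(self, alleles: tuple[str, str, str, str]) -> str:
        if alleles not in self._names:
            self._n_novel += 1
            self._names[alleles] = f"N{self._n_novel}:{mutation_string(alleles)}"
        return self._names[alleles]

    def as_dict(self) -> dict[str, str]:
        return {"".join(k): v for k, v in self._names.items()}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2) + "\n")


def assign_haplotype(
    calls: Iterable[AaCall],
    *,
    covered: Iterable[int] | None = None,
    namer: HaplotypeNamer | None = None,
) -> Haplotype:
    """Combine one individual's calls into a labelled haplotype.

    ``covered``, when given, is the set of canonical positions whose
    codons were actually sequenced in this individual; any canonical
    position missing from it makes the haplotype ``incomplete``, as does
    an ambiguous call at a canonical position.  Alleles default to wild
    type where no call exists.
    """
    alleles = list(WILD_ALLELES)
    reason = ""
    for call in calls:
        if call.protein_position not in CANONICAL_POSITIONS:
            continue
        idx = CANONICAL_POSITIONS.index(call.protein_position)
        if call.classification == CLASS_AMBIGUOUS:
            reason = f"ambiguous call at {call.protein_position}"
            break
        alleles[idx] = call.alt_residue
    if not reason and covered is not None:
        covered_set = set(covered)
        missing = [p for p in CANONICAL_POSITIONS if p not in covered_set]
        if missing:
            reason = "uncovered canonical position(s) " + ",".join(map(str, missing))
    tup = tuple(alleles)
    if reason:
        return Haplotype(
            alleles=tup, label="incomplete", n_mutant_sites=0,
            complete=False, reason=reason,
        )
    label = (namer or HaplotypeNamer()).label(tup)
    n_mut = sum(1 for a, w in zip(tup, WILD_ALLELES) if a != w)
    return Haplotype(alleles=tup, label=label, n_mutant_sites=n_mut)
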