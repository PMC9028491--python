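"""Bundled synthetic vgsc reference (stand-in for the real gene).

This module constructs, deterministically and in memory, a synthetic
*Aedes aegypti* vgsc gene model covering protein positions 950-1600.  It
is NOT the real GenBank reference sequence: only the features the
pipeline depends on are reproduced faithfully --

* the published primer pairs delimit two amplicons, DII-S6 and DIII-S6;
* the wild-type residues at every catalogued and surveyed site
  (S989, V1016, F1020, ..., T1520, F1534, E1553, ...) match the field's
  reference numbering;
* the DIII-S6 amplicon spans an exon/intron junction: the forward primer
  AaNavEx31P is anchored on the last bases of an exon and reads into a
  GT..AG intron, and one codon (1510) is split by that intron (phase 1);
* everything else (unconstrained residues, intron filler, flanks) is
  filled from a fixed-seed random stream, so the model is byte-stable.

Users with the real reference can supply it at runtime through
:func:`kdrseq.reference.load_gene_model`.
"""

from __future__ import annotations

from functools import lru_cache
from pathlib import Path

import json

import numpy as np

from kdrseq.reference import (
    CODONS_BY_AA,
    GeneModel,
    PrimerPair,
    RegionDef,
    kdr_catalog,
)

REFERENCE_ID = "vgsc_synthetic"

PRIMERS_DII = PrimerPair(
    name_fwd="AaNavF20",
    name_rev="AaNavR21",
    seq_fwd="ACAATGTGGATCGCTTCCC",
    seq_rev="TGGACAAAAGCAAGGCTAAG",
)
PRIMERS_DIII = PrimerPair(
    name_fwd="AaNavEx31P",
    name_rev="AaNavEx31Q",
    seq_fwd="TCGCGGGAGGTAAGTTATTG",
    seq_rev="GTTGATGTGCGATGGAAATG",
)

_FIRST_POSITION = 950
_LAST_POSITION = 1600

#: wild-type residues that the synthetic model must carry, i.e. every
#: site at which the surveillance pipeline may report a substitution
_WILD_RESIDUES = {
    # DII-S6 region
    960: "D", 966: "W", 967: "N", 972: "M", 977: "I", 985: "E", 987: "I",
    989: "S", 991: "W", 992: "D", 994: "M", 998: "D", 1003: "P", 1004: "F",
    1016: "V", 1020: "F",
    # DIII-S6 region
    1512: "V", 1514: "K", 1520: "T", 1524: "M", 1526: "L", 1527: "Y",
    1528: "F", 1533: "I", 1534: "F", 1543: "F", 1544: "I", 1548: "I",
    1553: "E", 1581: "G", 1584: "K",
}

#: codons pinned by the primer binding sites and the intron junction
_FIXED_CODONS = {
    # AaNavF20 = first 19 nt of exon 1 (codons 950-955 + first base of 956)
    950: "ACA", 951: "ATG", 952: "TGG", 953: "ATC", 954: "GCT", 955: "TCC",
    956: "CTG",
    # AaNavR21 binding site on the forward strand, codon-aligned at 1025
    1025: "CTT", 1026: "AGC", 1027: "CTT", 1028: "GCT", 1029: "TTT",
    1030: "GTC", 1031: "CAG",
    # AaNavEx31P exonic anchor: exon 1 ends ...TCGCGGGA|G with the final G
    # being base 1 of split codon 1510
    1507: "ATC", 1508: "GCG", 1509: "GGA", 1510: "GTA",
    # AaNavEx31Q binding site, codon-aligned at 1588
    1588: "CAT", 1589: "TTC", 1590: "CAT", 1591: "CGC", 1592: "ACA",
    1593: "TCA", 1594: "ACA",
}

_FLANK = 25
_INTRON_FILLER = 48
_BUILD_SEED = 747529  # fixed forever; the model must be byte-stable


def _preferred_codon(aa: str) -> str:
    return CODONS_BY_AA[aa][0]


@lru_cache(maxsize=1)
def bundled_gene_model() -> GeneModel:
    """Build (once) and return the bundled synthetic gene model."""
    rng = np.random.default_rng(_BUILD_SEED)
    residues = sorted(CODONS_BY_AA)  # 20 amino acids

    codons = []
    for pos in range(_FIRST_POSITION, _LAST_POSITION + 1):
        if pos in _FIXED_CODONS:
            codons.append(_FIXED_CODONS[pos])
            continue
        aa = _WILD_RESIDUES.get(pos)
        if aa is None:
            aa = residues[int(rng.integers(len(residues)))]
        codons.append(_preferred_codon(aa))
    cds = "".join(codons)

    def random_bases(n: int) -> str:
        return "".join("ACGT"[int(i)] for i in rng.integers(4, size=n))

    # exon 1 carries codons 950..1509 plus the first base of codon 1510
    exon1 = cds[: (1510 - _FIRST_POSITION) * 3 + 1]
    exon2 = cds[len(exon1):]
    intron = "GTAAGTTATTG" + random_bases(_INTRON_FILLER) + "AG"
    flank5 = random_bases(_FLANK)
    flank3 = random_bases(_FLANK)

    sequence = flank5 + exon1 + intron + exon2 + flank3
    e1_start = len(flank5)
    e1_end = e1_start + len(exon1)
    e2_start = e1_end + len(intron)
    e2_end = e2_start + len(exon2)

    model = GeneModel(
        reference_id=REFERENCE_ID,
        sequence=sequence,
        exons=((e1_start, e1_end), (e2_start, e2_end)),
        coding_start_protein_position=_FIRST_POSITION,
        regions=(
            RegionDef("DII-S6", PRIMERS_DII, (957, 1024)),
            RegionDef("DIII-S6", PRIMERS_DIII, (1511, 1587)),
        ),
    )
    return model


def write_bundled_reference(out_dir: str | Path) -> dict[str, Path]:
    """Write the bundled model as FASTA + annotation JSON + catalogue JSON.

    Returns the paths written, keyed ``fasta``/``annotation``/``catalog``.
    The FASTA is wrapped at 70 columns.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = bundled_gene_model()

    fasta = out / f"{REFERENCE_ID}.fasta"
    lines = [f">{model.reference_id} synthetic vgsc reference (not the real gene)"]
    seq = model.sequence
    lines += [seq[i : i + 70] for i in range(0, len(seq), 70)]
    fasta.write_text("\n".join(lines) + "\n")

    annotation = out / f"{REFERENCE_ID}.annotation.json"
    annotation.write_text(json.dumps(model.annotation_dict(), indent=2) + "\n")

    catalog = out / "kdr_catalog.json"
    entries = [
        {
            "protein_position": s.protein_position,
            "wild_type": s.wild_type,
            "known_mutants": sorted(s.known_mutants),
            "domain": s.domain,
            "validated": s.validated,
        }
        for s in kdr_catalog()
    ]
    catalog.write_text(json.dumps(entries, indent=2) + "\n")

    return {"fasta": fasta, "annotation": annotation, "catalog": catalog}
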