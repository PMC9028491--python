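"""Minimal VCF 4.2 export of the nucleotide substitutions behind AA calls.

One record per distinct single-nucleotide substitution against the
reference, with the protein-level consequence and the number of carrier
individuals in INFO.  Ambiguous calls (IUPAC codons) are skipped: they
have no single nucleotide ALT.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from kdrseq.calling import CLASS_AMBIGUOUS, AaCall
from kdrseq.reference import GeneModel

_HEADER = """\
##fileformat=VCFv4.2
##source=kdrseq
##INFO=<ID=PROT,Number=1,Type=String,Description="Protein-level substitution label">
##INFO=<ID=CLASS,Number=1,Type=String,Description="kdr classification of the call">
##INFO=<ID=NCARRIER,Number=1,Type=Integer,Description="Number of carrier individuals">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(path: str | Path, model: GeneModel, calls: Iterable[AaCall]) -> None:
    variants: dict[tuple[int, str, str], dict] = {}
    for call in calls:
        if call.classification == CLASS_AMBIGUOUS:
            continue
        intervals, ref_codon = model.codon_for_position(call.protein_position)
        genomic = [g for s, e in intervals for g in range(s, e)]
        for g, ref_base, obs_base in zip(genomic, ref_codon, call.obs_codon):
            if ref_base == obs_base:
                continue
            key = (g, ref_base, obs_base)
            entry = variants.setdefault(
                key,
                {"prot": call.label, "class": call.classification, "carriers": set()},
            )
            entry["carriers"].add(call.individual_id)
    with open(path, "w") as fh:
        fh.write(_HEADER)
        for (g, ref_base, obs_base), entry in sorted(variants.items()):
            info = (
                f"PROT={entry['prot']};CLASS={entry['class']};"
                f"NCARRIER={len(entry['carriers'])}"
            )
            fh.write(
                f"{model.reference_id}\t{g + 1}\t.\t{ref_base}\t{obs_base}\t.\t.\t{info}\n"
            )
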