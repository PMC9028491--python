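"""Synthetic cohort generator: clone-level amplicon FASTA with planted truth.

Emulates the survey's sampling design so every downstream stage is
testable without external data: each mosquito yields two PCR amplicons
(DII-S6 and DIII-S6), each sequenced as 2-3 plasmid clones; a declared
number of individuals fail amplification in one or both regions; planted
haplotypes and extra mutations are realized as minimal-nucleotide-edit
codon substitutions; clone reads carry i.i.d. per-base substitution
noise, random flanking context outside the primers, and a random strand.

Identical inputs (model, catalogue, spec -- including the seed) produce
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from kdrseq.haplotypes import CANONICAL_POSITIONS, WILD_ALLELES, mutation_string
from kdrseq.reference import (
    AMINO_ACIDS,
    CODONS_BY_AA,
    GeneModel,
    KdrSite,
)


class SpecificationError(ValueError):
    """The cohort specification is internally inconsistent or unrealizable."""


@dataclass(frozen=True)
class IndividualGroup:
    """``count`` individuals sharing a planted haplotype and extras."""

    haplotype: tuple[str, str, str, str] = WILD_ALLELES
    extra_mutations: tuple[tuple[int, str], ...] = ()
    count: int = 1

    def __post_init__(self):
        if self.count < 0:
            raise SpecificationError("group count must be >= 0")
        if len(self.haplotype) != 4:
            raise SpecificationError("haplotype must have 4 alleles")


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    groups: tuple[IndividualGroup, ...]

    @property
    def n_individuals(self) -> int:
        return sum(g.count for g in self.groups)


@dataclass(frozen=True)
class Dropout:
    """Amplification failures: individuals losing both or one region."""

    both_fail: int = 0
    one_fail: int = 0


@dataclass(frozen=True)
class CohortSpec:
    """Declarative description of a synthetic cohort.

    Defaults mirror the survey design: three clones per individual per
    region, noise-free reads (Sanger clones verified bidirectionally),
    30 nt of flanking context, no dropout.
    """

    populations: tuple[PopulationSpec, ...]
    clones_per_individual: int = 3
    noise_rate: float = 0.0
    dropout: Dropout = Dropout()
    flank_padding: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.clones_per_individual < 1:
            raise SpecificationError("clones_per_individual must be >= 1")
        if not 0.0 <= self.noise_rate < 1.0:
            raise SpecificationError("noise_rate must be in [0, 1)")
        if self.flank_padding < 0:
            raise SpecificationError("flank_padding must be >= 0")
        n = self.n_individuals
        if self.dropout.both_fail + self.dropout.one_fail > n:
            raise SpecificationError("dropout counts exceed cohort size")

    @property
    def n_individuals(self) -> int:
        return sum(p.n_individuals for p in self.populations)

    def with_seed(self, seed: int) -> "CohortSpec":
        return replace(self, seed=seed)

    # -- JSON round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "populations": [
                {
                    "name": p.name,
                    "individuals": [
                        {
                            "haplotype": list(g.haplotype),
                            "extra_mutations": [list(m) for m in g.extra_mutations],
                            "count": g.count,
                        }
                        for g in p.groups
                    ],
                }
                for p in self.populations
            ],
            "clones_per_individual": self.clones_per_individual,
            "noise_rate": self.noise_rate,
            "dropout": {"both_fail": self.dropout.both_fail,
                        "one_fail": self.dropout.one_fail},
            "flank_padding": self.flank_padding,
            "seed": self.seed,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        pops = tuple(
            PopulationSpec(
                name=p["name"],
                groups=tuple(
                    IndividualGroup(
                        haplotype=tuple(g.get("haplotype", WILD_ALLELES)),
                        extra_mutations=tuple(
                            (int(pos), alt) for pos, alt in g.get("extra_mutations", [])
                        ),
                        count=int(g.get("count", 1)),
                    )
                    for g in p["individuals"]
                ),
            )
            for p in d["populations"]
        )
        dropout = d.get("dropout", {})
        return cls(
            populations=pops,
            clones_per_individual=int(d.get("clones_per_individual", 3)),
            noise_rate=float(d.get("noise_rate", 0.0)),
            dropout=Dropout(
                both_fail=int(dropout.get("both_fail", 0)),
                one_fail=int(dropout.get("one_fail", 0)),
            ),
            flank_padding=int(d.get("flank_padding", 30)),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


def plant_codon(ref_codon: str, alt_residue: str) -> str:
    """Codon encoding ``alt_residue`` with the fewest edits to ``ref_codon``.

    Ties are broken by the lexicographically smallest codon, making the
    planted nucleotide sequence deterministic.
    """
    if alt_residue not in AMINO_ACIDS:
        raise SpecificationError(f"no codon encodes residue {alt_residue!r}")
    candidates = CODONS_BY_AA[alt_residue]
    return min(
        candidates,
        key=lambda c: (sum(a != b for a, b in zip(c, ref_codon)), c),
    )


@dataclass
class SimulatedCohort:
    """In-memory result of a simulation, writable as FASTA + TSV files."""

    records: dict[str, list[SeqRecord]]
    manifest: pd.DataFrame
    truth: pd.DataFrame
    spec: CohortSpec

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for region in sorted(self.records):
            path = out / f"{region}.fasta"
            with open(path, "w") as fh:
                SeqIO.write(self.records[region], fh, "fasta")
            paths[f"fasta:{region}"] = path
        manifest_path = out / "manifest.tsv"
        self.manifest.to_csv(manifest_path, sep="\t", index=False)
        paths["manifest"] = manifest_path
        truth_path = out / "truth.tsv"
        self.truth.to_csv(truth_path, sep="\t", index=False)
        paths["truth"] = truth_path
        spec_path = out / "cohort_spec.json"
        self.spec.to_json(spec_path)
        paths["spec"] = spec_path
        return paths


def _mutated_amplicon(
    model: GeneModel,
    region_name: str,
    mutations: Sequence[tuple[int, str]],
) -> str:
    amp_start, amp_end = model.amplicon_interval(region_name)
    seq = list(model.sequence[amp_start:amp_end])
    region = model.region(region_name)
    for pos, alt in mutations:
        if not region.contains(pos):
            continue
        intervals, ref_codon = model.codon_for_position(pos)
        new_codon = plant_codon(ref_codon, alt)
        k = 0
        for s, e in intervals:
            for g in range(s, e):
                off = g - amp_start
                if not 0 <= off < len(seq):
                    raise SpecificationError(
                        f"codon for position {pos} lies outside amplicon "
                        f"{region_name!r}"
                    )
                seq[off] = new_codon[k]
                k += 1
    return "".join(seq)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _add_noise(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return arr.tobytes().decode("ascii")


def _random_bases(n: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[int(i)] for i in rng.integers(4, size=n))


def simulate_cohort(
    model: GeneModel,
    catalog: Sequence[KdrSite],
    spec: CohortSpec,
    out_dir: str | Path | None = None,
) -> SimulatedCohort:
    """Generate clone-level FASTA records, a manifest and a truth table.

    Every planted mutation position must be inside one region's protein
    span (``SpecificationError`` otherwise).  Non-dropout individuals get
    ``clones_per_individual`` records per region; ``one_fail`` individuals
    lack one (randomly chosen) region and ``both_fail`` individuals both.
    """
    region_names = [r.name for r in model.regions]
    spanned = {
        pos
        for r in model.regions
        for pos in range(r.protein_span[0], r.protein_span[1] + 1)
    }

    # enumerate individuals in spec order
    individuals: list[dict] = []
    for pop in spec.populations:
        idx = 0
        for group in pop.groups:
            planted = [
                (pos, alt)
                for pos, wild, alt in zip(
                    CANONICAL_POSITIONS, WILD_ALLELES, group.haplotype
                )
                if alt != wild
            ] + list(group.extra_mutations)
            for pos, alt in planted:
                if pos not in spanned:
                    raise SpecificationError(
                        f"planted position {pos} is outside every amplified region"
                    )
                if alt not in AMINO_ACIDS:
                    raise SpecificationError(f"unknown residue {alt!r} at {pos}")
            for _ in range(group.count):
                idx += 1
                individuals.append(
                    {
                        "individual_id": f"{pop.name}-{idx:04d}",
                        "population": pop.name,
                        "haplotype": group.haplotype,
                        "extras": tuple(group.extra_mutations),
                        "mutations": tuple(planted),
                    }
                )

    rng = np.random.default_rng(spec.seed)

    # dropout assignment
    n = len(individuals)
    dropped_regions: dict[int, tuple[str, ...]] = {}
    n_drop = spec.dropout.both_fail + spec.dropout.one_fail
    if n_drop:
        chosen = rng.choice(n, size=n_drop, replace=False)
        for j, ind_idx in enumerate(chosen):
            if j < spec.dropout.both_fail:
                dropped_regions[int(ind_idx)] = tuple(region_names)
            else:
                lost = region_names[int(rng.integers(len(region_names)))]
                dropped_regions[int(ind_idx)] = (lost,)

    template_cache: dict[tuple[str, tuple], str] = {}
    records: dict[str, list[SeqRecord]] = {name: [] for name in region_names}
    manifest_rows = []
    truth_rows = []
    for i, ind in enumerate(individuals):
        lost = dropped_regions.get(i, ())
        for region_name in region_names:
            if region_name in lost:
                continue
            key = (region_name, ind["mutations"])
            if key not in template_cache:
                template_cache[key] = _mutated_amplicon(
                    model, region_name, ind["mutations"]
                )
            template = template_cache[key]
            for k in range(1, spec.clones_per_individual + 1):
                flank5 = _random_bases(spec.flank_padding, rng)
                flank3 = _random_bases(spec.flank_padding, rng)
                read = _add_noise(flank5 + template + flank3, spec.noise_rate, rng)
                if rng.random() < 0.5:
                    read = str(Seq(read).reverse_complement())
                record_id = f"{ind['individual_id']}|{region_name}|clone{k}"
                records[region_name].append(
                    SeqRecord(Seq(read), id=record_id, description="")
                )
                manifest_rows.append(
                    {
                        "individual_id": ind["individual_id"],
                        "population": ind["population"],
                        "region": region_name,
                        "record_id": record_id,
                    }
                )
        if not lost:
            dropout_status = "none"
        elif len(lost) == len(region_names):
            dropout_status = "both_fail"
        else:
            dropout_status = f"one_fail:{lost[0]}"
        truth_rows.append(
            {
                "individual_id": ind["individual_id"],
                "population": ind["population"],
                "allele_989": ind["haplotype"][0],
                "allele_1016": ind["haplotype"][1],
                "allele_1520": ind["haplotype"][2],
                "allele_1534": ind["haplotype"][3],
                "haplotype_mutations": mutation_string(ind["haplotype"]),
                "extra_mutations": ";".join(
                    f"{model.residue_at(pos)}{pos}{alt}" for pos, alt in ind["extras"]
                ),
                "dropout": dropout_status,
            }
        )

    manifest_cols = ["individual_id", "population", "region", "record_id"]
    truth_cols = [
        "individual_id", "population", "allele_989", "allele_1016",
        "allele_1520", "allele_1534", "haplotype_mutations",
        "extra_mutations", "dropout",
    ]
    cohort = SimulatedCohort(
        records=records,
        manifest=pd.DataFrame(manifest_rows, columns=manifest_cols),
        truth=pd.DataFrame(truth_rows, columns=truth_cols),
        spec=spec,
    )
    if out_dir is not None:
        cohort.write(out_dir)
    return cohort
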