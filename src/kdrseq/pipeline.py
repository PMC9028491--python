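"""End-to-end pipeline: extract -> consensus -> align -> call -> haplotype
-> filter -> frequency tables.

:func:`run_pipeline` drives every stage from one configuration object,
starting either from a cohort simulation or from existing FASTA files
plus a manifest, and writes all tabular outputs plus a JSON run log.
Identical configuration (seed included) yields identical output bytes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import pandas as pd

from Bio import SeqIO

import kdrseq
from kdrseq.align import Scoring
from kdrseq.amplicon import (
    AmbiguousAmpliconError,
    consensus_from_clones,
    extract_amplicon,
)
from kdrseq.calling import AaCall, CallSet, align_to_reference, call_substitutions
from kdrseq.cohort import CohortSpec, SimulatedCohort, simulate_cohort
from kdrseq.haplotypes import Haplotype, HaplotypeNamer, assign_haplotype
from kdrseq.reference import GeneModel, kdr_catalog, load_gene_model, load_kdr_catalog, validate_catalog
from kdrseq.report import (
    FrequencyTable,
    SampleStatus,
    filter_paired_samples,
    haplotype_frequency_table,
    mutation_frequency_table,
    population_shares,
)
from kdrseq.vcf import write_vcf


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending record."""


@dataclass(frozen=True)
class PipelineParams:
    max_primer_mismatch: int = 2
    identity_floor: float = 0.8
    consensus_policy: str = "majority"
    scoring: Scoring = Scoring()
    write_vcf: bool = True


@dataclass
class PipelineConfig:
    """What to run on and how.

    Exactly one of ``simulate`` (a :class:`CohortSpec`) or
    ``fasta``+``manifest`` (paths of real/pre-simulated data) must be
    given.  ``reference`` is ``None`` for the bundled synthetic model or
    a ``{"fasta": ..., "annotation": ...}`` pair; ``catalog`` is ``None``
    for the default kdr catalogue or a JSON path.
    """

    simulate: CohortSpec | None = None
    fasta: dict[str, str] | None = None
    manifest: str | None = None
    reference: dict[str, str] | None = None
    catalog: str | None = None
    params: PipelineParams = field(default_factory=PipelineParams)
    seed: int | None = None
    out_dir: str | None = None

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        params_raw = raw.get("params", {})
        scoring = Scoring(**params_raw.pop("scoring", {}))
        params = PipelineParams(scoring=scoring, **params_raw)
        simulate = None
        if "simulate" in raw:
            simulate = CohortSpec.from_dict(raw["simulate"])
        return cls(
            simulate=simulate,
            fasta=raw.get("fasta"),
            manifest=raw.get("manifest"),
            reference=raw.get("reference"),
            catalog=raw.get("catalog"),
            params=params,
            seed=raw.get("seed"),
            out_dir=raw.get("out_dir"),
        )


@dataclass
class PipelineResult:
    model: GeneModel
    statuses: list[SampleStatus]
    retained: list[SampleStatus]
    exclusions: pd.DataFrame
    extraction_report: pd.DataFrame
    calls: list[AaCall]
    call_sets: dict[tuple[str, str], CallSet]
    haplotypes: dict[str, Haplotype]
    namer: HaplotypeNamer
    mutation_table: FrequencyTable
    haplotype_table: FrequencyTable
    shares: pd.DataFrame
    cohort: SimulatedCohort | None = None
    paths: dict[str, Path] = field(default_factory=dict)

    @property
    def calls_frame(self) -> pd.DataFrame:
        rows = [
            {
                "individual_id": c.individual_id,
                "population": next(
                    (s.population for s in self.statuses
                     if s.individual_id == c.individual_id), ""),
                "region": c.region,
                "protein_position": c.protein_position,
                "label": c.label,
                "classification": c.classification,
                "ref_codon": c.ref_codon,
                "obs_codon": c.obs_codon,
            }
            for c in self.calls
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "individual_id", "population", "region", "protein_position",
                "label", "classification", "ref_codon", "obs_codon",
            ],
        )

    @property
    def haplotypes_frame(self) -> pd.DataFrame:
        pop = {s.individual_id: s.population for s in self.statuses}
        rows = [
            {
                "individual_id": ind,
                "population": pop.get(ind, ""),
                "allele_989": h.alleles[0],
                "allele_1016": h.alleles[1],
                "allele_1520": h.alleles[2],
                "allele_1534": h.alleles[3],
                "label": h.label if h.complete else "incomplete",
                "reason": h.reason,
            }
            for ind, h in self.haplotypes.items()
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "individual_id", "population", "allele_989", "allele_1016",
                "allele_1520", "allele_1534", "label", "reason",
            ],
        )


def _load_model_and_catalog(config: PipelineConfig):
    if config.reference is None:
        model = kdrseq.bundled_gene_model()
    else:
        model = load_gene_model(
            config.reference["fasta"], config.reference["annotation"]
        )
    catalog = (
        kdr_catalog() if config.catalog is None else load_kdr_catalog(config.catalog)
    )
    validate_catalog(model, catalog)
    return model, catalog


def _read_records(config: PipelineConfig, model: GeneModel):
    records: dict[str, dict[str, str]] = {}  # region -> record_id -> seq
    for region in (r.name for r in model.regions):
        records[region] = {}
        path = (config.fasta or {}).get(region)
        if path is None:
            continue
        for rec in SeqIO.parse(str(path), "fasta"):
            records[region][rec.id] = str(rec.seq).upper()
    manifest = pd.read_csv(config.manifest, sep="\t", dtype=str)
    return records, manifest


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages and (optionally) write outputs to ``out_dir``."""
    model, catalog = _load_model_and_catalog(config)
    params = config.params
    region_names = [r.name for r in model.regions]

    cohort = None
    if config.simulate is not None:
        spec = config.simulate
        if config.seed is not None:
            spec = spec.with_seed(config.seed)
        cohort = simulate_cohort(model, catalog, spec)
        records = {
            region: {rec.id: str(rec.seq) for rec in recs}
            for region, recs in cohort.records.items()
        }
        manifest = cohort.manifest
    elif config.fasta is not None and config.manifest is not None:
        records, manifest = _read_records(config, model)
    else:
        raise PipelineError("config: provide either 'simulate' or 'fasta'+'manifest'")

    # ---- cohort roster ---------------------------------------------------
    # Individuals whose amplification failed in both regions yield no
    # records at all, so the roster cannot come from the manifest alone:
    # the simulator's truth table (or manifest rows with an empty
    # record_id, for real data) supplies them.
    populations: dict[str, str] = {}
    individual_order: list[str] = []

    def register(ind: str, pop: str) -> None:
        if ind not in populations:
            populations[ind] = pop
            individual_order.append(ind)

    if cohort is not None:
        for row in cohort.truth.itertuples(index=False):
            register(row.individual_id, row.population)

    # ---- in-silico PCR per clone record ---------------------------------
    extraction_rows = []
    inserts: dict[tuple[str, str], list[str]] = {}
    for row in manifest.itertuples(index=False):
        ind, pop, region, record_id = (
            row.individual_id, row.population, row.region, row.record_id,
        )
        register(ind, pop)
        if record_id is None or (isinstance(record_id, float)) or record_id == "":
            continue  # collected individual without a sequenced record
        seq = records.get(region, {}).get(record_id)
        if seq is None:
            raise PipelineError(
                f"extract: record {record_id!r} listed in manifest but absent "
                f"from the {region} FASTA"
            )
        pair = model.region(region).primers
        try:
            hit = extract_amplicon(
                seq, pair, params.max_primer_mismatch,
                record_id=record_id, region=region,
            )
        except AmbiguousAmpliconError as exc:
            extraction_rows.append(
                {"record_id": record_id, "region": region, "strand": "",
                 "mismatches_fwd": "", "mismatches_rev": "",
                 "status": f"ambiguous: {exc}"}
            )
            continue
        if hit is None:
            extraction_rows.append(
                {"record_id": record_id, "region": region, "strand": "",
                 "mismatches_fwd": "", "mismatches_rev": "", "status": "not_found"}
            )
            continue
        extraction_rows.append(
            {"record_id": record_id, "region": region, "strand": hit.strand,
             "mismatches_fwd": hit.mismatches_fwd,
             "mismatches_rev": hit.mismatches_rev, "status": "ok"}
        )
        inserts.setdefault((ind, region), []).append(hit.insert)
    extraction_report = pd.DataFrame(
        extraction_rows,
        columns=["record_id", "region", "strand", "mismatches_fwd",
                 "mismatches_rev", "status"],
    )

    # ---- consensus, alignment, calling ----------------------------------
    call_sets: dict[tuple[str, str], CallSet] = {}
    consensus_records = []
    region_present: dict[str, dict[str, bool]] = {r: {} for r in region_names}
    for ind in individual_order:
        for region in region_names:
            clones = inserts.get((ind, region))
            if not clones:
                region_present[region][ind] = False
                continue
            consensus = consensus_from_clones(
                clones, policy=params.consensus_policy, scoring=params.scoring
            ).with_ids(ind, region)
            consensus_records.append(consensus)
            ra = align_to_reference(
                consensus.sequence, model, region,
                scoring=params.scoring, identity_floor=params.identity_floor,
            )
            if ra.unalignable:
                region_present[region][ind] = False
                continue
            region_present[region][ind] = True
            call_sets[(ind, region)] = call_substitutions(
                ra, model, catalog, individual_id=ind
            )

    statuses = [
        SampleStatus(
            individual_id=ind,
            population=populations[ind],
            dii_present=region_present[region_names[0]].get(ind, False),
            diii_present=region_present[region_names[1]].get(ind, False),
        )
        for ind in individual_order
    ]
    retained, exclusions = filter_paired_samples(statuses)
    retained_ids = {s.individual_id for s in retained}

    calls = [
        c
        for (ind, _), cs in call_sets.items()
        if ind in retained_ids
        for c in cs.calls
    ]

    namer = HaplotypeNamer()
    haplotypes: dict[str, Haplotype] = {}
    for ind in individual_order:
        if ind not in retained_ids:
            continue
        ind_calls = []
        covered: set[int] = set()
        for region in region_names:
            cs = call_sets.get((ind, region))
            if cs is not None:
                ind_calls.extend(cs.calls)
                covered.update(cs.covered_positions)
        haplotypes[ind] = assign_haplotype(ind_calls, covered=covered, namer=namer)

    mutation_table = mutation_frequency_table(calls, retained)
    haplotype_table = haplotype_frequency_table(haplotypes, retained)
    shares = population_shares(retained)

    result = PipelineResult(
        model=model,
        statuses=statuses,
        retained=retained,
        exclusions=exclusions,
        extraction_report=extraction_report,
        calls=calls,
        call_sets=call_sets,
        haplotypes=haplotypes,
        namer=namer,
        mutation_table=mutation_table,
        haplotype_table=haplotype_table,
        shares=shares,
        cohort=cohort,
    )

    if config.out_dir is not None:
        result.paths = _write_outputs(result, config, consensus_records)
    return result


def _write_outputs(result: PipelineResult, config: PipelineConfig, consensus_records):
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    if result.cohort is not None:
        paths.update(result.cohort.write(out / "cohort"))

    status_rows = pd.DataFrame(
        [
            {
                "individual_id": s.individual_id,
                "population": s.population,
                "DII-S6": s.dii_present,
                "DIII-S6": s.diii_present,
                "retained": s.retained,
            }
            for s in result.statuses
        ],
        columns=["individual_id", "population", "DII-S6", "DIII-S6", "retained"],
    )

    def write_df(name: str, df: pd.DataFrame, index: bool = False):
        path = out / name
        df.to_csv(path, sep="\t", index=index)
        paths[name] = path

    write_df("sample_status.tsv", status_rows)
    write_df("exclusions.tsv", result.exclusions)
    write_df("extraction_report.tsv", result.extraction_report)
    write_df("calls.tsv", result.calls_frame)
    write_df("haplotypes.tsv", result.haplotypes_frame)
    write_df("population_shares.tsv", result.shares)

    path = out / "consensus.fasta"
    with open(path, "w") as fh:
        for cons in consensus_records:
            fh.write(f">{cons.individual_id}|{cons.region} "
                     f"n_clones={cons.n_clones}\n{cons.sequence}\n")
    paths["consensus.fasta"] = path

    result.mutation_table.to_tsv(out / "mutation_frequencies.tsv", label="mutation")
    paths["mutation_frequencies.tsv"] = out / "mutation_frequencies.tsv"
    result.haplotype_table.to_tsv(out / "haplotype_frequencies.tsv", label="haplotype")
    paths["haplotype_frequencies.tsv"] = out / "haplotype_frequencies.tsv"
    result.namer.to_json(out / "haplotype_naming.json")
    paths["haplotype_naming.json"] = out / "haplotype_naming.json"

    if config.params.write_vcf:
        vcf_path = out / "calls.vcf"
        write_vcf(vcf_path, result.model, result.calls)
        paths["calls.vcf"] = vcf_path

    import numpy
    import Bio

    log = {
        "package": "kdrseq",
        "version": kdrseq.__version__,
        "dependency_versions": {
            "numpy": numpy.__version__,
            "pandas": pd.__version__,
            "biopython": Bio.__version__,
        },
        "seed": config.seed if config.seed is not None else (
            config.simulate.seed if config.simulate is not None else None
        ),
        "params": {
            "max_primer_mismatch": config.params.max_primer_mismatch,
            "identity_floor": config.params.identity_floor,
            "consensus_policy": config.params.consensus_policy,
            "scoring": {
                "match": config.params.scoring.match,
                "mismatch": config.params.scoring.mismatch,
                "gap_open": config.params.scoring.gap_open,
                "gap_extend": config.params.scoring.gap_extend,
            },
        },
        "n_individuals": len(result.statuses),
        "n_retained": len(result.retained),
    }
    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2) + "\n")
    paths["run_log.json"] = log_path
    return paths
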