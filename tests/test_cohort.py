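"""Synthetic cohort generator: determinism, dropout, noise, round trips."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from Bio.Seq import Seq

from kdrseq.cohort import (
    CohortSpec,
    Dropout,
    IndividualGroup,
    PopulationSpec,
    SpecificationError,
    simulate_cohort,
)
from kdrseq.pipeline import PipelineConfig, run_pipeline


def _spec(groups, seed=0, **kwargs):
    return CohortSpec(
        populations=(PopulationSpec(name="pop", groups=tuple(groups)),),
        seed=seed,
        **kwargs,
    )


def _read_bytes(directory):
    return {
        p.name: p.read_bytes() for p in sorted(directory.iterdir()) if p.is_file()
    }


def test_zero_individual_spec_gives_empty_outputs(model, catalog):
    cohort = simulate_cohort(model, catalog, _spec([IndividualGroup(count=0)]))
    assert all(not recs for recs in cohort.records.values())
    assert cohort.truth.empty
    assert cohort.manifest.empty


def test_identical_spec_gives_byte_identical_files(tmp_path, model, catalog):
    spec = _spec([IndividualGroup(haplotype=("P", "G", "T", "C"), count=3)], seed=11)
    simulate_cohort(model, catalog, spec, out_dir=tmp_path / "a")
    simulate_cohort(model, catalog, spec, out_dir=tmp_path / "b")
    assert _read_bytes(tmp_path / "a") == _read_bytes(tmp_path / "b")


def test_different_seeds_give_different_reads(model, catalog):
    mk = lambda seed: simulate_cohort(
        model, catalog, _spec([IndividualGroup(count=2)], seed=seed)
    )
    a, b = mk(1), mk(2)
    seqs_a = [str(r.seq) for r in a.records["DII-S6"]]
    seqs_b = [str(r.seq) for r in b.records["DII-S6"]]
    assert seqs_a != seqs_b


@given(
    n=st.integers(min_value=0, max_value=12),
    both=st.integers(min_value=0, max_value=4),
    one=st.integers(min_value=0, max_value=4),
)
def test_dropout_arithmetic(model, catalog, n, both, one):
    if both + one > n:
        with pytest.raises(SpecificationError):
            _spec([IndividualGroup(count=n)], dropout=Dropout(both, one))
        return
    spec = _spec([IndividualGroup(count=n)], dropout=Dropout(both, one), seed=5)
    cohort = simulate_cohort(model, catalog, spec)
    counts = cohort.truth["dropout"].value_counts().to_dict()
    assert counts.get("both_fail", 0) == both
    assert sum(v for k, v in counts.items() if k.startswith("one_fail")) == one
    # both-region individuals have clones_per_individual records per region
    ok_ids = set(cohort.truth.loc[cohort.truth.dropout == "none", "individual_id"])
    per_region = cohort.manifest.groupby(["individual_id", "region"]).size()
    for ind in ok_ids:
        for region in ("DII-S6", "DIII-S6"):
            assert per_region.get((ind, region), 0) == spec.clones_per_individual


def test_noise_rate_matches_observed_substitution_rate(model, catalog):
    spec = _spec(
        [IndividualGroup(count=1)],
        clones_per_individual=150,
        noise_rate=0.01,
        flank_padding=0,
        seed=3,
    )
    cohort = simulate_cohort(model, catalog, spec)
    mismatches = total = 0
    for region in ("DII-S6", "DIII-S6"):
        template = model.amplicon_sequence(region)
        rc = str(Seq(template).reverse_complement())
        for rec in cohort.records[region]:
            read = str(rec.seq)
            diff = min(
                sum(a != b for a, b in zip(read, template)),
                sum(a != b for a, b in zip(read, rc)),
            )
            mismatches += diff
            total += len(read)
    observed = mismatches / total
    # binomial 99.9% band around p=0.01 at n~85k
    assert 0.008 < observed < 0.012


def test_both_strands_are_emitted(model, catalog):
    spec = _spec([IndividualGroup(count=1)], clones_per_individual=40,
                 flank_padding=0, seed=4)
    cohort = simulate_cohort(model, catalog, spec)
    template = model.amplicon_sequence("DII-S6")
    strands = {str(r.seq) == template for r in cohort.records["DII-S6"]}
    assert strands == {True, False}


def test_record_ids_and_manifest_are_consistent(model, catalog):
    spec = _spec([IndividualGroup(count=2)], seed=9)
    cohort = simulate_cohort(model, catalog, spec)
    fasta_ids = {r.id for recs in cohort.records.values() for r in recs}
    assert fasta_ids == set(cohort.manifest["record_id"])
    for record_id in fasta_ids:
        ind, region, clone = record_id.split("|")
        assert region in ("DII-S6", "DIII-S6")
        assert clone.startswith("clone")


def test_unreachable_or_unmapped_plants_are_rejected(model, catalog):
    with pytest.raises(SpecificationError):
        simulate_cohort(
            model, catalog,
            _spec([IndividualGroup(extra_mutations=((1016, "*"),))]),
        )
    with pytest.raises(SpecificationError):
        simulate_cohort(
            model, catalog,
            _spec([IndividualGroup(extra_mutations=((2000, "A"),))]),
        )


def test_noise_free_round_trip_recovers_planted_calls(model, catalog):
    spec = _spec(
        [
            IndividualGroup(
                haplotype=("P", "G", "T", "C"),
                count=1,
            )
        ],
        clones_per_individual=3,
        seed=21,
    )
    result = run_pipeline(PipelineConfig(simulate=spec))
    assert len(result.retained) == 1
    labels = sorted(c.label for c in result.calls)
    assert labels == ["F1534C", "S989P", "V1016G"]


def test_spec_round_trips_through_json(tmp_path):
    spec = _spec(
        [IndividualGroup(haplotype=("P", "G", "T", "C"),
                         extra_mutations=((1020, "S"),), count=2)],
        noise_rate=0.01,
        dropout=Dropout(1, 0),
        seed=13,
    )
    path = tmp_path / "spec.json"
    spec.to_json(path)
    assert CohortSpec.from_json(path) == spec
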