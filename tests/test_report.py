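"""Paired-amplicon filter, frequency tables, rounding discipline."""

import pytest

from kdrseq.calling import CLASS_AMBIGUOUS, CLASS_VALIDATED, AaCall
from kdrseq.haplotypes import Haplotype
from kdrseq.report import (
    ConsistencyError,
    DuplicateSampleError,
    SampleStatus,
    filter_paired_samples,
    haplotype_frequency_table,
    mutation_frequency_table,
    percent,
    population_shares,
)


def _status(i, pop="town", dii=True, diii=True):
    return SampleStatus(f"ind-{i:04d}", pop, dii, diii)


def _call(ind, pos=1016, ref="V", alt="G", classification=CLASS_VALIDATED):
    return AaCall(
        individual_id=ind,
        region="DII-S6",
        protein_position=pos,
        ref_residue=ref,
        alt_residue=alt,
        ref_codon="GTA",
        obs_codon="GGA",
        classification=classification,
    )


@pytest.mark.parametrize(
    "count, denominator, expected",
    [
        (290, 394, 73.6),
        (274, 394, 69.5),
        (216, 394, 54.8),
        (50, 394, 12.7),
        (10, 394, 2.5),
        (2, 394, 0.5),
        (2, 83, 2.4),
        (139, 394, 35.3),
        (130, 394, 33.0),
        (83, 394, 21.1),
        (30, 394, 7.6),
        (12, 394, 3.0),
        (1, 8, 12.5),
        (1, 2000, 0.1),  # half-up at the rounding boundary
        (0, 100, 0.0),
        (5, 0, 0.0),  # degenerate empty column
    ],
)
def test_percentages_round_half_up_to_one_decimal(count, denominator, expected):
    assert percent(count, denominator) == expected


def test_filter_retains_exactly_the_paired_individuals():
    statuses = (
        [_status(i) for i in range(394)]
        + [_status(394 + i, dii=False, diii=False) for i in range(5)]
        + [_status(399 + i, dii=(i % 2 == 0), diii=(i % 2 == 1)) for i in range(12)]
    )
    retained, exclusions = filter_paired_samples(statuses)
    assert len(retained) == 394
    assert len(exclusions) == 17
    assert (exclusions["reason"] == "both_fail").sum() == 5
    assert (exclusions["reason"] == "one_fail").sum() == 12


def test_all_present_and_empty_inputs():
    statuses = [_status(i) for i in range(5)]
    retained, exclusions = filter_paired_samples(statuses)
    assert retained == statuses and exclusions.empty
    retained, exclusions = filter_paired_samples([])
    assert retained == [] and exclusions.empty


def test_duplicate_individual_ids_rejected():
    with pytest.raises(DuplicateSampleError):
        filter_paired_samples([_status(1), _status(1)])


def test_mutation_table_counts_carriers_once_and_sums_to_total():
    statuses = [_status(i, pop="A") for i in range(10)] + [
        _status(10 + i, pop="B") for i in range(10)
    ]
    calls = [
        _call("ind-0000"),
        _call("ind-0000"),  # same carrier twice -> counted once
        _call("ind-0001"),
        _call("ind-0010"),
        _call("ind-0002", pos=989, ref="S", alt="P"),
    ]
    table = mutation_frequency_table(calls, statuses)
    assert table.counts.loc["V1016G", "A"] == 2
    assert table.counts.loc["V1016G", "B"] == 1
    assert table.counts.loc["V1016G", "Total"] == 3
    assert table.percent.loc["V1016G", "Total"] == 15.0
    # conservation: Total equals the row-sum over populations
    pops = [c for c in table.counts.columns if c != "Total"]
    assert (table.counts[pops].sum(axis=1) == table.counts["Total"]).all()
    # zero-carrier cell renders as 0 (0.0%)
    assert table.formatted().loc["S989P", "B"] == "0 (0.0%)"
    # rows ordered by protein position
    assert list(table.counts.index) == ["S989P", "V1016G"]


def test_ambiguous_calls_are_excluded_from_carrier_counts():
    statuses = [_status(0)]
    calls = [_call("ind-0000", alt="F/L", classification=CLASS_AMBIGUOUS)]
    table = mutation_frequency_table(calls, statuses)
    assert table.counts.empty


def test_call_for_non_retained_individual_raises():
    with pytest.raises(ConsistencyError):
        mutation_frequency_table([_call("ghost")], [_status(0)])


def _hap(label, complete=True):
    return Haplotype(
        alleles=("S", "V", "T", "F"), label=label,
        n_mutant_sites=0, complete=complete,
    )


def test_haplotype_table_columns_sum_to_retained_n():
    statuses = [_status(i, pop="A") for i in range(3)] + [_status(3, pop="B")]
    haps = {
        "ind-0000": _hap("H9"),
        "ind-0001": _hap("H1"),
        "ind-0002": _hap("incomplete", complete=False),
        "ind-0003": _hap("H9"),
    }
    table = haplotype_frequency_table(haps, statuses)
    assert table.counts["A"].sum() == 3
    assert table.counts["B"].sum() == 1
    assert list(table.counts.index) == ["H1", "H9", "incomplete"]
    assert table.denominators["A"] == 3
    assert table.percent.loc["H9", "Total"] == 50.0


def test_all_wild_cohort_is_single_h1_row_at_100_percent():
    statuses = [_status(i) for i in range(4)]
    haps = {s.individual_id: _hap("H1") for s in statuses}
    table = haplotype_frequency_table(haps, statuses)
    assert list(table.counts.index) == ["H1"]
    assert table.percent.loc["H1", "Total"] == 100.0


def test_population_shares_use_retained_denominator():
    statuses = [_status(i, pop="A") for i in range(3)] + [
        _status(3 + i, pop="B") for i in range(1)
    ]
    shares = population_shares(statuses)
    assert shares.loc[shares.population == "A", "n"].item() == 3
    assert shares.loc[shares.population == "A", "share_pct"].item() == 75.0
    assert shares["n"].sum() == len(statuses)
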