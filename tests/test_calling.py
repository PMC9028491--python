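"""Alignment projection, codon translation and substitution calling."""

import pytest

from kdrseq.calling import (
    CLASS_AMBIGUOUS,
    CLASS_OTHER,
    CLASS_VALIDATED,
    CLASS_WATCH,
    align_to_reference,
    call_substitutions,
    expand_codon,
    translate_ambiguous,
)
from kdrseq.cohort import plant_codon


def _insert_local(model, region, protein_position):
    """Insert-local offsets of a codon's bases."""
    ins_start, _ = model.insert_interval(region)
    intervals, _ = model.codon_for_position(protein_position)
    return [g - ins_start for s, e in intervals for g in range(s, e)]


def _mutate(seq, offsets, new_bases):
    out = list(seq)
    for off, base in zip(offsets, new_bases):
        out[off] = base
    return "".join(out)


def _calls_for(model, catalog, region, consensus, **kwargs):
    ra = align_to_reference(consensus, model, region, **kwargs)
    return call_substitutions(ra, model, catalog, individual_id="ind1")


def test_reference_identical_consensus_yields_no_calls(model, catalog):
    for region in ("DII-S6", "DIII-S6"):
        cs = _calls_for(model, catalog, region, model.insert_sequence(region))
        assert cs.calls == ()
        assert not cs.frameshift
        span = model.region(region).protein_span
        assert cs.covered_positions == frozenset(range(span[0], span[1] + 1))


def test_planted_valine_to_glycine_is_validated_kdr_call(model, catalog):
    ref = model.insert_sequence("DII-S6")
    offs = _insert_local(model, "DII-S6", 1016)
    _, ref_codon = model.codon_for_position(1016)
    consensus = _mutate(ref, offs, plant_codon(ref_codon, "G"))
    cs = _calls_for(model, catalog, "DII-S6", consensus)
    assert [c.label for c in cs.calls] == ["V1016G"]
    assert cs.calls[0].classification == CLASS_VALIDATED


def test_watch_site_and_uncatalogued_site_classifications(model, catalog):
    ref = model.insert_sequence("DII-S6")
    offs_1020 = _insert_local(model, "DII-S6", 1020)
    _, codon_1020 = model.codon_for_position(1020)
    offs_960 = _insert_local(model, "DII-S6", 960)
    _, codon_960 = model.codon_for_position(960)
    consensus = _mutate(ref, offs_1020, plant_codon(codon_1020, "S"))
    consensus = _mutate(consensus, offs_960, plant_codon(codon_960, "G"))
    cs = _calls_for(model, catalog, "DII-S6", consensus)
    by_label = {c.label: c.classification for c in cs.calls}
    assert by_label == {"F1020S": CLASS_WATCH, "D960G": CLASS_OTHER}


def test_intron_split_codon_calls_across_the_junction(model, catalog):
    # codon 1512 (V) sits just downstream of the intron; mutate it via the
    # DIII consensus and expect a normal call
    ref = model.insert_sequence("DIII-S6")
    offs = _insert_local(model, "DIII-S6", 1512)
    _, ref_codon = model.codon_for_position(1512)
    consensus = _mutate(ref, offs, plant_codon(ref_codon, "A"))
    cs = _calls_for(model, catalog, "DIII-S6", consensus)
    assert [c.label for c in cs.calls] == ["V1512A"]


def test_ambiguous_codon_at_1534_is_not_counted_as_mutant(model, catalog):
    ref = model.insert_sequence("DIII-S6")
    offs = _insert_local(model, "DIII-S6", 1534)
    # wild-type codon TTC; Y in the first position covers TTC (F) and CTC (L)
    consensus = _mutate(ref, [offs[0]], "Y")
    cs = _calls_for(model, catalog, "DIII-S6", consensus)
    assert len(cs.calls) == 1
    call = cs.calls[0]
    assert call.classification == CLASS_AMBIGUOUS
    assert set(call.alt_residue.split("/")) == {"F", "L"}
    assert 1534 in cs.covered_positions


def test_in_frame_deletion_uncovers_codon_but_keeps_frame(model, catalog):
    ref = model.insert_sequence("DIII-S6")
    offs = sorted(_insert_local(model, "DIII-S6", 1520))
    deleted = ref[: offs[0]] + ref[offs[-1] + 1 :]
    cs = _calls_for(model, catalog, "DIII-S6", deleted)
    assert not cs.frameshift
    # the gap may be placed at an equivalent offset in the surrounding
    # repeat context, but it stays a single in-frame codon-sized hole
    assert 1 <= len(cs.uncovered_positions) <= 2
    assert all(1517 <= p <= 1521 for p in cs.uncovered_positions)
    assert 1534 in cs.covered_positions
    assert cs.calls == ()  # downstream codons still read in frame


def test_frameshifting_deletion_flags_individual_and_downstream(model, catalog):
    ref = model.insert_sequence("DIII-S6")
    offs = sorted(_insert_local(model, "DIII-S6", 1520))
    deleted = ref[: offs[0]] + ref[offs[0] + 1 :]  # single-base deletion
    cs = _calls_for(model, catalog, "DIII-S6", deleted)
    assert cs.frameshift
    assert 1520 in cs.uncovered_positions
    assert 1534 in cs.uncovered_positions
    assert 1515 in cs.covered_positions  # upstream codons unaffected


def test_unalignable_consensus_is_flagged_and_refused(model, catalog):
    ra = align_to_reference("ACGT" * 40, model, "DII-S6")
    assert ra.unalignable
    with pytest.raises(ValueError):
        call_substitutions(ra, model, catalog)


def test_no_call_at_synonymous_change(model, catalog):
    ref = model.insert_sequence("DII-S6")
    offs = _insert_local(model, "DII-S6", 1016)
    _, ref_codon = model.codon_for_position(1016)  # GTA (V)
    consensus = _mutate(ref, offs, "GTG")  # still valine
    cs = _calls_for(model, catalog, "DII-S6", consensus)
    assert cs.calls == ()


def test_expand_and_translate_ambiguous_codons():
    assert set(expand_codon("YTC")) == {"TTC", "CTC"}
    assert translate_ambiguous("YTC") == frozenset("FL")
    assert translate_ambiguous("GTA") == frozenset("V")


@pytest.mark.parametrize(
    "ref_codon, alt, expected",
    [
        ("GTA", "G", "GGA"),  # one-base edit
        ("ACA", "I", "ATA"),
        ("TTC", "L", "CTC"),  # ties broken lexicographically (CTC < TTA < TTG)
        ("AGC", "P", "CCC"),  # two-base edit is the minimum for AGC->Pro
    ],
)
def test_minimal_edit_codon_planting(ref_codon, alt, expected):
    assert plant_codon(ref_codon, alt) == expected
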