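"""Gene model: codon coordinate map, validation, kdr catalogue."""

import json

import pytest

from Bio.Seq import Seq

from kdrseq.reference import (
    ExonLayoutError,
    FrameError,
    GeneModel,
    InternalStopError,
    KdrSite,
    MissingSequenceError,
    UnmappedPositionError,
    kdr_catalog,
    load_gene_model,
    load_kdr_catalog,
    validate_catalog,
)


def _write_fasta(path, seq, rec_id="ref"):
    path.write_text(f">{rec_id}\n{seq}\n")


def test_single_exon_model_maps_length_over_three_codons(tmp_path):
    seq = "GCA" * 30  # 90 nt, poly-alanine, no stops
    fasta = tmp_path / "ref.fasta"
    _write_fasta(fasta, seq)
    annotation = {
        "reference_id": "ref",
        "exons": [[0, 90]],
        "coding_start_protein_position": 1,
        "regions": [],
    }
    model = load_gene_model(fasta, annotation)
    assert len(model.protein_positions) == 30
    intervals, triplet = model.codon_for_position(1)
    assert intervals == ((0, 3),)
    assert triplet == "GCA"


def test_intron_splitting_a_codon_after_first_base(tmp_path):
    # codons: ATG GCT | first base T of codon 3 ... intron ... GG + TAA? no stop:
    # exon1 = ATG GCT T ; intron = GTAAAG ; exon2 = GG GCA -> codons M A W A
    seq = "ATGGCTT" + "GTAAAG" + "GGGCA"
    fasta = tmp_path / "ref.fasta"
    _write_fasta(fasta, seq)
    annotation = {
        "reference_id": "ref",
        "exons": [[0, 7], [13, 18]],
        "coding_start_protein_position": 1,
        "regions": [],
    }
    model = load_gene_model(fasta, annotation)
    assert model.protein_sequence == "MAWA"
    intervals, triplet = model.codon_for_position(3)
    assert intervals == ((6, 7), (13, 15))
    assert triplet == "TGG"
    assert str(Seq(triplet).translate()) == "W"


@pytest.mark.parametrize(
    "annotation_patch, error",
    [
        ({"reference_id": "nope"}, MissingSequenceError),
        ({"exons": [[0, 6], [3, 12]]}, ExonLayoutError),
        ({"exons": [[0, 80]]}, FrameError),
        ({"exons": [[0, 200]]}, ExonLayoutError),
    ],
)
def test_invalid_annotations_raise_named_errors(tmp_path, annotation_patch, error):
    fasta = tmp_path / "ref.fasta"
    _write_fasta(fasta, "GCA" * 30)
    annotation = {
        "reference_id": "ref",
        "exons": [[0, 90]],
        "coding_start_protein_position": 1,
        "regions": [],
    }
    annotation.update(annotation_patch)
    with pytest.raises(error):
        load_gene_model(fasta, annotation)


def test_internal_stop_codon_rejected(tmp_path):
    fasta = tmp_path / "ref.fasta"
    _write_fasta(fasta, "GCATAAGCA")  # A * A
    annotation = {
        "reference_id": "ref",
        "exons": [[0, 9]],
        "coding_start_protein_position": 1,
        "regions": [],
    }
    with pytest.raises(InternalStopError):
        load_gene_model(fasta, annotation)


def test_bundled_model_regions_cover_canonical_sites(model):
    dii = model.region("DII-S6")
    diii = model.region("DIII-S6")
    assert dii.contains(989) and dii.contains(1016)
    assert diii.contains(1520) and diii.contains(1534)
    # watch sites from the survey's minor-mutation table are also in span
    assert dii.contains(960) and dii.contains(1020)
    assert diii.contains(1512) and diii.contains(1584)


def test_bundled_model_round_trips_through_files(tmp_path, model):
    from kdrseq.bundled import write_bundled_reference

    paths = write_bundled_reference(tmp_path)
    loaded = load_gene_model(paths["fasta"], paths["annotation"])
    assert loaded.sequence == model.sequence
    assert loaded.exons == model.exons
    assert loaded.regions == model.regions
    catalog = load_kdr_catalog(paths["catalog"])
    validate_catalog(loaded, catalog)


def test_codon_map_agrees_with_full_translation(model):
    # full-translation oracle: the triplet returned for position p must
    # translate to the p-th residue of the translated exonic sequence
    for p in model.protein_positions:
        _, triplet = model.codon_for_position(p)
        assert str(Seq(triplet).translate()) == model.residue_at(p)


def test_codon_map_total_and_injective(model):
    seen: set[int] = set()
    for p in model.protein_positions:
        intervals, _ = model.codon_for_position(p)
        bases = [g for s, e in intervals for g in range(s, e)]
        assert len(bases) == 3
        assert not (set(bases) & seen)
        seen.update(bases)
        assert all(model.is_exonic(g) for g in bases)


def test_intron_split_codon_in_bundled_model(model):
    intervals, triplet = model.codon_for_position(1510)
    assert len(intervals) == 2
    assert (intervals[0][1] - intervals[0][0], intervals[1][1] - intervals[1][0]) in {
        (1, 2),
        (2, 1),
    }
    assert str(Seq(triplet).translate()) == model.residue_at(1510)


def test_position_1016_is_wild_type_valine(model):
    _, triplet = model.codon_for_position(1016)
    assert str(Seq(triplet).translate()) == "V"


def test_unmapped_position_raises(model):
    with pytest.raises(UnmappedPositionError):
        model.codon_for_position(1)


def test_kdr_catalog_contents(catalog):
    by_pos = {site.protein_position: site for site in catalog}
    assert len(by_pos) == len(catalog)  # no duplicate positions
    assert by_pos[1534].known_mutants == frozenset("CL")
    assert by_pos[1534].validated
    assert not by_pos[1020].validated
    assert not by_pos[1553].validated
    for pos in (989, 1016, 1520, 1534):
        assert by_pos[pos].validated


def test_kdr_site_rejects_wild_type_as_mutant():
    with pytest.raises(ValueError):
        KdrSite(989, "S", frozenset("SP"), "DII-S6", True)


def test_catalog_validates_against_bundled_model(model, catalog):
    validate_catalog(model, catalog)
    bad = list(catalog) + [KdrSite(989, "S", frozenset("P"), "DII-S6", True)]
    with pytest.raises(ValueError):
        validate_catalog(model, bad)
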