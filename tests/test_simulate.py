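"""Synthetic clone-set generator: determinism, truth consistency, and
recovery scoring."""

from __future__ import annotations

import pytest

from clonepoly.errors import GenerationError, InputError
from clonepoly.io import write_clone_fasta
from clonepoly.pipeline import analyze_alignment
from clonepoly.simulate import (
    SimConfig,
    exon_intron_annotation,
    expected_singleton_recall,
    simulate,
    truth_compare,
)
from clonepoly.variants import call_sites


def test_same_seed_gives_byte_identical_fasta(tmp_path):
    cfg = SimConfig(seed=11, clones_per_isolate=9, alignment_length=200)
    outs = []
    for name in ("a", "b"):
        aln, _, _, _ = simulate(cfg)
        p = tmp_path / f"{name}.fasta"
        write_clone_fasta(aln, p)
        outs.append(p.read_bytes())
    assert outs[0] == outs[1]


def test_zero_everything_gives_identical_clones_per_species():
    cfg = SimConfig(
        seed=3, n_species=2, isolates_per_species=2, clones_per_isolate=5,
        alignment_length=120, interspecific_sites=0, intraspecific_sites=0,
        intra_isolate_sites=0, pcr_error_rate=0.0,
    )
    aln, _, _, truth = simulate(cfg)
    assert truth.sites == () and truth.errors == ()
    for clones in aln.species().values():
        assert len({aln.rows[c] for c in clones}) == 1


def test_planted_structure_matches_config_sums():
    cfg = SimConfig(
        seed=5, clones_per_isolate=12, alignment_length=400,
        interspecific_sites=6, intraspecific_sites=3, intra_isolate_sites=2,
        trimorphic_sites=1, indel_events=((50, 4),), pcr_error_rate=0.0,
    )
    aln, samples, ann, truth = simulate(cfg)
    expected = 6 + 3 * 3 + 9 * 2 + 1 + 4
    assert len(truth.sites) == expected
    cols = [s.column for s in truth.sites]
    assert len(set(cols)) == len(cols)
    # generator output passes CloneAlignment validation implicitly; check
    # carriers of intra-isolate sites have the minor count
    for s in truth.sites:
        if s.category == "intra_isolate":
            assert len(s.carriers) == cfg.minor_count >= 2


def test_citrinopileatus_like_fixture():
    """Three isolates of 9 clones, one intraspecific site, two planted
    single-clone errors: after correction there is no intra-isolate
    polymorphism but one inter-isolate variable site."""
    cfg = SimConfig(
        seed=7, n_species=1, isolates_per_species=3, clones_per_isolate=9,
        alignment_length=581, interspecific_sites=0, intraspecific_sites=1,
        intra_isolate_sites=0, pcr_error_rate=0.0, pcr_errors_exact=2,
    )
    aln, _, ann, truth = simulate(cfg)
    assert len(truth.errors) == 2
    result = analyze_alignment(aln, annotation=ann, min_clones=9)
    corrected = result["corrected"]
    for clones in corrected.isolates().values():
        assert call_sites(corrected, clones) == []
    species_sites = call_sites(corrected, corrected.clone_ids)
    assert len(species_sites) == 1
    assert species_sites[0].column == truth.sites[0].column


def test_planted_trimorphic_and_indel_are_recovered_with_classes():
    cfg = SimConfig(
        seed=9, clones_per_isolate=12, alignment_length=400,
        interspecific_sites=4, intraspecific_sites=2, intra_isolate_sites=1,
        trimorphic_sites=2, indel_events=((101, 4), (300, 3)),
        pcr_error_rate=0.0, minor_count=3,
    )
    aln, _, ann, truth = simulate(cfg)
    result = analyze_alignment(aln, annotation=ann, min_clones=10)
    report = truth_compare(
        corrected=result["corrected"], events=result["events"],
        sites=result["all_sites"], truth=truth,
    )
    assert report.site_recall == 1.0
    assert report.site_precision == 1.0
    assert report.class_accuracy == 1.0
    assert report.false_corrections == 0
    assert report.type_counts_match == 1.0


def test_exon_variants_constrained_synonymous_are_labelled_synonymous():
    ann = exon_intron_annotation(402, intron=(181, 240), frame_offset=0, gene_id="RPB2")
    cfg = SimConfig(
        seed=13, gene_id="RPB2", clones_per_isolate=12, alignment_length=402,
        annotation=ann, interspecific_sites=6, intraspecific_sites=3,
        intra_isolate_sites=2, pcr_error_rate=0.0, syn_fraction=1.0,
    )
    aln, _, _, truth = simulate(cfg)
    exon_sites = [s for s in truth.sites if s.intended_effect == "synonymous"]
    assert exon_sites, "expected some exon sites under syn_fraction=1"
    result = analyze_alignment(aln, annotation=ann, min_clones=10)
    report = truth_compare(
        corrected=result["corrected"], events=result["events"],
        sites=result["all_sites"], truth=truth,
    )
    assert report.effect_accuracy == 1.0
    by_col = {s.column: s for s in result["all_sites"]}
    for s in exon_sites:
        assert by_col[s.column].coding_effect == "synonymous"


def test_true_variants_never_removed_by_singleton_filter():
    for seed in range(10):
        cfg = SimConfig(
            seed=seed, clones_per_isolate=10, alignment_length=250,
            interspecific_sites=5, intraspecific_sites=2, intra_isolate_sites=2,
            minor_count=2, pcr_error_rate=0.0,
        )
        aln, _, _, truth = simulate(cfg)
        result = analyze_alignment(aln, min_clones=10)
        planted_cols = truth.site_columns
        assert all(e.column not in planted_cols for e in result["events"])
        called = {s.column for s in result["all_sites"]}
        assert planted_cols <= called


def test_config_validation():
    with pytest.raises(InputError):
        SimConfig(pcr_error_rate=0.5)
    with pytest.raises(InputError):
        SimConfig(minor_count=1)
    with pytest.raises(InputError):
        SimConfig(n_species=1, interspecific_sites=3)
    with pytest.raises(GenerationError):
        simulate(SimConfig(seed=0, alignment_length=20, interspecific_sites=30,
                           intraspecific_sites=0, intra_isolate_sites=0))


def test_expected_singleton_recall_closed_form():
    # rate 0 -> certain recall; more clones -> more collision opportunity
    assert expected_singleton_recall(0.0, 30) == 1.0
    assert expected_singleton_recall(0.002, 30) < expected_singleton_recall(0.002, 9)
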