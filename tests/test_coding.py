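"""Coding-effect assignment against the group consensus background."""

from __future__ import annotations

from itertools import product

import pytest

from clonepoly.coding import assign_effects, build_context
from clonepoly.errors import AnnotationError
from clonepoly.model import RegionAnnotation, RegionInterval
from clonepoly.variants import call_sites

from conftest import build_aln, clone_set

FOURFOLD_PREFIXES = ("GC", "CG", "GG", "CT", "CC", "TC", "AC", "GT")


def coding_ann(length: int, frame: int = 0) -> RegionAnnotation:
    return RegionAnnotation(
        "g", (RegionInterval(1, length, "exon"),), frame_offset=frame
    )


def split_ann() -> RegionAnnotation:
    return RegionAnnotation(
        "g",
        (
            RegionInterval(1, 6, "exon"),
            RegionInterval(7, 9, "intron"),
            RegionInterval(10, 15, "exon"),
        ),
        frame_offset=0,
    )


def aln_with_variant(consensus: str, column: int, alt: str, n: int = 6):
    """n-1 consensus clones plus one-mutation carriers (2 copies so the
    variant is not a singleton)."""
    variant = consensus[: column - 1] + alt + consensus[column:]
    rows, meta = clone_set("isoA", "sp1", [consensus] * (n - 2) + [variant] * 2)
    return build_aln(rows, meta)


def run_effect(consensus: str, column: int, alt: str, ann: RegionAnnotation):
    aln = aln_with_variant(consensus, column, alt)
    clones = list(aln.clone_ids)
    sites = call_sites(aln, clones, annotation=ann)
    assign_effects(sites, aln, clones, ann)
    (site,) = [s for s in sites if s.column == column]
    return site


def test_fourfold_third_positions_are_always_synonymous():
    """All third-position substitutions in every 4-fold degenerate codon
    family classify synonymous (exhaustive over the 8 families)."""
    for prefix in FOURFOLD_PREFIXES:
        for third, alt in product("ACGT", repeat=2):
            if third == alt:
                continue
            consensus = prefix + third + "GGA"  # trailing codon as padding
            site = run_effect(consensus, 3, alt, coding_ann(6))
            assert site.coding_effect == "synonymous", (prefix, third, alt)


def test_first_position_lys_to_glu_is_nonsynonymous():
    site = run_effect("AAAGGT", 1, "G", coding_ann(6))
    assert site.coding_effect == "nonsynonymous"


def test_stop_creating_change_flagged_nonsense():
    site = run_effect("TACGGT", 3, "A", coding_ann(6))  # TAC(Tyr) -> TAA(stop)
    assert site.coding_effect == "nonsynonymous"
    assert "nonsense" in site.flags


def test_intron_and_its_variants_are_noncoding():
    ann = split_ann()
    site = run_effect("ATGAAACCCGGGTTT"[:15], 8, "T", ann)
    assert site.region_type == "intron"
    assert site.coding_effect == "noncoding"


def test_frame_offset_shifts_codons():
    # frame 1: column 1 untranslated, codons start at column 2
    ann = coding_ann(7, frame=1)
    # columns 2-4 = GGT (Gly); third position change stays Gly
    site = run_effect("AGGTAAA", 4, "C", ann)
    assert site.coding_effect == "synonymous"
    site = run_effect("AGGTAAA", 1, "C", ann)
    assert site.coding_effect == "na"  # before frame start


def test_exon_gap_frameshift_vs_inframe():
    base = "ATGAAACCCGGG"
    ann = coding_ann(12)
    # 2-column deletion -> frameshift
    gapped = "ATGA--CCCGGG"
    rows, meta = clone_set("isoA", "sp1", [base] * 4 + [gapped] * 2)
    aln = build_aln(rows, meta)
    sites = call_sites(aln, list(aln.clone_ids), annotation=ann)
    assign_effects(sites, aln, list(aln.clone_ids), ann)
    assert {s.coding_effect for s in sites} == {"frameshift"}
    # 3-column deletion -> in-frame, reported nonsynonymous
    gapped3 = "ATG---CCCGGG"
    rows, meta = clone_set("isoB", "sp1", [base] * 4 + [gapped3] * 2)
    aln = build_aln(rows, meta)
    sites = call_sites(aln, list(aln.clone_ids), annotation=ann)
    assign_effects(sites, aln, list(aln.clone_ids), ann)
    assert {s.coding_effect for s in sites} == {"nonsynonymous"}
    assert all("inframe_indel" in s.flags for s in sites)


def test_consensus_gap_column_is_na():
    base = "ATG---CCCGGG"  # consensus majority carries the gap
    other = "ATGAAACCCGGG"
    rows, meta = clone_set("isoA", "sp1", [base] * 4 + [other] * 2)
    aln = build_aln(rows, meta)
    ann = coding_ann(12)
    ctx = build_context(aln, list(aln.clone_ids), ann)
    assert 4 not in ctx.cds_map and 7 in ctx.cds_map
    # the CDS skips the consensus-gap columns
    assert ctx.cds == "ATGCCCGGG"


def test_effect_invariant_to_clone_order_and_carrier():
    ann = coding_ann(6)
    consensus = "AAAGGT"
    variant = "GAAGGT"
    for arrangement in (
        [consensus] * 4 + [variant] * 2,
        [variant] * 2 + [consensus] * 4,
    ):
        rows, meta = clone_set("isoA", "sp1", arrangement)
        aln = build_aln(rows, meta)
        sites = call_sites(aln, list(aln.clone_ids), annotation=ann)
        assign_effects(sites, aln, list(aln.clone_ids), ann)
        assert [s.coding_effect for s in sites] == ["nonsynonymous"]


def test_build_context_requires_frame_for_exons():
    with pytest.raises(AnnotationError):
        RegionAnnotation("g", (RegionInterval(1, 6, "exon"),), frame_offset=None)
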