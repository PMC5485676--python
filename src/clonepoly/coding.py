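"""Synonymous / non-synonymous assignment for exon variants.

Each variant column is judged one at a time against the *consensus
background* of its clone group: the per-column majority sequence.  Exon
columns are concatenated in annotation order, consensus-gap columns are
dropped, and the resulting CDS is translated with the standard genetic
code (nuclear genes of fungi use translation table 1) starting at the
annotated frame offset.

Effect vocabulary:

* ``synonymous``    — every alternate allele preserves the amino acid;
* ``nonsynonymous`` — some alternate allele changes it (a stop-creating
                      change additionally carries a ``nonsense`` flag);
* ``frameshift``    — an exon gap allele whose merged run length within the
                      exon is not a multiple of 3 (in-frame deletions are
                      reported nonsynonymous);
* ``noncoding``     — intron / ITS1 / 5.8S / ITS2 / other regions;
* ``na``            — not judgeable: consensus-gap column, incomplete codon,
                      or N inside the affected codon.

Compound effects of multiple variants in one codon are out of scope; each
site is assessed independently, matching per-site variant tallies.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio.Seq import Seq

from .errors import AnnotationError, ConsistencyError
from .model import (
    GAP,
    MISSING,
    CloneAlignment,
    RegionAnnotation,
    VariantSite,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CodingContext:
    """Consensus background and exon-column -> CDS-position map for a group."""

    annotation: RegionAnnotation
    consensus: str
    cds_map: Mapping[int, int]  # 1-based alignment column -> 1-based CDS position
    cds: str

    @property
    def frame_offset(self) -> int:
        assert self.annotation.frame_offset is not None
        return self.annotation.frame_offset


def group_consensus(aln: CloneAlignment, group: Sequence[str]) -> str:
    """Per-column majority residue of a clone group (N ignored; ties go to
    the lexicographically smallest allele, logged)."""
    rows = [aln.rows[c] for c in group]
    out: list[str] = []
    for col in range(aln.columns):
        counts = Counter(r[col] for r in rows)
        counts.pop(MISSING, None)
        if not counts:
            out.append(MISSING)
            continue
        top = max(counts.values())
        winners = sorted(a for a, n in counts.items() if n == top)
        if len(winners) > 1:
            logger.info(
                "consensus tie at column %d between %s; using %r",
                col + 1, winners, winners[0],
            )
        out.append(winners[0])
    return "".join(out)


def build_context(
    aln: CloneAlignment, group: Sequence[str], annotation: RegionAnnotation
) -> CodingContext:
    """Build the consensus CDS context for effect assignment."""
    annotation.validate_coverage(aln.columns)
    if annotation.exon_intervals() and annotation.frame_offset is None:
        raise AnnotationError("exon intervals present but frame_offset missing")
    consensus = group_consensus(aln, group)
    cds_map: dict[int, int] = {}
    cds_chars: list[str] = []
    pos = 0
    for iv in annotation.exon_intervals():
        for col in range(iv.start, iv.end + 1):
            ch = consensus[col - 1]
            if ch == GAP:
                continue
            pos += 1
            cds_map[col] = pos
            cds_chars.append(ch)
    return CodingContext(
        annotation=annotation, consensus=consensus, cds_map=cds_map, cds="".join(cds_chars)
    )


def _translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


def effect_of(
    site: VariantSite, ctx: CodingContext, gap_run_length: int | None = None
) -> tuple[str, tuple[str, ...]]:
    """Coding effect of one variant site against the consensus background.

    `gap_run_length` is the merged length of the gap event containing this
    column within the exon (required to distinguish frameshifts from
    in-frame deletions when a gap allele is present; defaults to 1 column).
    Returns (effect, flags).
    """
    col = site.column
    region = ctx.annotation.region_at(col)
    if region != "exon":
        return "noncoding", ()
    alleles = set(site.allele_counts)
    if GAP in alleles:
        run = gap_run_length if gap_run_length is not None else 1
        if run % 3 == 0:
            return "nonsynonymous", ("inframe_indel",)
        return "frameshift", ()
    if col not in ctx.cds_map:
        return "na", ("consensus_gap",)
    cds_pos = ctx.cds_map[col]  # 1-based
    fo = ctx.frame_offset
    idx = cds_pos - 1 - fo  # 0-based position within the framed CDS
    if idx < 0:
        return "na", ("before_frame_start",)
    codon_start = fo + (idx // 3) * 3
    codon = ctx.cds[codon_start : codon_start + 3]
    if len(codon) < 3:
        return "na", ("incomplete_codon",)
    if MISSING in codon:
        logger.warning("N inside codon at column %d; effect is na", col)
        return "na", ("ambiguous_codon",)
    within = idx % 3
    ref_allele = ctx.consensus[col - 1]
    if codon[within] != ref_allele:
        raise ConsistencyError(
            f"consensus/cds mismatch at column {col}: codon {codon!r} vs "
            f"consensus {ref_allele!r}"
        )
    ref_aa = _translate_codon(codon)
    flags: list[str] = []
    effect = "synonymous"
    for alt in sorted(alleles - {ref_allele}):
        alt_codon = codon[:within] + alt + codon[within + 1 :]
        alt_aa = _translate_codon(alt_codon)
        if alt_aa != ref_aa:
            effect = "nonsynonymous"
            if alt_aa == "*":
                flags.append("nonsense")
    return effect, tuple(flags)


def assign_effects(
    sites: Sequence[VariantSite],
    aln: CloneAlignment,
    group: Sequence[str],
    annotation: RegionAnnotation,
) -> CodingContext:
    """Fill `region_type`, `coding_effect` and flags for every site in place.

    Gap-run lengths for frameshift decisions are measured on the carrier
    clone rows: the longest contiguous gap run through the column, clipped
    to the exon interval containing it.
    """
    ctx = build_context(aln, group, annotation)
    rows = [aln.rows[c] for c in group]
    for site in sites:
        site.region_type = ctx.annotation.region_at(site.column)
        run = None
        if GAP in site.allele_counts and site.region_type == "exon":
            run = _max_gap_run(rows, site.column, ctx.annotation)
        effect, flags = effect_of(site, ctx, gap_run_length=run)
        site.coding_effect = effect
        site.flags = tuple(dict.fromkeys(site.flags + flags))
    return ctx


def _max_gap_run(rows: Sequence[str], column: int, annotation: RegionAnnotation) -> int:
    """Longest gap run through `column` over carrier rows, within its exon."""
    iv = next(
        iv for iv in annotation.exon_intervals() if iv.start <= column <= iv.end
    )
    best = 1
    for r in rows:
        if r[column - 1] != GAP:
            continue
        lo = column
        while lo - 1 >= iv.start and r[lo - 2] == GAP:
            lo -= 1
        hi = column
        while hi + 1 <= iv.end and r[hi] == GAP:
            hi += 1
        best = max(best, hi - lo + 1)
    return best
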