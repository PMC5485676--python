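"""Core domain types.

The unit of analysis is a *clone alignment*: every sequenced clone of one
marker gene (ITS, RPB2, EF1a, ...) from a set of isolates and species,
already placed in one shared column coordinate system.  All coordinates in
this package are 1-based inclusive alignment columns, matching how variable
sites are labelled in the intra-isolate heterogeneity literature.

`N` is treated as missing data throughout: it never enters allele counts
and never counts as a difference.  The gap character `-` is a real allele
(an indel state), except that gap-vs-gap is never a difference.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

from .errors import AlignmentInputError, AnnotationError, FormatError, MetadataError

ALPHABET = frozenset("ACGTN-")
BASES = "ACGT"
GAP = "-"
MISSING = "N"

REGION_TYPES = frozenset({"exon", "intron", "ITS1", "5.8S", "ITS2", "other"})
NONCODING_REGIONS = frozenset({"intron", "ITS1", "5.8S", "ITS2", "other"})


@dataclass(frozen=True, slots=True)
class SampleRecord:
    """One row of the sample sheet: clone -> isolate -> species -> gene."""

    clone_id: str
    isolate_id: str
    species_id: str
    gene_id: str


@dataclass(frozen=True, slots=True)
class RegionInterval:
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    region_type: str


@dataclass(frozen=True)
class RegionAnnotation:
    """Region structure of one gene's alignment (exon/intron or ITS parts).

    `frame_offset` is the codon phase of the first exon column (0-2) and is
    required exactly when any interval is an exon.
    """

    gene_id: str
    intervals: tuple[RegionInterval, ...]
    frame_offset: int | None = None

    def __post_init__(self) -> None:
        if not self.intervals:
            raise AnnotationError("annotation has no intervals")
        prev_end = 0
        for iv in self.intervals:
            if iv.region_type not in REGION_TYPES:
                raise AnnotationError(
                    f"unknown region type {iv.region_type!r} "
                    f"(allowed: {sorted(REGION_TYPES)})"
                )
            if iv.start > iv.end:
                raise AnnotationError(f"interval ({iv.start},{iv.end}) has start > end")
            if iv.start != prev_end + 1:
                raise AnnotationError(
                    f"intervals must tile the alignment without gaps or overlap; "
                    f"interval starting at {iv.start} follows one ending at {prev_end}"
                )
            prev_end = iv.end
        has_exon = any(iv.region_type == "exon" for iv in self.intervals)
        if has_exon and self.frame_offset is None:
            raise AnnotationError("exon intervals present but no frame_offset given")
        if not has_exon and self.frame_offset is not None:
            raise AnnotationError("frame_offset given but no exon interval present")
        if self.frame_offset is not None and self.frame_offset not in (0, 1, 2):
            raise AnnotationError(f"frame_offset must be 0, 1 or 2, got {self.frame_offset}")

    @property
    def columns(self) -> int:
        return self.intervals[-1].end

    def validate_coverage(self, columns: int) -> None:
        if self.columns != columns:
            raise AnnotationError(
                f"annotation covers 1..{self.columns} but alignment has {columns} columns"
            )

    def region_at(self, column: int) -> str:
        if not 1 <= column <= self.columns:
            raise AnnotationError(f"column {column} outside annotation 1..{self.columns}")
        starts = [iv.start for iv in self.intervals]
        return self.intervals[bisect_right(starts, column) - 1].region_type

    def exon_intervals(self) -> tuple[RegionInterval, ...]:
        return tuple(iv for iv in self.intervals if iv.region_type == "exon")


@dataclass(frozen=True, slots=True)
class SingletonEvent:
    """A within-isolate single-occurrence allele replaced by the majority."""

    clone_id: str
    column: int
    observed_allele: str
    corrected_to: str
    isolate_id: str


@dataclass(frozen=True)
class CloneAlignment:
    """Aligned clone sequences of one gene plus their sample metadata.

    Rows are immutable strings over {A,C,G,T,N,-}; `clone_ids` fixes the
    row order so downstream reports are deterministic.
    """

    gene_id: str
    clone_ids: tuple[str, ...]
    rows: Mapping[str, str]
    samples: Mapping[str, SampleRecord]
    correction_log: tuple[SingletonEvent, ...] = ()

    def __post_init__(self) -> None:
        if len(self.clone_ids) < 2:
            raise FormatError("a clone alignment needs at least 2 clones")
        if set(self.clone_ids) != set(self.rows):
            raise MetadataError("clone_ids and rows disagree")
        missing = set(self.clone_ids) - set(self.samples)
        if missing:
            raise MetadataError(f"no sample record for clone(s): {sorted(missing)}")
        extra = set(self.samples) - set(self.clone_ids)
        if extra:
            raise MetadataError(f"sample record(s) without a sequence: {sorted(extra)}")
        lengths = {len(self.rows[c]) for c in self.clone_ids}
        if len(lengths) != 1:
            bad = next(
                c for c in self.clone_ids
                if len(self.rows[c]) != len(self.rows[self.clone_ids[0]])
            )
            raise AlignmentInputError(
                f"rows have unequal lengths {sorted(lengths)}; first offender: {bad!r}"
            )
        for cid in self.clone_ids:
            bad_chars = set(self.rows[cid]) - ALPHABET
            if bad_chars:
                col = next(
                    i + 1 for i, ch in enumerate(self.rows[cid]) if ch not in ALPHABET
                )
                raise FormatError(
                    f"illegal residue {sorted(bad_chars)[0]!r} in clone {cid!r} "
                    f"at column {col}"
                )

    @property
    def columns(self) -> int:
        return len(self.rows[self.clone_ids[0]])

    def row(self, clone_id: str) -> str:
        return self.rows[clone_id]

    def isolates(self) -> dict[str, tuple[str, ...]]:
        """Clone ids grouped by isolate, preserving row order."""
        out: dict[str, list[str]] = {}
        for cid in self.clone_ids:
            out.setdefault(self.samples[cid].isolate_id, []).append(cid)
        return {k: tuple(v) for k, v in out.items()}

    def species(self) -> dict[str, tuple[str, ...]]:
        """Clone ids grouped by species, preserving row order."""
        out: dict[str, list[str]] = {}
        for cid in self.clone_ids:
            out.setdefault(self.samples[cid].species_id, []).append(cid)
        return {k: tuple(v) for k, v in out.items()}

    def with_rows(
        self, rows: Mapping[str, str], log: Iterable[SingletonEvent] = ()
    ) -> "CloneAlignment":
        return replace(
            self,
            rows=dict(rows),
            correction_log=self.correction_log + tuple(log),
        )


SITE_CLASSES = ("transition_CT", "transition_AG", "transversion", "indel", "trimorphic")

CODING_EFFECTS = ("synonymous", "nonsynonymous", "frameshift", "noncoding", "na")


@dataclass
class VariantSite:
    """One polymorphic alignment column within a scope (group of clones)."""

    column: int
    gene_id: str
    level: str  # intra-isolate | intraspecific | interspecific
    group: str  # isolate id, species id, or species-pair / "all" label
    allele_counts: dict[str, int]  # residue -> clone count, N excluded
    site_class: str
    region_type: str = ""
    coding_effect: str = ""
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class SpectrumSummary:
    """Counts and percentages per substitution class for one scope."""

    gene_id: str
    group: str
    counts: dict[str, int]
    proportions: dict[str, float] | None  # percent; None when no sites

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class SequenceType:
    """A distinct full-length clone sequence (haplotype) within a scope."""

    type_id: str
    residues: str
    count: int
    members: tuple[str, ...]
    frequency: float


@dataclass(frozen=True)
class PairwiseDistance:
    """Per-column differences between two aligned clone rows.

    Differences count residue-vs-residue mismatches and gap-vs-residue
    columns; gap-vs-gap matches and any column with N in either row is
    excluded from the comparison entirely.
    """

    clone_a: str
    clone_b: str
    differing_columns: int
    compared_columns: int

    @property
    def p_distance(self) -> float:
        return self.differing_columns / self.compared_columns

    @property
    def divergence_pct(self) -> float:
        return self.p_distance * 100.0

    @property
    def similarity_pct(self) -> float:
        return (1.0 - self.p_distance) * 100.0


@dataclass(frozen=True)
class DiversitySummary:
    """One row of the hierarchical diversity table.

    max_divergence_pct and min_similarity_pct are raw (unrounded)
    percentages; formatting to 2 decimals happens at report-writing time.
    min_divergence_pct is only populated for interspecific rows.
    """

    gene_id: str
    level: str
    group: str
    n_clones: int
    n_polymorphic_sites: int
    max_divergence_pct: float | None
    min_similarity_pct: float | None
    pi: float | None
    n_types: int | None = None
    min_divergence_pct: float | None = None


@dataclass(frozen=True)
class BarcodeGapVerdict:
    """Does the largest intraspecific divergence stay below the smallest
    interspecific one for this gene?"""

    gene_id: str
    max_intraspecific_pct: float | None
    min_interspecific_pct: float | None
    gap_holds: bool | None
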