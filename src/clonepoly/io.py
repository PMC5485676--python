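"""Reading and writing of external artifacts.

Formats are deliberately minimal and bit-exact:

* aligned multi-FASTA, one gene per file (read via Bio.SeqIO, written as
  plain single-line records so re-runs are byte-identical);
* sample sheet: TSV with header ``clone_id  isolate_id  species_id  gene_id``;
* region annotation: TSV with header ``start  end  region_type  frame_offset``
  (frame_offset filled on the first exon row, blank elsewhere);
* report tables: TSV with LF line endings and a fixed column order, plus a
  JSON mirror.  Percentages are formatted to 2 decimals and nucleotide
  diversity to 4.

Input FASTA must already be aligned; ragged records are an error, never
silently re-aligned (see `clonepoly.align` for the explicit opt-in aligner).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import (
    AlignmentInputError,
    AnnotationError,
    FormatError,
    MetadataError,
)
from .model import (
    ALPHABET,
    BarcodeGapVerdict,
    CloneAlignment,
    DiversitySummary,
    RegionAnnotation,
    RegionInterval,
    SampleRecord,
    SequenceType,
    SingletonEvent,
    SpectrumSummary,
    SITE_CLASSES,
    VariantSite,
)
from .util import fmt_pct, fmt_pi, round_half_even

SAMPLE_SHEET_COLUMNS = ("clone_id", "isolate_id", "species_id", "gene_id")
ANNOTATION_COLUMNS = ("start", "end", "region_type", "frame_offset")


def read_sample_sheet(path: str | Path) -> list[SampleRecord]:
    """Parse the clone -> isolate -> species -> gene sample sheet."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty sample sheet") from None
        if tuple(h.strip() for h in header) != SAMPLE_SHEET_COLUMNS:
            raise FormatError(
                f"{path}: sample sheet header must be "
                f"{' / '.join(SAMPLE_SHEET_COLUMNS)}, got {header}"
            )
        records = []
        seen: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns, got {len(row)}")
            rec = SampleRecord(*(c.strip() for c in row))
            if rec.clone_id in seen:
                raise MetadataError(f"{path}:{lineno}: duplicate clone_id {rec.clone_id!r}")
            seen.add(rec.clone_id)
            records.append(rec)
    if not records:
        raise FormatError(f"{path}: sample sheet has no records")
    return records


def read_clone_fasta(
    path: str | Path, samples: str | Path | Sequence[SampleRecord]
) -> CloneAlignment:
    """Read an aligned clone FASTA and bind it to its sample sheet.

    Residues are upcased and U is mapped to T.  Every record id must have
    exactly one SampleRecord and vice versa; ragged record lengths and
    out-of-alphabet residues are hard errors.
    """
    path = Path(path)
    if not isinstance(samples, (str, Path)):
        records = list(samples)
    else:
        records = read_sample_sheet(samples)

    rows: dict[str, str] = {}
    order: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in rows:
            raise MetadataError(f"{path}: duplicate FASTA record id {rec.id!r}")
        seq = str(rec.seq).upper().replace("U", "T")
        bad = set(seq) - ALPHABET
        if bad:
            col = next(i + 1 for i, ch in enumerate(seq) if ch not in ALPHABET)
            raise FormatError(
                f"{path}: illegal residue {sorted(bad)[0]!r} in record "
                f"{rec.id!r} at column {col}"
            )
        rows[rec.id] = seq
        order.append(rec.id)
    if not rows:
        raise FormatError(f"{path}: no records")

    first = order[0]
    for cid in order:
        if len(rows[cid]) != len(rows[first]):
            raise AlignmentInputError(
                f"{path}: record {cid!r} has length {len(rows[cid])} but "
                f"{first!r} has {len(rows[first])}; input must be aligned"
            )

    by_id = {r.clone_id: r for r in records}
    unknown = [cid for cid in order if cid not in by_id]
    if unknown:
        raise MetadataError(f"{path}: clone id(s) not in sample sheet: {unknown}")
    absent = sorted(set(by_id) - set(order))
    if absent:
        raise MetadataError(f"{path}: sample sheet clone(s) missing from FASTA: {absent}")

    genes = {by_id[cid].gene_id for cid in order}
    if len(genes) != 1:
        raise MetadataError(f"{path}: clones span multiple genes {sorted(genes)}")

    return CloneAlignment(
        gene_id=genes.pop(),
        clone_ids=tuple(order),
        rows=rows,
        samples={cid: by_id[cid] for cid in order},
    )


def write_clone_fasta(aln: CloneAlignment, path: str | Path) -> Path:
    """Write aligned clones as single-line FASTA records (deterministic)."""
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        for cid in aln.clone_ids:
            fh.write(f">{cid}\n{aln.rows[cid]}\n")
    return path


def write_sample_sheet(records: Iterable[SampleRecord], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        fh.write("\t".join(SAMPLE_SHEET_COLUMNS) + "\n")
        for r in records:
            fh.write(f"{r.clone_id}\t{r.isolate_id}\t{r.species_id}\t{r.gene_id}\n")
    return path


def read_annotation(
    path: str | Path, columns: int, gene_id: str = ""
) -> RegionAnnotation:
    """Read the 4-column region annotation TSV and check full coverage."""
    path = Path(path)
    intervals: list[RegionInterval] = []
    frame_offset: int | None = None
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        first = True
        for lineno, row in enumerate(reader, start=1):
            if not row or all(not c.strip() for c in row):
                continue
            if first and not row[0].strip().isdigit():
                if tuple(c.strip() for c in row[:4]) != ANNOTATION_COLUMNS:
                    raise FormatError(
                        f"{path}:{lineno}: annotation header must be "
                        f"{' / '.join(ANNOTATION_COLUMNS)}"
                    )
                first = False
                continue
            first = False
            if len(row) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 columns")
            try:
                start, end = int(row[0]), int(row[1])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            region_type = row[2].strip()
            if len(row) > 3 and row[3].strip():
                fo = int(row[3])
                if frame_offset is not None and frame_offset != fo:
                    raise AnnotationError(f"{path}:{lineno}: conflicting frame_offset values")
                frame_offset = fo
            intervals.append(RegionInterval(start, end, region_type))
    if not intervals:
        raise FormatError(f"{path}: no intervals")
    intervals.sort(key=lambda iv: iv.start)
    ann = RegionAnnotation(gene_id=gene_id, intervals=tuple(intervals), frame_offset=frame_offset)
    ann.validate_coverage(columns)
    return ann


def write_annotation(ann: RegionAnnotation, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        wrote_frame = False
        for iv in ann.intervals:
            frame = ""
            if iv.region_type == "exon" and not wrote_frame:
                frame = str(ann.frame_offset)
                wrote_frame = True
            fh.write(f"{iv.start}\t{iv.end}\t{iv.region_type}\t{frame}\n")
    return path


def write_singleton_audit(events: Iterable[SingletonEvent], path: str | Path) -> Path:
    """TSV audit of every applied singleton correction."""
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        fh.write("clone_id\tcolumn\tobserved_allele\tcorrected_to\tisolate_id\n")
        for e in sorted(events, key=lambda e: (e.isolate_id, e.column, e.clone_id)):
            fh.write(
                f"{e.clone_id}\t{e.column}\t{e.observed_allele}\t"
                f"{e.corrected_to}\t{e.isolate_id}\n"
            )
    return path


def _alleles_str(counts: dict[str, int]) -> str:
    return ",".join(f"{a}:{n}" for a, n in sorted(counts.items()))


def write_reports(
    outdir: str | Path,
    *,
    summaries: Sequence[DiversitySummary],
    verdicts: Sequence[BarcodeGapVerdict] = (),
    sites: Sequence[VariantSite] = (),
    spectra: Sequence[SpectrumSummary] = (),
    types: Sequence[tuple[str, str, SequenceType]] = (),
    indel_events: Sequence[tuple[str, str, int, int]] = (),
) -> dict[str, Path]:
    """Write the deterministic TSV report set plus a JSON mirror.

    `types` rows are (level, group, SequenceType); `indel_events` rows are
    (level, group, start_column, end_column) of merged gap runs.
    Re-running on identical input yields byte-identical files.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        p = outdir / "diversity_summary.tsv"
        with p.open("w", newline="\n") as fh:
            fh.write(
                "gene_id\tlevel\tgroup\tn_clones\tn_polymorphic_sites\tn_types\t"
                "max_divergence_pct\tmin_divergence_pct\tmin_similarity_pct\tpi\n"
            )
            for s in summaries:
                fh.write(
                    f"{s.gene_id}\t{s.level}\t{s.group}\t{s.n_clones}\t"
                    f"{s.n_polymorphic_sites}\t{'' if s.n_types is None else s.n_types}\t"
                    f"{fmt_pct(s.max_divergence_pct)}\t{fmt_pct(s.min_divergence_pct)}\t"
                    f"{fmt_pct(s.min_similarity_pct)}\t{fmt_pi(s.pi)}\n"
                )
        paths["diversity_summary"] = p

        p = outdir / "barcode_gap.tsv"
        with p.open("w", newline="\n") as fh:
            fh.write("gene_id\tmax_intraspecific_pct\tmin_interspecific_pct\tgap_holds\n")
            for v in verdicts:
                holds = "" if v.gap_holds is None else str(v.gap_holds).lower()
                fh.write(
                    f"{v.gene_id}\t{fmt_pct(v.max_intraspecific_pct)}\t"
                    f"{fmt_pct(v.min_interspecific_pct)}\t{holds}\n"
                )
        paths["barcode_gap"] = p

        p = outdir / "variant_sites.tsv"
        with p.open("w", newline="\n") as fh:
            fh.write(
                "gene_id\tlevel\tgroup\tcolumn\talleles\tsite_class\t"
                "region_type\tcoding_effect\tflags\n"
            )
            for s in sites:
                fh.write(
                    f"{s.gene_id}\t{s.level}\t{s.group}\t{s.column}\t"
                    f"{_alleles_str(s.allele_counts)}\t{s.site_class}\t"
                    f"{s.region_type}\t{s.coding_effect}\t{';'.join(s.flags)}\n"
                )
        paths["variant_sites"] = p

        p = outdir / "spectrum.tsv"
        with p.open("w", newline="\n") as fh:
            head = "\t".join(
                [f"n_{c}" for c in SITE_CLASSES] + [f"pct_{c}" for c in SITE_CLASSES]
            )
            fh.write(f"gene_id\tgroup\tn_sites\t{head}\n")
            for sp in spectra:
                counts = "\t".join(str(sp.counts.get(c, 0)) for c in SITE_CLASSES)
                if sp.proportions is None:
                    pcts = "\t".join("" for _ in SITE_CLASSES)
                else:
                    pcts = "\t".join(fmt_pct(sp.proportions.get(c, 0.0)) for c in SITE_CLASSES)
                fh.write(f"{sp.gene_id}\t{sp.group}\t{sp.total}\t{counts}\t{pcts}\n")
        paths["spectrum"] = p

        if types:
            p = outdir / "sequence_types.tsv"
            with p.open("w", newline="\n") as fh:
                fh.write("level\tgroup\ttype_id\tcount\tfrequency\tmembers\n")
                for level, group, t in types:
                    fh.write(
                        f"{level}\t{group}\t{t.type_id}\t{t.count}\t"
                        f"{round_half_even(t.frequency, 4):.4f}\t{','.join(t.members)}\n"
                    )
            paths["sequence_types"] = p

        if indel_events:
            p = outdir / "indel_events.tsv"
            with p.open("w", newline="\n") as fh:
                fh.write("level\tgroup\tstart\tend\tlength\n")
                for level, group, start, end in indel_events:
                    fh.write(f"{level}\t{group}\t{start}\t{end}\t{end - start + 1}\n")
            paths["indel_events"] = p

        mirror = {
            "diversity_summary": [
                {
                    "gene_id": s.gene_id,
                    "level": s.level,
                    "group": s.group,
                    "n_clones": s.n_clones,
                    "n_polymorphic_sites": s.n_polymorphic_sites,
                    "n_types": s.n_types,
                    "max_divergence_pct": None
                    if s.max_divergence_pct is None
                    else round_half_even(s.max_divergence_pct, 2),
                    "min_divergence_pct": None
                    if s.min_divergence_pct is None
                    else round_half_even(s.min_divergence_pct, 2),
                    "min_similarity_pct": None
                    if s.min_similarity_pct is None
                    else round_half_even(s.min_similarity_pct, 2),
                    "pi": None if s.pi is None else round_half_even(s.pi, 4),
                }
                for s in summaries
            ],
            "barcode_gap": [
                {
                    "gene_id": v.gene_id,
                    "max_intraspecific_pct": None
                    if v.max_intraspecific_pct is None
                    else round_half_even(v.max_intraspecific_pct, 2),
                    "min_interspecific_pct": None
                    if v.min_interspecific_pct is None
                    else round_half_even(v.min_interspecific_pct, 2),
                    "gap_holds": v.gap_holds,
                }
                for v in verdicts
            ],
            "variant_sites": [
                {
                    "gene_id": s.gene_id,
                    "level": s.level,
                    "group": s.group,
                    "column": s.column,
                    "allele_counts": dict(sorted(s.allele_counts.items())),
                    "site_class": s.site_class,
                    "region_type": s.region_type,
                    "coding_effect": s.coding_effect,
                    "flags": list(s.flags),
                }
                for s in sites
            ],
            "spectrum": [
                {
                    "gene_id": sp.gene_id,
                    "group": sp.group,
                    "n_sites": sp.total,
                    "counts": {c: sp.counts.get(c, 0) for c in SITE_CLASSES},
                    "proportions_pct": None
                    if sp.proportions is None
                    else {
                        c: round_half_even(sp.proportions.get(c, 0.0), 2)
                        for c in SITE_CLASSES
                    },
                }
                for sp in spectra
            ],
        }
        p = outdir / "report.json"
        with p.open("w", newline="\n") as fh:
            json.dump(mirror, fh, indent=1, sort_keys=True)
            fh.write("\n")
        paths["report_json"] = p
        return paths
    except OSError as exc:
        raise FormatError(f"failed writing reports under {outdir}: {exc}") from exc
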