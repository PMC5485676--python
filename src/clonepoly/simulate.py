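"""Synthetic cloned-amplicon datasets with ground truth.

The generator emulates the design of clone-based heterogeneity surveys of
fungal marker genes: a few species, a few isolates per species, ~30
sequenced clones per isolate and gene, alignments of ~560-600 columns with
either ITS1/5.8S/ITS2 or exon/intron structure.  Variation is *planted* at
three hierarchical levels —

* interspecific sites: one species' clones all carry the alternate allele;
* intraspecific sites: all clones of a proper subset of one species'
  isolates carry it;
* intra-isolate sites: a minor subset (>= 2 clones, so never a singleton)
  of one isolate's clones carry it;

— plus optional multi-column indel runs, tri-morphic columns, and per-base
per-clone PCR errors (substitutions private to one clone, the "singletons"
that the error filter must remove).  Planted substitution alleles follow a
configurable transition:transversion ratio; exon substitutions are
constrained synonymous with probability `syn_fraction` by snapping the
site to the third position of a four-fold degenerate codon (and
nonsynonymous sites to the first or second position of a codon verified to
change its amino acid).

Everything is deterministic given the seed, and the emitted `SimTruth`
records every planted site and error so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import GenerationError, InputError
from .model import (
    BASES,
    GAP,
    CloneAlignment,
    RegionAnnotation,
    RegionInterval,
    SampleRecord,
    SingletonEvent,
    VariantSite,
)

TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSION_PARTNERS = {
    "A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G"),
}
# codon prefixes whose third position is fully degenerate (Ala, Arg4, Gly,
# Leu4, Pro, Ser4, Thr, Val)
FOURFOLD_PREFIXES = ("GC", "CG", "GG", "CT", "CC", "TC", "AC", "GT")


def its_annotation(length: int, gene_id: str = "ITS") -> RegionAnnotation:
    """ITS1 / 5.8S / ITS2 split in roughly the proportions of the fungal
    rDNA internal transcribed spacer region (for 581 columns: 1-200,
    201-358, 359-581)."""
    if length < 10:
        return RegionAnnotation(gene_id, (RegionInterval(1, length, "other"),))
    a = round(length * 200 / 581)
    b = round(length * 358 / 581)
    return RegionAnnotation(
        gene_id,
        (
            RegionInterval(1, a, "ITS1"),
            RegionInterval(a + 1, b, "5.8S"),
            RegionInterval(b + 1, length, "ITS2"),
        ),
    )


def exon_intron_annotation(
    length: int,
    intron: tuple[int, int],
    frame_offset: int = 0,
    gene_id: str = "RPB2",
) -> RegionAnnotation:
    """Two exons flanking one intron, the layout of the protein-coding
    marker amplicons (RPB2/EF1a)."""
    s, e = intron
    if not 1 < s <= e < length:
        raise InputError("intron must lie strictly inside the alignment")
    return RegionAnnotation(
        gene_id,
        (
            RegionInterval(1, s - 1, "exon"),
            RegionInterval(s, e, "intron"),
            RegionInterval(e + 1, length, "exon"),
        ),
        frame_offset=frame_offset,
    )


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters.  Defaults mirror the sampling design of the
    clone surveys this package analyses: 3 species x 3 isolates x 30
    clones of an ITS-like 581-column alignment, ITS-scale planted
    variation, and a low per-base PCR error rate."""

    seed: int = 0
    gene_id: str = "ITS"
    n_species: int = 3
    isolates_per_species: int = 3
    clones_per_isolate: int = 30
    alignment_length: int = 581
    annotation: RegionAnnotation | None = None
    interspecific_sites: int = 17
    intraspecific_sites: int = 4  # per species
    intra_isolate_sites: int = 2  # per isolate
    minor_count: int = 3
    indel_events: tuple[tuple[int, int], ...] = ()  # (start, length)
    trimorphic_sites: int = 0
    pcr_error_rate: float = 0.002
    pcr_errors_exact: int | None = None
    ts_tv_ratio: float = 2.0
    syn_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 <= self.pcr_error_rate <= 0.01:
            raise InputError("pcr_error_rate must lie in [0, 0.01]")
        if self.minor_count < 2:
            raise InputError("minor_count must be >= 2 (true variants are never singletons)")
        if self.n_species < 1 or self.isolates_per_species < 1:
            raise InputError("need at least one species and isolate")
        if self.clones_per_isolate < 2:
            raise InputError("need at least 2 clones per isolate")
        if self.interspecific_sites and self.n_species < 2:
            raise InputError("interspecific sites need >= 2 species")
        if self.intraspecific_sites and self.isolates_per_species < 2:
            raise InputError("intraspecific sites need >= 2 isolates per species")
        if self.intra_isolate_sites and self.minor_count >= self.clones_per_isolate:
            raise InputError("minor_count must be < clones_per_isolate")
        if self.trimorphic_sites and 2 * self.minor_count >= self.clones_per_isolate:
            raise InputError("trimorphic sites need clones_per_isolate > 2*minor_count")
        if not 0.0 <= self.syn_fraction <= 1.0:
            raise InputError("syn_fraction must lie in [0, 1]")
        if self.ts_tv_ratio <= 0:
            raise InputError("ts_tv_ratio must be positive")


@dataclass(frozen=True)
class PlantedSite:
    column: int
    category: str  # interspecific | intraspecific | intra_isolate | trimorphic | indel
    group: str  # species or isolate label owning the variant
    ref_allele: str
    alt_alleles: tuple[str, ...]
    carriers: tuple[str, ...]
    intended_class: str
    intended_effect: str | None = None
    event: tuple[int, int] | None = None  # (start, length) for indel runs


@dataclass(frozen=True)
class PlantedError:
    clone_id: str
    isolate_id: str
    column: int
    from_allele: str
    to_allele: str


@dataclass(frozen=True)
class SimTruth:
    sites: tuple[PlantedSite, ...]
    errors: tuple[PlantedError, ...]
    species_roots: dict[str, str]
    clean_rows: dict[str, str]  # rows before PCR errors
    config: SimConfig

    @property
    def site_columns(self) -> set[int]:
        return {s.column for s in self.sites}


def _classify_pair(ref: str, alt: str) -> str:
    pair = {ref, alt}
    if pair == {"C", "T"}:
        return "transition_CT"
    if pair == {"A", "G"}:
        return "transition_AG"
    return "transversion"


class _Generator:
    def __init__(self, config: SimConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.L = config.alignment_length
        self.ann = config.annotation or its_annotation(self.L, config.gene_id)
        self.ann.validate_coverage(self.L)
        self.used: set[int] = set()
        self.used_codons: set[int] = set()
        self.sites: list[PlantedSite] = []

        self.species_ids = [f"sp{i + 1}" for i in range(config.n_species)]
        self.isolate_ids: dict[str, list[str]] = {
            sp: [f"{sp}_iso{j + 1}" for j in range(config.isolates_per_species)]
            for sp in self.species_ids
        }
        self.clone_ids: dict[str, list[str]] = {}
        self.samples: list[SampleRecord] = []
        for sp in self.species_ids:
            for iso in self.isolate_ids[sp]:
                clones = [
                    f"{iso}_cl{k + 1:02d}" for k in range(config.clones_per_isolate)
                ]
                self.clone_ids[iso] = clones
                self.samples.extend(
                    SampleRecord(c, iso, sp, config.gene_id) for c in clones
                )

        self.indel_cols: set[int] = set()
        for start, length in config.indel_events:
            cols = set(range(start, start + length))
            if not cols <= set(range(1, self.L + 1)):
                raise GenerationError(
                    f"indel event ({start},{length}) exceeds alignment length {self.L}"
                )
            if cols & self.indel_cols:
                raise GenerationError("indel events overlap")
            self.indel_cols |= cols

        # codon bookkeeping over the ungapped ancestor (exon columns in
        # annotation order, framed at frame_offset)
        self.exon_cols = [
            col
            for iv in self.ann.exon_intervals()
            for col in range(iv.start, iv.end + 1)
        ]
        self.codons: list[tuple[int, int, int]] = []  # complete codons, columns
        if self.exon_cols:
            fo = self.ann.frame_offset or 0
            framed = self.exon_cols[fo:]
            for k in range(0, len(framed) - 2, 3):
                tri = tuple(framed[k : k + 3])
                if not (set(tri) & self.indel_cols):
                    self.codons.append(tri)  # type: ignore[arg-type]

    # -- column accounting ------------------------------------------------
    def _free_columns(self) -> list[int]:
        return [
            c
            for c in range(1, self.L + 1)
            if c not in self.used and c not in self.indel_cols
        ]

    def _take_noncoding(self) -> int:
        pool = [c for c in self._free_columns() if self.ann.region_at(c) != "exon"]
        if not pool:
            raise GenerationError(
                "no free non-coding column left; increase alignment_length"
            )
        col = int(self.rng.choice(pool))
        self.used.add(col)
        return col

    def _take_codon(self) -> tuple[int, int, int]:
        pool = [
            i
            for i, tri in enumerate(self.codons)
            if i not in self.used_codons and not (set(tri) & self.used)
        ]
        if not pool:
            raise GenerationError("no free codon left; increase alignment_length")
        i = int(self.rng.choice(pool))
        self.used_codons.add(i)
        return self.codons[i]

    # -- allele drawing ---------------------------------------------------
    def _draw_transition(self) -> bool:
        r = self.cfg.ts_tv_ratio
        return bool(self.rng.random() < r / (r + 1.0))

    def _draw_alt(self, ref: str) -> str:
        if self._draw_transition():
            return TRANSITION_PARTNER[ref]
        return str(self.rng.choice(TRANSVERSION_PARTNERS[ref]))

    # -- substitution-site planting --------------------------------------
    def _plant_substitution(self, category: str, group: str, carriers: Sequence[str]) -> None:
        """Choose a column, realize the intended coding effect on the
        ancestor, and record the planted site."""
        free = self._free_columns()
        if not free:
            raise GenerationError(
                f"cannot place {category} site: alignment_length {self.L} too cramped"
            )
        col = int(self.rng.choice(free))
        if self.ann.region_at(col) == "exon":
            want_syn = bool(self.rng.random() < self.cfg.syn_fraction)
            self._plant_exon(category, group, carriers, want_syn)
        else:
            self.used.add(col)
            ref = self.ancestor[col - 1]
            alt = self._draw_alt(ref)
            self.sites.append(
                PlantedSite(
                    column=col, category=category, group=group,
                    ref_allele=ref, alt_alleles=(alt,), carriers=tuple(carriers),
                    intended_class=_classify_pair(ref, alt),
                    intended_effect="noncoding",
                )
            )

    def _plant_exon(
        self, category: str, group: str, carriers: Sequence[str], want_syn: bool
    ) -> None:
        from Bio.Seq import Seq

        tri = self._take_codon()
        if want_syn:
            prefix = FOURFOLD_PREFIXES[int(self.rng.integers(len(FOURFOLD_PREFIXES)))]
            self.ancestor[tri[0] - 1] = prefix[0]
            self.ancestor[tri[1] - 1] = prefix[1]
            col = tri[2]
            ref = self.ancestor[col - 1]
            alt = self._draw_alt(ref)
            effect = "synonymous"
        else:
            within = int(self.rng.integers(2))  # first or second codon position
            col = tri[within]
            codon = "".join(self.ancestor[c - 1] for c in tri)
            ref = codon[within]
            ref_aa = str(Seq(codon).translate())
            preferred = self._draw_alt(ref)
            candidates = [preferred] + [b for b in BASES if b not in (ref, preferred)]
            alt = None
            for cand in candidates:
                alt_codon = codon[:within] + cand + codon[within + 1 :]
                aa = str(Seq(alt_codon).translate())
                if aa != ref_aa and aa != "*":
                    alt = cand
                    break
            if alt is None:
                # degenerate first-position family (Leu/Arg): rewrite the
                # codon to Lys and substitute the first position
                for c, b in zip(tri, "AAA"):
                    self.ancestor[c - 1] = b
                within, col, ref = 0, tri[0], "A"
                alt = "G" if self._draw_transition() else "C"
            effect = "nonsynonymous"
        self.used.update(tri)
        self.sites.append(
            PlantedSite(
                column=col, category=category, group=group,
                ref_allele=ref, alt_alleles=(alt,), carriers=tuple(carriers),
                intended_class=_classify_pair(ref, alt),
                intended_effect=effect,
            )
        )

    def _plant_trimorphic(self, group: str, carriers_a: Sequence[str], carriers_b: Sequence[str]) -> None:
        col = self._take_noncoding()
        ref = self.ancestor[col - 1]
        alt1 = TRANSITION_PARTNER[ref]
        alt2 = TRANSVERSION_PARTNERS[ref][int(self.rng.integers(2))]
        self.sites.append(
            PlantedSite(
                column=col, category="trimorphic", group=group,
                ref_allele=ref, alt_alleles=(alt1, alt2),
                carriers=tuple(carriers_a) + tuple(carriers_b),
                intended_class="trimorphic",
                intended_effect="noncoding",
            )
        )
        self._tri_map[col] = (tuple(carriers_a), alt1, tuple(carriers_b), alt2)

    # -- main -------------------------------------------------------------
    def run(self) -> tuple[CloneAlignment, list[SampleRecord], RegionAnnotation, SimTruth]:
        cfg = self.cfg
        self.ancestor = [str(b) for b in self.rng.choice(list(BASES), size=self.L)]
        self._tri_map: dict[int, tuple[tuple[str, ...], str, tuple[str, ...], str]] = {}

        all_isolates = [iso for sp in self.species_ids for iso in self.isolate_ids[sp]]

        # interspecific sites: all clones of one randomly chosen species
        for _ in range(cfg.interspecific_sites):
            sp = self.species_ids[int(self.rng.integers(cfg.n_species))]
            carriers = [c for iso in self.isolate_ids[sp] for c in self.clone_ids[iso]]
            self._plant_substitution("interspecific", sp, carriers)

        # intraspecific sites: a proper non-empty subset of a species' isolates
        for sp in self.species_ids:
            for _ in range(cfg.intraspecific_sites):
                k = int(self.rng.integers(1, cfg.isolates_per_species))
                chosen = self.rng.choice(self.isolate_ids[sp], size=k, replace=False)
                carriers = [c for iso in chosen for c in self.clone_ids[iso]]
                self._plant_substitution("intraspecific", sp, carriers)

        # intra-isolate sites: minor_count carrier clones inside one isolate
        for iso in all_isolates:
            for _ in range(cfg.intra_isolate_sites):
                carriers = [
                    str(c)
                    for c in self.rng.choice(
                        self.clone_ids[iso], size=cfg.minor_count, replace=False
                    )
                ]
                self._plant_substitution("intra_isolate", iso, carriers)

        # trimorphic sites: two disjoint minor carrier sets in one isolate
        for t in range(cfg.trimorphic_sites):
            iso = all_isolates[t % len(all_isolates)]
            picked = self.rng.choice(
                self.clone_ids[iso], size=2 * cfg.minor_count, replace=False
            )
            self._plant_trimorphic(
                iso,
                [str(c) for c in picked[: cfg.minor_count]],
                [str(c) for c in picked[cfg.minor_count :]],
            )

        # indel runs: minor_count carrier clones of a rotating isolate
        indel_sites: list[PlantedSite] = []
        for e, (start, length) in enumerate(cfg.indel_events):
            iso = all_isolates[(cfg.trimorphic_sites + e) % len(all_isolates)]
            carriers = tuple(
                str(c)
                for c in self.rng.choice(
                    self.clone_ids[iso], size=cfg.minor_count, replace=False
                )
            )
            regions = {self.ann.region_at(c) for c in range(start, start + length)}
            if regions == {"exon"}:
                effect = "nonsynonymous" if length % 3 == 0 else "frameshift"
            elif "exon" in regions:
                effect = None  # straddles a boundary; effect judged per column
            else:
                effect = "noncoding"
            for col in range(start, start + length):
                indel_sites.append(
                    PlantedSite(
                        column=col, category="indel", group=iso,
                        ref_allele=self.ancestor[col - 1], alt_alleles=(GAP,),
                        carriers=carriers, intended_class="indel",
                        intended_effect=effect, event=(start, length),
                    )
                )
        self.sites.extend(indel_sites)

        # realize rows ----------------------------------------------------
        roots: dict[str, list[str]] = {
            sp: list(self.ancestor) for sp in self.species_ids
        }
        for s in self.sites:
            if s.category == "interspecific":
                roots[s.group][s.column - 1] = s.alt_alleles[0]
        species_roots = {sp: "".join(r) for sp, r in roots.items()}

        rows: dict[str, list[str]] = {}
        for sp in self.species_ids:
            for iso in self.isolate_ids[sp]:
                for c in self.clone_ids[iso]:
                    rows[c] = list(roots[sp])
        for s in self.sites:
            if s.category == "interspecific":
                continue
            if s.category == "trimorphic":
                ca, a1, cb, a2 = self._tri_map[s.column]
                for c in ca:
                    rows[c][s.column - 1] = a1
                for c in cb:
                    rows[c][s.column - 1] = a2
            else:
                for c in s.carriers:
                    rows[c][s.column - 1] = s.alt_alleles[0]

        clean_rows = {c: "".join(r) for c, r in rows.items()}

        # PCR errors ------------------------------------------------------
        errors: list[PlantedError] = []
        planted_cols = {s.column for s in self.sites}
        eligible = [
            c for c in range(1, self.L + 1)
            if c not in planted_cols and c not in self.indel_cols
        ]
        ordered_clones = [r.clone_id for r in self.samples]
        iso_of = {r.clone_id: r.isolate_id for r in self.samples}
        if cfg.pcr_errors_exact is not None:
            if cfg.pcr_errors_exact > len(eligible):
                raise GenerationError("not enough error-free columns for exact errors")
            cols = self.rng.choice(eligible, size=cfg.pcr_errors_exact, replace=False)
            for col in sorted(int(c) for c in cols):
                clone = ordered_clones[int(self.rng.integers(len(ordered_clones)))]
                errors.append(self._apply_error(rows, clone, iso_of[clone], col))
        elif cfg.pcr_error_rate > 0:
            hits = self.rng.random((len(ordered_clones), len(eligible))) < cfg.pcr_error_rate
            for ci, col_i in zip(*np.nonzero(hits)):
                clone = ordered_clones[int(ci)]
                col = eligible[int(col_i)]
                errors.append(self._apply_error(rows, clone, iso_of[clone], col))

        aln = CloneAlignment(
            gene_id=cfg.gene_id,
            clone_ids=tuple(ordered_clones),
            rows={c: "".join(r) for c, r in rows.items()},
            samples={r.clone_id: r for r in self.samples},
        )
        truth = SimTruth(
            sites=tuple(self.sites),
            errors=tuple(errors),
            species_roots=species_roots,
            clean_rows=clean_rows,
            config=cfg,
        )
        self._verify(truth)
        return aln, list(self.samples), self.ann, truth

    def _apply_error(
        self, rows: dict[str, list[str]], clone: str, isolate: str, col: int
    ) -> PlantedError:
        current = rows[clone][col - 1]
        alts = [b for b in BASES if b != current]
        alt = alts[int(self.rng.integers(len(alts)))]
        rows[clone][col - 1] = alt
        return PlantedError(
            clone_id=clone, isolate_id=isolate, column=col,
            from_allele=current, to_allele=alt,
        )

    def _verify(self, truth: SimTruth) -> None:
        cols = [s.column for s in truth.sites]
        if len(cols) != len(set(cols)):
            raise GenerationError("planted site columns collide (generator bug)")
        cfg = self.cfg
        n_iso = cfg.n_species * cfg.isolates_per_species
        expected = (
            cfg.interspecific_sites
            + cfg.n_species * cfg.intraspecific_sites
            + n_iso * cfg.intra_isolate_sites
            + cfg.trimorphic_sites
            + sum(length for _, length in cfg.indel_events)
        )
        if len(truth.sites) != expected:
            raise GenerationError(
                f"planted {len(truth.sites)} sites but config implies {expected}"
            )


def simulate(
    config: SimConfig,
) -> tuple[CloneAlignment, list[SampleRecord], RegionAnnotation, SimTruth]:
    """Generate one dataset; deterministic given `config.seed`."""
    return _Generator(config).run()


def expected_singleton_recall(error_rate: float, n_clones: int) -> float:
    """Closed-form expectation of the singleton filter's recall of planted
    PCR errors.

    An error at (clone, column) stays a detectable single-occurrence allele
    unless some other clone of the same isolate draws an error at the same
    column *with the same allele* (probability error_rate/3 per clone,
    alleles uniform over the 3 alternatives), which lifts its count to 2.
    Errors with different alleles at one column remain singletons.  Hence
    recall = (1 - e/3)^(n-1).
    """
    return (1.0 - error_rate / 3.0) ** (n_clones - 1)


@dataclass(frozen=True)
class RecoveryReport:
    """Agreement between pipeline output and generator truth."""

    site_recall: float
    site_precision: float
    class_accuracy: float
    effect_accuracy: float | None
    singleton_recall: float
    n_planted_errors: int
    n_recovered_errors: int
    false_corrections: int
    false_correction_rate: float
    type_counts_match: float  # fraction of isolates with matching type counts

    def to_dict(self) -> dict:
        return {
            "site_recall": self.site_recall,
            "site_precision": self.site_precision,
            "class_accuracy": self.class_accuracy,
            "effect_accuracy": self.effect_accuracy,
            "singleton_recall": self.singleton_recall,
            "n_planted_errors": self.n_planted_errors,
            "n_recovered_errors": self.n_recovered_errors,
            "false_corrections": self.false_corrections,
            "false_correction_rate": self.false_correction_rate,
            "type_counts_match": self.type_counts_match,
        }


def truth_compare(
    *,
    corrected: CloneAlignment,
    events: Sequence[SingletonEvent],
    sites: Sequence[VariantSite],
    truth: SimTruth,
) -> RecoveryReport:
    """Score site calling, classification, effects, singleton correction
    and type counts against the planted truth.

    `sites` should be called on the union of all clones of the corrected
    alignment (every planted site is polymorphic there).
    """
    if set(corrected.clone_ids) != set(truth.clean_rows):
        raise InputError("alignment and truth describe different clone sets")

    planted = {s.column: s for s in truth.sites}
    called = {s.column: s for s in sites}
    hit = set(planted) & set(called)
    site_recall = len(hit) / len(planted) if planted else 1.0
    site_precision = len(hit) / len(called) if called else 1.0

    class_ok = sum(1 for c in hit if called[c].site_class == planted[c].intended_class)
    class_accuracy = class_ok / len(hit) if hit else 1.0

    effect_cols = [
        c
        for c in hit
        if planted[c].intended_effect is not None and called[c].coding_effect
    ]
    if effect_cols:
        effect_ok = sum(
            1 for c in effect_cols
            if called[c].coding_effect == planted[c].intended_effect
        )
        effect_accuracy: float | None = effect_ok / len(effect_cols)
    else:
        effect_accuracy = None

    planted_err = {(e.clone_id, e.column) for e in truth.errors}
    event_keys = {(e.clone_id, e.column) for e in events}
    recovered = planted_err & event_keys
    singleton_recall = len(recovered) / len(planted_err) if planted_err else 1.0
    false_events = [e for e in events if (e.clone_id, e.column) not in planted_err]
    false_rate = len(false_events) / len(planted) if planted else (
        1.0 if false_events else 0.0
    )

    from .diversity import enumerate_types

    match = 0
    isolates = corrected.isolates()
    for iso, clones in isolates.items():
        got = len(enumerate_types(corrected, clones))
        want = len({truth.clean_rows[c] for c in clones})
        match += got == want
    type_match = match / len(isolates)

    return RecoveryReport(
        site_recall=site_recall,
        site_precision=site_precision,
        class_accuracy=class_accuracy,
        effect_accuracy=effect_accuracy,
        singleton_recall=singleton_recall,
        n_planted_errors=len(planted_err),
        n_recovered_errors=len(recovered),
        false_corrections=len(false_events),
        false_correction_rate=false_rate,
        type_counts_match=type_match,
    )
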