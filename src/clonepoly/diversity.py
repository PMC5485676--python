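"""Sequence types, pairwise divergence, and Nei-Li nucleotide diversity.

Conventions (chosen to reproduce printed similarity figures of cloned
amplicon studies, where a k-difference pair over an L-column alignment is
reported as k/L):

* pairwise divergence uses the full alignment column count as denominator,
  minus columns with N in either row; gap-vs-gap is a match, gap-vs-residue
  a difference, and each column of an indel run counts separately;
* nucleotide diversity pi is the mean pairwise number of differences per
  valid site.  The default "complete deletion" restricts to columns free of
  gaps and N in *every* row of the group (DnaSP-style); "pairwise" deletion
  instead drops only the columns invalid within each pair.  An alternative
  haplotype-frequency estimator with the n/(n-1) small-sample factor is
  available behind `estimator="haplotype"`.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

from .errors import InputError
from .model import (
    GAP,
    MISSING,
    BarcodeGapVerdict,
    CloneAlignment,
    DiversitySummary,
    PairwiseDistance,
    SequenceType,
)
from .util import round_half_even, unordered_pairs

logger = logging.getLogger(__name__)


def enumerate_types(aln: CloneAlignment, group: Sequence[str]) -> list[SequenceType]:
    """Partition a clone group into distinct full-length sequence types.

    Types are ordered by descending multiplicity, then by first occurrence
    in the group; frequencies are multiplicities over the group size.
    """
    group = list(group)
    if not group:
        raise InputError("cannot enumerate types of an empty group")
    members: dict[str, list[str]] = {}
    first_seen: dict[str, int] = {}
    for i, cid in enumerate(group):
        row = aln.rows[cid]
        members.setdefault(row, []).append(cid)
        first_seen.setdefault(row, i)
    ordered = sorted(members, key=lambda r: (-len(members[r]), first_seen[r]))
    total = len(group)
    return [
        SequenceType(
            type_id=f"T{i + 1}",
            residues=row,
            count=len(members[row]),
            members=tuple(members[row]),
            frequency=len(members[row]) / total,
        )
        for i, row in enumerate(ordered)
    ]


def pairwise_distance(
    a: str, b: str, clone_a: str = "a", clone_b: str = "b"
) -> PairwiseDistance:
    """Column-wise differences between two aligned rows (see module notes)."""
    if len(a) != len(b):
        raise InputError(f"rows differ in length ({len(a)} vs {len(b)})")
    compared = 0
    diffs = 0
    for x, y in zip(a, b):
        if x == MISSING or y == MISSING:
            continue
        compared += 1
        if x != y:  # gap-vs-gap is equality, hence a match
            diffs += 1
    if compared == 0:
        raise InputError("no comparable columns (all masked by N)")
    return PairwiseDistance(
        clone_a=clone_a, clone_b=clone_b, differing_columns=diffs, compared_columns=compared
    )


def _pair_diff_on(a: str, b: str, cols: Iterable[int]) -> int:
    return sum(1 for i in cols if a[i] != b[i])


def nucleotide_diversity(
    rows: Sequence[str],
    deletion: str = "complete",
    estimator: str = "mean_pairwise",
) -> float | None:
    """Nei-Li nucleotide diversity of a set of aligned rows.

    With complete deletion, pi = (sum over unordered pairs of per-pair
    differences) / n_pairs / L_valid, where L_valid counts columns with no
    gap and no N in any row.  Returns None (with a warning) when no valid
    column remains.
    """
    if len(rows) < 2:
        raise InputError("nucleotide diversity needs >= 2 rows")
    if len({len(r) for r in rows}) != 1:
        raise InputError("rows differ in length")
    if deletion not in ("complete", "pairwise"):
        raise InputError(f"unknown deletion mode {deletion!r}")
    if estimator not in ("mean_pairwise", "haplotype"):
        raise InputError(f"unknown estimator {estimator!r}")

    n = len(rows)
    if deletion == "complete":
        valid = [
            i
            for i in range(len(rows[0]))
            if all(r[i] != GAP and r[i] != MISSING for r in rows)
        ]
        if not valid:
            logger.warning("no gap/N-free column; nucleotide diversity undefined")
            return None

        def pair_pi(a: str, b: str) -> float:
            return _pair_diff_on(a, b, valid) / len(valid)

    else:

        def pair_pi(a: str, b: str) -> float:
            compared = diffs = 0
            for x, y in zip(a, b):
                if x in (GAP, MISSING) or y in (GAP, MISSING):
                    continue
                compared += 1
                if x != y:
                    diffs += 1
            if compared == 0:
                raise InputError("a pair shares no comparable column")
            return diffs / compared

    if estimator == "mean_pairwise":
        pis = [pair_pi(a, b) for a, b in unordered_pairs(rows)]
        return sum(pis) / len(pis)

    # haplotype-frequency form: pi = n/(n-1) * sum_{i != j} x_i x_j pi_ij
    seen: dict[str, int] = {}
    for r in rows:
        seen[r] = seen.get(r, 0) + 1
    haps = list(seen)
    total = 0.0
    for i, hi in enumerate(haps):
        for hj in haps[i + 1 :]:
            total += 2 * (seen[hi] / n) * (seen[hj] / n) * pair_pi(hi, hj)
    return total * n / (n - 1)


def _group_rows(aln: CloneAlignment, group: Sequence[str]) -> list[str]:
    return [aln.rows[c] for c in group]


def _pair_stats(
    aln: CloneAlignment, pairs: Iterable[tuple[str, str]]
) -> tuple[float, float] | None:
    """(max divergence %, min divergence %) over clone-id pairs, or None."""
    divs = [
        pairwise_distance(aln.rows[a], aln.rows[b], a, b).divergence_pct
        for a, b in pairs
    ]
    if not divs:
        return None
    return max(divs), min(divs)


def summarize_levels(
    aln: CloneAlignment,
    min_clones_note: int | None = None,
    pi_deletion: str = "complete",
    pi_estimator: str = "mean_pairwise",
) -> tuple[list[DiversitySummary], BarcodeGapVerdict]:
    """Hierarchical diversity table plus the barcoding-gap verdict.

    Emits one intra-isolate row per isolate, one intraspecific row per
    species, and one interspecific row per species pair.  The gap holds for
    the gene iff the largest intraspecific divergence is strictly below the
    smallest cross-species divergence.  Groups with a single clone yield
    rows with missing pairwise fields.
    """
    from .variants import call_sites  # local import to avoid a cycle

    summaries: list[DiversitySummary] = []

    def make_row(level: str, label: str, clones: Sequence[str]) -> DiversitySummary:
        n = len(clones)
        if n < 2:
            return DiversitySummary(
                gene_id=aln.gene_id, level=level, group=label, n_clones=n,
                n_polymorphic_sites=0, max_divergence_pct=None,
                min_similarity_pct=None, pi=None, n_types=1 if n else 0,
            )
        sites = call_sites(aln, clones, level=level, group_label=label)
        stats = _pair_stats(aln, unordered_pairs(clones))
        assert stats is not None
        max_div, _ = stats
        max_div = round_half_even(max_div, 2)
        pi = nucleotide_diversity(
            _group_rows(aln, clones), deletion=pi_deletion, estimator=pi_estimator
        )
        return DiversitySummary(
            gene_id=aln.gene_id, level=level, group=label, n_clones=n,
            n_polymorphic_sites=len(sites),
            max_divergence_pct=max_div,
            min_similarity_pct=100.0 - max_div,  # exact complement at 2 dp
            pi=pi,
            n_types=len(enumerate_types(aln, clones)),
        )

    isolates = aln.isolates()
    for isolate_id, clones in isolates.items():
        summaries.append(make_row("intra-isolate", isolate_id, clones))

    species = aln.species()
    max_intra: float | None = None
    for species_id, clones in species.items():
        row = make_row("intraspecific", species_id, clones)
        summaries.append(row)
        if row.max_divergence_pct is not None:
            max_intra = (
                row.max_divergence_pct
                if max_intra is None
                else max(max_intra, row.max_divergence_pct)
            )

    min_inter: float | None = None
    species_ids = list(species)
    for sa, sb in unordered_pairs(species_ids):
        cross = [(a, b) for a in species[sa] for b in species[sb]]
        stats = _pair_stats(aln, cross)
        union = list(species[sa]) + list(species[sb])
        label = f"{sa}|{sb}"
        sites = call_sites(aln, union, level="interspecific", group_label=label)
        if stats is None:
            summaries.append(
                DiversitySummary(
                    gene_id=aln.gene_id, level="interspecific", group=label,
                    n_clones=len(union), n_polymorphic_sites=len(sites),
                    max_divergence_pct=None, min_similarity_pct=None, pi=None,
                )
            )
            continue
        max_div, min_div = (round_half_even(v, 2) for v in stats)
        pi = nucleotide_diversity(
            _group_rows(aln, union), deletion=pi_deletion, estimator=pi_estimator
        )
        summaries.append(
            DiversitySummary(
                gene_id=aln.gene_id, level="interspecific", group=label,
                n_clones=len(union), n_polymorphic_sites=len(sites),
                max_divergence_pct=max_div,
                min_similarity_pct=100.0 - max_div,
                pi=pi,
                n_types=len(enumerate_types(aln, union)),
                min_divergence_pct=min_div,
            )
        )
        min_inter = min_div if min_inter is None else min(min_inter, min_div)

    if max_intra is None or min_inter is None:
        gap_holds = None
    else:
        gap_holds = max_intra < min_inter
    verdict = BarcodeGapVerdict(
        gene_id=aln.gene_id,
        max_intraspecific_pct=max_intra,
        min_interspecific_pct=min_inter,
        gap_holds=gap_holds,
    )
    return summaries, verdict
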