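"""Polymorphic-site calling and substitution-spectrum classification.

A *site* is an alignment column where at least two distinct non-N alleles
(gap included) occur within the group of clones under consideration.  Each
site falls into exactly one spectrum class:

* ``indel``         — a gap allele is present (gap dominance keeps the
                      classes disjoint even when substitution alleles
                      co-occur; such sites carry a ``mixed_indel`` flag);
* ``trimorphic``    — three or more residue alleles, no gap;
* ``transition_CT`` — alleles exactly {C, T};
* ``transition_AG`` — alleles exactly {A, G};
* ``transversion``  — any other purine/pyrimidine residue pair.

Indel runs are counted per column (a 4-base deletion is 4 sites) for the
site tallies, and additionally merged into events for a secondary table.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Sequence

from .errors import ConsistencyError, InputError
from .model import (
    GAP,
    MISSING,
    CloneAlignment,
    RegionAnnotation,
    SpectrumSummary,
    SITE_CLASSES,
    VariantSite,
)

logger = logging.getLogger(__name__)

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def classify_site(alleles: set[str] | frozenset[str]) -> str:
    """Spectrum class of an allele set (total over all 2..5-element subsets
    of {A,C,G,T,-})."""
    alleles = set(alleles)
    if len(alleles) < 2:
        raise ConsistencyError(f"classify_site needs >= 2 alleles, got {sorted(alleles)}")
    if GAP in alleles:
        return "indel"
    if len(alleles) > 2:
        return "trimorphic"
    if alleles == {"C", "T"}:
        return "transition_CT"
    if alleles == {"A", "G"}:
        return "transition_AG"
    return "transversion"


def call_sites(
    aln: CloneAlignment,
    group: Sequence[str],
    level: str = "intra-isolate",
    group_label: str | None = None,
    annotation: RegionAnnotation | None = None,
) -> list[VariantSite]:
    """Call polymorphic columns within a clone group.

    N residues are excluded from allele counts; a column whose non-N
    alleles are fewer than two (including all-gap columns) is not a site.
    """
    group = list(group)
    if not group:
        raise InputError("cannot call sites on an empty clone group")
    unknown = [c for c in group if c not in aln.rows]
    if unknown:
        raise ConsistencyError(f"group references unknown clone(s): {unknown}")
    label = group_label if group_label is not None else "+".join(group)
    rows = [aln.rows[c] for c in group]
    sites: list[VariantSite] = []
    for col in range(aln.columns):
        counts = Counter(r[col] for r in rows)
        counts.pop(MISSING, None)
        if len(counts) < 2:
            continue
        alleles = set(counts)
        site_class = classify_site(alleles)
        flags: tuple[str, ...] = ()
        if site_class == "indel" and len(alleles - {GAP}) > 1:
            flags = ("mixed_indel",)
            logger.info(
                "column %d in %s %s mixes gap with substitution alleles %s; "
                "classed indel", col + 1, level, label, sorted(alleles - {GAP}),
            )
        sites.append(
            VariantSite(
                column=col + 1,
                gene_id=aln.gene_id,
                level=level,
                group=label,
                allele_counts=dict(counts),
                site_class=site_class,
                region_type=annotation.region_at(col + 1) if annotation else "",
                flags=flags,
            )
        )
    return sites


def spectrum(
    sites: Sequence[VariantSite], gene_id: str = "", group: str = ""
) -> SpectrumSummary:
    """Counts and percentages per site class; proportions are None (not
    0/0) when there are no sites."""
    counts = {c: 0 for c in SITE_CLASSES}
    for s in sites:
        counts[s.site_class] += 1
    total = sum(counts.values())
    if total == 0:
        proportions = None
    else:
        proportions = {c: counts[c] / total * 100.0 for c in SITE_CLASSES}
    if not gene_id and sites:
        gene_id = sites[0].gene_id
    if not group and sites:
        group = sites[0].group
    return SpectrumSummary(gene_id=gene_id, group=group, counts=counts, proportions=proportions)


def merged_indel_events(sites: Sequence[VariantSite]) -> list[tuple[int, int]]:
    """Merge consecutive indel-class site columns into (start, end) events."""
    cols = sorted(s.column for s in sites if s.site_class == "indel")
    events: list[tuple[int, int]] = []
    for c in cols:
        if events and c == events[-1][1] + 1:
            events[-1] = (events[-1][0], c)
        else:
            events.append((c, c))
    return events
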