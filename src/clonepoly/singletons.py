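"""Singleton (PCR/cloning error) detection and correction.

A *singleton* is an allele — gap included, N excluded — observed in exactly
one clone of an isolate's clone set at a column where some other allele is
carried by at least two clones.  Cloned-amplicon studies treat such
single-occurrence variants as polymerase or cloning artifacts and replace
them with the isolate-majority allele before any polymorphism counting.

The scope of "single occurrence" is the isolate, never the species: an
allele seen once in each of two isolates is kept in both.  Isolates with
fewer than `min_clones` clones are skipped with a warning, since singleton
status carries no signal at shallow clone sampling.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Iterable

from .errors import ConsistencyError, InputError
from .model import MISSING, CloneAlignment, SingletonEvent

logger = logging.getLogger(__name__)

DEFAULT_MIN_CLONES = 10


def detect_singletons(
    aln: CloneAlignment, min_clones: int = DEFAULT_MIN_CLONES
) -> list[SingletonEvent]:
    """Find every within-isolate single-occurrence allele.

    For each isolate with >= `min_clones` clones and each column, every
    allele with within-isolate count exactly 1, at a column where another
    allele has count >= 2, yields one event corrected to the isolate
    majority allele (ties broken to the lexicographically smallest, logged).
    """
    if min_clones < 2:
        raise InputError(f"min_clones must be >= 2, got {min_clones}")
    events: list[SingletonEvent] = []
    for isolate_id, clones in aln.isolates().items():
        if len(clones) < min_clones:
            logger.warning(
                "isolate %s has %d clone(s) < min_clones=%d; singleton "
                "correction skipped for it",
                isolate_id, len(clones), min_clones,
            )
            continue
        rows = [aln.rows[c] for c in clones]
        for col in range(aln.columns):
            column = [r[col] for r in rows]
            counts = Counter(ch for ch in column if ch != MISSING)
            if len(counts) < 2:
                continue
            top = max(counts.values())
            if top < 2:
                continue
            majority = min(a for a, n in counts.items() if n == top)
            if sum(1 for n in counts.values() if n == top) > 1:
                logger.info(
                    "majority tie at column %d in isolate %s resolved to %r",
                    col + 1, isolate_id, majority,
                )
            for allele, n in counts.items():
                if n != 1:
                    continue
                clone_id = clones[column.index(allele)]
                events.append(
                    SingletonEvent(
                        clone_id=clone_id,
                        column=col + 1,
                        observed_allele=allele,
                        corrected_to=majority,
                        isolate_id=isolate_id,
                    )
                )
    return events


def apply_corrections(
    aln: CloneAlignment, events: Iterable[SingletonEvent]
) -> CloneAlignment:
    """Return a new alignment with every event's cell replaced.

    The input alignment is untouched; the applied events are appended to the
    result's `correction_log` as the audit trail.
    """
    events = list(events)
    rows = {cid: list(aln.rows[cid]) for cid in aln.clone_ids}
    for e in events:
        if e.clone_id not in rows:
            raise ConsistencyError(f"event references unknown clone {e.clone_id!r}")
        if not 1 <= e.column <= aln.columns:
            raise ConsistencyError(
                f"event column {e.column} outside alignment 1..{aln.columns}"
            )
        cell = rows[e.clone_id][e.column - 1]
        if cell != e.observed_allele:
            raise ConsistencyError(
                f"event expects {e.observed_allele!r} at clone {e.clone_id!r} "
                f"column {e.column} but alignment holds {cell!r}"
            )
        rows[e.clone_id][e.column - 1] = e.corrected_to
    return aln.with_rows({cid: "".join(chars) for cid, chars in rows.items()}, events)


def correct_singletons(
    aln: CloneAlignment, min_clones: int = DEFAULT_MIN_CLONES
) -> tuple[CloneAlignment, list[SingletonEvent]]:
    """One detect/apply round.  A single round is idempotent: corrections
    move count-1 alleles onto the majority and leave >=2 counts untouched,
    so no new singletons can appear."""
    events = detect_singletons(aln, min_clones=min_clones)
    return apply_corrections(aln, events), events
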