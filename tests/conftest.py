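"""Shared fixtures and alignment builders for the test suite."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from clonepoly.model import CloneAlignment, SampleRecord

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def build_aln(
    rows: dict[str, str],
    meta: dict[str, tuple[str, str]] | None = None,
    gene_id: str = "ITS",
) -> CloneAlignment:
    """Build a CloneAlignment; `meta` maps clone -> (isolate, species).

    Without `meta`, clone ids of the form ``iso_clN`` put everything in one
    isolate/species per the prefix before the last underscore.
    """
    if meta is None:
        meta = {}
        for cid in rows:
            iso = cid.rsplit("_", 1)[0] if "_" in cid else "iso1"
            meta[cid] = (iso, "sp1")
    samples = {
        cid: SampleRecord(cid, meta[cid][0], meta[cid][1], gene_id) for cid in rows
    }
    return CloneAlignment(
        gene_id=gene_id, clone_ids=tuple(rows), rows=dict(rows), samples=samples
    )


def clone_set(
    isolate: str, species: str, seqs: list[str], gene_id: str = "ITS"
) -> tuple[dict[str, str], dict[str, tuple[str, str]]]:
    rows = {f"{isolate}_cl{i + 1:02d}": s for i, s in enumerate(seqs)}
    meta = {cid: (isolate, species) for cid in rows}
    return rows, meta


def merge_sets(*sets) -> "CloneAlignment":
    rows: dict[str, str] = {}
    meta: dict[str, tuple[str, str]] = {}
    for r, m in sets:
        rows.update(r)
        meta.update(m)
    return build_aln(rows, meta)


@pytest.fixture
def tiny_isolate():
    """One isolate of 12 clones: 11 share a haplotype, 1 carries a G at
    column 3 (a singleton)."""
    base = "ACATGTACGT"
    variant = base[:2] + "G" + base[3:]
    rows, meta = clone_set("isoA", "sp1", [base] * 11 + [variant])
    return build_aln(rows, meta)
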