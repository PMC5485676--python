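"""End-to-end orchestration: validate -> correct -> call -> classify ->
effects -> summarize -> write reports.

`run_analysis` is the library surface under the command-line interface.
All results are computed in memory first and written only when every stage
has succeeded, so a validation failure never leaves a partial report set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .coding import assign_effects
from .diversity import enumerate_types, summarize_levels
from .errors import InputError
from .io import (
    read_annotation,
    read_clone_fasta,
    write_reports,
    write_singleton_audit,
)
from .model import CloneAlignment, RegionAnnotation, VariantSite
from .singletons import DEFAULT_MIN_CLONES, correct_singletons
from .variants import call_sites, merged_indel_events, spectrum


@dataclass
class RunConfig:
    """Options of one analysis run; every default reproduces the package's
    documented conventions (isolate-scoped singleton rule, complete-deletion
    mean-pairwise pi, 2/4-decimal rounding)."""

    fasta: str
    samples: str
    annotation: str | None = None
    min_clones: int = DEFAULT_MIN_CLONES
    pi_deletion: str = "complete"  # complete | pairwise
    pi_estimator: str = "mean_pairwise"  # mean_pairwise | haplotype
    outdir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise InputError(f"unknown config key(s): {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def analyze_alignment(
    aln: CloneAlignment,
    annotation: RegionAnnotation | None = None,
    min_clones: int = DEFAULT_MIN_CLONES,
    pi_deletion: str = "complete",
    pi_estimator: str = "mean_pairwise",
) -> dict[str, Any]:
    """Run the full in-memory analysis of one clone alignment.

    Returns a dict with the corrected alignment, singleton events, variant
    sites per level, spectra, types, diversity summaries and the
    barcode-gap verdict.
    """
    corrected, events = correct_singletons(aln, min_clones=min_clones)

    sites: list[VariantSite] = []
    for isolate_id, clones in corrected.isolates().items():
        sites.extend(
            call_sites(corrected, clones, level="intra-isolate",
                       group_label=isolate_id, annotation=annotation)
        )
    species_sites: dict[str, list[VariantSite]] = {}
    for species_id, clones in corrected.species().items():
        ss = call_sites(corrected, clones, level="intraspecific",
                        group_label=species_id, annotation=annotation)
        species_sites[species_id] = ss
        sites.extend(ss)
    all_sites = call_sites(
        corrected, corrected.clone_ids, level="interspecific",
        group_label="all", annotation=annotation,
    )
    sites.extend(all_sites)

    if annotation is not None:
        for isolate_id, clones in corrected.isolates().items():
            assign_effects(
                [s for s in sites if s.level == "intra-isolate" and s.group == isolate_id],
                corrected, clones, annotation,
            )
        for species_id, clones in corrected.species().items():
            assign_effects(species_sites[species_id], corrected, clones, annotation)
        assign_effects(all_sites, corrected, corrected.clone_ids, annotation)
    else:
        for s in sites:
            s.coding_effect = "na"

    spectra = [
        spectrum(ss, gene_id=corrected.gene_id, group=species_id)
        for species_id, ss in species_sites.items()
    ]
    spectra.append(spectrum(all_sites, gene_id=corrected.gene_id, group="all"))

    types = []
    for isolate_id, clones in corrected.isolates().items():
        for t in enumerate_types(corrected, clones):
            types.append(("intra-isolate", isolate_id, t))
    for species_id, clones in corrected.species().items():
        for t in enumerate_types(corrected, clones):
            types.append(("intraspecific", species_id, t))

    indels = []
    for species_id, ss in species_sites.items():
        for start, end in merged_indel_events(ss):
            indels.append(("intraspecific", species_id, start, end))

    summaries, verdict = summarize_levels(
        corrected, pi_deletion=pi_deletion, pi_estimator=pi_estimator
    )
    return {
        "corrected": corrected,
        "events": events,
        "sites": sites,
        "all_sites": all_sites,
        "spectra": spectra,
        "types": types,
        "indel_events": indels,
        "summaries": summaries,
        "verdict": verdict,
    }


def run_analysis(config: RunConfig) -> dict[str, Any]:
    """Read inputs, analyze, and write the report set plus a run manifest.

    Returns the manifest dict.  Raises (without writing anything) on any
    validation failure.
    """
    aln = read_clone_fasta(config.fasta, config.samples)
    annotation = None
    if config.annotation:
        annotation = read_annotation(config.annotation, aln.columns, gene_id=aln.gene_id)

    result = analyze_alignment(
        aln,
        annotation=annotation,
        min_clones=config.min_clones,
        pi_deletion=config.pi_deletion,
        pi_estimator=config.pi_estimator,
    )

    outdir = Path(config.outdir)
    paths = write_reports(
        outdir,
        summaries=result["summaries"],
        verdicts=[result["verdict"]],
        sites=result["sites"],
        spectra=result["spectra"],
        types=result["types"],
        indel_events=result["indel_events"],
    )
    paths["singleton_audit"] = write_singleton_audit(
        result["events"], outdir / "singleton_audit.tsv"
    )

    manifest = {
        "software": {"name": "clonepoly", "version": __version__},
        "inputs": {
            "fasta": str(config.fasta),
            "samples": str(config.samples),
            "annotation": str(config.annotation) if config.annotation else None,
        },
        "options": {
            "min_clones": config.min_clones,
            "pi_deletion": config.pi_deletion,
            "pi_estimator": config.pi_estimator,
        },
        "counts": {
            "clones_in": len(aln.clone_ids),
            "clones_analyzed": len(result["corrected"].clone_ids),
            "isolates": len(aln.isolates()),
            "species": len(aln.species()),
            "alignment_columns": aln.columns,
            "singletons_corrected": len(result["events"]),
            "sites_called": len(result["sites"]),
            "sites_classified": sum(1 for s in result["sites"] if s.site_class),
            "sites_union_scope": len(result["all_sites"]),
        },
        "outputs": {k: str(v) for k, v in sorted(paths.items())},
    }
    with (outdir / "manifest.json").open("w", newline="\n") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
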