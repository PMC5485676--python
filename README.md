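# clonepoly

Analysis of intra-isolate sequence heterogeneity in cloned fungal
marker-gene amplicons (ITS, RPB2, EF1α).

When a marker gene is PCR-amplified from a single fungal isolate, cloned,
and ~30 clones are Sanger-sequenced, the clone set often is not uniform:
some differences are PCR/cloning artifacts, others are genuine
within-genome or within-mycelium polymorphism. Whether a marker is usable
as a DNA barcode then hinges on how this intra-isolate and intraspecific
variation compares with divergence between species. `clonepoly` implements
the standard clone-survey workflow for researchers in fungal taxonomy,
barcoding and population genetics:

1. **Singleton correction** — an allele (gap included) seen in exactly one
   clone of an isolate's set, at a column where another allele occurs ≥ 2
   times, is treated as a polymerase/cloning error and replaced with the
   isolate-majority allele. Every correction is written to an audit table.
2. **Polymorphic-site calling and classification** — sites are called at
   the intra-isolate, intraspecific and interspecific levels and each is
   classed as a C/T transition, A/G transition, transversion, indel
   (counted per column), or tri-morphic site, yielding the substitution
   spectrum per gene and species.
3. **Coding effects** — exon substitutions are judged synonymous or
   non-synonymous by substituting each alternate allele into the
   group-consensus CDS and translating the affected codon (standard code);
   exon gaps are frameshifts unless the merged run length is a multiple
   of 3; ITS/intron columns are non-coding.
4. **Diversity summaries** — distinct sequence types (haplotypes) with
   multiplicities; pairwise divergence/similarity; and Nei–Li nucleotide
   diversity

   π = Σ_{i<j} d_ij / C(n,2) / L_valid,

   the mean number of pairwise differences per valid site, with complete
   deletion of gap/N columns by default. Per-level tables report clone
   counts, polymorphic-site counts, maximum divergence (= 100 − minimum
   similarity) and π, and each gene gets a barcoding-gap verdict:
   `gap_holds` iff the largest intraspecific divergence is below the
   smallest interspecific divergence.
5. **Synthetic clone sets** — a generator plants hierarchical variants,
   indel runs, tri-morphic columns and per-clone PCR errors with full
   ground truth, so the whole pipeline is testable end to end
   (`truth-compare` scores site recall/precision, class and effect
   accuracy, singleton recall, and type-count agreement).

Pairwise divergence uses the full alignment column count as denominator
(gap-vs-gap is a match, any-N columns are excluded), the convention under
which a pair differing at 8 of 591 columns diverges by 1.35% and a pair
differing at 12 of 563 columns is 97.87% similar.

## Worked example

Simulate a three-species ITS-like survey (3 isolates per species, 30
clones each, 581 columns) and analyse it:

```sh
clonepoly simulate --seed 42 --outdir data --clones 30 --length 581
# simulated 270 clones, 47 planted site(s), 292 planted error(s) -> data
clonepoly run --fasta data/clones.fasta --samples data/samples.tsv \
              --annotation data/annotation.tsv --outdir results
# analyzed 270 clones; corrected 290 singleton(s); reports in results
```

`results/diversity_summary.tsv` starts:

```
gene_id  level          group     n_clones  n_polymorphic_sites  n_types  max_divergence_pct  min_divergence_pct  min_similarity_pct  pi
ITS      intra-isolate  sp1_iso1  30        2                    4        0.34                                    99.66               0.0006
ITS      intra-isolate  sp1_iso2  30        3                    5        0.52                                    99.48               0.0009
```

Isolate `sp1_iso1` retains 2 genuine polymorphic sites after error
correction; its most divergent clone pair differs at 0.34% of columns
(99.66% similarity) and the isolate's nucleotide diversity is π = 0.0006.
`results/barcode_gap.tsv` gives the verdict:

```
gene_id  max_intraspecific_pct  min_interspecific_pct  gap_holds
ITS      1.20                   1.72                   true
```

— the worst within-species divergence (1.20%) stays below the smallest
between-species divergence (1.72%), so this marker shows a barcoding gap
in this dataset. Because the dataset was simulated, recovery can be
scored against the planted truth:

```sh
clonepoly truth-compare --seed 42
```

```json
{
 "class_accuracy": 1.0,
 "effect_accuracy": 1.0,
 "false_corrections": 0,
 "singleton_recall": 0.9931506849315068,
 "site_precision": 0.9791666666666666,
 "site_recall": 1.0,
 ...
}
```

All 47 planted sites are recovered with correct classes; 290 of 292
planted PCR errors are corrected (the two misses are same-column
same-allele collisions between two clones of one isolate, which the
closed-form expectation `(1 − e/3)^(n−1)` predicts), and the residual
uncorrected errors account for the site precision slightly below 1.

Other subcommands: `clonepoly validate` (input checking only) and
`clonepoly align` (opt-in star alignment of unaligned clones against a
reference clone with an affine-gap Needleman–Wunsch; the analysis itself
requires pre-aligned input). Everything is also available as a library:

```python
from clonepoly import SimConfig, simulate, analyze_alignment

aln, samples, annotation, truth = simulate(SimConfig(seed=42))
result = analyze_alignment(aln, annotation=annotation)
print(result["verdict"])   # BarcodeGapVerdict(gene_id='ITS', ..., gap_holds=True)
```

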