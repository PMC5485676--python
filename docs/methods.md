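# Methods

## Data model

The unit of analysis is a *clone alignment*: all sequenced clones of one
marker gene (ITS, RPB2, EF1α, or user-defined), from every isolate and
species under study, in one shared column coordinate system. Input must be
pre-aligned; ragged FASTA is rejected rather than silently aligned, and an
explicit opt-in star aligner is provided separately. All coordinates are
1-based inclusive alignment columns. The residue alphabet is
{A, C, G, T, N, -}: `N` is missing data (excluded from allele counts and
from pairwise comparisons at that column), while the gap `-` is a real
allele representing an indel state, except that gap-vs-gap never counts as
a difference.

A sample sheet maps each clone to its isolate, species and gene; a region
annotation tiles the columns with exon/intron or ITS1/5.8S/ITS2 intervals
and, when exons are present, the codon phase of the first exon column.

## Singleton correction

Cloned-amplicon surveys treat an allele observed in exactly one clone of
an isolate's set as a polymerase or cloning artifact. The rule implemented
here: at each column of each isolate with at least `min_clones` clones,
every allele (gap included, N excluded) with within-isolate count exactly
1, at a column where some other allele has count ≥ 2, is replaced by the
isolate-majority allele.

Choices worth knowing:

* **Scope is the isolate, never the species.** An allele seen once in each
  of two isolates is genuine shared variation and is kept in both.
* **`min_clones` defaults to 10.** Below roughly ten clones, "seen once"
  carries no statistical signal; surveys of this kind sequence ~30 clones
  per isolate. Smaller isolates are skipped with a warning.
* **Majority ties** (possible under heavy N-masking) resolve to the
  lexicographically smallest top allele and are logged, for determinism.
* **A singleton co-occurring with genuine polymorphism** (e.g. 20×A + 9×G
  + 1×C) is corrected to the column majority (A), not to the carrier
  row's nearest haplotype, and the event is recorded in the audit table so
  the choice can be reviewed.
* One detect/apply round is idempotent: corrections move count-1 alleles
  onto the majority and never touch counts ≥ 2, so no new singletons can
  arise. Columns monomorphic after correction are non-polymorphic
  everywhere downstream.

## Site calling and the substitution spectrum

A polymorphic site is a column with ≥ 2 distinct non-N alleles within the
group of clones considered (an isolate, a species, a species pair, or the
whole set). Classes are disjoint: any gap allele makes the site an
`indel` (sites also carrying ≥ 2 substitution alleles get a `mixed_indel`
flag); gap-free sites with > 2 alleles are `trimorphic`; the two-allele
sites split into `transition_CT`, `transition_AG` and `transversion`.
Indel runs count one site per column — a 4-base deletion is 4 sites —
matching how such surveys list positions individually; merged (start, end)
events are reported in a secondary table. Spectrum tables give counts and
percentages per class; totals are always computed from the called sites,
never copied from any external tally.

## Coding effects

Effects are judged one site at a time against the *consensus background*
of the group: the per-column majority sequence (ties lexicographic,
logged). Exon columns are concatenated in annotation order, consensus-gap
columns dropped, and the CDS translated with the standard genetic code
(table 1 — fungal nuclear genes) from the annotated frame offset. A
substitution is `synonymous` iff every alternate allele preserves the
amino acid of the affected codon; stop-creating changes are
`nonsynonymous` with a `nonsense` flag. An exon gap allele is a
`frameshift` unless the merged gap run within the exon has length a
multiple of 3 (then `nonsynonymous`, flagged `inframe_indel`). Columns
that cannot be judged (consensus gap, incomplete codon, N in the codon,
before the frame start) are `na`; non-exon regions are `noncoding`.
Compound effects of multiple variants sharing a codon are out of scope by
design: the per-site convention matches per-site variant tallies.

## Distances and nucleotide diversity

* **Pairwise divergence** between two rows counts residue-vs-residue and
  gap-vs-residue mismatches over all columns except those with N in
  either row; gap-vs-gap is a match and stays in the denominator. This
  full-column-denominator convention is what makes printed similarity
  figures pure arithmetic: 8 differences over 591 columns → 1.35%
  divergence; 12 over 563 → 97.87% similarity. Similarity = 100 −
  divergence exactly.
* **"Variation" per level** is the maximum pairwise divergence within the
  scope (intra-isolate and intraspecific rows) and the min/max of
  cross-species pairs (interspecific rows); `min_similarity_pct` is
  computed as the exact 2-decimal complement of the rounded maximum
  divergence.
* **Nucleotide diversity** is the Nei–Li mean number of pairwise
  differences per site: π = Σ_{i<j} d_ij / C(n,2) / L_valid. The default
  uses *complete deletion*: L_valid counts columns free of gaps and N in
  every row of the group, and per-pair differences are counted on those
  columns only; no multiple-hit (Jukes–Cantor) correction is applied.
  *Pairwise deletion* (per-pair valid columns) is available via an
  option, as is the haplotype-frequency form n/(n−1)·Σ x_i x_j π_ij —
  which is algebraically identical to the mean pairwise form and kept
  only as a cross-check. If no valid column remains, π is reported
  missing with a warning. The intraspecific-similarity conventions of
  published clone surveys are not always recoverable from printed numbers
  alone; both deletion modes are exposed so either can be matched.
* **Barcoding gap:** for each gene, `gap_holds` is true iff the maximum
  intraspecific divergence is strictly below the minimum interspecific
  divergence.
* **Rounding:** percentages half-even to 2 decimals, π half-even to 4,
  applied at report-writing time only.

## Star aligner

The optional aligner places unaligned clones into one coordinate system by
globally aligning each clone to a chosen reference clone (affine-gap
Needleman–Wunsch; a gap of length k costs `gap_open + gap_extend·k`;
defaults match = 1, mismatch = −1, open = 4, extend = 1) and propagating
reference-relative insertions to all rows (left-aligned within their
padded block). Full progressive MSA is deliberately avoided: clones are
near-identical, so reference propagation is adequate and deterministic.
Traceback ties prefer match > deletion > insertion.

## Synthetic clone sets

The generator emulates the sampling design of clone-based heterogeneity
surveys; its defaults are the study conditions, not tuning knobs:
3 species × 3 isolates × 30 clones, 581 columns with an ITS1/5.8S/ITS2
annotation (an exon–intron helper covers the protein-coding layout),
17 interspecific sites, 4 intraspecific sites per species, 2
intra-isolate sites per isolate with minor-allele count 3, per-base
per-clone PCR error rate 0.002, transition:transversion ratio 2:1 and
80% of exon variants constrained synonymous — magnitudes in line with
ITS-scale surveys (tens of between-species differences, a handful of
within-species sites, singleton counts small relative to ~30-clone
depth, T/C-dominated spectra, mostly synonymous exon variation).

Mechanics:

* One ancestral sequence is drawn uniformly; interspecific sites put the
  alternate allele on all clones of one randomly chosen species;
  intraspecific sites on all clones of a proper non-empty subset of one
  species' isolates; intra-isolate sites on `minor_count ≥ 2` clones of
  one isolate — so no planted variant is ever a singleton. Tri-morphic
  columns carry two alternate alleles in disjoint minor sets of one
  isolate (placed in non-coding regions); indel runs delete a block from
  `minor_count` clones of a rotating isolate. Planted columns are
  pairwise distinct across categories.
* Exon substitutions intended synonymous snap to the third position of a
  free codon whose prefix is set to one of the eight four-fold families;
  intended nonsynonymous sites go to a first/second codon position with
  an allele verified to change the amino acid (degenerate Leu/Arg cases
  fall back to a Lys codon). This guarantees intended effects exactly
  rather than in expectation.
* PCR errors are substitutions only (drawn uniformly from the 3 non-
  current bases), placed per clone × column by Bernoulli draws — or as an
  exact count on distinct columns — and only at non-planted columns, so
  error/variant collisions cannot occur. The filter's expected recall is
  then closed-form: an error escapes correction only when another clone
  of the same isolate draws the same allele at the same column, giving
  recall = (1 − e/3)^(n−1) for n clones at rate e.
* Everything is deterministic given the seed, and `SimTruth` carries
  every planted site (with intended class and effect), every planted
  error, the species roots and the pre-error rows, so `truth_compare` can
  score site precision/recall, class and effect accuracy, singleton
  recall and false corrections, and per-isolate type-count agreement.

What the generator does *not* emulate: coalescent genealogies, rDNA
copy-number dynamics and concerted evolution, chimeric clones, alignment
uncertainty (clones are generated in a fixed coordinate system), and
quality-score-dependent error profiles. Passing recovery tests therefore
demonstrates the pipeline's correctness under its stated conventions, not
robustness to misalignment or chimera-rich libraries.

## Problem sizes used in the automated checks

The test suite and acceptance script run on simulated data at the scale
the statistics need, not larger: worked examples on single pairs of
~560–590-column rows; oracle equivalence on 100 random groups of ≤ 10
rows × ≤ 200 columns; filter guarantees over 50 seeded replicates of
4-isolate sets; the collision-adjusted recall check over 1000 replicates
of one 30-clone isolate with 120 columns (several thousand planted
errors, enough for a tight binomial interval); and the headline
similarity figure on the 3-isolate × 9-clone design it describes.

## Known limitations

* Effects ignore compound codon changes and alternative genetic codes.
* The singleton rule is frequency-based only; no quality scores, strand
  information or chimera detection.
* Interspecific site lists are computed on the union of clone sets in one
  shared coordinate system; cross-species alignability is assumed, not
  checked.
* Divergence percentages depend on the stated gap conventions; numbers
  produced under other conventions (e.g. pairwise deletion with gap
  exclusion) will differ at the second decimal.
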