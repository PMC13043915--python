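# Methods

## Filtering model

The classifier treats each deduplicated single-end alignment independently
and evaluates three predicates against a padded target window, in strict
precedence order `start_in` > `end_in` > `span_mismatch`:

* **start_in / end_in** — the leftmost (rightmost) aligned reference base
  lies inside the padded window. Termini are reference coordinates
  irrespective of strand; strand is carried as metadata only. This models
  reverse-transcription truncation at the crosslink, which places a read
  terminus at the site on either strand.
* **span_mismatch** — the alignment strictly contains the padded window
  (start before it *and* end after it) and the MD tag records ≥ 1
  substitution. This models read-through with a crosslink-induced
  mutation. By default the substitution may be anywhere in the read, since
  the MD tag is a per-read annotation; `mismatch_in_window=True` restricts
  it to the padded window. Deletions (`^` runs in the MD tag) are parsed
  and reported but not counted as mismatches unless `count_deletions=True`
  — crosslink artefacts in this assay are predominantly substitutions and
  truncations.

A read exactly coterminal with the window is classified by its terminus,
so the strict-containment requirement of the spanning predicate never
excludes a read that any predicate would accept. Precedence makes the
categories mutually exclusive; enlarging the pad can only add reads
(monotonicity, property-tested).

**Pad placement.** The window is specified as an 18-nt interval "+2 nt".
The published interval is 18 nt long and the side of the extra 2 nt is not
derivable from it, so the pad is split symmetrically by default —
`floor(pad/2)` left, `ceil(pad/2)` right — with `pad_left`/`pad_right`
overrides. User-facing coordinates are 1-based inclusive; internally
everything is 0-based half-open (SAM convention), and the conversion is
unit-tested.

## Preprocessing

* **Adapter trimming** removes the best (leftmost) 3′ adapter occurrence:
  a full internal match anywhere, or a terminal adapter *prefix* of at
  least `min_overlap` (default 5) bases ending exactly at the read's 3′
  end. `N` matches anything when `match_wildcards` is on. Matching is
  exact by default (`max_error_rate=0`, exposed as config): the simulator
  emits verbatim adapters, so error-tolerant alignment would add code
  paths the data cannot exercise. Reads shorter than `min_length`
  (default 18 nt) after trimming are discarded.
* **UMI extraction** moves the first 8 bases into the read identifier
  (separator `_`), the convention the deduplicator consumes.
* **Deduplication** groups alignments by (contig, 5′ position on the
  read's strand, strand) and collapses UMIs within a group. `exact`
  (default) keeps one representative per distinct UMI — fully
  deterministic and exactly invertible against the simulator's truth
  table. `directional` additionally merges UMIs at Hamming distance 1
  when the larger family's count ≥ 2×(smaller) − 1, the standard
  sequencing-error-tolerant network rule. The representative is the first
  read in coordinate-sorted order, so output is order-independent.

## Normalization chain

Per condition: `peak_percent = 100 · peak/minigene`, `minigene_fraction =
minigene/total_unique`, and the transfection adjustment divides the
*non-reference* condition's minigene fraction by the relative transfection
rate (mutant/WT; default 0.796, overridable, or computable from matched
input-library minigene counts). The adjustment attaches to the
minigene-fraction step, in the order the operations are defined;
`peak_percent` is reported on unadjusted counts alongside, so both
readings of the chain are available in the report. Empty denominators
propagate NaN instead of raising, so degenerate small runs still produce
a report. The report carries the mutant/WT `peak_percent_ratio`, the
quantity the condition comparison turns on.

The assay-side normalizations are standard: fold change
2^−((Ct_t−Ct_r)_treated − (Ct_t−Ct_r)_control); RIP-dPCR
(copies_antibody/copies_IgG)/transfection_efficiency (the two divisions
commute, so their order is not a modelling choice); reporter Gluc/SEAP.
Group summaries report mean and min–max range, matching dot-plot style
presentation. Significance testing is intentionally out of scope; tables
carry a pass-through `p_value` column for externally computed values.

## Synthetic library generator

The reference is one "minigene" contig of alternating exon/intron
features (defaults: six exons, five introns, ~5.7 kb, an 18-nt window 200
nt into the fourth intron) plus a featureless 10-kb host contig standing
in for the transfected cell's transcriptome background. Sequence is
uniform i.i.d. over A/C/G/T; coordinates depend only on the layout, so
different seeds share annotation.

Molecule classes map one-to-one onto the filter predicates:

* *site_truncation* — the 5′ terminus (strand-aware) sits at a uniformly
  chosen crosslink position inside the padded window; with probability
  `substitution_rate_at_crosslink` the crosslink base is also substituted.
* *site_span* — the insert strictly contains the padded window; one
  substitution at a uniform window position is guaranteed, plus
  independent extras at the remaining window positions at the same rate.
* *background* — position uniform across contigs (proportional to contig
  length), rejection-sampled so neither terminus falls in the padded
  window, and mismatch-free — so no background molecule satisfies any
  predicate, and every site molecule satisfies at least one (tested
  against the truth table).

Insert lengths are uniform on [24, read_length − umi_length]; each FASTQ
read is UMI + insert + adapter, truncated to `read_length` (100 nt
default), so adapters appear exactly when the insert leaves room — which
also exercises the no-trim path. Site occupancy thins site molecules per
molecule (Bernoulli), giving kept counts the binomial variance the
parameter-recovery analysis assumes; a mutant condition is the same
generator at a lower occupancy. PCR duplicates are exact copies, 1 +
Poisson(`pcr_duplication_rate`) per molecule, sharing position and UMI.
Base qualities are constant (nothing downstream reads them), reads are
emitted on both strands with probability ½, and ground-truth alignments
(pure-match CIGAR, MD/NM computed from the planted substitutions) are
written directly — alignment itself is off-the-shelf and out of scope, so
no aligner runs. `samtools calmd` is used in the test suite as an
independent oracle that the emitted MD tags are exactly what the
reference implies.

**What the generator does not emulate:** sequencing errors outside
crosslink sites, spliced alignments, indel artefacts, UMI errors coupled
with PCR (duplicates are exact copies, so `exact` dedup is lossless by
construction — the directional mode is exercised on constructed cases
instead), non-uniform genomic composition, and quality variation. Passing
tests therefore demonstrate correctness of the bookkeeping and the
classifier on reads whose generative story matches the model, not
robustness to alignment artefacts in real libraries.

## Problem sizes and numerical choices

The occupancy-recovery study simulates 600 configured site molecules
(350 truncation + 250 spanning) per condition at WT occupancy 0.8 versus
mutant 0.32, over 20,000 background molecules with PCR duplication rate
1.0 — chosen so background dominates the minigene denominator, as in real
libraries where window reads are a small fraction of minigene reads, which
is what makes the peak-percent ratio an approximately unbiased estimate of
the occupancy ratio. The check uses the delta-method binomial 95% interval
around the true ratio 0.4, with seeds fixed; the whole pair runs in
seconds on one CPU. Classifier equivalence is checked against an
independent brute-force evaluation of the three predicates on an
exhaustive grid of ~1,400 read placements around the window.

Ties and degenerate inputs: dedup representatives are chosen in
coordinate-sorted order; unsorted alignment input is rejected with advice
to sort; reads without MD tags are skipped with a warning and counted;
malformed MD tags raise a parse error naming the offending token; and all
ratio operations return NaN on empty denominators rather than raising.
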