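# Methods

## Model and assumptions

`chromodraft` arranges fragments (contigs or scaffolds) onto draft
chromosomes purely from their pairwise local alignments to a reference
genome of a closely related species. The underlying assumption is
collinearity: over the evolutionary distance between target and
reference, large-scale synteny is conserved well enough that a
fragment's strongest alignment is its true home. The method makes no
attempt to detect cross-species rearrangements; a real translocation in
the target relative to the reference will be reproduced as a
reference-like arrangement (this is the price of needing neither
mate-pair data nor multiple references).

Every internal coordinate is zero-based half-open; BLAST tabular
(1-based inclusive, strand encoded by descending subject coordinates)
and GFF3 (1-based inclusive) are converted at the format boundary only.

### Anchoring

For each fragment the alignments are ordered by
(score desc, ref_id asc, ref_start asc, fragment_start asc) and the top
two scores s₁ ≥ s₂ enter the ratio test. The fragment is anchored when
s₁/s₂ **strictly exceeds** the threshold; a ratio exactly at the
threshold does not anchor. Alignments past the top two carry no weight.
Two cases the ratio does not define are resolved as package policy:

* **Single alignment ⇒ anchored.** There is no competing evidence and
  discarding such fragments would throw away the easiest placements.
  Users who distrust solitary weak hits should pre-filter the alignments
  by score or E-value.
* **Exact best-score ties ⇒ never anchored** (a ratio of 1 cannot exceed
  a threshold > 1); the unplaced/unlocalized split then uses the
  chromosomes of the two tied alignments under the deterministic
  ordering above.

The classification is invariant under rescaling all scores by any
positive constant, so any monotone score (bit score, chain score,
percent-identity-weighted length) works identically.

### Placement and layout

An anchored fragment's full extent is extrapolated from its winning
alignment (equations in the README). The extrapolated start may be
negative when a fragment overhangs the reference start; layout clamps
each chromosome's coordinate frame by an initial shift of
max(0, −smallest start).

Overlaps are resolved by gap insertion: walking the anchors in
(start, end, fragment id) order, whenever a fragment's shifted start
falls inside its predecessor (overlap N), the running shift grows by
N + S, where S is the user's gap size. The shift is **cumulative** — it
moves every downstream fragment equally — rather than local to the
overlapping pair. Cumulative shifting preserves all downstream
inter-fragment distances, guarantees that resolving one overlap can
never create another, and leaves formerly overlapping neighbours exactly
S apart. Reference-derived spacing between non-overlapping neighbours is
kept and materialized as `N` runs (recorded as `GAP` rows of the
fragment map), which keeps assembled coordinates collinear with the
reference frame; the alternative — concatenating fragments with a fixed
gap — would shrink chromosomes but destroy that collinearity.

Assembled chromosomes end at their last fragment; they are not padded to
the reference chromosome length, and reference chromosomes that anchor
no fragment are omitted. Unlocalized and unplaced fragments are excluded
from the sequences and reported as id lists.

## Parameters

* **ratio threshold** (`--ratio-threshold`, dimensionless, required,
  must be > 1). Larger values anchor more conservatively; anchoring is
  monotone in the threshold (raising it can only demote fragments).
  There is no universally correct default, so the CLI refuses to guess;
  1.2–1.5 is a sensible starting range.
* **gap size S** (`--gap-size`, bp, required, ≥ 0). The run of `N`
  inserted between formerly overlapping fragments. Choose it at least as
  large as the sequencing library insert size so downstream scaffolding
  evidence is not contradicted.

## The simulator

`chromodraft.simulator` shreds a uniform-random reference (default two
chromosomes, the fragment tiling covering every base) into fragments of
uniform random length, reverse-complementing each with probability
`reverse_fraction`, and emits the exact full-length alignment of every
fragment with score 2 × length. Optional confounders: consecutive-shred
overlap (`overlap_bp`), fragments with two equal-score alignments on
different chromosomes (`n_ambiguous`, forcing unplaced calls), and
alignment-free junk (`n_unaligned`). One `random.Random(seed)` instance
drives everything, so output is byte-reproducible.

What it deliberately does **not** emulate: sequencing error, assembly
chimerism, repeat-induced multi-mapping with unequal scores, genuine
rearrangement between target and reference, and partial (clipped)
alignments. Passing the shred-recovery suite therefore shows the
pipeline's bookkeeping is exact — placement algebra, orientation
handling, gap insertion, sequence emission — not that anchoring is
robust to noisy real alignments; that robustness rests on the score
ratio supplied by the aligner.

## Numerical and procedural choices

* The ratio test uses exact floating-point division of scores; scores
  are never mutated or normalized.
* Deterministic tie-breaks everywhere (alignment ordering above; layout
  order (start, end, fragment id); chromosomes emitted in sorted id
  order), so identical inputs give byte-identical outputs with no
  randomness anywhere in the pipeline.
* A 1 bp reverse-strand hit cannot be expressed in BLAST tabular
  (sstart == send); such records parse as direct. This is a limitation
  of the format, not of the record model.
* Degenerate inputs: an empty alignment file yields an empty map with
  every fragment unplaced; an empty anchor list yields an empty layout;
  a zero runner-up score anchors iff the best score is positive.
* Validation is strict: fragment-map rows must be sorted and disjoint
  per chromosome, a fragment may appear only once, and alignments must
  fit inside their fragment — violations name the offending records.

## Validation

The test suite checks, among others: equivalence of the closed-form
placement with an independent per-base walk oracle over randomized exact
alignments in both orientations; transfer/invert round-trip identity
with strand flipping; exact shred-and-reassemble recovery of a
2 × 100 kb genome cut into 1–5 kb fragments with half the shreds
reverse-complemented (sizes chosen so the full suite runs in seconds
while leaving dozens of fragments per chromosome); overlap scenarios
with known N and S; the classification truth table with threshold
monotonicity; and byte-identical CLI re-runs.
`scripts/acceptance.py` recomputes these quantities from scratch at a
user-supplied seed.

## Known limitations

* Single reference only; no rearrangement detection, no mate-pair or
  optical-map integration, no gap-size estimation from insert libraries.
* BLAST tabular is the only alignment dialect read (the in-memory
  record is dialect-agnostic, so chain/net or PAF readers could be added
  without touching the pipeline).
* Unlocalized fragments are listed but not emitted as `*_random`-style
  sequences.
* Interoperability with other tools' fragment-map files is not
  guaranteed; the 8-column TSV here is this package's own format.
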