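# chromodraft

Reference-assisted arrangement of draft-assembly fragments (contigs or
scaffolds) into draft chromosome sequences, using nothing but their
pairwise alignments to the chromosomes of a closely related reference
genome. No mate-pair libraries, physical maps or read data are needed —
only a fragments FASTA, a reference FASTA and BLAST-tabular alignments
with bit scores.

It is aimed at genome projects for species without chromosome maps: a
*de novo* assembly of hundreds of thousands of fragments becomes a few
dozen putative chromosomes that can carry annotations, variants and
synteny analyses.

## Method

All coordinates are zero-based half-open. For each fragment the two
greatest alignment scores *s₁ ≥ s₂* are compared against a ratio
threshold *t > 1*:

* **anchored** if *s₁ / s₂ > t* (or the fragment has a single alignment):
  the fragment is placed at its best-scoring alignment;
* **unplaced** if the test fails and the two alignments lie on different
  reference chromosomes (alignment-free fragments are unplaced too);
* **unlocalized** if the test fails but both alignments lie on the same
  chromosome.

An anchored fragment of length *L* whose alignment covers
[*S̄*, *Ē*) of the fragment and [*S*, *E*) of the reference is extrapolated
to the full-fragment interval

```
direct:   S_F = S − S̄,        E_F = S_F + L
reverse:  E_F = E + S̄,        S_F = E_F − L
```

Anchored fragments are laid out per chromosome in placement order. When a
fragment overlaps its predecessor by *N* bp, it — and everything
downstream — is shifted right by *N + S* bp, where *S* is the gap
(insertion) size, so formerly overlapping neighbours end up exactly *S*
apart and non-overlapping spacing is preserved. Uncovered stretches
become runs of `N`. Annotations are lifted from fragment to chromosome
coordinates with the same algebra: a region [*s*, *e*) maps to
[*S_F* + *s*, *S_F* + *e*) for a direct placement and to
[*E_F* − *e*, *E_F* − *s*) for a reverse one, with feature strands
flipped.

## Worked example

A bundled simulator shreds a synthetic reference into fragments and emits
the exact alignments a perfect aligner would report, so the whole
pipeline runs without any external tool:

```
chromodraft simulate --seed 7 --n-chromosomes 2 --chromosome-length 6000 \
    --fragment-length-min 200 --fragment-length-max 700 --output-prefix sim
chromodraft fragmentmap --alignments sim_alignments.txt \
    --fragments sim_fragments.fa --ratio-threshold 1.5 --gap-size 50 \
    --output-prefix out
chromodraft assemble --map out_map.txt --fragments sim_fragments.fa \
    --output out_chromosomes.fa
chromodraft stat --map out_map.txt --fragments sim_fragments.fa
```

The `fragmentmap` step logs

```
INFO chromodraft: anchored 31, unlocalized 0, unplaced 0 of 31 fragments
```

and `stat` prints (tab-separated: category, key, count, bp)

```
fragments	anchored	31	12000
fragments	unlocalized	0	0
fragments	unplaced	0	0
chromosome	chr1	17	6000	0
chromosome	chr2	14	6000	0
total	length	12000
total	gap_bp	0
total	n_fraction	0.000000
```

i.e. all 31 shreds were anchored, both 6 kb chromosomes were rebuilt at
full length, and — because the shreds tile the reference without
conflicts — no `N` gaps were inserted. `out_map.txt` records each
fragment's interval and orientation; the emitted
`out_chromosomes.fa` is identical to `sim_reference.fa`. The
`transfer` and `track` subcommands lift BED/GFF3 annotations through the
map and export a BED6 browser track of fragment positions.

The two required parameters deserve explicit choices: the ratio threshold
must exceed 1 (1.2–1.5 is a reasonable starting point; higher is
stricter) and the gap size should be at least the sequencing library
insert size.

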