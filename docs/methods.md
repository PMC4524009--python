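# Methods

## Linking model

A long sequence that spans the break between two contigs carries, at
some spacing, one k-mer from the end of the first contig and one from
the start of the second. `pairlink` samples candidate pairs
systematically: for every window start `w ∈ {0, t, 2t, …}` with
`w + d ≤ |read|`, the pair `(read[w:w+k], read[w+d−k:w+d])` is
considered. The spacing `d` is therefore the *outer* span of the pair —
5' end of the first k-mer to 3' end of the second — so the pair behaves
exactly like an inward-facing mate pair of insert length `d`. This
convention is what makes the gap estimate

```
gap = d − ((L1 − p1) + (p2 + k))
```

exact integer arithmetic: for an error-free read the two sides of the
junction contribute `(L1 − p1)` and `(p2 + k)` bases of the span, and
whatever is left over is the gap (negative values are overlaps).
Positions `p1`, `p2` are 0-based k-mer starts re-expressed in the
joint's reading direction: a k-mer matching a contig's reverse strand at
forward coordinate `s` enters the formula as `p = L − (s + k)` with the
contig oriented `−`.

Candidate pairs pass four gates before becoming link evidence:

1. **membership** — both k-mers (ACGT-only) must be present in the
   assembly's k-mer set, checked against a Bloom filter (below);
2. **uniqueness** — both must occur exactly once across all contigs and
   both strands; repeated k-mers are rejected outright, not
   down-weighted;
3. **different contigs** — same-contig pairs are tallied and dropped;
4. **distance** — the calculated footprint `D = (L1 − p1) + (p2 + k)`
   must satisfy `|D − d| < e·d`, with strict bounds: at `d = 4000`,
   `e = 0.1` the accepted half-width is 400 bp and a footprint of
   exactly 4400 bp (a 400 bp implied overlap) is rejected.

Every surviving *observation* counts as one link (frequency-weighted
evidence); the same k-mer pair seen in three reads contributes three.
The two directed readings of a joint are folded onto one canonical key
(`(c1,o1)→(c2,o2)` ≡ `(c2,¬o2)→(c1,¬o1)`; the lexicographically smaller
tuple is stored), which also makes the link set invariant under
reverse-complementing the entire read set. If one unordered contig pair
accumulates observations in more than one orientation combination, only
the best-supported combination survives; the rest are reclassified as
orientation conflicts in the pairing-issue log. The log closes exactly:
accepted + same-contig + non-unique + out-of-tolerance +
orientation-conflict = all observations whose two k-mers occur on the
contigs (observations with an unplaced member are tallied separately).

A link's gap estimate is the arithmetic mean of its per-observation
gaps, rounded half away from zero (symmetric for gaps and overlaps).

## Membership filter

Contigs are shredded to k-mers on both strands as-seen (no
canonicalization — queries then need no canonical form and strand
bookkeeping stays downstream). The filter is sized from the exact
expected count `n = 2·Σ max(0, |c| − k + 1)` and the requested
false-positive rate `p` by the standard optimal formulas
`m = ⌈−n ln p / ln²2⌉`, `h = round((m/n) ln 2)`. k-mers are packed into
64-bit integers (2 bits per base, limiting k ≤ 32; useful k here is
15–26) and hashed with two fixed-seed splitmix64 streams combined by
double hashing, so construction is vectorized and byte-deterministic:
the same contigs in the same order always serialize to the same
`.bloom` file. The filter guarantees no false negatives; measured FPR
stays within 2× the target across p ∈ [1e-4, 1e-2]. An exact-set
backend with the identical query contract replaces the filter when `-x`
is given, and doubles as the oracle in equivalence tests (at p = 1e-6
both backends yield identical link sets on the test fixture). A saved
filter records (m, h, k, p, count); loading it under a different run k
is a hard error.

## Layout

Scaffolds are seeded from unused contigs in descending length (input
order breaks ties — deterministic, and long contigs are the most
reliably placed). Each seed extends rightward, then leftward, one
neighbour at a time: among the links leaving the current extremity in
the current orientation, the best-supported neighbour is chosen only if
it carries ≥ `l` links and the runner-up carries ≤ `a` times its count;
a tie for best is inherently ambiguous and stops extension, as does a
chosen neighbour that already sits in any scaffold (no splicing, which
also guarantees termination on cyclic link graphs). Orientations
compose: extending through a `−` contig flips the sense of its outgoing
links. Every contig ends in exactly one scaffold; singletons are
legitimate scaffolds.

Between iterative rounds (ascending `d` list) the membership structure
is rebuilt from the current scaffolds, because pad characters change
the sequence content; a pre-built filter supplied with `-r` is honoured
for the first round only. Sequence counts cannot increase across
rounds, and a converged assembly re-runs to itself unchanged (pads are
non-ACGT, so no k-mer spans a previous joint).

## Output encoding

Estimated gaps `g ≥ 1` become `g` N characters; overlaps and abutments
(`g ≤ 0`) become a single lowercase `n` (a zero-length separator would
silently erase the joint, so abutment is folded into the overlap
marker). The `.scaffold` summary uses one line per scaffold,
`scaffoldN,totalSize,chain`, with chain tokens
`<f|r><contigId>z<len>[m<gap>]` — a deterministic, parseable stand-in
grammar, not a claim of byte compatibility with any other tool.

## Error model

Run lengths of the three error types follow two-component mixtures:

* mismatch: `a_m · Poisson(λ_m) + (1 − a_m) · Geometric(p_m)`, tallied
  zero-indexed (a "run of 0" is a single mismatched base);
* insertion/deletion: `a_x · Weibull(λ_x, κ_x) + (1 − a_x) ·
  Geometric(p_x)`, tallied one-indexed, Weibull draws rounded to the
  nearest integer with a floor of 1.

The structured components reflect systematic base-caller failure modes;
the geometric components capture by-chance matches (independent
Bernoulli trials). The simulator alternates correct stretches of
geometric length (mean `stretch_mean`, default 14 bp, consistent with
the 13–15 bp bursts seen in early-chemistry 2D data) with error events
whose type is drawn from configurable weights. Mismatches substitute
through a 4×4 profile (zero diagonal, rows summing to 1) whose default
encodes the qualitative trend that A and T are more stable than C and G
and that wrong calls skew toward C and G; insertions add uniform bases
without consuming template; deletions skip template. The `r7_preset()`
parameters are *calibrated*, not transcribed from any fitted table:
they were tuned once so that simulated reads land at ≈78 % mean
identity (inside the reported 77.1 ± 10.6 % band for early-chemistry 2D
data), with equal insertion and deletion weights so the read→genome
coordinate mapping drifts without bias — the property that keeps
distance estimates centred at scale.

Fitting maximizes the mixture likelihood over the tally (L-BFGS-B with
box bounds, five starts: three moment-based plus two jittered; the best
likelihood wins, and failure of every start raises an explicit error).
Goodness of fit uses the plain Kolmogorov–Smirnov statistic: both the
empirical and fitted CDFs are step functions on the integers, so the
sup-distance is evaluated at the atoms from both sides, and the p-value
comes from the continuous Kolmogorov distribution — conservative for
discrete data; no discreteness correction is applied. A fitted weight
within 0.05 of the {0, 1} boundary is flagged degenerate (the sample is
effectively single-component).

## Synthetic fixtures

`make_truth` plants the ground truth the scaffolder is scored against:
a uniform-ACGT random genome cut into contigs (lengths =
`min_contig_len` plus a multinomial split of the slack; gaps uniform on
an inclusive range; optionally reverse-complemented with recorded `−`
orientation). `junction_spanning_reads` places reads so every junction
is straddled with at least a set flank, removing coverage luck from
truth-recovery experiments; depth is then the experiment's knob, not a
confounder. What the generator does *not* emulate: repeats (k-mer
uniqueness is nearly guaranteed in uniform random sequence at k = 15),
compositional bias, chimeric reads, and coverage fluctuation — so
passing tests demonstrate the correctness of the linking/layout
machinery and its noise tolerance, not performance on repeat-rich real
genomes.

## Problem sizes and defaults

The canonical fixture is a 200 kbp genome in 20 contigs with gaps of
100–500 bp; error-free experiments use 200 8-kbp reads, noise
experiments 40 reads per junction (≈30× genome coverage). Fixture runs
use `d = 6000` so the distance tolerance `e·d = 600` brackets the
largest planted gap — at `d = 4000` the default `e = 0.1` would reject
the very pairs that span a 450 bp gap. Tool defaults: `k = 15`,
`t = 2`, `e = 0.1`, `l = 5`, `a = 0.3`, `p = 0.001`, minimum contig
length 500 bp. Mixture-recovery checks use n = 10⁵ samples (parameter
recovery within 10 %) and 100 replicates of n = 4000 per error type for
the KS pass-rate harness.

## Known limitations

* k ≤ 32 (2-bit packing); no counting filter, no `.gz` input.
* One orientation combination per contig pair survives linking; genuine
  palindromic joins at even k would be discarded as self-conflicting.
* The layout is greedy: a skipped ambiguous neighbour is not re-queued,
  and no gap filling or base correction is attempted — scaffolding
  only.
* FASTQ qualities are read and discarded; the linking logic never uses
  them.
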