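# Methods

## Model

A Universal Sequence Map (USM) embeds a symbolic sequence S = s_1 … s_N over
an alphabet A into the unit hypercube [0,1]^h, h = ⌈log₂ max(2, |A|)⌉.  Each
symbol owns a cube corner E(s) (the binary expansion of its alphabet index),
and each unit receives two coordinates by the chaos-game iteration

    c_i^f = c_{i-1}^f + (E(s_i) − c_{i-1}^f)/2        (forward)
    c_i^b = c_{i+1}^b + (E(s_i) − c_{i+1}^b)/2        (backward)

Every step halves the distance to a corner, so in each dimension the binary
expansion of c_i^f stores the corner digits of units i, i−1, i−2, … — one
digit per unit — and c_i^b the digits of units i, i+1, i+2, ….  This is the
source of every property the package uses: coordinates are decodable back to
symbols, and the number of leading binary digits two coordinates share equals
the number of consecutive units of context they share.

**Circular seeding.**  The succession needs a pre-first (forward) and
post-last (backward) position.  Rather than the historical 0.5 start, the
seed is the fixed point reached by iterating full passes over the sequence
treated as a ring.  Each pass is an affine contraction with factor 2^−N, so
the fixed point is unique and convergence is immediate for all but the
shortest sequences.  Circularity makes the first coordinate sit exactly half
way between the last coordinate and the first unit's corner, and makes every
unit's history the infinite cyclic repetition of the sequence — decodes near
a sequence end wrap around rather than running out of digits.

**Distances.**  For two unit-interval numbers the iterated common-prefix
length is

    L(c1, c2):  x = 0;  while round(c1·2^x) == round(c2·2^x): x += 1;  return x

with half-up rounding (half-away-from-zero on these non-negative values).
In exact arithmetic L equals the number of leading binary digits shared: the
comparison at step x tests which side of .5 the remainders fall on, i.e. the
(x+1)-th digit itself.  The directional distance d_CGR is the minimum of L
over dimensions (an element-wise map followed by a min reduce); at the first
differing unit at least one dimension's digit differs, so d_CGR is exactly
the shared-context length in units.  The bidirectional combination

    d_USM = d_CGR(forward) + d_CGR(backward) − 1

counts the focal pair once and is the exact length of the identical segment
running through the two units; mismatched units give 0 + 0 − 1, clamped to 0.
The distance map is the table of d_USM over all unit pairs.  Every cell is a
pure function of two coordinate pairs, so any sub-block can be computed on
any worker and reassembled (the map/reduce contract); `dist_map` exposes the
block form directly, and `reduce_stat` applies a pairwise-associative
statistic (max, sum) by row-wise then across-row reduction.

## Numerical resolution and its consequences

A double holds 52 fraction bits, so a single coordinate pair can certify at
most ~52 shared units: `DEFAULT_CAP = 52` and a distance equal to the cap
means *saturated — at least this long*, not an exact value.  Two further
effects matter near that horizon:

- The encoder performs one rounding addition per step.  The stored value
  therefore differs from the ideal coordinate by ≲ 2^−53, which can flip
  stored digits at depth ~45–53 when the perturbation carries across a run
  of equal digits.  Distance reads in that band can be off by a few units in
  either direction; reads of small values are reliable.
- A long run of a single symbol drives a component onto its corner exactly
  (0.0 or 1.0): the halving recurrence rounds onto the boundary after ~53
  steps.  `decode_symbols` treats an exact-corner component as that digit
  repeating forever; `decode_bits` keeps the strict [0,1) domain.
- The terminal set bit of a terminating expansion is exactly where the
  rounding of the infinite circular expansion landed, so `decode_bits`
  withholds it by default; `all_bits=True` gives the complete expansion of
  the stored double (with which digit re-accumulation is exact).

## Alignment

The aligner finds all longest identical segments from coordinates alone.
An identical segment of length v crosses the distance map as a diagonal run
of v cells all holding v, so the maximum can be located by sampling each
diagonal with an adaptive stride of best-so-far + 1: any run longer than the
current best spans at least stride-many consecutive cells and cannot be
missed, and the stride only grows, so the scan is exact.  Each positive
sample is resolved into its full segment; a confirmation pass at stride
best-so-far then enumerates every tied hit, reported sorted by base start.
On saturated regions the effective stride reaches the cap, giving on the
order of one evaluation per cap² cells — the sparse-evaluation behavior the
cell-independent map makes possible.

Resolving a segment from one in-segment cell computes the forward extent f
and backward extent b (focal included each time); the hit has length
f + b − 1 starting at (i − f + 1, j − f + 1).  Two corrections keep this
exact at the edges:

- **Stitching.**  A saturated directional read certifies cap units; the
  routine re-anchors cap−1 units along the diagonal and reads again,
  accumulating until the distance resolves.
- **Certified boundaries.**  Because deep digits can be perturbed (above),
  every claimed run edge is verified with an exact focal read: the first
  binary digit of each component is the unit's own corner digit, so symbol
  equality of any cell is readable from coordinates without error.  A
  refuted claim is repaired by bisection over these exact reads (true
  matches from a focal cell form a contiguous run, so the boundary is
  monotone).  This keeps the scan provably exact while leaving the sparse
  jump behavior intact; the cost is O(log) extra reads per segment.
- **Trimming.**  Circular seeding lets raw distances count matches that
  wrap around a sequence end; extents are clipped to each sequence's linear
  span (every clipped unit is a genuine linear predecessor/successor, so no
  re-verification beyond the clip is needed).

One known degenerate case: after a mantissa-saturating run drives a
component to 1.0, the next 0-digit step lands exactly on 0.5, whose first
digit reads as 1.  The optional (default-on) symbolic verification layer
catches this; it never participates in the distance computation itself and
can be disabled to demonstrate the coordinates-only claim.

## Synthetic data and what the tests show

`usm.fixtures` generates uniform random sequences and pairs with planted
shared segments: the same random segment spliced into both sequences,
mismatches forced at all four edges, and candidates with accidental equal-or
-longer common substrings rejected and redrawn (deterministically from the
seed).  The symbolic oracles — circular match extent and DP longest common
substring — never touch coordinates, so their agreement with the distance
and alignment modules is a genuine cross-check of the coordinate arithmetic.

The generator emulates composition-free uniform sequences only: no GC bias,
no repeat families, no ambiguity codes.  Passing tests therefore demonstrate
the correctness of the arithmetic and the aligner on any input (the planted
construction is adversarial about edges and the cap), but say nothing about
biological plausibility of inputs; real genomes simply arrive as FASTA and
run through the same entry points.  Genome-scale tests use synthetic random
genomes (34 kb and 50 kb) with planted structure reproducing the published
workflow's shape — a 140-unit slice-constructed probe whose 113-unit maximal
hit straddles the cap, and a probe with three tied 12-unit matches; the
checks against the real phage and pneumococcal genomes run identically once
their FASTA files are downloaded, which the test environment does not
require.  Problem sizes throughout (sequences ≤ 2 000 units in property
suites, 10⁴ oracle cells, 200 DP-checked pairs) were chosen to exercise
every code path — both cap sides, stitching, ties, wrap trimming — at small
cost; the algorithms are insensitive to scale beyond the cap boundary.

## Parameter summary

| Parameter | Default | Meaning |
|---|---|---|
| `cap` | 52 | saturation threshold for L, in units; the double-precision resolution bound.  Values at the cap mean "at least this"; the aligner stitches across it.  Lowering it only adds stitching steps; raising it past 52 reads unreliable digits. |
| seed tolerance | 2⁻⁶⁰ | per-component circular-seed convergence; with the 2⁻ᴺ per-pass contraction, ⌈60/N⌉+1 passes suffice and reproduce the reference coordinates bit-for-bit. |
| `on_unknown` | `error` | policy for symbols outside a supplied alphabet (`error`/`skip`/`extend`); genomes may carry ambiguity codes, and silently mapping them would corrupt distances. |
| `verify` | on | symbolic re-check of reported hits when sequences are in memory; independent of the coordinate-only scan. |

## Limitations

- Identity only: no substitutions, gaps, or reverse-complement search.
- Exactness of distance values (as opposed to the aligner's certified
  output) degrades within ~8 units of the cap, as analyzed above.
- Coordinates are materialized for whole sequences (two h-vectors per
  unit); a 2 Mbp genome at h = 2 costs ~130 MB, and no streaming mode is
  provided.
- Alphabets larger than 2^h leave unassigned corners; decoding a coordinate
  that was not produced by a valid encoding can hit such a corner and
  raises rather than guessing.
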