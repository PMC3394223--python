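# usm — Universal Sequence Maps

Alignment-free sequence comparison and exact segment alignment from
chaos-game coordinates.

Comparing two sequences with dynamic programming couples every position to
its neighbours, which resists decomposition.  This package takes the
iterated-map route instead: every unit of a sequence over any alphabet is
encoded as a pair of coordinates in the unit hypercube — a forward and a
backward Chaos Game Representation (CGR) succession, seeded as if the
sequence were circular — and all comparison then happens between
coordinates, never between symbols.  The toolkit is aimed at anyone who
needs pairwise identical-segment detection that decomposes into fully
independent cell evaluations (map) aggregated by simple statistics
(reduce): each distance is a pure function of two coordinate pairs, so a
distance map can be computed block-wise on as many workers as you like.

## The model in brief

For S = s₁…s_N over alphabet A, each symbol owns a corner E(s) of
[0,1]^h with h = ⌈log₂ max(2,|A|)⌉, and

    cᵢᶠ = cᵢ₋₁ᶠ + (E(sᵢ) − cᵢ₋₁ᶠ)/2,    cᵢᵇ = cᵢ₊₁ᵇ + (E(sᵢ) − cᵢ₊₁ᵇ)/2.

Each coordinate's binary expansion stores one corner digit per unit of
context, so coordinates decode bijectively back to symbols, and the shared
leading-digit count of two coordinates,

    L(c₁,c₂):  x = 0;  while round(c₁·2ˣ) == round(c₂·2ˣ): x += 1,

counts shared context in units.  Taking min(L) over dimensions per
direction and combining both directions,

    d_USM(Ca, Cb) = d_CGRᶠ + d_CGRᵇ − 1,

is the exact length of the identical segment running through the two units
(0 for mismatched units).  The aligner finds all longest identical segments
by sparse adaptive-stride sampling of the (never materialized) distance
map, stitching across the ~52-unit double-precision resolution window, with
every claimed boundary certified by exact first-digit reads.  See
`docs/methods.md` for the full treatment.

## Worked example

The classic demonstration pair — base `acggctgctatctgcgtacggtcgac`, probe
`aaagctatctgaaaggtcaaa`:

```
$ usm align --base-seq acggctgctatctgcgtacggtcgac --probe-seq aaagctatctgaaaggtcaaa
largest identical segment has length 8 and aligns with position 6 in base sequence and position 3 in probe sequence
{"max_length": 8, "hits": [{"length": 8, "base_start": 6, "probe_start": 3, "segment": "gctatctg"}]}
```

`gctatctg` (8 units) is indeed the longest substring the two sequences
share, found without ever comparing symbols.  The encoding behind it:

```
$ usm encode --seq acggctgctatctgcgtacggtcgac --format tsv --decimals 4 | head -3
0	a	0.0906	0.2994	0.2135	0.3036
1	c	0.0453	0.6497	0.4271	0.6072
2	g	0.5226	0.3248	0.8543	0.2145
```

(index, symbol, forward x/y, backward x/y; the first forward row sits half
way between the last row and the 'a' corner — the circular-seeding
fingerprint).  A single-cell distance, here two 1-D coordinates sharing a
6-unit context:

```
$ usm dist --c1 0.01 --c2 0.001
6
```

The same operations are the library surface:

```python
from usm import encode, align, dist_map, reduce_stat

base = encode("acggctgctatctgcgtacggtcgac")
probe = encode("aaagctatctgaaaggtcaaa", base.assignment)
result = align(base, probe)        # max_length 8, hit at (6, 3)
dmap = dist_map(base, probe)       # 26 x 21 table of d_USM values
reduce_stat(dmap, "max")           # 8
```

Genome-scale FASTA goes through the same entry points
(`usm align --base genome.fa --probe-seq ...`); multi-hit probes report all
tied maximal segments sorted by position in the base sequence.

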