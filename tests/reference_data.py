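"""Frozen reference values for the worked nucleotide example.

The 26-unit base / 21-unit probe pair below is the canonical published
worked example for circularly-seeded bidirectional chaos-game encoding; the
coordinate tables (truncated toward zero at 4 decimals), the full-precision
coordinates of the highlighted unit pair, the binary-expansion digit lists,
and the 26x21 distance map are the reference implementation's printed
outputs, frozen here verbatim for regression checks.
"""

BASE_SEQ = "acggctgctatctgcgtacggtcgac"
PROBE_SEQ = "aaagctatctgaaaggtcaaa"

# one row per unit: (symbol, corner, forward coords, backward coords),
# coordinates truncated toward zero at 4 decimal places
BASE_TABLE = [
    ("a", (0, 0), (0.0906, 0.2994), (0.2135, 0.3036)),
    ("c", (0, 1), (0.0453, 0.6497), (0.4271, 0.6072)),
    ("g", (1, 0), (0.5226, 0.3248), (0.8543, 0.2145)),
    ("g", (1, 0), (0.7613, 0.1624), (0.7086, 0.4290)),
    ("c", (0, 1), (0.3806, 0.5812), (0.4173, 0.8580)),
    ("t", (1, 1), (0.6903, 0.7906), (0.8347, 0.7161)),
    ("g", (1, 0), (0.8451, 0.3953), (0.6695, 0.4322)),
    ("c", (0, 1), (0.4225, 0.6976), (0.3390, 0.8645)),
    ("t", (1, 1), (0.7112, 0.8488), (0.6781, 0.7291)),
    ("a", (0, 0), (0.3556, 0.4244), (0.3563, 0.4582)),
    ("t", (1, 1), (0.6778, 0.7122), (0.7127, 0.9164)),
    ("c", (0, 1), (0.3389, 0.8561), (0.4254, 0.8328)),
    ("t", (1, 1), (0.6694, 0.9280), (0.8508, 0.6656)),
    ("g", (1, 0), (0.8347, 0.4640), (0.7016, 0.3312)),
    ("c", (0, 1), (0.4173, 0.7320), (0.4033, 0.6624)),
    ("g", (1, 0), (0.7086, 0.3660), (0.8067, 0.3248)),
    ("t", (1, 1), (0.8543, 0.6830), (0.6134, 0.6497)),
    ("a", (0, 0), (0.4271, 0.3415), (0.2269, 0.2994)),
    ("c", (0, 1), (0.2135, 0.6707), (0.4539, 0.5988)),
    ("g", (1, 0), (0.6067, 0.3353), (0.9079, 0.1976)),
    ("g", (1, 0), (0.8033, 0.1676), (0.8158, 0.3953)),
    ("t", (1, 1), (0.9016, 0.5838), (0.6316, 0.7907)),
    ("c", (0, 1), (0.4508, 0.7919), (0.2633, 0.5814)),
    ("g", (1, 0), (0.7254, 0.3959), (0.5266, 0.1629)),
    ("a", (0, 0), (0.3627, 0.1979), (0.0533, 0.3259)),
    ("c", (0, 1), (0.1813, 0.5989), (0.1067, 0.6518)),
]

PROBE_TABLE = [
    ("a", (0, 0), (0.0277, 0.0471), (0.0835, 0.0537)),
    ("a", (0, 0), (0.0138, 0.0235), (0.1670, 0.1074)),
    ("a", (0, 0), (0.0069, 0.0117), (0.3341, 0.2148)),
    ("g", (1, 0), (0.5034, 0.0058), (0.6683, 0.4297)),
    ("c", (0, 1), (0.2517, 0.5029), (0.3367, 0.8595)),
    ("t", (1, 1), (0.6258, 0.7514), (0.6735, 0.7191)),
    ("a", (0, 0), (0.3129, 0.3757), (0.3471, 0.4382)),
    ("t", (1, 1), (0.6564, 0.6878), (0.6943, 0.8764)),
    ("c", (0, 1), (0.3282, 0.8439), (0.3886, 0.7529)),
    ("t", (1, 1), (0.6641, 0.9219), (0.7773, 0.5058)),
    ("g", (1, 0), (0.8320, 0.4609), (0.5547, 0.0117)),
    ("a", (0, 0), (0.4160, 0.2304), (0.1094, 0.0234)),
    ("a", (0, 0), (0.2080, 0.1152), (0.2189, 0.0469)),
    ("a", (0, 0), (0.1040, 0.0576), (0.4378, 0.0939)),
    ("g", (1, 0), (0.5520, 0.0288), (0.8756, 0.1879)),
    ("g", (1, 0), (0.7760, 0.0144), (0.7513, 0.3758)),
    ("t", (1, 1), (0.8880, 0.5072), (0.5026, 0.7516)),
    ("c", (0, 1), (0.4440, 0.7536), (0.0052, 0.5033)),
    ("a", (0, 0), (0.2220, 0.3768), (0.0104, 0.0067)),
    ("a", (0, 0), (0.1110, 0.1884), (0.0208, 0.0134)),
    ("a", (0, 0), (0.0555, 0.0942), (0.0417, 0.0268)),
]

# full-precision coordinates of the highlighted homologous 'c' units:
# base unit index 7 and probe unit index 4 (0-based)
BASE_UNIT8_FWD = (0.4225834224013004, 0.6976523056276487)
BASE_UNIT8_BWD = (0.3390888473255761, 0.8645502159677478)
PROBE_UNIT5_FWD = (0.2517343767806896, 0.502943755599859)
PROBE_UNIT5_BWD = (0.33679262961989864, 0.8595585153381897)

# reference binary expansions of the two base-unit-8 forward components
BITS_DIM1 = [0, 1, 1, 0, 1, 1, 0, 0, 0, 0, 1, 0, 1, 1, 1, 0, 0, 1, 1, 0, 1, 1,
             0, 1, 0, 1, 0, 1, 1, 0, 1, 1, 0, 0, 0, 0, 1, 0, 1, 1, 1, 0, 0, 1,
             1, 0, 1, 1, 0, 1, 0, 1]
BITS_DIM2 = [1, 0, 1, 1, 0, 0, 1, 0, 1, 0, 0, 1, 1, 0, 0, 1, 0, 1, 0, 1, 0, 1,
             1, 1, 0, 1, 1, 0, 1, 1, 0, 0, 1, 0, 1, 0, 0, 1, 1, 0, 0, 1, 0, 1,
             0, 1, 0, 1, 1, 1]

# cyclic decode of the unit-8 forward coordinates, after reversal
# (periods in the published rendering mark the circular stitch; stripped here)
DECODED_FWD_REVERSED = "tctgcgtacggtcgac" + BASE_SEQ + "acggctgc"
# cyclic decode of the unit-8 backward coordinates (focal unit first)
DECODED_BWD = "ctatctgcgtacggtcgac" + BASE_SEQ + "acggct"

# the 26 x 21 distance map of the pair (rows = base units, cols = probe units)
DIST_MATRIX = [
    [1, 1, 1, 0, 0, 0, 1, 0, 0, 0, 0, 1, 1, 1, 0, 0, 0, 0, 2, 1, 1],
    [0, 0, 0, 0, 1, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0],
    [0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 2, 1, 0, 0, 0, 0, 0],
    [0, 0, 0, 3, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 1, 2, 0, 0, 0, 0, 0],
    [0, 0, 0, 0, 3, 0, 0, 0, 3, 0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0],
    [0, 0, 0, 0, 0, 3, 0, 1, 0, 3, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0],
    [0, 0, 0, 8, 0, 0, 0, 0, 0, 0, 3, 0, 0, 0, 1, 1, 0, 0, 0, 0, 0],
    [0, 0, 0, 0, 8, 0, 0, 0, 2, 0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0],
    [0, 0, 0, 0, 0, 8, 0, 1, 0, 2, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0],
    [1, 1, 1, 0, 0, 0, 8, 0, 0, 0, 0, 1, 1, 1, 0, 0, 0, 0, 1, 1, 1],
    [0, 0, 0, 0, 0, 1, 0, 8, 0, 1, 0, 0, 0, 0, 0, 0, 2, 0, 0, 0, 0],
    [0, 0, 0, 0, 2, 0, 0, 0, 8, 0, 0, 0, 0, 0, 0, 0, 0, 2, 0, 0, 0],
    [0, 0, 0, 0, 0, 2, 0, 1, 0, 8, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0],
    [0, 0, 0, 2, 0, 0, 0, 0, 0, 0, 8, 0, 0, 0, 1, 1, 0, 0, 0, 0, 0],
    [0, 0, 0, 0, 2, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0],
    [0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 1, 2, 0, 0, 0, 0, 0],
    [0, 0, 0, 0, 0, 2, 0, 1, 0, 1, 0, 0, 0, 0, 0, 0, 2, 0, 0, 0, 0],
    [1, 1, 1, 0, 0, 0, 2, 0, 0, 0, 0, 1, 1, 1, 0, 0, 0, 0, 1, 1, 1],
    [0, 0, 0, 0, 1, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0],
    [0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 4, 1, 0, 0, 0, 0, 0],
    [0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 1, 4, 0, 0, 0, 0, 0],
    [0, 0, 0, 0, 0, 1, 0, 2, 0, 1, 0, 0, 0, 0, 0, 0, 4, 0, 0, 0, 0],
    [0, 0, 0, 0, 1, 0, 0, 0, 2, 0, 0, 0, 0, 0, 0, 0, 0, 4, 0, 0, 0],
    [0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 2, 0, 0, 0, 1, 1, 0, 0, 0, 0, 0],
    [1, 1, 1, 0, 0, 0, 1, 0, 0, 0, 0, 2, 1, 1, 0, 0, 0, 0, 1, 1, 1],
    [0, 0, 0, 0, 1, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 2, 0, 0, 0],
]

# published alignment of the pair: max length, 0-based base and probe starts
ALIGN_MAX = 8
ALIGN_BASE_START = 6
ALIGN_PROBE_START = 3
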