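"""Synthetic sequences and purely symbolic oracles.

Everything here works on symbol strings only — never on coordinates — so
agreement between these oracles and the distance/aligner modules is a
genuine cross-check of the coordinate arithmetic, not a tautology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distance import DEFAULT_CAP
from .errors import UsmError

__all__ = [
    "PlantedPair",
    "random_sequence",
    "plant_segment",
    "oracle_match_extent",
    "oracle_longest_common_substring",
]


def random_sequence(alphabet, n: int, seed: int) -> str:
    """Uniform random symbol string of length *n*; deterministic per seed."""
    if n < 1:
        raise UsmError("sequence length must be >= 1")
    symbols = list(alphabet)
    rng = np.random.default_rng(seed)
    return "".join(symbols[k] for k in rng.integers(0, len(symbols), size=n))


@dataclass(frozen=True)
class PlantedPair:
    """Two random sequences sharing exactly one maximal planted segment."""

    base_seq: str
    probe_seq: str
    planted: tuple[tuple[str, int, int], ...]


def _splice(seq: str, start: int, piece: str) -> str:
    return seq[:start] + piece + seq[start + len(piece) :]


def plant_segment(
    alphabet,
    base_len: int,
    probe_len: int,
    seg_len: int,
    base_start: int,
    probe_start: int,
    seed: int,
    *,
    unique: bool = True,
    max_attempts: int = 200,
) -> PlantedPair:
    """A random pair whose unique maximal common segment is the planted one.

    The same random segment is spliced into both sequences at the stated
    starts; flanking symbols at all four segment edges are forced to
    mismatch so the planted segment cannot extend, and candidates where the
    random context accidentally contains a common substring of length >=
    seg_len elsewhere are rejected and redrawn (seeds derived from *seed*,
    so the construction is deterministic).  With ``unique=False`` the
    rejection step is skipped — useful for planting segments so short that
    equally long matches necessarily occur by chance.
    """
    symbols = list(alphabet)
    if len(symbols) < 2:
        raise UsmError("planting needs at least two symbols to force edge mismatches")
    if not (0 <= base_start and base_start + seg_len <= base_len):
        raise UsmError("planted span does not fit in the base sequence")
    if not (0 <= probe_start and probe_start + seg_len <= probe_len):
        raise UsmError("planted span does not fit in the probe sequence")

    for attempt in range(max_attempts):
        rng = np.random.default_rng([seed, attempt])
        draw = lambda n: "".join(symbols[k] for k in rng.integers(0, len(symbols), n))
        segment = draw(seg_len)
        base = _splice(draw(base_len), base_start, segment)
        probe = _splice(draw(probe_len), probe_start, segment)

        # force mismatches at the four segment edges (where both exist)
        def clash(s: str) -> str:
            others = [x for x in symbols if x != s]
            return others[int(rng.integers(0, len(others)))]

        if base_start > 0 and probe_start > 0:
            probe = _splice(probe, probe_start - 1, clash(base[base_start - 1]))
        be, pe = base_start + seg_len, probe_start + seg_len
        if be < base_len and pe < probe_len:
            probe = _splice(probe, pe, clash(base[be]))

        pair = PlantedPair(base, probe, ((segment, base_start, probe_start),))
        if not unique:
            return pair
        length, positions = oracle_longest_common_substring(base, probe)
        if length == seg_len and positions == [(base_start, probe_start)]:
            return pair
    raise UsmError(
        f"could not plant a unique maximal segment of length {seg_len} "
        f"in {max_attempts} attempts"
    )


def oracle_match_extent(
    base_seq: str, probe_seq: str, i: int, j: int, cap: int = DEFAULT_CAP
) -> int:
    """Symbolic ground truth for d_USM: circular match run through (i, j).

    Both sequences are read as rings (mirroring circular seeding).  The run
    of equal symbols through the focal pair is extended left while
    predecessors match and right while successors match, each direction
    capped at *cap* steps, and the focal pair counted once.
    """
    nb, npr = len(base_seq), len(probe_seq)
    if not (0 <= i < nb and 0 <= j < npr):
        raise UsmError(f"cell ({i}, {j}) outside the {nb}x{npr} map")
    if base_seq[i] != probe_seq[j]:
        return 0
    f = 1
    while f < cap and base_seq[(i - f) % nb] == probe_seq[(j - f) % npr]:
        f += 1
    b = 1
    while b < cap and base_seq[(i + b) % nb] == probe_seq[(j + b) % npr]:
        b += 1
    return f + b - 1


def oracle_longest_common_substring(a: str, b: str) -> tuple[int, list[tuple[int, int]]]:
    """Classic DP longest common substring with all tied 0-based start pairs.

    Row-rolling dynamic programming (vectorized across *b*); returns the
    maximal length (0 for disjoint alphabets) and the sorted, deduplicated
    list of (start in a, start in b) achieving it.
    """
    if not a or not b:
        raise UsmError("oracle requires non-empty strings")
    b_arr = np.frombuffer(b.encode("utf-32-le"), dtype=np.uint32)
    prev = np.zeros(len(b), dtype=np.int64)
    best = 0
    ends: list[tuple[int, int]] = []
    for i, ch in enumerate(a):
        code = ord(ch)
        cur = np.zeros(len(b), dtype=np.int64)
        eq = b_arr == code
        cur[0] = eq[0]
        cur[1:] = np.where(eq[1:], prev[:-1] + 1, 0)
        row_max = int(cur.max())
        if row_max > best:
            best = row_max
            ends = [(i, int(j)) for j in np.flatnonzero(cur == best)]
        elif row_max == best and best > 0:
            ends.extend((i, int(j)) for j in np.flatnonzero(cur == best))
        prev = cur
    if best == 0:
        return 0, []
    starts = sorted({(ie - best + 1, je - best + 1) for ie, je in ends})
    return best, starts
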