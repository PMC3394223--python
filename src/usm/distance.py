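"""Coordinate-only similarity between sequence units.

All comparisons here read numeric coordinates only — never symbols.  The
primitive L counts how many leading binary digits two unit-interval numbers
share (under half-up rounding), which is exactly how many consecutive units
of shared context the two coordinates encode.  Taking L per cube dimension
and reducing with min gives the directional distance d_CGR; the forward and
backward directional distances of a unit pair combine into

    d_USM = d_CGR^forward + d_CGR^backward - 1

the exact length of the identical segment running through the two units
(the focal pair is counted by both directions, hence the -1; mismatched
units give 0+0-1, clamped to 0).  A full table of d_USM over all unit pairs
is the distance map; every cell is a pure function of two coordinate pairs,
so any sub-block can be computed independently and reassembled — the
map/reduce contract the aligner and any distributed evaluation rely on.

Double precision bounds L: beyond DEFAULT_CAP shared digits two coordinates
are numerically indistinguishable, so a value equal to the cap means
"saturated, at least this long", not an exact length.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce as _reduce
from typing import Callable, NamedTuple, Sequence

import numpy as np

from ._util import round_half_up
from .encoding import USMEncoding
from .errors import UsmError

__all__ = [
    "DEFAULT_CAP",
    "DistanceMap",
    "prefix_length",
    "dist_cgr",
    "dist_usm",
    "dist_usm_detail",
    "dist_map",
    "reduce_stat",
]

#: saturation threshold for L: a double carries 52 fraction bits, so common
#: prefixes longer than 52 digits cannot be told apart reliably.
DEFAULT_CAP = 52


def prefix_length(c1: float, c2: float, cap: int = DEFAULT_CAP) -> int:
    """Length of the common binary prefix of two unit-interval numbers.

    Literal iterated loop: x = 0; while round(c1 * 2**x) == round(c2 * 2**x)
    and x < cap: x += 1; return x.  Rounding is half away from zero
    (half-up on these non-negative values); doubling is exact, so no error
    accumulates.  A return equal to *cap* means saturated.
    """
    if cap < 1:
        raise UsmError("cap must be >= 1")
    x = 0
    v1, v2 = c1, c2
    while round_half_up(v1) == round_half_up(v2) and x < cap:
        x += 1
        v1 *= 2.0
        v2 *= 2.0
    return x


def dist_cgr(
    ca: Sequence[float], cb: Sequence[float], cap: int = DEFAULT_CAP
) -> int:
    """Directional distance between two coordinate vectors.

    Element-wise map of :func:`prefix_length` over the dimensions, followed
    by a min reduction.  The two-stage decomposition is part of the contract:
    per-dimension lengths are independent map results.
    """
    if len(ca) != len(cb):
        raise UsmError(f"dimension mismatch: {len(ca)} vs {len(cb)}")
    per_dim = map(lambda pair: prefix_length(pair[0], pair[1], cap), zip(ca, cb))
    return _reduce(min, per_dim)


class USMDistance(NamedTuple):
    """d_USM with its directional parts and saturation status."""

    value: int
    forward: int
    backward: int
    saturated: bool


CoordPair = tuple[Sequence[float], Sequence[float]]


def dist_usm_detail(Ca: CoordPair, Cb: CoordPair, cap: int = DEFAULT_CAP) -> USMDistance:
    """d_USM between two (forward, backward) coordinate pairs, with detail.

    ``saturated`` is set when either directional distance hit *cap*, in which
    case ``value`` is a lower bound and the aligner must stitch.
    """
    f = dist_cgr(Ca[0], Cb[0], cap)
    b = dist_cgr(Ca[1], Cb[1], cap)
    value = max(f + b - 1, 0)  # mismatched units give -1, clamped
    return USMDistance(value, f, b, f >= cap or b >= cap)


def dist_usm(Ca: CoordPair, Cb: CoordPair, cap: int = DEFAULT_CAP) -> int:
    """Exact length of the identical segment through two homologous units."""
    return dist_usm_detail(Ca, Cb, cap).value


@dataclass
class DistanceMap:
    """Table of d_USM over all unit pairs of a base and a probe sequence.

    Rows are base units, columns probe units.  ``values[i, j] == 0`` exactly
    when the two units' symbols differ.
    """

    values: np.ndarray
    base_length: int
    probe_length: int
    saturation_cap: int
    row_offset: int = 0
    col_offset: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def reduce(self, statistic: Callable[[int, int], int] | str) -> int:
        return reduce_stat(self, statistic)

    def to_tsv(self) -> str:
        return "\n".join("\t".join(str(v) for v in row) for row in self.values) + "\n"


def _cell(base: USMEncoding, probe: USMEncoding, i: int, j: int, cap: int) -> int:
    return dist_usm(base.usm(i), probe.usm(j), cap)


def dist_map(
    base: USMEncoding,
    probe: USMEncoding,
    cap: int = DEFAULT_CAP,
    *,
    rows: tuple[int, int] | None = None,
    cols: tuple[int, int] | None = None,
) -> DistanceMap:
    """d_USM distance map between two encodings over the same cube.

    *rows* / *cols* select a half-open rectangular sub-block; each cell is a
    pure function of its two coordinate pairs, so blocks computed separately
    reassemble into exactly the whole-matrix result (cell independence).
    """
    if base.assignment.to_dict() != probe.assignment.to_dict():
        raise UsmError("base and probe are framed by different corner assignments")
    r0, r1 = rows if rows is not None else (0, len(base))
    c0, c1 = cols if cols is not None else (0, len(probe))
    bf, bb = base.cgr_forward, base.cgr_backward
    pf, pb = probe.cgr_forward, probe.cgr_backward
    values = np.empty((r1 - r0, c1 - c0), dtype=np.int64)
    for i in range(r0, r1):
        Ca = (tuple(bf[i]), tuple(bb[i]))
        for j in range(c0, c1):
            values[i - r0, j - c0] = dist_usm(Ca, (tuple(pf[j]), tuple(pb[j])), cap)
    return DistanceMap(values, len(base), len(probe), cap, r0, c0)


_STATS: dict[str, Callable[[int, int], int]] = {
    "max": lambda a, b: a if a >= b else b,
    "sum": lambda a, b: a + b,
    "min": lambda a, b: a if a <= b else b,
}


def reduce_stat(dmap: DistanceMap, statistic: Callable[[int, int], int] | str) -> int:
    """Nested reduction of a distance map with a pairwise-associative statistic.

    Each row is reduced to one value, then the row results are reduced; any
    associative pair statistic (max, sum, ...) gives a partition-independent
    answer.
    """
    if dmap.values.size == 0:
        raise UsmError("cannot reduce an empty distance map")
    stat = _STATS[statistic] if isinstance(statistic, str) else statistic
    row_results = [_reduce(stat, (int(v) for v in row)) for row in dmap.values]
    return _reduce(stat, row_results)
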