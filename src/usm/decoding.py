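"""Bijective decoding of chaos-game coordinates back to symbols.

A coordinate component stores one binary digit per sequence unit, most recent
unit first, so repeated doubling reads the unit history straight back out:
the integer part after each doubling is the next digit.  Assembling the k-th
digit of every component yields the corner — hence the symbol — of the unit k
steps away from the focal unit.  Forward coordinates therefore decode the
sequence *backwards* from the focal unit (callers reverse the string),
backward coordinates decode it forwards.
"""

from __future__ import annotations

from typing import Sequence

from .alphabet import CornerAssignment
from .errors import DecodeError

__all__ = ["decode_bits", "decode_symbols"]


def decode_bits(
    x: float, max_bits: int | None = None, *, all_bits: bool = False
) -> list[int]:
    """Binary expansion of x in [0, 1), most significant digit first.

    Digits are read by repeated doubling (digit = integer part after
    doubling, continue with the fractional part); doubling a double is
    exact, so no error accumulates and the expansion terminates within ~60
    digits for typical coordinates (0.0 yields []).  *max_bits* truncates
    the expansion.

    A stored coordinate is the rounded image of the true coordinate, whose
    circular expansion never terminates; the terminal set bit of the
    stored value's (always terminating) expansion is where that rounding
    landed and carries no reliable sequence context, so by default it is
    not emitted.  Pass ``all_bits=True`` for the complete expansion of the
    floating-point value itself — with it, re-accumulating the digits
    (sum of digit * 2**-k) reproduces *x* exactly.
    """
    if not (0.0 <= x < 1.0):
        raise DecodeError(f"coordinate {x!r} outside [0, 1)")
    bits: list[int] = []
    while x != 0.0 and (max_bits is None or len(bits) < max_bits):
        if not all_bits and x == 0.5:  # only the terminal bit remains
            break
        x *= 2.0
        digit = int(x)
        bits.append(digit)
        x -= digit
    return bits


def decode_symbols(
    coord: Sequence[float],
    assignment: CornerAssignment,
    max_units: int | None = None,
) -> str:
    """Decode one coordinate vector into the symbol string it encodes.

    For depth k = 1, 2, ... the k-th binary digit of each component is
    assembled into a corner and the owning symbol emitted; decoding stops when
    the shortest component expansion is exhausted (components routinely hold
    unequal digit counts) or *max_units* is reached.  A component sitting
    exactly on 0.0 or 1.0 — reachable when a long run of one symbol saturates
    the mantissa — contributes its digit at every depth; if every component is
    corner-saturated, *max_units* is required to bound the output.

    Raises :class:`DecodeError` if *coord* has the wrong dimensionality or an
    assembled corner is unassigned (possible when 2**dims > |alphabet|).
    """
    if len(coord) != assignment.dims:
        raise DecodeError(
            f"coordinate has {len(coord)} components, cube has {assignment.dims}"
        )
    expansions: list[list[int] | int] = [
        int(x) if x in (0.0, 1.0) else decode_bits(x, max_units) for x in coord
    ]
    finite_lengths = [len(e) for e in expansions if isinstance(e, list)]
    if not finite_lengths and max_units is None:
        raise DecodeError(
            "every component sits on a cube corner; pass max_units to decode"
        )
    depth = min(finite_lengths) if finite_lengths else max_units
    if max_units is not None:
        depth = min(depth, max_units)
    out = []
    for k in range(depth):
        corner = tuple(e if isinstance(e, int) else e[k] for e in expansions)
        symbol = assignment.symbol_of(corner)
        if symbol is None:
            raise DecodeError(f"corner {corner} at depth {k + 1} matches no symbol")
        out.append(symbol)
    return "".join(out)
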