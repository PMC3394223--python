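"""Small numeric helpers shared across modules."""

from __future__ import annotations

import math

_TWO_52 = 2.0**52


def round_half_up(v: float) -> int:
    """Round a non-negative value half away from zero.

    Doubles at or above 2**52 are already integers, so they are returned
    unchanged; below that bound ``v + 0.5`` is exact and floor is safe.
    This matches ECMAScript's Math.round on non-negative input, unlike
    Python's banker's rounding.
    """
    if v >= _TWO_52:
        return int(v)
    return math.floor(v + 0.5)


def truncate_toward_zero(x: float, decimals: int = 4) -> float:
    """Truncate (not round) *x* toward zero at *decimals* decimal places."""
    scale = 10.0**decimals
    return math.trunc(x * scale) / scale
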