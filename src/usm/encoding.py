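"""Forward and backward chaos-game coordinate successions with circular seeding.

Each unit s_i of a sequence S = s_1 ... s_N is encoded twice by the iterated
map

    c_i = c_{i-1} + (E(s_i) - c_{i-1}) / 2

where E(s) is the hypercube corner of symbol s: once running forward over the
sequence (c_i^f) and once backward (c_i^b).  Because every step moves half the
remaining distance to a corner, the d-th coordinate of unit i stores the
corner digits of units i, i-1, i-2, ... (forward) or i, i+1, i+2, ...
(backward) as its binary expansion — one digit per unit per dimension.

The succession is seeded *circularly*: rather than starting from 0.5, the
pre-first (forward) or post-last (backward) position is the unique fixed
point reached by iterating full passes over the sequence treated as a ring.
Each full pass contracts any starting point by 2^-N, so convergence to the
fixed point is immediate for all but the shortest sequences, and the first
coordinate of the succession ends up exactly half way between the last
coordinate and the first unit's corner.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from ._util import truncate_toward_zero
from .alphabet import CornerAssignment, build_corner_assignment, extract_alphabet
from .errors import UnknownSymbolError, UsmError

__all__ = ["USMEncoding", "encode", "solve_circular_seed"]

#: per-component convergence tolerance for the circular seed
SEED_TOL = 2.0**-60

UnknownPolicy = Literal["error", "skip", "extend"]


def _one_pass(seed: list[float], corner_seq: Sequence[Sequence[float]]) -> list[float]:
    c = list(seed)
    h = len(c)
    for corner in corner_seq:
        # literal recurrence: one rounding addition per component, halving exact
        c = [c[d] + (corner[d] - c[d]) / 2 for d in range(h)]
    return c


def solve_circular_seed(
    corner_sequence: Sequence[Sequence[float]],
    direction: Literal["forward", "backward"] = "forward",
) -> list[float]:
    """Fixed-point seed of the circular succession over *corner_sequence*.

    Returns the coordinate which, used as the pre-first (forward) or
    post-last (backward) position, reproduces itself after one full pass over
    the circular sequence.  Starting from 0.5 per component, full passes are
    iterated until the seed moves by less than 2**-60 per component; each
    pass contracts by 2**-N, so ceil(60/N)+1 passes always suffice.
    """
    if not len(corner_sequence):
        raise UsmError("cannot seed an empty corner sequence")
    order = list(corner_sequence)
    if direction == "backward":
        order.reverse()
    elif direction != "forward":
        raise ValueError(f"direction must be 'forward' or 'backward', got {direction!r}")
    n = len(order)
    h = len(order[0])
    seed = [0.5] * h
    for _ in range(math.ceil(60 / n) + 1):
        nxt = _one_pass(seed, order)
        if max(abs(a - b) for a, b in zip(nxt, seed)) < SEED_TOL:
            seed = nxt
            break
        seed = nxt
    return seed


@dataclass
class USMEncoding:
    """A sequence together with its per-unit USM coordinates.

    Attributes
    ----------
    seq:
        The encoded symbol string (after any unknown-symbol policy applied).
    assignment:
        The :class:`CornerAssignment` framing the hypercube.
    corners_per_unit:
        (N, dims) integer array; row i is the corner of unit i.
    cgr_forward, cgr_backward:
        (N, dims) float arrays of the forward / backward successions.
    """

    seq: str
    assignment: CornerAssignment
    corners_per_unit: np.ndarray
    cgr_forward: np.ndarray
    cgr_backward: np.ndarray

    def __len__(self) -> int:
        return len(self.seq)

    def usm(self, i: int) -> tuple[tuple[float, ...], tuple[float, ...]]:
        """The (forward, backward) coordinate pair of unit *i* (0-based)."""
        return tuple(self.cgr_forward[i]), tuple(self.cgr_backward[i])

    # -- serialization ----------------------------------------------------

    def to_json(self, *, indent: int | None = None) -> str:
        payload = {
            "seq": self.seq,
            "assignment": self.assignment.to_dict(),
            "cgr_forward": self.cgr_forward.tolist(),
            "cgr_backward": self.cgr_backward.tolist(),
        }
        return json.dumps(payload, indent=indent)

    def to_tsv(self, *, decimals: int | None = None) -> str:
        """One row per unit: index, symbol, forward components, backward components.

        With *decimals* set, components are truncated toward zero at that many
        decimal places (the convention used by the printed reference tables).
        """

        def fmt(x: float) -> str:
            if decimals is None:
                return repr(x)
            return f"{truncate_toward_zero(x, decimals):.{decimals}f}"

        lines = []
        for i, s in enumerate(self.seq):
            parts = [str(i), s]
            parts += [fmt(x) for x in self.cgr_forward[i]]
            parts += [fmt(x) for x in self.cgr_backward[i]]
            lines.append("\t".join(parts))
        return "\n".join(lines) + "\n"


def _apply_policy(
    seq: str, assignment: CornerAssignment, on_unknown: UnknownPolicy
) -> tuple[str, CornerAssignment]:
    unknown_positions = [i for i, s in enumerate(seq) if s not in assignment]
    if not unknown_positions:
        return seq, assignment
    if on_unknown == "error":
        i = unknown_positions[0]
        raise UnknownSymbolError(seq[i], i)
    if on_unknown == "skip":
        return "".join(s for s in seq if s in assignment), assignment
    if on_unknown == "extend":
        extra = dict.fromkeys(seq[i] for i in unknown_positions)
        return seq, build_corner_assignment(list(assignment.alphabet) + list(extra))
    raise ValueError(f"unknown-symbol policy {on_unknown!r} not recognized")


def encode(
    seq: str,
    alphabet: Iterable[str] | CornerAssignment | None = None,
    *,
    upper: bool = False,
    on_unknown: UnknownPolicy = "error",
) -> USMEncoding:
    """Encode *seq* into forward and backward circularly-seeded coordinates.

    Parameters
    ----------
    seq:
        Non-empty symbol string.
    alphabet:
        Optional explicit alphabet (ordered symbols or a prebuilt
        :class:`CornerAssignment`); extracted from *seq* when omitted.
        Supplying the base sequence's alphabet when encoding a probe
        guarantees both live in the same hypercube.
    upper:
        Upper-case *seq* before processing (genome FASTA convenience).
    on_unknown:
        Policy for symbols absent from a supplied alphabet: ``'error'``
        (default, raises :class:`UnknownSymbolError` naming symbol and
        position), ``'skip'`` (drop them), or ``'extend'`` (grow the
        alphabet, rebuilding the cube).
    """
    if upper:
        seq = seq.upper()
    if not seq:
        raise UsmError("cannot encode an empty sequence")
    if alphabet is None:
        assignment = build_corner_assignment(extract_alphabet(seq))
    elif isinstance(alphabet, CornerAssignment):
        assignment = alphabet
    else:
        assignment = build_corner_assignment(alphabet)
    seq, assignment = _apply_policy(seq, assignment, on_unknown)
    if not seq:
        raise UsmError("no encodable symbols left after applying the unknown-symbol policy")

    n = len(seq)
    h = assignment.dims
    float_corners = {
        s: tuple(float(d) for d in assignment.corner_of(s)) for s in set(seq)
    }
    corner_seq = [float_corners[s] for s in seq]

    fwd = np.empty((n, h), dtype=float)
    c = solve_circular_seed(corner_seq, "forward")
    for i, corner in enumerate(corner_seq):
        c = [c[d] + (corner[d] - c[d]) / 2 for d in range(h)]
        fwd[i] = c

    bwd = np.empty((n, h), dtype=float)
    c = solve_circular_seed(corner_seq, "backward")
    for i in range(n - 1, -1, -1):
        corner = corner_seq[i]
        c = [c[d] + (corner[d] - c[d]) / 2 for d in range(h)]
        bwd[i] = c

    corners_per_unit = np.array(
        [assignment.corner_of(s) for s in seq], dtype=np.int8
    )
    return USMEncoding(seq, assignment, corners_per_unit, fwd, bwd)
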