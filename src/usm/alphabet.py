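"""Alphabets and their binary hypercube corner assignment.

A Universal Sequence Map places every symbol of an alphabet A on a distinct
corner of the unit hypercube [0,1]^h, with h chosen minimal: h =
ceil(log2(max(2, |A|))).  The k-th symbol (in alphabet order) sits on the
corner whose coordinates are the h-digit big-endian binary expansion of k.
For the nucleotide alphabet 'acgt' this is the classic chaos-game square:
a=(0,0), c=(0,1), g=(1,0), t=(1,1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import AlphabetError

__all__ = ["CornerAssignment", "extract_alphabet", "build_corner_assignment"]

Corner = tuple[int, ...]


def extract_alphabet(seq: str) -> list[str]:
    """Distinct symbols of *seq* in order of first appearance.

    Raises :class:`AlphabetError` on an empty sequence.
    """
    if not seq:
        raise AlphabetError("cannot extract an alphabet from an empty sequence")
    return list(dict.fromkeys(seq))


@dataclass(frozen=True)
class CornerAssignment:
    """An ordered alphabet plus its hypercube corner for every symbol.

    Attributes
    ----------
    alphabet:
        Ordered distinct symbols.
    dims:
        Hypercube dimensionality h = ceil(log2(max(2, |alphabet|))).
    corners:
        Per-symbol corner, aligned with ``alphabet``; each corner is a tuple
        of ``dims`` binary digits (big-endian expansion of the symbol index).
    cube_axes:
        One string per dimension listing the symbols whose corner digit in
        that dimension is 0 (the 'acgt' square yields ["ac", "ag"]).
    """

    alphabet: tuple[str, ...]
    dims: int
    corners: tuple[Corner, ...]
    cube_axes: tuple[str, ...]
    _by_symbol: dict = field(repr=False, compare=False, default_factory=dict)
    _by_corner: dict = field(repr=False, compare=False, default_factory=dict)

    def __post_init__(self):
        self._by_symbol.update(zip(self.alphabet, self.corners))
        self._by_corner.update(zip(self.corners, self.alphabet))

    def __len__(self) -> int:
        return len(self.alphabet)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._by_symbol

    def corner_of(self, symbol: str) -> Corner:
        return self._by_symbol[symbol]

    def symbol_of(self, corner: Sequence[int]) -> str | None:
        """Symbol owning *corner*, or None if the corner is unassigned."""
        return self._by_corner.get(tuple(corner))

    def to_dict(self) -> dict:
        """Plain-mapping form for JSON serialization."""
        return {
            "alphabet": "".join(self.alphabet),
            "dims": self.dims,
            "corners": {s: list(c) for s, c in zip(self.alphabet, self.corners)},
            "cube_axes": list(self.cube_axes),
        }


def build_corner_assignment(alphabet: Iterable[str]) -> CornerAssignment:
    """Assign each symbol of *alphabet* a distinct corner of a compact cube.

    The cube is minimal: 2**dims >= |alphabet| with dims as small as possible
    (a single-symbol alphabet still gets one dimension so coordinates stay
    well defined).  Duplicated symbols raise :class:`AlphabetError`.
    """
    symbols = tuple(alphabet)
    if not symbols:
        raise AlphabetError("alphabet must be non-empty")
    if len(set(symbols)) != len(symbols):
        raise AlphabetError("alphabet contains duplicate symbols")
    dims = (max(2, len(symbols)) - 1).bit_length()
    corners = tuple(
        tuple(int(b) for b in format(k, f"0{dims}b")) for k in range(len(symbols))
    )
    cube_axes = tuple(
        "".join(s for s, c in zip(symbols, corners) if c[d] == 0)
        for d in range(dims)
    )
    return CornerAssignment(symbols, dims, corners, cube_axes)
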