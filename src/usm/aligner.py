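"""Exact longest-identical-segment alignment from coordinates alone.

The distance map of two sequences contains, along each diagonal, a run of
equal values v wherever an identical segment of length v crosses it, so the
maximum can be found without resolving the whole table: a single resolved
cell reveals the entire run it belongs to.  The aligner walks every diagonal
sampling cells with an adaptive stride of best-so-far + 1 — a run longer
than the current best occupies that many consecutive diagonal cells and
cannot slip between samples — and resolves each positive sample into a full
segment.  A confirmation pass at stride best-so-far then enumerates every
segment achieving the maximum.  With long identical regions the stride grows
to the saturation cap and beyond, realizing the sparse evaluation the
distance map's cell independence makes possible (order 1 evaluation per
cap**2 cells on saturated diagonals).

Two corrections keep coordinate arithmetic honest at the edges:

* **Stitching.**  A directional distance equal to the saturation cap only
  says "at least cap"; the aligner re-anchors cap-1 units further along the
  diagonal and re-evaluates, accumulating length until the distance resolves
  below the cap.
* **Trimming.**  Circular seeding makes coordinates encode the sequence as a
  ring, so raw distances can count matches wrapping around a sequence end;
  extents are clipped to each sequence's linear span, and by construction
  every clipped unit is a genuine linear match.

The distance computation never reads symbols.  As a separate safety layer,
reported hits are verified symbol-by-symbol when the sequences are in memory
(on by default, and switch-off-able precisely to demonstrate the
coordinates-only claim).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

from .distance import DEFAULT_CAP, dist_cgr
from .encoding import USMEncoding, encode
from .errors import UsmError

__all__ = ["AlignmentHit", "AlignmentResult", "align", "resolve_segment"]


@dataclass(frozen=True, order=True)
class AlignmentHit:
    """One identical shared segment (0-based starts, length in units)."""

    base_start: int
    probe_start: int
    length: int
    segment: str | None = field(default=None, compare=False)


@dataclass
class AlignmentResult:
    """All maximal identical segments plus the maximal length.

    ``evaluations`` counts directional distance evaluations performed; the
    full distance map would need ``2 * base_length * probe_length``.
    """

    max_length: int
    hits: list[AlignmentHit]
    base_length: int
    probe_length: int
    evaluations: int

    def describe(self) -> str:
        if not self.hits:
            return "no identical segment found"
        lines = [
            f"largest identical segment has length {self.max_length} and aligns "
            f"with position {h.base_start} in base sequence and position "
            f"{h.probe_start} in probe sequence"
            for h in self.hits
        ]
        return "\n".join(lines)


class _Scanner:
    """Shared per-alignment state: coordinate tables and evaluation counter."""

    def __init__(self, base: USMEncoding, probe: USMEncoding, cap: int):
        if cap < 2:
            raise UsmError("the aligner requires a saturation cap >= 2")
        if base.assignment.to_dict() != probe.assignment.to_dict():
            raise UsmError("base and probe are framed by different corner assignments")
        self.bf = [tuple(r) for r in base.cgr_forward]
        self.bb = [tuple(r) for r in base.cgr_backward]
        self.pf = [tuple(r) for r in probe.cgr_forward]
        self.pb = [tuple(r) for r in probe.cgr_backward]
        self.nb = len(base)
        self.np = len(probe)
        self.cap = cap
        self.evaluations = 0

    def _match(self, i: int, j: int) -> bool:
        """Exact coordinate-only test that units i and j carry the same symbol.

        The first binary digit of every component is the unit's own corner
        digit, so comparing which side of 0.5 each component falls on reads
        symbol equality without error — unlike deep digits, which can be
        perturbed by the encoder's accumulated rounding.
        """
        self.evaluations += 1
        return all((x >= 0.5) == (y >= 0.5) for x, y in zip(self.bf[i], self.pf[j]))

    def _dist_dir(self, i: int, j: int, forward: bool) -> int:
        self.evaluations += 1
        if forward:
            return dist_cgr(self.bf[i], self.pf[j], self.cap)
        return dist_cgr(self.bb[i], self.pb[j], self.cap)

    def _extent(self, i: int, j: int, forward: bool) -> int:
        """Linear match extent from (i, j) in one direction, focal included.

        True matches from the focal cell form a contiguous diagonal run, so
        the routine hunts for the run's boundary: each directional distance
        read proposes a jump (stitching past saturation by re-anchoring at
        the claimed edge), and every claimed edge is certified by an exact
        focal match read — deep mantissa digits can be off by a rounding
        carry near the resolution horizon, in either direction, so a refuted
        claim is repaired by bisection over exact reads.  Extents are
        clipped at the nearer sequence end: circular wrap never inflates the
        returned linear extent.
        """
        step = -1 if forward else 1
        avail = min(i, j) + 1 if forward else min(self.nb - i, self.np - j)
        if not self._match(i, j):
            return 0
        lo = 0  # largest offset certified to match
        while True:
            if lo >= avail - 1:
                return avail
            d = self._dist_dir(i + step * lo, j + step * lo, forward)
            claim_end = lo + max(d, 1) - 1  # last matching offset per the read
            clipped = claim_end > avail - 1
            cand = min(claim_end, avail - 1)
            if cand > lo:
                if self._match(i + step * cand, j + step * cand):
                    lo = cand
                    if d >= self.cap or clipped:
                        continue  # saturated or clipped: read again from here
                else:
                    hi = cand  # certified mismatch: bisect the boundary
                    while hi - lo > 1:
                        mid = (lo + hi) // 2
                        if self._match(i + step * mid, j + step * mid):
                            lo = mid
                        else:
                            hi = mid
                    return lo + 1
            # the run is claimed to end at offset lo: certify the next cell
            if lo >= avail - 1:
                return avail
            if not self._match(i + step * (lo + 1), j + step * (lo + 1)):
                return lo + 1
            lo += 1  # the claim undershot; extend and re-read

    def resolve(self, i: int, j: int) -> AlignmentHit | None:
        """The full identical segment through cell (i, j), or None on mismatch."""
        f = self._extent(i, j, forward=True)
        if f == 0:  # differing symbols: backward extent is 0 as well
            return None
        b = self._extent(i, j, forward=False)
        return AlignmentHit(i - f + 1, j - f + 1, f + b - 1)

    def diagonals(self) -> Iterator[tuple[int, int, int]]:
        """(i0, j0, run length) of every diagonal of the conceptual map."""
        for d in range(-(self.np - 1), self.nb):
            i0, j0 = max(d, 0), max(-d, 0)
            yield i0, j0, min(self.nb - i0, self.np - j0)


def resolve_segment(
    base: USMEncoding,
    probe: USMEncoding,
    i: int,
    j: int,
    cap: int = DEFAULT_CAP,
) -> AlignmentHit | None:
    """Identical segment through base unit *i* and probe unit *j*, from coordinates.

    Returns None when the two units' symbols differ.  Directional distances
    are stitched across the saturation cap and clipped to the sequences'
    linear extents; see the module docstring.
    """
    if not (0 <= i < len(base) and 0 <= j < len(probe)):
        raise UsmError(f"cell ({i}, {j}) outside the {len(base)}x{len(probe)} map")
    scanner = _Scanner(base, probe, cap)
    hit = scanner.resolve(i, j)
    if hit is None:
        return hit
    segment = base.seq[hit.base_start : hit.base_start + hit.length]
    return AlignmentHit(hit.base_start, hit.probe_start, hit.length, segment)


def _scan(scanner: _Scanner, stride_fn, on_hit) -> None:
    """Walk every diagonal, sampling cells and resolving positive samples.

    After a resolved segment the walk jumps past its end on the diagonal
    (all intervening cells belong to the same run); after a mismatch it
    advances by the current stride.
    """
    for i0, j0, run in scanner.diagonals():
        k = 0
        while k < run:
            hit = scanner.resolve(i0 + k, j0 + k)
            if hit is None:
                k += stride_fn()
            else:
                on_hit(hit)
                k = hit.base_start + hit.length - i0  # first cell past the run
                if k <= 0:  # wholly behind (cannot happen, but stay safe)
                    k = run


def align(
    base: USMEncoding,
    probe: USMEncoding | str,
    *,
    cap: int = DEFAULT_CAP,
    verify: bool = True,
) -> AlignmentResult:
    """All longest identical segments between *base* and *probe*.

    *probe* may be a raw string, in which case it is encoded with the base's
    corner assignment.  The scan is exact: the reported maximum equals the
    true longest common substring length, and every hit of that length is
    reported, sorted by base start.  With ``verify`` (default) each hit is
    additionally checked symbol-by-symbol; the distance scan itself never
    reads symbols.
    """
    if isinstance(probe, str):
        if not probe:
            raise UsmError("cannot align an empty probe")
        probe = encode(probe, base.assignment)
    scanner = _Scanner(base, probe, cap)

    best = 0

    def grow(hit: AlignmentHit) -> None:
        nonlocal best
        if hit.length > best:
            best = hit.length

    _scan(scanner, lambda: best + 1, grow)

    hits: set[AlignmentHit] = set()
    if best > 0:
        def collect(hit: AlignmentHit) -> None:
            if hit.length == best:
                hits.add(hit)

        _scan(scanner, lambda: best, collect)

    ordered = sorted(hits)
    if verify:
        for h in ordered:
            b_seg = base.seq[h.base_start : h.base_start + h.length]
            p_seg = probe.seq[h.probe_start : h.probe_start + h.length]
            if b_seg != p_seg:
                raise UsmError(
                    f"coordinate-resolved hit {h} fails symbolic verification"
                )
    final = [
        AlignmentHit(
            h.base_start,
            h.probe_start,
            h.length,
            base.seq[h.base_start : h.base_start + h.length],
        )
        for h in ordered
    ]
    return AlignmentResult(best, final, len(base), len(probe), scanner.evaluations)
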