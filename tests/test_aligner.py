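import numpy as np
import pytest

from reference_data import (
    ALIGN_BASE_START,
    ALIGN_MAX,
    ALIGN_PROBE_START,
    BASE_SEQ,
    PROBE_SEQ,
)

from usm import UsmError, align, encode, resolve_segment
from usm.fixtures import (
    oracle_longest_common_substring,
    plant_segment,
    random_sequence,
)


class TestResolveSegment:
    def test_reference_cell_resolves_whole_segment(self, base_enc, probe_enc):
        """From the highlighted 'c' pair alone: length 8 at (6, 3)."""
        hit = resolve_segment(base_enc, probe_enc, 7, 4)
        assert (hit.length, hit.base_start, hit.probe_start) == (8, 6, 3)
        assert hit.segment == "gctatctg"

    def test_any_in_segment_cell_reports_the_same_hit(self, base_enc, probe_enc):
        for i, j in [(6, 3), (8, 5), (13, 10)]:
            hit = resolve_segment(base_enc, probe_enc, i, j)
            assert (hit.length, hit.base_start, hit.probe_start) == (8, 6, 3)

    def test_mismatched_units_give_none(self, base_enc, probe_enc):
        assert resolve_segment(base_enc, probe_enc, 0, 3) is None

    def test_index_bounds(self, base_enc, probe_enc):
        with pytest.raises(UsmError):
            resolve_segment(base_enc, probe_enc, 26, 0)

    def test_stitching_across_the_cap(self):
        """A planted segment far longer than the cap is resolved exactly.

        With cap 52 a single coordinate pair can only certify 52 units per
        direction; the 200-unit segment requires re-anchoring ~4 times.
        """
        pair = plant_segment("acgt", 2000, 2000, 200, 700, 300, seed=21)
        eb = encode(pair.base_seq, "acgt")
        ep = encode(pair.probe_seq, eb.assignment)
        for i_off in (0, 1, 99, 150, 199):
            hit = resolve_segment(eb, ep, 700 + i_off, 300 + i_off)
            assert (hit.length, hit.base_start, hit.probe_start) == (200, 700, 300)

    def test_no_circular_wrap_leakage(self):
        """Matches continuing across the seam are trimmed to the linear span."""
        # probe equals the last 4 + first 3 units of the circularized base
        base = "ggttacc"
        probe = base[-4:] + base[:3]
        eb = encode(base)
        ep = encode(probe, eb.assignment)
        hit = resolve_segment(eb, ep, len(base) - 1, 3)
        assert hit.base_start + hit.length <= len(base)
        assert hit.probe_start + hit.length <= len(probe)
        assert (
            base[hit.base_start : hit.base_start + hit.length]
            == probe[hit.probe_start : hit.probe_start + hit.length]
        )


class TestAlign:
    def test_worked_example(self, base_enc):
        result = align(base_enc, PROBE_SEQ)
        assert result.max_length == ALIGN_MAX
        assert len(result.hits) == 1
        hit = result.hits[0]
        assert (hit.base_start, hit.probe_start) == (ALIGN_BASE_START, ALIGN_PROBE_START)
        assert "length 8" in result.describe()
        assert "position 6 in base" in result.describe()

    def test_probe_identical_to_base(self, base_enc):
        """Self-alignment exercises the fully saturated diagonal."""
        result = align(base_enc, BASE_SEQ)
        assert result.max_length == len(BASE_SEQ)
        assert any(h.base_start == 0 and h.probe_start == 0 for h in result.hits)

    def test_empty_probe_rejected(self, base_enc):
        with pytest.raises(UsmError):
            align(base_enc, "")

    def test_no_shared_symbols(self):
        eb = encode("aaaa", "ac")
        result = align(eb, encode("cccc", eb.assignment))
        assert result.max_length == 0
        assert result.hits == []

    def test_coordinates_only_mode(self, base_enc):
        """verify=False returns the same hits without ever reading symbols."""
        assert align(base_enc, PROBE_SEQ, verify=False).hits == align(
            base_enc, PROBE_SEQ
        ).hits

    @pytest.mark.parametrize("seg_len,base_len,probe_len", [
        (5, 80, 60),
        (50, 600, 400),
        (64, 800, 600),
        (65, 800, 600),
        (113, 1500, 1000),
        (200, 2000, 2000),
    ])
    def test_planted_segment_recovered_exactly(self, seg_len, base_len, probe_len):
        """Planted maximal segments, straddling the cap, are found exactly."""
        bs, ps = base_len // 3, probe_len // 4
        pair = plant_segment("acgt", base_len, probe_len, seg_len, bs, ps, seed=seg_len)
        eb = encode(pair.base_seq, "acgt")
        result = align(eb, pair.probe_seq)
        assert result.max_length == seg_len
        assert [(h.base_start, h.probe_start) for h in result.hits] == [(bs, ps)]

    def test_matches_dp_oracle_on_random_pairs(self):
        """Alignment equals DP longest-common-substring on 200 random pairs.

        Lengths up to 500; every reported span is additionally verified
        symbol by symbol against both sequences.
        """
        rng = np.random.default_rng(17)
        for _ in range(200):
            nb = int(rng.integers(20, 501))
            npr = int(rng.integers(20, 501))
            base = random_sequence("acgt", nb, int(rng.integers(2**31)))
            probe = random_sequence("acgt", npr, int(rng.integers(2**31)))
            eb = encode(base, "acgt")
            result = align(eb, probe)
            length, positions = oracle_longest_common_substring(base, probe)
            assert result.max_length == length
            assert [(h.base_start, h.probe_start) for h in result.hits] == positions
            for h in result.hits:
                assert (
                    base[h.base_start : h.base_start + h.length]
                    == probe[h.probe_start : h.probe_start + h.length]
                )

    def test_hits_stay_within_linear_extent(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            base = random_sequence("ac", int(rng.integers(5, 40)), int(rng.integers(2**31)))
            probe = random_sequence("ac", int(rng.integers(5, 40)), int(rng.integers(2**31)))
            eb = encode(base, "ac")
            result = align(eb, probe)
            for h in result.hits:
                assert 0 <= h.base_start and h.base_start + h.length <= len(base)
                assert 0 <= h.probe_start and h.probe_start + h.length <= len(probe)


class TestGenomeScale:
    """Genome-scale behavior on synthetic genomes.

    The genomes here are random sequences with planted structure (labelled
    synthetic); they emulate the real use case of probing a ~34 kb phage-like
    genome with a slice-constructed probe, and multi-match probing of a long
    bacterial-like genome.
    """

    def test_sliced_probe_with_stitched_113_unit_hit(self):
        """probe = genome[0:20] + genome[30000:30100] + genome[10000:10020].

        The synthetic genome is built so genome[30100:30113] equals
        genome[10000:10013]; the middle slice then extends 13 units into the
        probe's tail, giving a maximal hit of 113 at base 30000 / probe 20 —
        longer than the saturation cap, so the aligner must stitch.
        """
        rng = np.random.default_rng(31)
        n = 34_000
        genome = list(random_sequence("ACGT", n, 31))
        genome[30100:30113] = genome[10000:10013]
        # block accidental extensions at the construction's seams
        genome[30113] = {"A": "C"}.get(genome[10013], "A")
        genome[29999] = {"A": "C"}.get(genome[19], "A")
        genome = "".join(genome)
        probe = genome[0:20] + genome[30000:30100] + genome[10000:10020]
        assert len(probe) == 140

        eb = encode(genome, "ACGT")
        result = align(eb, probe)
        assert result.max_length == 113
        assert [(h.base_start, h.probe_start) for h in result.hits] == [(30000, 20)]
        # sparse scan: far fewer evaluations than the full distance map
        assert result.evaluations < 2 * len(genome) * len(probe) / 4

    def test_multiple_tied_matches_reported_sorted(self):
        """Three equal-length planted matches are all reported, by base start."""
        rng = np.random.default_rng(41)
        probe = random_sequence("ACGT", 26, 43)
        pieces = [probe[0:12], probe[5:17], probe[14:26]]
        starts = [9_000, 24_500, 41_111]
        for attempt in range(50):
            genome = list(random_sequence("ACGT", 50_000, 1000 + attempt))
            for s, piece in zip(starts, pieces):
                genome[s : s + 12] = piece
            genome = "".join(genome)
            length, positions = oracle_longest_common_substring(genome, probe)
            if length == 12 and [p[0] for p in positions] == starts:
                break
        else:
            pytest.fail("could not construct a clean 3-match genome")

        eb = encode(genome, "ACGT")
        result = align(eb, probe)
        assert result.max_length == 12
        assert [h.base_start for h in result.hits] == starts
        assert [h.probe_start for h in result.hits] == [0, 5, 14]
        segs = [h.segment for h in result.hits]
        assert segs == pieces
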