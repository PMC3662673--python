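"""Motif counting, microsatellites, spectral tandem finder, repeat pairs."""

import numpy as np
import pytest

from mitocomp import repeats


def _random_seq(seed, n, probs=None):
    rng = np.random.default_rng(seed)
    if probs is None:
        return "".join(rng.choice(list("ACGT"), size=n))
    return "".join(rng.choice(list("ACGT"), p=probs, size=n))


class TestCountMotif:
    @pytest.mark.parametrize("seq,motif,expected", [
        ("ATATAT", "AT", 3),
        ("AAAA", "AA", 3),
        ("ACGT", "ACGTACGT", 0),
        ("TTATATATTTATATAT", "TTATATAT", 2),
    ])
    def test_overlapping_counts(self, seq, motif, expected):
        assert repeats.count_motif(seq, motif) == expected

    def test_circular_option_counts_wrap(self):
        assert repeats.count_motif("TACG", "GT", circular=True) == 1
        assert repeats.count_motif("TACG", "GT") == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_scan(self, seed):
        seq = _random_seq(seed, 2000, probs=[0.4, 0.1, 0.1, 0.4])
        rng = np.random.default_rng(100 + seed)
        for _ in range(10):
            k = int(rng.integers(1, 9))
            i = int(rng.integers(0, len(seq) - k))
            motif = seq[i : i + k]
            brute = sum(seq[j : j + k] == motif
                        for j in range(len(seq) - k + 1))
            assert repeats.count_motif(seq, motif) == brute


class TestMicrosatellites:
    def test_at4_run(self):
        hits = repeats.find_microsatellites("ATATATAT")
        assert len(hits) == 1
        assert (hits[0].unit, hits[0].copies) == ("AT", 4.0)

    def test_unit_one_excluded_when_range_starts_at_two(self):
        hits = repeats.find_microsatellites("AAAAAA", unit_len_range=(2, 8))
        assert hits == []

    def test_planted_attttt_recovered_exactly(self):
        seq = "GCGC" + "ATTTT" * 4 + "GCGC"
        hits = repeats.find_microsatellites(seq)
        hit = next(h for h in hits if h.period == 5)
        assert hit.spans[0] == (4, 24)
        assert hit.unit == "ATTTT"
        assert hit.copies == 4.0

    def test_units_are_primitive_and_spans_disjoint(self):
        for seed in range(10):
            seq = _random_seq(seed, 1500, probs=[0.44, 0.06, 0.06, 0.44])
            hits = repeats.find_microsatellites(seq)
            for h in hits:
                assert repeats._smallest_period(h.unit) == len(h.unit)
                assert h.identity == 1.0
            spans = sorted(h.spans[0] for h in hits)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2


class TestPeriodogram:
    def test_pure_at_dinucleotide_peak(self):
        pg = repeats.periodogram("AT" * 32)
        assert pg.peaks
        assert pg.peaks[0][0] == pytest.approx(2.0)

    def test_planted_period5_dominates_half_window(self):
        rng = np.random.default_rng(5)
        flank = "".join(rng.choice(list("ACGT"), size=60))
        seq = flank + "CGATT" * 30 + flank
        pg = repeats.periodogram(seq)
        assert round(pg.peaks[0][0]) == 5

    def test_window_bounds_checked(self):
        with pytest.raises(ValueError):
            repeats.periodogram("ACGT" * 10, (0, 100))

    def test_random_sequence_rarely_peaks(self):
        n_with_peak = sum(
            bool(repeats.periodogram(_random_seq(3000 + s, 1000)).peaks)
            for s in range(40))
        assert n_with_peak <= 4


class TestFindTandemRepeats:
    def test_perfect_at8(self):
        seq = "GCGCGG" + "AT" * 8 + "CCGGCC"
        hits = repeats.find_tandem_repeats(seq)
        hit = next(h for h in hits if h.period == 2)
        assert hit.identity == 1.0
        assert hit.spans[0] == (6, 22)

    def test_planted_array_in_random_flanks(self):
        rng = np.random.default_rng(8)
        flank = "".join(rng.choice(list("ACGT"), size=200))
        seq = flank + "ATTTG" * 5 + flank[::-1]
        hits = repeats.find_tandem_repeats(seq)
        hit = next(h for h in hits if h.period == 5)
        assert abs(hit.spans[0][0] - 200) <= 5
        assert hit.copies >= 3.5

    def test_random_sequence_mostly_empty(self):
        n_hit = sum(bool(repeats.find_tandem_repeats(_random_seq(s, 1000)))
                    for s in range(20))
        assert n_hit <= 2


class TestApproximatePairs:
    def test_identical_duplicated_30mer(self):
        rng = np.random.default_rng(9)
        unit = "".join(rng.choice(list("ACGT"), size=30))
        seq = unit + "".join(rng.choice(list("ACGT"), size=100)) + unit
        hits = repeats.find_approximate_repeat_pairs(seq, min_len=30)
        top = max(hits, key=lambda h: h.identity)
        assert top.identity == 1.0
        assert top.spans == ((0, 30), (130, 160))
        assert top.unit == unit  # consensus of identical copies is the unit

    def test_consensus_marks_mismatches(self):
        a = "AAAAAAAAAAAAAAAAAAAAAAAAA"
        b = "AAAAAAAAAAAATAAAAAAAAAAAA"
        gap = "CGCGCGCGCGCGCGCGCGCGCGCGCGCGCG"
        hits = repeats.find_approximate_repeat_pairs(a + gap + b, min_len=20)
        assert hits
        assert "(A/T)" in hits[0].unit or hits[0].identity == 1.0

    def test_exact_floor_matches_suffix_oracle(self):
        """At identity 1.0 the detector must find the longest duplicated
        substring pairs an exhaustive comparison finds."""
        for seed in range(5):
            rng = np.random.default_rng(40 + seed)
            core = "".join(rng.choice(list("ACGT"), size=25))
            seq = ("".join(rng.choice(list("ACGT"), size=40)) + core
                   + "".join(rng.choice(list("ACGT"), size=60)) + core
                   + "".join(rng.choice(list("ACGT"), size=40)))
            hits = repeats.find_approximate_repeat_pairs(
                seq, min_len=20, min_identity=1.0)
            # oracle: longest repeated pair length by exhaustive scan
            n = len(seq)
            best = 0
            for i in range(n):
                for j in range(i + 20, n):
                    k = 0
                    while (j + k < n and i + k < j
                           and seq[i + k] == seq[j + k]):
                        k += 1
                    best = max(best, k)
            assert best >= 25
            assert hits
            assert max(h.spans[0][1] - h.spans[0][0] for h in hits) == best

    def test_random_sequence_mostly_empty(self):
        n_hit = sum(
            bool(repeats.find_approximate_repeat_pairs(
                _random_seq(2000 + s, 1000), min_len=30))
            for s in range(20))
        assert n_hit <= 2

    def test_identity_floor_validated(self):
        with pytest.raises(ValueError):
            repeats.find_approximate_repeat_pairs("ACGT" * 30,
                                                  min_identity=0.3)


class TestDegenerateMotif:
    def test_tna_with_restricted_n(self):
        # hand enumeration over TTATAA: TTA at 0 and TAA at 3 match T[AT]A
        hits = repeats.degenerate_motif_search("TTATAA", "TNA",
                                               code={"N": {"A", "T"}})
        assert hits == [0, 3]

    def test_no_wildcard_equals_exact_positions(self):
        seq = "ATATATAT"
        got = repeats.degenerate_motif_search(seq, "ATA")
        brute = [i for i in range(len(seq) - 2) if seq[i : i + 3] == "ATA"]
        assert got == brute

    def test_planted_termination_factor_motif(self, langii_genome):
        genome, _ = langii_genome
        hits = repeats.degenerate_motif_search(
            genome.sequence, "TTAAATNNNNTNAGAT", code={"N": {"A", "T"}})
        assert len(hits) >= 1
        # the plant lies in the spacer between trnS2 and ND1
        s2 = genome.feature_by_name("trnS2")
        nd1 = genome.feature_by_name("ND1")
        assert any(s2.end <= h < nd1.start for h in hits)

    def test_unknown_symbol_rejected(self):
        with pytest.raises(ValueError):
            repeats.degenerate_motif_search("ACGT", "AXG")
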