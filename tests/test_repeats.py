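"""Tandem-repeat, OL-motif and hairpin detectors."""

import random

import pytest

from mitocomp.genetic_code import revcomp
from mitocomp.repeats import (
    _primitive,
    cr_report,
    find_hairpin,
    find_ol_motifs,
    find_tandem_repeats,
)


def random_flank(rng, k):
    return "".join(rng.choice("ACGT") for _ in range(k))


class TestTandemRepeats:
    def test_simple_planted_ac_repeat(self):
        reps = find_tandem_repeats("GGACACACAGG")
        assert any(r.unit == "AC" and r.copies >= 3 for r in reps)

    def test_planted_acacat_52_recovered_exactly(self):
        rng = random.Random(1)
        seq = random_flank(rng, 100) + "ACACAT" * 52 + random_flank(rng, 100)
        reps = find_tandem_repeats(seq)
        hit = [r for r in reps if r.unit_len == 6]
        assert len(hit) == 1
        assert hit[0].unit == min("ACACAT"[i:] + "ACACAT"[:i] for i in range(6))
        assert hit[0].copies == pytest.approx(52, abs=1)

    def test_unit_reduced_to_primitive(self):
        rng = random.Random(2)
        seq = random_flank(rng, 60) + "ATAT" * 20 + random_flank(rng, 60)
        reps = find_tandem_repeats(seq)
        big = max(reps, key=lambda r: r.span)
        assert big.unit == "AT"

    def test_planted_units_recovered_across_sizes(self):
        rng = random.Random(7)
        for unit_len in (2, 3, 5, 9, 17, 24, 33, 50):
            while True:
                unit = random_flank(rng, unit_len)
                if _primitive(unit) == unit:
                    break
            copies = rng.randint(3, 60)
            seq = random_flank(rng, 60) + unit * copies + random_flank(rng, 60)
            reps = find_tandem_repeats(seq)
            hit = [r for r in reps
                   if r.unit_len == unit_len and abs(r.copies - copies) <= 1]
            assert hit, (unit_len, copies)

    def test_random_sequence_null_rate(self):
        """No unit >= 6 array with >= 3 copies at 85% identity in i.i.d.
        sequence (allowed failures <= 5 of 100 seeds)."""
        failures = 0
        for seed in range(100):
            rng = random.Random(10_000 + seed)
            reps = find_tandem_repeats(random_flank(rng, 500))
            if any(r.unit_len >= 6 and r.copies >= 3 for r in reps):
                failures += 1
        assert failures <= 5

    def test_determinism(self):
        rng = random.Random(13)
        seq = random_flank(rng, 300) + "TATCATATA" * 7 + random_flank(rng, 100)
        assert find_tandem_repeats(seq) == find_tandem_repeats(seq)

    def test_reported_5prime_to_3prime(self):
        rng = random.Random(19)
        seq = (random_flank(rng, 50) + "ACGTAG" * 10 + "GGG"
               + random_flank(rng, 40) + "TTAGC" * 8 + random_flank(rng, 50))
        reps = find_tandem_repeats(seq)
        starts = [r.start for r in reps]
        assert starts == sorted(starts)


class TestOLMotifs:
    def test_both_motifs_found(self):
        hits = find_ol_motifs("AAAATGGGGAACCA")
        assert hits.both_found
        assert hits.hits_5p == [1] and hits.hits_3p == [10]

    def test_motif_free_sequence(self):
        hits = find_ol_motifs("GGGGGGGGGG")
        assert not hits.both_found and not hits.hits_5p

    def test_all_synthetic_strains_carry_motifs(self, sim_genomes):
        from mitocomp.genome import extract_element

        for g in sim_genomes:
            assert find_ol_motifs(extract_element(g, "OL")).both_found


def oracle_hairpin(seq, min_stem=4, max_loop=30, min_loop=3, allow_gu=True):
    """Brute force over every (start, stem, loop) placement."""
    pairs = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
    if allow_gu:
        pairs = pairs | {("G", "T"), ("T", "G")}
    n = len(seq)
    best = None
    for start in range(n):
        for stem in range(min_stem, n):
            for loop in range(min_loop, max_loop + 1):
                end = start + 2 * stem + loop
                if end > n:
                    continue
                ok = all(
                    (seq[start + k], seq[end - 1 - k]) in pairs
                    for k in range(stem)
                )
                if ok:
                    key = (stem, -loop)
                    if best is None or key > (best[0], -best[1]):
                        best = (stem, loop)
    return best


class TestHairpin:
    def test_perfect_palindrome(self):
        h = find_hairpin("GGGGGAAAACCCCC")
        assert (h.stem_bp, h.loop_len) == (5, 4)

    def test_broken_stem_shrinks(self):
        h = find_hairpin("GGGGGAAAACCCAC", allow_gu=False)
        assert h is None or h.stem_bp < 5

    def test_matches_brute_force_on_short_sequences(self):
        rng = random.Random(29)
        for _ in range(40):
            n = rng.randint(20, 60)
            seq = "".join(rng.choice("ACGT") for _ in range(n))
            got = find_hairpin(seq)
            want = oracle_hairpin(seq)
            if want is None:
                assert got is None
            else:
                assert got is not None
                assert (got.stem_bp, got.loop_len) == want

    def test_stem_invariant_under_reverse_complement(self):
        # Watson–Crick pairing only: the G·T wobble maps to A·C under
        # complementation, so the invariance holds just for WC stems.
        rng = random.Random(41)
        for _ in range(20):
            seq = "".join(rng.choice("ACGT") for _ in range(50))
            a = find_hairpin(seq, allow_gu=False)
            b = find_hairpin(revcomp(seq), allow_gu=False)
            assert (a is None) == (b is None)
            if a is not None:
                assert a.stem_bp == b.stem_bp

    def test_min_loop_respected(self):
        h = find_hairpin("GGGGGAAAACCCCC")
        assert h.loop_len >= 3


class TestCRReport:
    def test_known_length_and_composition(self):
        seq = "AT" * 30 + "GC" * 20
        rep = cr_report({"x": seq})[0]
        assert rep.length == 100
        assert rep.pct_AT == pytest.approx(60.0)

    def test_identical_crs_identical_reports(self):
        rng = random.Random(43)
        seq = "".join(rng.choice("ACGT") for _ in range(200)) + "ACACAT" * 10
        a, b = cr_report({"x": seq, "y": seq})
        assert a.length == b.length and a.repeats == b.repeats

    def test_planted_four_array_architecture_in_order(self, sim_genomes, sim_truths):
        from mitocomp.genome import extract_element

        g = sim_genomes[0]
        rep = cr_report({g.strain_id: extract_element(g, "D-loop")})[0]
        big = [r for r in rep.repeats if r.copies >= 2.8 and r.span >= 18]
        planted = sim_truths.vntr[g.strain_id]
        # the four planted arrays appear, in 5'->3' order
        found_lens = [r.unit_len for r in big]
        want_lens = [len(u) for u, _ in planted]
        idx = 0
        for L in found_lens:
            if idx < 4 and L == want_lens[idx]:
                idx += 1
        assert idx == 4, (found_lens, want_lens)
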