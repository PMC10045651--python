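"""Pi, sliding windows, K2P and Nei–Gojobori Ka/Ks against oracles."""

import math
import random
from itertools import combinations, permutations

import pytest

from mitocomp.align import ElementAlignment
from mitocomp.diversity import (
    SaturationError,
    gene_distance_table,
    jukes_cantor,
    k2p_distance,
    nei_gojobori_kaks,
    nucleotide_diversity,
    pathway_differences,
    sliding_window_pi,
    syn_site_fraction,
)
from mitocomp.genetic_code import VERTEBRATE_MITO


def make_aln(rows, element="e"):
    return ElementAlignment(element, [f"s{i}" for i in range(len(rows))], rows)


class TestPi:
    def test_two_seqs_one_diff_in_ten(self):
        aln = make_aln(["AAAAAAAAAA", "AAAAAAAAAT"])
        assert nucleotide_diversity(aln).pi == pytest.approx(0.1)

    def test_identical_rows_zero(self):
        assert nucleotide_diversity(make_aln(["ACGT"] * 4)).pi == 0.0

    def test_matches_brute_force_pair_average(self):
        rng = random.Random(17)
        for _ in range(25):
            rows = ["".join(rng.choice("ACGT-") for _ in range(40)) for _ in range(4)]
            # ensure every pair has at least one comparable site
            rows = [r[:-4] + "ACGT" for r in rows]
            got = nucleotide_diversity(make_aln(rows)).pi
            props = []
            for a, b in combinations(rows, 2):
                pairs = [(x, y) for x, y in zip(a, b) if x in "ACGT" and y in "ACGT"]
                props.append(sum(x != y for x, y in pairs) / len(pairs))
            assert got == pytest.approx(sum(props) / len(props))

    def test_concatenation_site_weighted_mean(self):
        a = make_aln(["AAAA", "AAAT"])
        b = make_aln(["CCCCCC", "CCCCCC"])
        cat = make_aln(["AAAACCCCCC", "AAATCCCCCC"])
        pa = nucleotide_diversity(a).pi
        pb = nucleotide_diversity(b).pi
        assert nucleotide_diversity(cat).pi == pytest.approx((4 * pa + 6 * pb) / 10)


class TestSlidingWindow:
    def test_window_count_formula(self):
        aln = make_aln(["A" * 600, "A" * 600])
        prof = sliding_window_pi(aln, window=500, step=10)
        assert len(prof.pi_values) == 11

    def test_short_alignment_single_window(self):
        aln = make_aln(["ACGT" * 10, "ACGT" * 10])
        prof = sliding_window_pi(aln, window=500, step=10)
        assert len(prof.pi_values) == 1 and prof.window_bp == 40

    def test_planted_divergent_block_peaks_only_there(self):
        rng = random.Random(4)
        base = "".join(rng.choice("ACGT") for _ in range(800))
        other = list(base)
        for i in range(400, 500):  # all differences inside one block
            other[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[other[i]]
        aln = make_aln([base, "".join(other)])
        prof = sliding_window_pi(aln, window=200, step=20)
        for mid, pi in zip(prof.midpoints, prof.pi_values):
            start, end = mid - 100, mid + 100
            overlaps = not (end <= 400 or start >= 500)
            assert (pi > 0) == overlaps

    def test_mean_of_windows_tracks_global_pi(self, sim_alignments):
        aln = next(a for a in sim_alignments if a.element == "NAD5")
        prof = sliding_window_pi(aln)
        mean_win = sum(prof.pi_values) / len(prof.pi_values)
        global_pi = nucleotide_diversity(aln).pi
        assert mean_win == pytest.approx(global_pi, rel=0.25)


class TestK2P:
    def test_identical_zero(self):
        assert k2p_distance("ACGT" * 5, "ACGT" * 5) == 0.0

    def test_closed_form_p_01_q_0(self):
        a = "A" * 100
        b = "G" * 10 + "A" * 90  # 10 transitions in 100 sites
        assert k2p_distance(a, b) == pytest.approx(-0.5 * math.log(0.8))

    def test_symmetry(self):
        rng = random.Random(9)
        for _ in range(10):
            a = "".join(rng.choice("ACGT") for _ in range(60))
            b = "".join(rng.choice("ACGT") for _ in range(60))
            try:
                assert k2p_distance(a, b) == pytest.approx(k2p_distance(b, a))
            except SaturationError:
                pass

    def test_approaches_p_distance_at_low_divergence(self):
        n = 100_000
        a = "A" * n
        b = "G" * 50 + "C" * 50 + "A" * (n - 100)  # p = 0.001
        p = 100 / n
        assert k2p_distance(a, b) == pytest.approx(p, abs=1e-4)
        assert k2p_distance(a, b) >= p

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            k2p_distance("A" * 10, "G" * 10)

    def test_gene_table_mean_arithmetic(self):
        rows = ["AAAA", "AAAA", "AAAA", "AAAT"]  # two pairs at d, four at 0
        d = k2p_distance(rows[0], rows[3])
        ds = gene_distance_table([make_aln(rows, "g")])[0]
        assert ds.overall_mean == pytest.approx(3 * d / 6)
        assert ds.pairwise.diagonal().sum() == 0


def oracle_pathways(ca, cb, code):
    """Independent exhaustive pathway enumerator for one codon pair."""
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return 0.0, 0.0
    results_ok, results_blocked = [], []
    for order in permutations(diff):
        cur, sd, nd, blocked = ca, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if code.is_stop(nxt):
                blocked = True
            if (not code.is_stop(cur) and not code.is_stop(nxt)
                    and code.translate_codon(cur) == code.translate_codon(nxt)):
                sd += 1
            else:
                nd += 1
            cur = nxt
        (results_blocked if blocked else results_ok).append((sd, nd))
    use = results_ok or results_blocked
    return (sum(x for x, _ in use) / len(use), sum(y for _, y in use) / len(use))


class TestNeiGojobori:
    def test_site_counts_sum_to_three(self):
        for codon in VERTEBRATE_MITO.codon_to_aa:
            s = syn_site_fraction(codon)
            assert 0 <= s <= 3
        # fourfold third position: GGN (Gly) has exactly 1 synonymous site
        assert syn_site_fraction("GGA") == pytest.approx(1.0)

    def test_identical_sequences_reported_zero(self):
        r = nei_gojobori_kaks("ATGAAACCC", "ATGAAACCC")
        assert r.ka == 0 and r.ks == 0
        assert r.ratio is None and r.ratio_reported == 0.0

    def test_single_synonymous_change_sign_structure(self):
        r = nei_gojobori_kaks("ATGGGAAAA", "ATGGGGAAA")  # GGA->GGG Gly
        assert r.ka == 0 and r.ks > 0

    def test_sn_sites_sum_exact(self):
        rng = random.Random(23)
        sense = sorted(VERTEBRATE_MITO.codon_to_aa)
        for _ in range(20)    :
            seq = "".join(rng.choice(sense) for _ in range(30))
            r = nei_gojobori_kaks(seq, seq)
            assert r.syn_sites + r.nonsyn_sites == pytest.approx(3 * r.codons)

    def test_pathway_counts_match_oracle(self):
        rng = random.Random(31)
        sense = sorted(VERTEBRATE_MITO.codon_to_aa)
        for _ in range(300):
            ca, cb = rng.choice(sense), rng.choice(sense)
            got = pathway_differences(ca, cb)
            want = oracle_pathways(ca, cb, VERTEBRATE_MITO)
            assert got == pytest.approx(want), (ca, cb)

    def test_random_pairs_match_oracle_totals(self):
        rng = random.Random(37)
        sense = sorted(VERTEBRATE_MITO.codon_to_aa)
        for _ in range(40):
            a = [rng.choice(sense) for _ in range(30)]
            b = [c if rng.random() < 0.7 else rng.choice(sense) for c in a]
            r = nei_gojobori_kaks("".join(a), "".join(b))
            sd = nd = 0.0
            for ca, cb in zip(a, b):
                s, n = oracle_pathways(ca, cb, VERTEBRATE_MITO)
                sd += s
                nd += n
            ps, pn = sd / r.syn_sites, nd / r.nonsyn_sites
            assert r.ks == pytest.approx(jukes_cantor(ps))
            assert r.ka == pytest.approx(jukes_cantor(pn))

    def test_gap_codons_wholly_excluded(self):
        r = nei_gojobori_kaks("ATG-AACCC", "ATGAAACCC")
        assert r.codons == 2

    def test_jukes_cantor_domain(self):
        with pytest.raises(SaturationError):
            jukes_cantor(0.75)


class TestParameterRecovery:
    def test_k2p_recovers_planted_divergence(self, sim, sim_alignments):
        """Per-gene overall mean K2P within 3 binomial SE of the planted
        expectation (rate x mean pairwise path length of the tree)."""
        cfg = sim[0]
        from mitocomp.simulate import PAIR_PATHS

        mean_path = sum(PAIR_PATHS.values()) / len(PAIR_PATHS)
        pcgs = [a for a in sim_alignments
                if a.element in ("NAD1", "NAD2", "NAD4", "NAD5", "COX1", "Cytb",
                                 "ATP8", "NAD4L")]
        for ds in gene_distance_table(pcgs):
            rate = cfg.rate_for(ds.gene)
            d_star = rate * mean_path
            L = next(a.n_columns for a in pcgs if a.element == ds.gene)
            se = math.sqrt(d_star * (1 - d_star) / L)
            assert abs(ds.overall_mean - d_star) <= 3 * se, ds.gene
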