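"""Nucleotide diversity, K2P distances and Nei–Gojobori Ka/Ks.

Pi is the average pairwise proportion of differing sites with pairwise
deletion of gap/N sites.  K2P corrects the observed divergence separating
transitions (A<->G, C<->T) from transversions:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Ka/Ks follows the counting method of Nei and Gojobori (1986) under the
vertebrate mitochondrial code: per-codon synonymous site fractions are the
fraction of single-base changes that preserve the amino acid (changes to
stop codons count as nonsynonymous, so S + N = 3 per codon); multi-difference
codon pairs are averaged over all minimal substitution pathways excluding
pathways through stop codons; the proportions are Jukes–Cantor corrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd

from .align import ElementAlignment
from .genetic_code import VERTEBRATE_MITO, GeneticCode

_VALID = frozenset("ACGT")
_TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})


class SaturationError(ValueError):
    """Distance correction undefined: divergence beyond the model's domain."""


# ---------------------------------------------------------------------------
# Nucleotide diversity
# ---------------------------------------------------------------------------

@dataclass
class DiversityResult:
    element: str
    pi: float
    n_seqs: int
    sites_used: float  # mean pairwise comparable sites


def _pair_diff(a: str, b: str) -> tuple[int, int]:
    """(differences, comparable sites) with pairwise gap/N deletion."""
    diffs = sites = 0
    for x, y in zip(a, b):
        if x in _VALID and y in _VALID:
            sites += 1
            if x != y:
                diffs += 1
    return diffs, sites


def nucleotide_diversity(aln: ElementAlignment) -> DiversityResult:
    """Pi = mean over all sequence pairs of (differences / comparable sites)."""
    rows = aln.rows
    if len(rows) < 2:
        raise ValueError("nucleotide diversity requires >= 2 sequences")
    props, sites_used = [], []
    for a, b in combinations(rows, 2):
        d, s = _pair_diff(a, b)
        if s == 0:
            raise ValueError(f"no comparable sites in a pair of {aln.element!r}")
        props.append(d / s)
        sites_used.append(s)
    return DiversityResult(
        element=aln.element,
        pi=float(np.mean(props)),
        n_seqs=len(rows),
        sites_used=float(np.mean(sites_used)),
    )


@dataclass
class SlidingWindowProfile:
    element: str
    window_bp: int
    step_bp: int
    midpoints: list[float]
    pi_values: list[float]


def sliding_window_pi(
    aln: ElementAlignment, window: int = 500, step: int = 10
) -> SlidingWindowProfile:
    """Pi in sliding windows over alignment columns.

    Window count is floor((L - window)/step) + 1; an alignment shorter than
    the window yields a single whole-length window.
    """
    L = aln.n_columns
    starts = list(range(0, L - window + 1, step)) if L >= window else [0]
    win = window if L >= window else L
    mids, pis = [], []
    for s in starts:
        sub = ElementAlignment(
            aln.element, aln.strain_ids, [r[s : s + win] for r in aln.rows]
        )
        mids.append(s + win / 2)
        pis.append(nucleotide_diversity(sub).pi)
    return SlidingWindowProfile(aln.element, win, step, mids, pis)


# ---------------------------------------------------------------------------
# Kimura 2-parameter distance
# ---------------------------------------------------------------------------

def k2p_distance(a: str, b: str) -> float:
    """K2P distance between two (possibly gapped) aligned rows."""
    sites = ts = tv = 0
    for x, y in zip(a, b):
        if x in _VALID and y in _VALID:
            sites += 1
            if x != y:
                if (x, y) in _TRANSITIONS:
                    ts += 1
                else:
                    tv += 1
    if sites == 0:
        raise ValueError("no comparable sites")
    P, Q = ts / sites, tv / sites
    w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"K2P undefined at P={P:.3f}, Q={Q:.3f}")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


@dataclass
class DistanceSet:
    gene: str
    taxa: list[str]
    pairwise: np.ndarray  # symmetric, zero diagonal

    @property
    def overall_mean(self) -> float:
        n = len(self.taxa)
        vals = [self.pairwise[i, j] for i in range(n) for j in range(i + 1, n)]
        return float(np.mean(vals))


def gene_distance_table(gene_alns: list[ElementAlignment]) -> list[DistanceSet]:
    """Pairwise K2P matrix and overall mean per gene alignment."""
    out = []
    for aln in gene_alns:
        n = len(aln.rows)
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                mat[i, j] = mat[j, i] = k2p_distance(aln.rows[i], aln.rows[j])
        out.append(DistanceSet(gene=aln.element, taxa=list(aln.strain_ids), pairwise=mat))
    return out


# ---------------------------------------------------------------------------
# Nei–Gojobori Ka/Ks
# ---------------------------------------------------------------------------

def syn_site_fraction(codon: str, code: GeneticCode = VERTEBRATE_MITO) -> float:
    """Synonymous sites of one sense codon (0..3); changes to stops = nonsynonymous."""
    aa = code.translate_codon(codon)
    s = 0.0
    for pos in range(3):
        syn = 0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if not code.is_stop(mutant) and code.translate_codon(mutant) == aa:
                syn += 1
        s += syn / 3.0
    return s


def pathway_differences(
    ca: str, cb: str, code: GeneticCode = VERTEBRATE_MITO
) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons.

    Averaged over all minimal substitution pathways; pathways that pass
    through a stop codon are excluded (all pathways are used if every one is
    blocked).
    """
    diff_pos = [i for i in range(3) if ca[i] != cb[i]]
    if not diff_pos:
        return 0.0, 0.0
    valid, blocked = [], []
    for order in permutations(diff_pos):
        cur = ca
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if code.is_stop(nxt):
                through_stop = True
            if code.translate_codon(cur) == code.translate_codon(nxt) and not (
                code.is_stop(cur) or code.is_stop(nxt)
            ):
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked if through_stop else valid).append((sd, nd))
    paths = valid if valid else blocked
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC correction d = -3/4 ln(1 - 4p/3); p >= 3/4 is out of domain."""
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.3f} >= 3/4; correction undefined")
    return -0.75 * math.log(1 - 4 * p / 3)


@dataclass
class KaKsResult:
    gene: str
    ka: float
    ks: float
    ratio: float | None  # None when ks == 0 (reported as 0.000 by convention)
    syn_sites: float
    nonsyn_sites: float
    codons: int

    @property
    def ratio_reported(self) -> float:
        return self.ratio if self.ratio is not None else 0.0


def nei_gojobori_kaks(
    codon_a: str,
    codon_b: str,
    code: GeneticCode = VERTEBRATE_MITO,
    gene: str = "",
) -> KaKsResult:
    """NG86 Ka/Ks between two aligned in-frame coding sequences.

    Codon pairs containing gaps or N (and terminal/observed stop codons) are
    wholly excluded.
    """
    if len(codon_a) != len(codon_b):
        raise ValueError("coding sequences must have equal aligned length")
    usable = []
    for i in range(0, len(codon_a) - len(codon_a) % 3, 3):
        x, y = codon_a[i : i + 3], codon_b[i : i + 3]
        if not (set(x) <= _VALID and set(y) <= _VALID):
            continue
        if code.is_stop(x) or code.is_stop(y):
            continue
        usable.append((x, y))
    if not usable:
        raise ValueError("no comparable codons")
    S = sum((syn_site_fraction(x, code) + syn_site_fraction(y, code)) / 2 for x, y in usable)
    N = 3 * len(usable) - S
    Sd = Nd = 0.0
    for x, y in usable:
        sd, nd = pathway_differences(x, y, code)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    ks, ka = jukes_cantor(pS), jukes_cantor(pN)
    ratio = ka / ks if ks > 0 else None
    return KaKsResult(
        gene=gene, ka=ka, ks=ks, ratio=ratio,
        syn_sites=S, nonsyn_sites=N, codons=len(usable),
    )


@dataclass
class GeneKaKs:
    gene: str
    ka_mean: float
    ks_mean: float
    ratio_mean: float  # mean of defined pairwise ratios (0.0 if none defined)
    ratio_of_means: float  # alternative aggregation: mean Ka / mean Ks
    n_pairs: int
    n_defined: int


def gene_kaks(
    aln: ElementAlignment, code: GeneticCode = VERTEBRATE_MITO, trim_stop: bool = True
) -> GeneKaKs:
    """Per-gene Ka/Ks aggregated over all sequence pairs of an in-frame alignment.

    The reported per-gene value is the mean of the defined pairwise ratios
    (pairs with Ks = 0 excluded); the ratio of mean Ka to mean Ks is kept as
    an alternative aggregation.  With ``trim_stop`` the trailing complete or
    incomplete stop codon columns are dropped before counting.
    """
    rows = aln.rows
    if trim_stop:
        # trailing incomplete codon dropped; an observed full stop codon is
        # excluded inside nei_gojobori_kaks itself
        ncols = aln.n_columns - aln.n_columns % 3
        rows = [r[:ncols] for r in rows]
    results, ratios = [], []
    for a, b in combinations(rows, 2):
        r = nei_gojobori_kaks(a, b, code, gene=aln.element)
        results.append(r)
        if r.ratio is not None:
            ratios.append(r.ratio)
    ka_mean = float(np.mean([r.ka for r in results]))
    ks_mean = float(np.mean([r.ks for r in results]))
    return GeneKaKs(
        gene=aln.element,
        ka_mean=ka_mean,
        ks_mean=ks_mean,
        ratio_mean=float(np.mean(ratios)) if ratios else 0.0,
        ratio_of_means=(ka_mean / ks_mean) if ks_mean > 0 else 0.0,
        n_pairs=len(results),
        n_defined=len(ratios),
    )


def diversity_dataframe(
    pis: list[DiversityResult],
    kaks: list[GeneKaKs],
    dists: list[DistanceSet],
) -> pd.DataFrame:
    """Per-gene summary: Pi, Ka, Ks, Ka/Ks and overall mean K2P (3 decimals)."""
    pi_by = {r.element: r for r in pis}
    kk_by = {r.gene: r for r in kaks}
    rows = []
    for d in dists:
        pi = pi_by.get(d.gene)
        kk = kk_by.get(d.gene)
        rows.append(
            {
                "gene": d.gene,
                "pi": round(pi.pi, 3) if pi else None,
                "pi_full": pi.pi if pi else None,
                "ka": round(kk.ka_mean, 3) if kk else None,
                "ks": round(kk.ks_mean, 3) if kk else None,
                "kaks": round(kk.ratio_mean, 3) if kk else None,
                "kaks_full": kk.ratio_mean if kk else None,
                "mean_k2p": round(d.overall_mean, 3),
                "mean_k2p_full": d.overall_mean,
            }
        )
    return pd.DataFrame(rows)
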