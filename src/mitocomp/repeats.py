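"""Control-region tandem repeats, OL conserved motifs and stem-loop detection.

The tandem-repeat detector is a deterministic seed–extend–refine scan: for
each candidate period it finds runs where the sequence matches itself
shifted by the period, extends them while the identity stays above the
threshold, builds a majority-vote consensus unit, reduces the unit to its
primitive (non-periodic) form and canonicalises its rotation.  Overlapping
candidate arrays are resolved by (higher identity, longer span, smaller
unit).  The hairpin detector is an exhaustive inverted-repeat scan over all
(stem, loop) placements maximising the contiguous paired stem length.
"""

from __future__ import annotations

from dataclasses import dataclass

from .composition import base_composition

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU_PAIRS = {("G", "T"), ("T", "G")}

#: Conserved motifs flanking the light-strand replication origin.
OL_MOTIF_5P = "AAAAT"
OL_MOTIF_3P = "AACCA"


# ---------------------------------------------------------------------------
# Tandem repeats
# ---------------------------------------------------------------------------

@dataclass
class TandemRepeat:
    start: int  # 1-based inclusive span in the scanned sequence
    end: int
    unit: str  # primitive unit, canonical (lexicographically smallest) rotation
    unit_original_phase: str  # unit as first observed 5'->3'
    copies: float
    identity: float

    @property
    def unit_len(self) -> int:
        return len(self.unit)

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def _primitive(unit: str) -> str:
    """Smallest unit whose exact tandem repetition yields ``unit``."""
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return unit[:d]
    return unit


def _canonical_rotation(unit: str) -> str:
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def _consensus_unit(seq: str, start: int, end: int, p: int) -> str:
    """Majority-vote consensus over full/partial copies of period p in seq[start:end]."""
    cols: list[dict[str, int]] = [dict() for _ in range(p)]
    for i in range(start, end):
        c = cols[(i - start) % p]
        ch = seq[i]
        c[ch] = c.get(ch, 0) + 1
    return "".join(max(sorted(c), key=lambda k: c[k]) for c in cols)


def find_tandem_repeats(
    seq: str,
    min_unit: int = 2,
    max_unit: int = 50,
    min_copies: float = 2.0,
    min_identity: float = 0.85,
) -> list[TandemRepeat]:
    """Non-crossing maximal tandem arrays, reported 5'->3'.

    Deterministic: for a given input and parameters the output is unique.
    """
    import numpy as np

    seq = seq.upper()
    n = len(seq)
    candidates: list[TandemRepeat] = []
    max_unit = min(max_unit, n // 2)
    # Extension scoring: +1 per self-shift match, -penalty per mismatch; the
    # array boundary is the running-score maximum, so flank excursions never
    # inflate the span.  A point mutation inside an array breaks the
    # self-shift comparison twice (at the site and one period later), so the
    # abandon budget is generous relative to the drift of random flanks
    # (expected score drift ~ -2.75/base), which still cannot bridge the
    # spacer between two distinct arrays.
    penalty = 4
    budget = 8 * penalty
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    for p in range(min_unit, max_unit + 1):
        if 2 * p > n:
            break
        m = (arr[:-p] == arr[p:])
        cs = np.concatenate(([0], np.cumsum(m)))
        if len(m) < p:
            break
        wsum = cs[p:] - cs[:-p]  # matches of seq[i:i+p] vs seq[i+p:i+2p]
        # tolerant seed: a near-period window (>= 90% matching), so mutated
        # copies of long units can still nucleate an array
        seed_min = p - max(0, p // 10)
        i = 0
        imax = n - 2 * p
        while i <= imax:
            if wsum[i] < seed_min:
                i += 1
                continue
            end = i + 2 * p
            score = float(wsum[i] - (p - wsum[i]) * penalty)
            best_score, best_end = score, end
            while end < n:
                score += 1 if m[end - p] else -penalty
                end += 1
                if score > best_score:
                    best_score, best_end = score, end
                if score < best_score - budget:
                    break
            score, best = 0.0, 0.0
            best_start = i
            j = i - 1
            while j >= 0:
                score += 1 if m[j] else -penalty
                if score > best:
                    best, best_start = score, j
                if score < best - budget:
                    break
                j -= 1
            span_start, span_end = best_start, best_end
            if (span_end - span_start) / p >= min_copies:
                # refine the span against the consensus pattern (one mismatch
                # event per mutation, unlike the self-shift comparison), so
                # quasi-matching junk at the edges is dropped
                unit = _consensus_unit(seq, span_start, span_end, p)
                new_span = _refine_span(seq, span_start, span_end, unit, penalty)
                advance = max(span_end - p + 1, i + 1)
                span_start, span_end = new_span
                if span_end - span_start >= p * min_copies:
                    unit = _consensus_unit(seq, span_start, span_end, p)
                    ident = _array_identity(seq, span_start, span_end, unit)
                    # reduce to a shorter period when a divisor explains the
                    # span exactly or within the array's own mismatch level
                    unit, ident = _reduce_unit(
                        seq, span_start, span_end, unit, ident, min_unit, min_identity
                    )
                    copies = (span_end - span_start) / len(unit)
                    if (
                        len(unit) >= min_unit
                        and copies >= min_copies
                        and ident >= min_identity
                    ):
                        candidates.append(
                            TandemRepeat(
                                start=span_start + 1,
                                end=span_end,
                                unit=_canonical_rotation(unit),
                                unit_original_phase=unit,
                                copies=copies,
                                identity=ident,
                            )
                        )
                i = advance
            else:
                i += 1
    # resolve overlaps: higher identity, then longer span, then smaller unit.
    # Identity is compared at 0.1 resolution so a long array carrying a few
    # isolated mismatches is not shattered by tiny perfect fragments of
    # itself; within a bucket the longer span wins.
    candidates.sort(
        key=lambda r: (-round(r.identity / 0.1), -r.span, r.unit_len, r.start)
    )
    chosen: list[TandemRepeat] = []
    for cand in candidates:
        if all(cand.end < c.start or cand.start > c.end for c in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda r: r.start)
    return chosen


def _refine_span(
    seq: str, start: int, end: int, unit: str, penalty: int
) -> tuple[int, int]:
    """Maximal-scoring subsegment of [start, end) against the consensus pattern.

    Scoring +1 per consensus match, -penalty per mismatch (Kadane), with the
    phase anchored at ``start``; shrinks the span only.
    """
    p = len(unit)
    best_sum = -1.0
    best = (start, start)
    run_sum = 0.0
    run_start = start
    for x in range(start, end):
        s = 1.0 if seq[x] == unit[(x - start) % p] else -float(penalty)
        if run_sum <= 0:
            run_sum = s
            run_start = x
        else:
            run_sum += s
        if run_sum > best_sum:
            best_sum = run_sum
            best = (run_start, x + 1)
    return best


def _reduce_unit(
    seq: str,
    start: int,
    end: int,
    unit: str,
    ident: float,
    min_unit: int,
    min_identity: float,
) -> tuple[str, float]:
    """Prefer the shortest divisor period that explains the span as well.

    Catches both exact reductions (e.g. a 4-mer that is a doubled 2-mer) and
    approximate ones, where a long period re-describes a mutated short-period
    array (e.g. a TA microsatellite reported with period 30).
    """
    p = len(unit)
    for d in range(min_unit, p):
        if p % d != 0:
            continue
        cons = _consensus_unit(seq, start, end, d)
        id_d = _array_identity(seq, start, end, cons)
        if id_d >= max(min_identity, ident - 0.02):
            return cons, id_d
    return unit, ident


def _array_identity(seq: str, start: int, end: int, unit: str) -> float:
    p = len(unit)
    matches = 0
    for i in range(start, end):
        if seq[i] == unit[(i - start) % p]:
            matches += 1
    return matches / (end - start)


# ---------------------------------------------------------------------------
# OL motifs and hairpin
# ---------------------------------------------------------------------------

@dataclass
class MotifHits:
    hits_5p: list[int]  # 1-based start positions of the 5' motif
    hits_3p: list[int]
    both_found: bool


def find_ol_motifs(seq: str) -> MotifHits:
    """Positions of the conserved 5'-AAAAT and AACCA-3' motifs in an OL window."""
    seq = seq.upper()

    def allpos(motif: str) -> list[int]:
        out, i = [], seq.find(motif)
        while i != -1:
            out.append(i + 1)
            i = seq.find(motif, i + 1)
        return out

    h5, h3 = allpos(OL_MOTIF_5P), allpos(OL_MOTIF_3P)
    return MotifHits(h5, h3, bool(h5) and bool(h3))


@dataclass
class Hairpin:
    stem_bp: int
    loop_len: int
    start: int  # 1-based start of the 5' stem arm
    end: int  # 1-based end of the 3' stem arm
    pairing: list[tuple[int, int, bool]]  # (pos5, pos3, is_GU) 1-based


def _paired(x: str, y: str, allow_gu: bool) -> bool:
    return (x, y) in _PAIRS or (allow_gu and (x, y) in _GU_PAIRS)


def find_hairpin(
    seq: str,
    min_stem: int = 4,
    max_loop: int = 30,
    min_loop: int = 3,
    allow_gu: bool = True,
) -> Hairpin | None:
    """Best single hairpin: maximise contiguous stem, ties -> smaller loop, then 5'."""
    seq = seq.upper()
    n = len(seq)
    if n > 200:
        raise ValueError("hairpin scan is meant for short (<=200 bp) windows")
    best: Hairpin | None = None
    for l0 in range(1, n):  # loop start (0-based); stem grows outward from it
        for loop in range(min_loop, max_loop + 1):
            if l0 + loop >= n:
                break
            s = 0
            while (
                l0 - s - 1 >= 0
                and l0 + loop + s < n
                and _paired(seq[l0 - s - 1], seq[l0 + loop + s], allow_gu)
            ):
                s += 1
            if s >= min_stem:
                cand = _make_hairpin(seq, l0, s, loop)
                if (
                    best is None
                    or cand.stem_bp > best.stem_bp
                    or (cand.stem_bp == best.stem_bp and cand.loop_len < best.loop_len)
                ):
                    best = cand
    return best


def _make_hairpin(seq: str, l0: int, s: int, loop: int) -> Hairpin:
    pairing = []
    for k in range(s):
        p5 = l0 - s + k
        p3 = l0 + loop + s - 1 - k
        gu = (seq[p5], seq[p3]) in _GU_PAIRS
        pairing.append((p5 + 1, p3 + 1, gu))
    return Hairpin(
        stem_bp=s, loop_len=loop, start=l0 - s + 1, end=l0 + loop + s, pairing=pairing
    )


# ---------------------------------------------------------------------------
# Control-region report
# ---------------------------------------------------------------------------

@dataclass
class CRReport:
    strain_id: str
    length: int
    pct_AT: float
    repeats: list[TandemRepeat]


def cr_report(cr_seqs: dict[str, str], **repeat_params) -> list[CRReport]:
    """Per-strain control-region summary: length, A+T% and ordered repeat arrays."""
    out = []
    for sid, seq in cr_seqs.items():
        comp = base_composition(seq, element="D-loop")
        out.append(
            CRReport(
                strain_id=sid,
                length=len(seq),
                pct_AT=comp.pct_AT,
                repeats=find_tandem_repeats(seq, **repeat_params),
            )
        )
    return out
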