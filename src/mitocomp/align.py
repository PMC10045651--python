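"""Global pairwise alignment (affine gaps, optional band) and star MSA.

The aligner is a Gotoh three-state dynamic program.  A gap of length L costs
``gap_open + (L-1) * gap_extend`` (the opening penalty covers the first gap
position).  Ties are broken deterministically: diagonal first, then the
vertical (gap-in-second-sequence) state, then horizontal — so outputs are
identical across platforms.  The multiple alignment is a star alignment
around the centre sequence (the one with the greatest summed pairwise score),
merged under "once a gap, always a gap".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

NEG_INF = np.float32(-1e18)

# default scoring scheme (match/mismatch/open/extend)
DEFAULT_SCORING = (1.0, -1.0, -4.0, -1.0)
#: band width used for sequences longer than this (None = unbanded below)
BAND_THRESHOLD = 2000
DEFAULT_BAND = 200


class BandError(ValueError):
    """The alignment band cannot connect the DP corners."""


@dataclass
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)


@njit(cache=True)
def _gotoh_fill(a, b, match, mismatch, open_, extend, band):  # pragma: no cover - numba
    n, m = a.shape[0], b.shape[0]
    M = np.full((n + 1, m + 1), NEG_INF, dtype=np.float32)
    X = np.full((n + 1, m + 1), NEG_INF, dtype=np.float32)  # gap in b (consumes a)
    Y = np.full((n + 1, m + 1), NEG_INF, dtype=np.float32)  # gap in a (consumes b)
    # traceback: for M which of M/X/Y fed the diagonal; for X/Y the source state
    tm = np.zeros((n + 1, m + 1), dtype=np.int8)
    tx = np.zeros((n + 1, m + 1), dtype=np.int8)
    ty = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = open_ + (i - 1) * extend
        tx[i, 0] = 1
    for j in range(1, m + 1):
        Y[0, j] = open_ + (j - 1) * extend
        ty[0, j] = 2
    for i in range(1, n + 1):
        jlo, jhi = 1, m
        if band > 0:
            jlo = max(1, i - band)
            jhi = min(m, i + band)
        for j in range(jlo, jhi + 1):
            # M state: diagonal move; tie-break M > X > Y
            best = M[i - 1, j - 1]
            src = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                src = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                src = 2
            if best > NEG_INF / 2:
                s = match if a[i - 1] == b[j - 1] else mismatch
                M[i, j] = best + s
                tm[i, j] = src
            # X state: vertical move (gap in b); tie-break M > X > Y
            bx = M[i - 1, j] + open_
            sx = 0
            if X[i - 1, j] + extend > bx:
                bx = X[i - 1, j] + extend
                sx = 1
            if Y[i - 1, j] + open_ > bx:
                bx = Y[i - 1, j] + open_
                sx = 2
            if bx > NEG_INF / 2:
                X[i, j] = bx
                tx[i, j] = sx
            # Y state: horizontal move (gap in a); tie-break M > X > Y
            by = M[i, j - 1] + open_
            sy = 0
            if X[i, j - 1] + open_ > by:
                by = X[i, j - 1] + open_
                sy = 1
            if Y[i, j - 1] + extend > by:
                by = Y[i, j - 1] + extend
                sy = 2
            if by > NEG_INF / 2:
                Y[i, j] = by
                ty[i, j] = sy
    return M, X, Y, tm, tx, ty


_CODE = np.full(128, 4, dtype=np.uint8)
for _i, _ch in enumerate("ACGT"):
    _CODE[ord(_ch)] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]


def align_pair(
    a: str,
    b: str,
    match: float = DEFAULT_SCORING[0],
    mismatch: float = DEFAULT_SCORING[1],
    gap_open: float = DEFAULT_SCORING[2],
    gap_extend: float = DEFAULT_SCORING[3],
    band: int | None = None,
) -> PairwiseAlignment:
    """Optimal global alignment of two sequences under the affine scheme.

    With ``band`` set, the DP is restricted to |i − j| ≤ band; the band must
    be at least the length difference to connect the corners.
    """
    if not a or not b:
        raise ValueError("align_pair requires non-empty sequences")
    if band is not None and band < abs(len(a) - len(b)):
        raise BandError(
            f"band {band} too narrow for length difference "
            f"{abs(len(a) - len(b))}; widen the band"
        )
    ea, eb = _encode(a), _encode(b)
    M, X, Y, tm, tx, ty = _gotoh_fill(
        ea,
        eb,
        np.float32(match),
        np.float32(mismatch),
        np.float32(gap_open),
        np.float32(gap_extend),
        np.int64(band if band is not None else 0),
    )
    n, m = len(a), len(b)
    # choose final state: prefer M, then X, then Y on ties
    mf, xf, yf = float(M[n, m]), float(X[n, m]), float(Y[n, m])
    if mf >= xf and mf >= yf:
        state = 0
    elif xf >= yf:
        state = 1
    else:
        state = 2
    score = (mf, xf, yf)[state]
    if score < float(NEG_INF) / 2:
        raise BandError("band too narrow to connect corners; widen the band")
    out_a, out_b = [], []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            src = tm[i, j]
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif state == 1:
            src = tx[i, j]
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            src = ty[i, j]
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
        state = int(src)
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    return PairwiseAlignment("".join(reversed(out_a)), "".join(reversed(out_b)), score)


def _auto_band(a: str, b: str) -> int | None:
    if max(len(a), len(b)) > BAND_THRESHOLD:
        return max(DEFAULT_BAND, abs(len(a) - len(b)))
    return None


@dataclass
class ElementAlignment:
    """Gap-aware multiple alignment of one element across strains."""

    element: str
    strain_ids: list[str]
    rows: list[str]
    source: str = "computed"  # or "imported"

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows of {self.element!r} alignment differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)


def star_msa(
    seqs: dict[str, str],
    element: str = "",
    band: int | None = None,
    **scoring,
) -> ElementAlignment:
    """Star multiple alignment around the centre sequence.

    The centre is the sequence maximising the summed pairwise alignment score
    against all others (ties broken by input order); the other sequences are
    merged against it under "once a gap, always a gap".
    """
    ids = list(seqs)
    if len(ids) < 2:
        raise ValueError("star_msa requires at least 2 sequences")
    raw = [seqs[k] for k in ids]
    if len(set(raw)) == 1:  # fast path: identical sequences
        return ElementAlignment(element, ids, raw)

    k = len(ids)
    pair: dict[tuple[int, int], PairwiseAlignment] = {}
    totals = [0.0] * k
    for i in range(k):
        for j in range(i + 1, k):
            use_band = band if band is not None else _auto_band(raw[i], raw[j])
            aln = align_pair(raw[i], raw[j], band=use_band, **scoring)
            pair[(i, j)] = aln
            totals[i] += aln.score
            totals[j] += aln.score
    center = max(range(k), key=lambda i: (totals[i], -i))

    master = raw[center]  # centre row with accumulated gaps
    merged: list[tuple[int, str]] = []  # (orig index, gapped row)
    for other in range(k):
        if other == center:
            continue
        if (center, other) in pair:
            ca, cb = pair[(center, other)].aligned_a, pair[(center, other)].aligned_b
        else:
            p = pair[(other, center)]
            ca, cb = p.aligned_b, p.aligned_a
        master, merged, row = _merge_into(master, merged, ca, cb)
        merged.append((other, row))

    rows_by_index = {center: master, **dict(merged)}
    return ElementAlignment(element, ids, [rows_by_index[i] for i in range(k)])


def _merge_into(master, merged, ca, cb):
    """Merge pairwise alignment (ca=centre, cb=other) into the master profile."""
    out_master, out_rows = [], [[] for _ in merged]
    out_new = []
    pi = 0  # position in ca/cb
    mi = 0  # position in master
    la, lm = len(ca), len(master)
    while pi < la or mi < lm:
        a_ch = ca[pi] if pi < la else None
        m_ch = master[mi] if mi < lm else None
        if m_ch == "-" and a_ch != "-":
            # gap already present in master from an earlier merge
            out_master.append("-")
            for r, (_, row) in zip(out_rows, merged):
                r.append(row[mi])
            out_new.append("-")
            mi += 1
        elif a_ch == "-" and m_ch != "-":
            # new gap in centre introduced by this pairwise alignment
            out_master.append("-")
            for r in out_rows:
                r.append("-")
            out_new.append(cb[pi])
            pi += 1
        else:
            # both '-' or both residues: columns agree
            out_master.append(m_ch if m_ch is not None else "-")
            for r, (_, row) in zip(out_rows, merged):
                r.append(row[mi])
            out_new.append(cb[pi] if pi < la else "-")
            pi += 1
            mi += 1
    new_merged = [
        (idx, "".join(r)) for (idx, _), r in zip(merged, out_rows)
    ]
    return "".join(out_master), new_merged, "".join(out_new)


def concatenate_alignments(alignments: list[ElementAlignment], element: str = "concat") -> ElementAlignment:
    """Column-wise concatenation (all alignments must share strain order)."""
    ids = alignments[0].strain_ids
    for aln in alignments[1:]:
        if aln.strain_ids != ids:
            raise ValueError("alignments have different strain orderings")
    rows = ["".join(aln.rows[i] for aln in alignments) for i in range(len(ids))]
    return ElementAlignment(element, list(ids), rows)


def read_alignment_fasta(path, element: str = "") -> ElementAlignment:
    """Import an aligned FASTA (rows over {A,C,G,T,N,-})."""
    from Bio import SeqIO

    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    if len(rows) < 2:
        raise ValueError(f"alignment {path} has fewer than 2 rows")
    return ElementAlignment(element or "imported", ids, rows, source="imported")


def write_alignment_fasta(aln: ElementAlignment, path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(aln.strain_ids, aln.rows):
            fh.write(f">{sid}\n{row}\n")
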