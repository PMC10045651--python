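"""Template-constrained tRNA cloverleaf assignment and cross-strain comparison.

Folding is not free-energy minimisation: the biological question is which
cloverleaf region (acceptor stem, DHU arm, anticodon arm, variable loop,
TψC arm) a variant falls in, so a fixed structural template is fitted by
exhaustive search over arm-size parameters, scoring Watson–Crick pairs 2 and
G–T (the DNA representation of the G–U wobble) 1.  Mitochondrial
tRNA-Ser(AGY) lacks the DHU stem; a zero-size DHU stem is part of the
template space and is reported as ``dhu_present=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .align import ElementAlignment
from .genetic_code import revcomp

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GT = {("G", "T"), ("T", "G")}

#: region name -> reporting category
REGION_CATEGORY = {
    "acceptor_5p": "acceptor",
    "acceptor_3p": "acceptor",
    "dhu_stem_5p": "DHU",
    "dhu_stem_3p": "DHU",
    "ac_stem_5p": "anticodon",
    "ac_stem_3p": "anticodon",
    "t_stem_5p": "TpsiC",
    "t_stem_3p": "TpsiC",
    "spacer1": "loops",
    "spacer2": "loops",
    "dhu_loop": "loops",
    "ac_loop": "loops",
    "var_loop": "loops",
    "t_loop": "loops",
}

#: region order; sizes are (fixed or parameter name)
_ACCEPTOR = 7
_AC_STEM = 5
_AC_LOOP = 7
_SPACER1 = 2
_SPACER2 = 1

_D_CHOICES = (4, 3, 0)  # 0 = DHU stem absent (loop retained)
_T_CHOICES = (5, 4)
_L1_RANGE = range(4, 13)  # DHU loop
_L2_RANGE = range(4, 10)  # TψC loop
_V_RANGE = range(3, 24)  # variable loop


def _layout(d: int, l1: int, v: int, t: int, l2: int) -> list[tuple[str, int]]:
    return [
        ("acceptor_5p", _ACCEPTOR),
        ("spacer1", _SPACER1),
        ("dhu_stem_5p", d),
        ("dhu_loop", l1),
        ("dhu_stem_3p", d),
        ("spacer2", _SPACER2),
        ("ac_stem_5p", _AC_STEM),
        ("ac_loop", _AC_LOOP),
        ("ac_stem_3p", _AC_STEM),
        ("var_loop", v),
        ("t_stem_5p", t),
        ("t_loop", l2),
        ("t_stem_3p", t),
        ("acceptor_3p", _ACCEPTOR),
    ]


def template_length(d: int, l1: int, v: int, t: int, l2: int) -> int:
    return sum(size for _, size in _layout(d, l1, v, t, l2))


def _pair_score(x: str, y: str) -> int:
    if (x, y) in _WC:
        return 2
    if (x, y) in _GT:
        return 1
    return 0


@dataclass
class CloverleafAnnotation:
    trna_id: str
    regions: dict[str, tuple[int, int]]  # 1-based inclusive; empty = (s, s-1)
    anticodon: str
    dhu_present: bool
    score: int
    fold_failed: bool = False
    stem_pairs: dict[str, int] = field(default_factory=dict)

    def region_at(self, pos: int) -> str | None:
        """Region name covering a 1-based sequence position."""
        for name, (s, e) in self.regions.items():
            if s <= pos <= e:
                return name
        return None


def _stem_pairs(seq: str, r5: tuple[int, int], r3: tuple[int, int]) -> tuple[int, int]:
    """(paired count, score) between two stem arms (outermost pairs first)."""
    s5, e5 = r5
    s3, e3 = r3
    n = e5 - s5 + 1
    paired = score = 0
    for k in range(n):
        x = seq[s5 - 1 + k]
        y = seq[e3 - 1 - k]
        sc = _pair_score(x, y)
        if sc:
            paired += 1
        score += sc
    return paired, score


def fold_cloverleaf(
    seq: str, anticodon_hint: str | None = None, trna_id: str = ""
) -> CloverleafAnnotation:
    """Best template assignment for a genomic tRNA sequence (55–95 nt).

    Returns a fold-failure annotation when no assignment pairs at least 5 of
    the 7 acceptor positions.
    """
    seq = seq.upper()
    L = len(seq)
    if not (55 <= L <= 95):
        return _fold_failure(trna_id, L)
    best = None
    for d in _D_CHOICES:
        for t in _T_CHOICES:
            for l2 in _L2_RANGE:
                # solve l1 + v = L − fixed part of the layout
                fixed = template_length(d, 0, 0, t, l2)
                rest = L - fixed
                for l1 in _L1_RANGE:
                    v = rest - l1
                    if v not in _V_RANGE:
                        continue
                    cand = _score_layout(seq, d, l1, v, t, l2, anticodon_hint)
                    if cand is None:
                        continue
                    if best is None or cand[0] > best[0]:
                        best = cand
    if best is None:
        return _fold_failure(trna_id, L)
    _, regions, anticodon, dhu_pairs, score, pairs = best
    return CloverleafAnnotation(
        trna_id=trna_id,
        regions=regions,
        anticodon=anticodon,
        dhu_present=dhu_pairs >= 2,
        score=score,
        stem_pairs=pairs,
    )


def _fold_failure(trna_id: str, L: int) -> CloverleafAnnotation:
    return CloverleafAnnotation(
        trna_id=trna_id,
        regions={},
        anticodon="",
        dhu_present=False,
        score=0,
        fold_failed=True,
    )


def _score_layout(seq, d, l1, v, t, l2, anticodon_hint):
    pos = 1
    regions: dict[str, tuple[int, int]] = {}
    for name, size in _layout(d, l1, v, t, l2):
        regions[name] = (pos, pos + size - 1)
        pos += size
    acc_pairs, acc_score = _stem_pairs(seq, regions["acceptor_5p"], regions["acceptor_3p"])
    if acc_pairs < 5:
        return None
    ac_pairs, ac_score = _stem_pairs(seq, regions["ac_stem_5p"], regions["ac_stem_3p"])
    t_pairs, t_score = _stem_pairs(seq, regions["t_stem_5p"], regions["t_stem_3p"])
    if d > 0:
        dhu_pairs, dhu_score = _stem_pairs(
            seq, regions["dhu_stem_5p"], regions["dhu_stem_3p"]
        )
    else:
        dhu_pairs = dhu_score = 0
    score = acc_score + ac_score + t_score + dhu_score
    s, e = regions["ac_loop"]
    anticodon = seq[s + 1 : s + 4]  # central 3 bases of the 7-nt loop
    key = score
    if anticodon_hint and anticodon == anticodon_hint.upper():
        key += 3
    pairs = {
        "acceptor": acc_pairs,
        "DHU": dhu_pairs,
        "anticodon": ac_pairs,
        "TpsiC": t_pairs,
    }
    return (key, regions, anticodon, dhu_pairs, score, pairs)


def build_template_trna(
    length: int, anticodon: str, rng, with_dhu: bool = True
) -> tuple[str, dict[str, tuple[int, int]]]:
    """Construct a synthetic genomic tRNA with perfect Watson–Crick stems.

    Returns (sequence, region spans).  The construction retries until
    ``fold_cloverleaf`` recovers the planted layout exactly, so generated
    fixtures are unambiguous under the template search.
    """
    choices = []
    d_opts = (4, 3) if with_dhu else (0,)
    for d in d_opts:
        for t in _T_CHOICES:
            for l2 in _L2_RANGE:
                fixed = template_length(d, 0, 0, t, l2)
                for l1 in _L1_RANGE:
                    v = length - fixed - l1
                    if v in _V_RANGE:
                        choices.append((d, l1, v, t, l2))
    if not choices:
        raise ValueError(f"no cloverleaf layout for tRNA length {length}")
    d, l1, v, t, l2 = choices[0]
    for _ in range(50):
        seq, regions = _build_once(d, l1, v, t, l2, anticodon, rng)
        fold = fold_cloverleaf(seq, anticodon_hint=anticodon)
        if not fold.fold_failed and fold.regions == regions:
            return seq, regions
    return seq, regions  # rare: accept the last construction


def _build_once(d, l1, v, t, l2, anticodon, rng):
    def rand(k: int) -> str:
        return "".join(rng.choice(["A", "C", "G", "T"]) for _ in range(k))

    def stem(k: int) -> tuple[str, str]:
        s5 = rand(k)
        return s5, revcomp(s5)

    acc5, acc3 = stem(_ACCEPTOR)
    dhu5, dhu3 = stem(d) if d else ("", "")
    ac5, ac3 = stem(_AC_STEM)
    t5, t3 = stem(t)
    ac_loop = rand(2) + anticodon.upper() + rand(2)
    parts = [
        acc5, rand(_SPACER1), dhu5, rand(l1), dhu3, rand(_SPACER2),
        ac5, ac_loop, ac3, rand(v), t5, rand(l2), t3, acc3,
    ]
    seq = "".join(parts)
    pos = 1
    regions = {}
    for name, size in _layout(d, l1, v, t, l2):
        regions[name] = (pos, pos + size - 1)
        pos += size
    return seq, regions


# ---------------------------------------------------------------------------
# Cross-strain comparison
# ---------------------------------------------------------------------------

@dataclass
class TrnaVariantReport:
    trna_id: str
    substitutions: dict[str, int]  # category -> count
    indels: dict[str, int]
    affected_regions: set[str]
    unchanged: bool
    unassigned: bool = False  # reference fold failed

    @property
    def n_substitutions(self) -> int:
        return sum(self.substitutions.values())

    @property
    def n_indels(self) -> int:
        return sum(self.indels.values())


_CATEGORIES = ("acceptor", "DHU", "anticodon", "TpsiC", "loops")


def compare_trnas(
    alns: dict[str, ElementAlignment],
    folds: dict[str, CloverleafAnnotation],
) -> list[TrnaVariantReport]:
    """Map cross-strain tRNA variants onto cloverleaf regions.

    ``folds`` holds the reference fold per tRNA (first strain of each
    alignment); variant columns are assigned to the region of the reference
    position they map to through the alignment.
    """
    reports = []
    for trna_id, aln in alns.items():
        fold = folds.get(trna_id)
        unassigned = fold is None or fold.fold_failed
        subs = {c: 0 for c in _CATEGORIES}
        inds = {c: 0 for c in _CATEGORIES}
        ref_row = aln.rows[0]
        ref_pos = 0
        for j in range(aln.n_columns):
            ref_ch = ref_row[j]
            if ref_ch != "-":
                ref_pos += 1
            column = aln.column(j)
            symbols = set(column)
            if len(symbols) == 1:
                continue
            if unassigned:
                category = "loops"
            else:
                region = fold.region_at(max(ref_pos, 1))
                category = REGION_CATEGORY.get(region or "", "loops")
            if "-" in symbols:
                inds[category] += 1
            else:
                subs[category] += 1
        total = sum(subs.values()) + sum(inds.values())
        affected = {
            c for c in _CATEGORIES if subs[c] or inds[c]
        }
        reports.append(
            TrnaVariantReport(
                trna_id=trna_id,
                substitutions=subs,
                indels=inds,
                affected_regions=affected,
                unchanged=(total == 0),
                unassigned=unassigned,
            )
        )
    return reports


def trna_variant_dataframe(reports: list[TrnaVariantReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        for cat in _CATEGORIES:
            if r.substitutions[cat] or r.indels[cat]:
                rows.append(
                    {
                        "trna": r.trna_id,
                        "region": cat,
                        "substitutions": r.substitutions[cat],
                        "indels": r.indels[cat],
                    }
                )
        if r.unchanged:
            rows.append({"trna": r.trna_id, "region": "-", "substitutions": 0, "indels": 0})
    return pd.DataFrame(rows)
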