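"""Base composition, A+T content and AT/GC strand skews.

AT skew = (A − T)/(A + T) and GC skew = (G − C)/(G + C), computed from raw
counts over non-N bases.  A zero denominator is reported as skew 0 with an
explicit flag rather than NaN, which keeps tabular output clean without
losing the information.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .genome import Mitogenome, extract_element


@dataclass
class CompositionStats:
    element: str
    pct_T: float
    pct_C: float
    pct_A: float
    pct_G: float
    pct_AT: float
    pct_GC: float
    at_skew: float
    gc_skew: float
    at_skew_undefined: bool = False
    gc_skew_undefined: bool = False
    n_bases: int = 0


def skew(x: float, y: float) -> tuple[float, bool]:
    """(x − y)/(x + y), returning (0, True) when x + y == 0."""
    if x + y == 0:
        return 0.0, True
    return (x - y) / (x + y), False


def base_composition(seq: str, element: str = "complete") -> CompositionStats:
    """Composition percentages and skews of one sequence (N/gaps excluded)."""
    counts = Counter(seq.upper())
    a, c, g, t = counts["A"], counts["C"], counts["G"], counts["T"]
    n = a + c + g + t
    if n == 0:
        raise ValueError(f"no countable bases in element {element!r}")
    at_skew, at_undef = skew(a, t)
    gc_skew, gc_undef = skew(g, c)
    return CompositionStats(
        element=element,
        pct_T=100 * t / n,
        pct_C=100 * c / n,
        pct_A=100 * a / n,
        pct_G=100 * g / n,
        pct_AT=100 * (a + t) / n,
        pct_GC=100 * (g + c) / n,
        at_skew=at_skew,
        gc_skew=gc_skew,
        at_skew_undefined=at_undef,
        gc_skew_undefined=gc_undef,
        n_bases=n,
    )


def skew_from_percentages(pct_a: float, pct_t: float) -> float:
    """Skew recomputed from already-tabulated mean percentages."""
    return (pct_a - pct_t) / (pct_a + pct_t)


_FIELDS = ("pct_T", "pct_C", "pct_A", "pct_G", "pct_AT", "pct_GC", "at_skew", "gc_skew")


def _mean_stats(element: str, per_strain: list[CompositionStats]) -> CompositionStats:
    """Arithmetic mean of per-strain stats (the tabulated 'average' rows)."""
    out = {f: sum(getattr(s, f) for s in per_strain) / len(per_strain) for f in _FIELDS}
    return CompositionStats(
        element=element,
        at_skew_undefined=any(s.at_skew_undefined for s in per_strain),
        gc_skew_undefined=any(s.gc_skew_undefined for s in per_strain),
        n_bases=sum(s.n_bases for s in per_strain),
        **out,
    )


def _pooled_stats(element: str, seqs: list[str]) -> CompositionStats:
    return base_composition("".join(seqs), element)


def element_composition_table(
    genomes: list[Mitogenome], mode: str = "mean"
) -> list[CompositionStats]:
    """One composition row per element class, per PCG, and for the complete genome.

    Class rows (tRNAs, rRNAs, PCGs) are computed on the concatenated class
    sequence of each strain; ``mode='mean'`` (default) averages the
    per-strain values arithmetically, ``mode='pool'`` pools the concatenated
    sequences of all strains before counting.
    """
    if mode not in ("mean", "pool"):
        raise ValueError("mode must be 'mean' or 'pool'")
    rows: list[CompositionStats] = []

    def add(element: str, seq_of_strain) -> None:
        per_strain, seqs = [], []
        for g in genomes:
            s = seq_of_strain(g)
            if s is None:
                continue
            seqs.append(s)
            per_strain.append(base_composition(s, element))
        if not per_strain:
            return
        rows.append(
            _mean_stats(element, per_strain) if mode == "mean" else _pooled_stats(element, seqs)
        )

    def class_concat(role: str):
        def getter(g: Mitogenome):
            parts = [extract_element(g, el.name) for el in g.elements_by_role(role)]
            return "".join(parts) or None

        return getter

    add("tRNAs", class_concat("tRNA"))
    add("rRNAs", class_concat("rRNA"))
    add("D-loop", lambda g: next(
        (extract_element(g, el.name) for el in g.elements_by_role("control_region")), None
    ))
    pcg_names = [el.name for el in genomes[0].elements_by_role("PCG")]
    for name in pcg_names:
        add(name, lambda g, name=name: (
            extract_element(g, name) if any(e.name == name for e in g.elements) else None
        ))
    add("PCGs", class_concat("PCG"))
    add("Complete genome", lambda g: g.sequence)
    return rows


def composition_dataframe(rows: list[CompositionStats], ndigits: int = 2) -> pd.DataFrame:
    """Report-style table: percentages and skews rounded, full precision kept."""
    recs = []
    for r in rows:
        rec = {"element": r.element}
        for f in _FIELDS:
            rec[f] = round(getattr(r, f), ndigits)
            rec[f + "_full"] = getattr(r, f)
        recs.append(rec)
    return pd.DataFrame(recs)
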