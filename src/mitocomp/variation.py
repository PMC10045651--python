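"""Variable-site classification of element alignments.

Columns containing any gap or N are excluded from the totals
(complete-deletion), matching the convention of standard polymorphism
software, which is why the published complete-genome site total is smaller
than any of the four genome lengths.  A variable column is *singleton* when
it is not parsimony-informative; *parsimony-informative* requires at least
two distinct bases each carried by at least two sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .align import ElementAlignment, concatenate_alignments

log = logging.getLogger(__name__)

_VALID = frozenset("ACGT")


@dataclass
class SiteClassification:
    element: str
    total_sites: int
    invariable: int
    variable: int
    singleton: int
    parsimony_informative: int

    @property
    def pct_variable(self) -> float:
        return 100.0 * self.variable / self.total_sites if self.total_sites else 0.0

    def __post_init__(self) -> None:
        assert self.variable == self.singleton + self.parsimony_informative
        assert self.invariable + self.variable == self.total_sites


def classify_column(column: str) -> str | None:
    """Classify one alignment column.

    Returns None (excluded) for columns containing gap/N, otherwise one of
    'invariable', 'singleton', 'parsimony_informative'.
    """
    if not set(column) <= _VALID:
        return None
    counts: dict[str, int] = {}
    for ch in column:
        counts[ch] = counts.get(ch, 0) + 1
    if len(counts) == 1:
        return "invariable"
    if sum(1 for v in counts.values() if v >= 2) >= 2:
        return "parsimony_informative"
    return "singleton"


def classify_sites(aln: ElementAlignment) -> SiteClassification:
    """Per-element site classification over included (gap/N-free) columns."""
    if len(aln.rows) < 2:
        raise ValueError("classify_sites requires an alignment of >= 2 rows")
    tallies = {"invariable": 0, "singleton": 0, "parsimony_informative": 0}
    for j in range(aln.n_columns):
        cls = classify_column(aln.column(j))
        if cls is not None:
            tallies[cls] += 1
    variable = tallies["singleton"] + tallies["parsimony_informative"]
    return SiteClassification(
        element=aln.element,
        total_sites=tallies["invariable"] + variable,
        invariable=tallies["invariable"],
        variable=variable,
        singleton=tallies["singleton"],
        parsimony_informative=tallies["parsimony_informative"],
    )


def variation_table(alignments: list[ElementAlignment]) -> list[SiteClassification]:
    """Published-style variation table.

    Per-element rows for PCGs and the D-loop, concatenated class rows for
    tRNAs and rRNAs, and a complete-genome row over the concatenation of all
    element alignments in genome order.  Missing elements are skipped with a
    log entry.
    """
    rows: list[SiteClassification] = []
    by_name = {a.element: a for a in alignments}

    def concat_row(label: str, members: list[ElementAlignment]):
        if not members:
            log.warning("no alignments for %s; row skipped", label)
            return
        cat = concatenate_alignments(members, element=label)
        rows.append(classify_sites(cat))

    concat_row("Complete genome", alignments)
    concat_row("tRNAs", [a for a in alignments if a.element.startswith("tRNA")])
    concat_row("rRNAs", [a for a in alignments if a.element.endswith("rRNA")])
    for name, aln in by_name.items():
        if name == "D-loop" or not (
            name.startswith("tRNA") or name.endswith("rRNA") or name == "OL"
        ):
            rows.append(classify_sites(aln))
    return rows


def variation_dataframe(rows: list[SiteClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "element": r.element,
                "total_sites": r.total_sites,
                "invariable": r.invariable,
                "variable": r.variable,
                "singleton": r.singleton,
                "parsimony_informative": r.parsimony_informative,
                "pct_variable": round(r.pct_variable, 2),
                "pct_variable_full": r.pct_variable,
            }
            for r in rows
        ]
    )
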