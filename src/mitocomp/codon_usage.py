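"""Codon counting over concatenated protein-coding genes and RSCU.

RSCU (relative synonymous codon usage) of codon *i* in a synonymous family of
size *k* with family total *n* is ``count_i / (n / k)`` — the observed count
over the count expected if all members of the family were used equally.
Stop codons are excluded from the families and tallied separately; a family
with zero total has its RSCU reported as 0 with an explicit flag.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .genetic_code import VERTEBRATE_MITO, GeneticCode


def count_codons(pcg_seqs: list[str]) -> Counter:
    """Frame-0 codon counts over coding-orientation sequences.

    A trailing incomplete codon (the 1–2 nt incomplete stop) is dropped;
    codons containing N are skipped.
    """
    counts: Counter = Counter()
    for seq in pcg_seqs:
        seq = seq.upper()
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[i : i + 3]
            if set(codon) <= set("ACGT"):
                counts[codon] += 1
    return counts


@dataclass
class RSCURow:
    codon: str
    amino_acid: str
    count: int
    rscu: float
    family_size: int
    undefined: bool = False  # family total was zero


@dataclass
class RSCUTable:
    strain_id: str
    rows: list[RSCURow]
    stop_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_codons(self) -> int:
        return sum(r.count for r in self.rows)

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "strain": self.strain_id,
                    "codon": r.codon,
                    "amino_acid": r.amino_acid,
                    "count": r.count,
                    "rscu": r.rscu,
                    "family_size": r.family_size,
                }
                for r in self.rows
            ]
        )


def rscu(
    counts: Counter, code: GeneticCode = VERTEBRATE_MITO, strain_id: str = ""
) -> RSCUTable:
    """RSCU per sense codon under the given code's synonymous families."""
    rows = []
    for aa, family in sorted(code.families.items()):
        total = sum(counts.get(c, 0) for c in family)
        k = len(family)
        for codon in family:
            cnt = counts.get(codon, 0)
            if total == 0:
                rows.append(RSCURow(codon, aa, 0, 0.0, k, undefined=True))
            else:
                rows.append(RSCURow(codon, aa, cnt, cnt / (total / k), k))
    stops = {c: counts.get(c, 0) for c in sorted(code.stop_codons)}
    return RSCUTable(strain_id=strain_id, rows=rows, stop_counts=stops)


def rscu_summary(tables: list[RSCUTable]) -> dict:
    """Number of codons with RSCU strictly > 1, per strain and pooled.

    The pooled value is computed on summed codon counts, not on averaged
    RSCU values.
    """
    per_strain = {
        t.strain_id: sum(1 for r in t.rows if r.rscu > 1.0) for t in tables
    }
    pooled_counts: Counter = Counter()
    for t in tables:
        for r in t.rows:
            pooled_counts[r.codon] += r.count
        for c, n in t.stop_counts.items():
            pooled_counts[c] += n
    pooled_table = rscu(pooled_counts, strain_id="pooled")
    pooled = sum(1 for r in pooled_table.rows if r.rscu > 1.0)
    return {"per_strain": per_strain, "pooled": pooled}
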