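"""Vertebrate mitochondrial genetic code.

The vertebrate mitochondrial code differs from the standard code in four
assignments: AGA and AGG are stop codons (not arginine), ATA is methionine
(not isoleucine) and TGA is tryptophan (not stop).  Truncated protein genes
end in a 1–2 nt incomplete stop token (T or TA) that is completed to TAA by
polyadenylation of the mRNA; those tokens are recognised here but never
poly-A-completed before codon-level analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_BASES = "TCAG"

# Standard-code layout, then apply the four vertebrate-mitochondrial changes.
_STANDARD = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGG GG".replace(" ", "")
)


def _standard_map() -> dict[str, str]:
    table = {}
    i = 0
    for b1 in _BASES:
        for b2 in _BASES:
            for b3 in _BASES:
                table[b1 + b2 + b3] = _STANDARD[i]
                i += 1
    return table


@dataclass(frozen=True)
class GeneticCode:
    """A codon translation table with explicit stop set and incomplete-stop tokens.

    ``families`` partitions the sense codons by encoded amino acid; these are
    the synonymous families used for RSCU and for synonymous/nonsynonymous
    site counting.
    """

    name: str
    codon_to_aa: dict[str, str]  # sense codons only
    stop_codons: frozenset[str]
    incomplete_stop_tokens: frozenset[str] = frozenset({"T", "TA"})
    _families: dict[str, tuple[str, ...]] = field(default=None, repr=False, compare=False)

    def translate_codon(self, codon: str) -> str:
        """Amino acid for a sense codon, '*' for a stop, 'X' if N-containing."""
        codon = codon.upper()
        if codon in self.stop_codons:
            return "*"
        if codon in self.codon_to_aa:
            return self.codon_to_aa[codon]
        return "X"

    def is_stop(self, codon: str) -> bool:
        return codon.upper() in self.stop_codons

    @property
    def families(self) -> dict[str, tuple[str, ...]]:
        """Synonymous families: amino acid -> sorted tuple of its sense codons."""
        if self._families is None:
            fams: dict[str, list[str]] = {}
            for codon, aa in self.codon_to_aa.items():
                fams.setdefault(aa, []).append(codon)
            object.__setattr__(
                self, "_families", {aa: tuple(sorted(c)) for aa, c in fams.items()}
            )
        return self._families

    def translate(self, seq: str) -> str:
        """Translate an in-frame sequence; trailing incomplete codon dropped."""
        aas = []
        for i in range(0, len(seq) - len(seq) % 3, 3):
            aas.append(self.translate_codon(seq[i : i + 3]))
        return "".join(aas)


def vertebrate_mito_code() -> GeneticCode:
    table = _standard_map()
    table["AGA"] = "*"
    table["AGG"] = "*"
    table["ATA"] = "M"
    table["TGA"] = "W"
    stops = frozenset(c for c, aa in table.items() if aa == "*")
    sense = {c: aa for c, aa in table.items() if aa != "*"}
    return GeneticCode(name="vertebrate_mitochondrial", codon_to_aa=sense, stop_codons=stops)


#: Module-level singleton; all analyses default to this code.
VERTEBRATE_MITO = vertebrate_mito_code()

COMPLEMENT = str.maketrans("ACGTNacgtn-", "TGCANtgcan-")


def revcomp(seq: str) -> str:
    """Reverse complement (N and '-' preserved)."""
    return seq.translate(COMPLEMENT)[::-1]
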