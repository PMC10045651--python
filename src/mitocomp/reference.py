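"""Packaged published reference tables for the four *Pelodiscus sinensis* strains.

The gene table stores per-strain element lengths, intergenic spacers
(negative = overlap) and PCG start/stop codons.  Walking the table
cumulatively from tRNA-Phe at position 1 reconstructs full per-strain
annotations whose circular closure reproduces the published genome lengths
exactly, so no sequence download is needed for coordinate-level analyses.

Note: the published control-region section lengths differ by exactly 1 bp
from the gene-table D-loop lengths; both are stored and the discrepancy is
flagged rather than reconciled.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

from .genome import ElementAnnotation

STRAINS = ("HB", "JB", "RB", "WB")

#: Published complete-genome lengths (bp) per strain.
GENOME_LENGTHS = {"HB": 17116, "JB": 17182, "RB": 17235, "WB": 17219}

#: Control-region lengths as published in the control-region section; these
#: differ by 1 bp from the gene table's D-loop lengths (flagged, not fixed).
CR_SECTION_LENGTHS = {"HB": 1596, "JB": 1659, "RB": 1710, "WB": 1698}
CR_LENGTH_DISCREPANCY = True

#: Published control-region A+T content (%) per strain.
CR_AT_CONTENT = {"HB": 63.87, "JB": 64.58, "RB": 63.71, "WB": 64.45}


def _data_path(name: str):
    return resources.files("mitocomp.data").joinpath(name)


@lru_cache(maxsize=None)
def load_gene_table() -> pd.DataFrame:
    """Published per-strain gene lengths / spacers / codons, one row per element."""
    with resources.as_file(_data_path("psinensis_gene_table.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#", keep_default_na=False)
    for s in STRAINS:
        df[f"{s}_len"] = df[f"{s}_len"].astype(int)
        df[f"{s}_ig"] = df[f"{s}_ig"].astype(int)
    return df


@lru_cache(maxsize=None)
def load_composition_reference() -> pd.DataFrame:
    """Published per-element mean base composition and skews."""
    with resources.as_file(_data_path("psinensis_composition.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")


@lru_cache(maxsize=None)
def load_variation_reference() -> pd.DataFrame:
    """Published variation-site classification table."""
    with resources.as_file(_data_path("psinensis_variation.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def reference_annotations(strain: str) -> list[ElementAnnotation]:
    """Reconstruct full 1-based coordinates for one strain from the gene table.

    Elements are laid out from tRNA-Phe at position 1; a negative spacer
    after an element makes the next element start inside it (overlap).
    """
    if strain not in STRAINS:
        raise ValueError(f"unknown strain {strain!r}; expected one of {STRAINS}")
    df = load_gene_table()
    elements = []
    pos = 1
    for _, row in df.iterrows():
        length = int(row[f"{strain}_len"])
        spacer = int(row[f"{strain}_ig"])
        el = ElementAnnotation(
            name=row["name"],
            role=row["role"],
            start=pos,
            end=pos + length - 1,
            strand=row["strand"],
            start_codon=row[f"{strain}_start"] or None,
            stop_codon=row[f"{strain}_stop"] or None,
        )
        elements.append(el)
        pos = el.end + 1 + spacer
    return elements


def reference_genome_length(strain: str) -> int:
    """Genome length implied by the cumulative walk (equals GENOME_LENGTHS)."""
    els = reference_annotations(strain)
    # last element is the D-loop with a zero spacer back to tRNA-Phe
    return els[-1].end
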