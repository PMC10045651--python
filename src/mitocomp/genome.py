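"""Annotated circular mitogenome model and FASTA / annotation-table I/O.

Coordinates are exposed 1-based inclusive (GenBank convention) and converted
to 0-based half-open only inside slicing arithmetic, so feature tables
round-trip losslessly.  The stored sequence is the heavy strand; ``strand='L'``
means the element is reverse-complemented on extraction.  A wrap-around
element (spanning the circular origin) is encoded with ``start > end`` and is
only permitted as the last element in genomic order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import VERTEBRATE_MITO, GeneticCode, revcomp

log = logging.getLogger(__name__)

IUPAC_DNA = set("ACGTRYSWKMBDHVN")

#: The 13 mitochondrial protein-coding genes, canonical vertebrate naming.
PCG_NAMES = frozenset(
    {
        "NAD1", "NAD2", "NAD3", "NAD4", "NAD4L", "NAD5", "NAD6",
        "COX1", "COX2", "COX3", "ATP6", "ATP8", "Cytb",
    }
)

ROLES = ("PCG", "tRNA", "rRNA", "control_region", "OL")

#: Elements encoded on the light strand in the vertebrate arrangement:
#: NAD6 plus eight tRNAs.
L_STRAND_ELEMENTS = frozenset(
    {
        "NAD6", "tRNA-Gln", "tRNA-Ala", "tRNA-Asn", "tRNA-Cys",
        "tRNA-Tyr", "tRNA-Ser(UCN)", "tRNA-Glu", "tRNA-Pro",
    }
)


class GenomeError(ValueError):
    """Malformed genome, annotation or coordinate input."""


@dataclass
class ElementAnnotation:
    """One annotated element on the circle.

    start/end are 1-based inclusive on the reported (heavy-strand) sequence;
    start > end denotes a wrap across the circular origin.
    """

    name: str
    role: str
    start: int
    end: int
    strand: str = "H"
    start_codon: str | None = None
    stop_codon: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise GenomeError(f"unknown role {self.role!r} for element {self.name!r}")
        if self.strand not in ("H", "L"):
            raise GenomeError(f"strand must be 'H' or 'L', got {self.strand!r}")
        if (self.role == "PCG") != (self.name in PCG_NAMES):
            raise GenomeError(
                f"role/name mismatch: {self.name!r} with role {self.role!r}"
            )

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    def length(self, genome_length: int) -> int:
        if self.wraps:
            return genome_length - self.start + 1 + self.end
        return self.end - self.start + 1


@dataclass
class Mitogenome:
    """A circular mitochondrial genome with ordered element annotations."""

    strain_id: str
    sequence: str
    elements: list[ElementAnnotation] = field(default_factory=list)

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    def element(self, name: str) -> ElementAnnotation:
        for el in self.elements:
            if el.name == name:
                return el
        raise GenomeError(f"element {name!r} not annotated in strain {self.strain_id}")

    def element_names(self) -> list[str]:
        return [el.name for el in self.elements]

    def elements_by_role(self, role: str) -> list[ElementAnnotation]:
        return [el for el in self.elements if el.role == role]

    def validate(self) -> None:
        n = self.length_bp
        names = [el.name for el in self.elements]
        if len(set(names)) != len(names):
            dup = sorted({x for x in names if names.count(x) > 1})
            raise GenomeError(f"duplicate element names {dup} in strain {self.strain_id}")
        wrapping = [el for el in self.elements if el.wraps]
        if len(wrapping) > 1:
            raise GenomeError("at most one wrap-around element is allowed")
        if wrapping and self.elements[-1] is not wrapping[0]:
            raise GenomeError("a wrap-around element must be the last element")
        for el in self.elements:
            if not (1 <= el.start <= n and 1 <= el.end <= n):
                raise GenomeError(
                    f"element {el.name!r} coordinates {el.start}..{el.end} "
                    f"outside 1..{n}"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[Mitogenome]:
    """Read a multi-record FASTA into Mitogenomes (no annotations attached).

    Sequences are uppercased; any character outside the IUPAC DNA alphabet
    raises with the offending record and 1-based position.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise GenomeError(f"no FASTA records in {path}")
    genomes = []
    for rec in records:
        seq = str(rec.seq).upper()
        for i, ch in enumerate(seq):
            if ch not in IUPAC_DNA:
                raise GenomeError(
                    f"record {rec.id!r}: invalid character {ch!r} at position {i + 1}"
                )
        genomes.append(Mitogenome(strain_id=rec.id, sequence=seq))
    return genomes


def write_fasta(genomes: Iterable[Mitogenome], path: str | Path, width: int = 70) -> None:
    recs = [
        SeqRecord(Seq(g.sequence), id=g.strain_id, description="")
        for g in genomes
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ("name", "role", "start", "end", "strand", "start_codon", "stop_codon")

_GENBANK_ROLE = {
    "CDS": "PCG",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "D-loop": "control_region",
    "D_loop": "control_region",
    "rep_origin": "OL",
}


def read_annotations(path: str | Path, genome: Mitogenome) -> Mitogenome:
    """Attach element annotations from a TSV or GenBank feature table.

    Elements are attached in genomic order starting at tRNA-Phe; a
    wrap-around element is permitted only as the last element.  Returns a new
    Mitogenome (the input is not mutated).
    """
    path = Path(path)
    if path.suffix.lower() in (".gb", ".gbk", ".genbank"):
        elements = _read_genbank_features(path)
    else:
        elements = _read_tsv_annotations(path)
    if not elements:
        log.warning("empty annotation table %s; genome %s unchanged", path, genome.strain_id)
        return genome
    annotated = replace(genome, elements=_genomic_order(elements))
    annotated.validate()
    cr = annotated.elements_by_role("control_region")
    if len(cr) > 1:
        raise GenomeError("overlapping/duplicate control_region features")
    return annotated


def _read_tsv_annotations(path: Path) -> list[ElementAnnotation]:
    elements = []
    with open(path) as fh:
        header = None
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
                missing = set(_TSV_COLUMNS[:5]) - set(header)
                if missing:
                    raise GenomeError(f"annotation TSV missing columns {sorted(missing)}")
                continue
            row = dict(zip(header, fields))
            elements.append(
                ElementAnnotation(
                    name=row["name"],
                    role=row["role"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row.get("strand", "H") or "H",
                    start_codon=row.get("start_codon") or None,
                    stop_codon=row.get("stop_codon") or None,
                )
            )
    return elements


def _read_genbank_features(path: Path) -> list[ElementAnnotation]:
    rec = SeqIO.read(str(path), "genbank")
    elements = []
    for feat in rec.features:
        role = _GENBANK_ROLE.get(feat.type)
        if role is None:
            continue
        quals = feat.qualifiers
        name = (quals.get("gene") or quals.get("product") or [feat.type])[0]
        if role == "control_region":
            name = "D-loop"
        elif role == "OL":
            name = "OL"
        strand = "L" if feat.location.strand == -1 else "H"
        elements.append(
            ElementAnnotation(
                name=name,
                role=role,
                start=int(feat.location.start) + 1,
                end=int(feat.location.end),
                strand=strand,
            )
        )
    return elements


def write_annotations(genome: Mitogenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for el in genome.elements:
            fh.write(
                "\t".join(
                    [
                        el.name,
                        el.role,
                        str(el.start),
                        str(el.end),
                        el.strand,
                        el.start_codon or "",
                        el.stop_codon or "",
                    ]
                )
                + "\n"
            )


def _genomic_order(elements: list[ElementAnnotation]) -> list[ElementAnnotation]:
    """Order by start coordinate, rotated so tRNA-Phe comes first, wrap last."""
    ordered = sorted(elements, key=lambda e: (e.start, e.end))
    names = [e.name for e in ordered]
    if "tRNA-Phe" in names:
        i = names.index("tRNA-Phe")
        ordered = ordered[i:] + ordered[:i]
    wrapping = [e for e in ordered if e.wraps]
    if wrapping:
        ordered = [e for e in ordered if not e.wraps] + wrapping
    return ordered


# ---------------------------------------------------------------------------
# Extraction and per-element arithmetic
# ---------------------------------------------------------------------------

def extract_element(genome: Mitogenome, name: str) -> str:
    """Element sequence in coding orientation (L-strand reverse-complemented)."""
    el = genome.element(name)
    seq = genome.sequence
    if el.wraps:
        sub = seq[el.start - 1 :] + seq[: el.end]
    else:
        sub = seq[el.start - 1 : el.end]
    return revcomp(sub) if el.strand == "L" else sub


def intergenic_lengths(genome: Mitogenome) -> list[tuple[str, int]]:
    """Spacer after each element on the circle; negative means overlap.

    spacer(i) = start(i+1) − end(i) − 1, with the last element closing the
    circle back to the first.
    """
    out = []
    els = genome.elements
    n = genome.length_bp
    for i, el in enumerate(els):
        nxt = els[(i + 1) % len(els)]
        if el.wraps:
            spacer = nxt.start - el.end - 1
        elif i + 1 < len(els):
            spacer = nxt.start - el.end - 1
        else:  # close the circle: last element's end to first element's start
            spacer = (n - el.end) + (nxt.start - 1)
        out.append((el.name, spacer))
    return out


@dataclass
class CodonAudit:
    gene: str
    start_codon: str
    stop_codon: str
    complete: bool  # True when the gene ends in a full stop codon
    internal_stop: bool  # True when an in-frame stop precedes the terminal codon


def audit_codons(
    genome: Mitogenome, code: GeneticCode = VERTEBRATE_MITO
) -> list[CodonAudit]:
    """Start/stop codon audit of every protein-coding gene.

    The stop is the terminal full codon when length ≡ 0 (mod 3), otherwise
    the trailing 1–2 nt incomplete stop token.  An in-frame stop before the
    terminal codon is flagged rather than silently accepted.
    """
    audits = []
    for el in genome.elements_by_role("PCG"):
        seq = extract_element(genome, el.name)
        rem = len(seq) % 3
        full_len = len(seq) - rem
        if rem == 0:
            stop = seq[-3:]
            complete = code.is_stop(stop)
            body = seq[3:-3]
        else:
            stop = seq[full_len:]
            complete = False
            body = seq[3:full_len]  # every full codon after the start
        internal = any(
            code.is_stop(body[i : i + 3]) for i in range(0, len(body) - 2, 3)
        )
        audits.append(
            CodonAudit(
                gene=el.name,
                start_codon=seq[:3],
                stop_codon=stop,
                complete=complete,
                internal_stop=internal,
            )
        )
    return audits
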