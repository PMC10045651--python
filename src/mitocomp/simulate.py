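"""Seeded generator of four related mitogenome strains with known truth.

The generator emulates the comparative setting of four conspecific strains:
a circular ancestor with the canonical vertebrate gene order (13 PCGs,
22 tRNAs, 2 rRNAs, OL, control region) is evolved independently along a
fixed 4-taxon tree ((S1,S2),S3,S4) with element-specific substitution rates.
Default rates are calibrated so the 4-strain variable-site percentages land
near the published comparison (control region ~7%, PCGs ~2–4%, tRNA/rRNA
~1.6–1.7%): with total tree length 2.0 the expected variable fraction of an
element is ~2x its per-unit-branch rate.

Biological constraints honoured by the mutation process:

* PCGs remain valid ORFs (start codon and stop plan preserved; proposals
  creating in-frame stops are rejected);
* the OL is treated as functionally conserved (no random mutation), except
  for an optional planted stem-breaking substitution in one strain;
* control-region VNTR arrays evolve by copy number (per-strain copies from
  the plan), while the flanks accumulate point mutations;
* single-base indels occur only outside PCGs, OL and repeat arrays.

All randomness flows from one seed through numpy SeedSequence spawning in a
fixed order, so outputs are byte-identical for a given configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genetic_code import VERTEBRATE_MITO, revcomp
from .genome import ElementAnnotation, Mitogenome
from .reference import load_gene_table
from .trna import build_template_trna

STRAIN_NAMES = ("S1", "S2", "S3", "S4")

#: branch lengths of the fixed tree, in units of the element rate;
#: total tree length 2.0, internal branch joins S1+S2, S3 nearer than S4.
BRANCHES = {"AB": 0.30, "S1": 0.35, "S2": 0.35, "S3": 0.45, "S4": 0.55}

#: path length between each strain pair (sum of branches separating them)
PAIR_PATHS = {
    ("S1", "S2"): 0.70,
    ("S1", "S3"): 1.10,
    ("S1", "S4"): 1.20,
    ("S2", "S3"): 1.10,
    ("S2", "S4"): 1.20,
    ("S3", "S4"): 1.00,
}

#: genomic anticodons (DNA alphabet) of the 22 vertebrate mitochondrial tRNAs
ANTICODONS = {
    "tRNA-Phe": "GAA", "tRNA-Val": "TAC", "tRNA-Leu(UUR)": "TAA",
    "tRNA-Ile": "GAT", "tRNA-Gln": "TTG", "tRNA-Met": "CAT",
    "tRNA-Trp": "TCA", "tRNA-Ala": "TGC", "tRNA-Asn": "GTT",
    "tRNA-Cys": "GCA", "tRNA-Tyr": "GTA", "tRNA-Ser(UCN)": "TGA",
    "tRNA-Asp": "GTC", "tRNA-Lys": "TTT", "tRNA-Gly": "TCC",
    "tRNA-Arg": "TCG", "tRNA-His": "GTG", "tRNA-Ser(AGY)": "GCT",
    "tRNA-Leu(CUN)": "TAG", "tRNA-Glu": "TTC", "tRNA-Thr": "TGT",
    "tRNA-Pro": "TGG",
}

#: base sampling probabilities (T, C, A, G) targeting ~63% A+T
BASE_PROBS = {"T": 0.29, "C": 0.25, "A": 0.34, "G": 0.12}

#: designed 34-nt light-strand replication origin: 5' AAAAT motif, an 11 bp
#: perfectly paired stem (arms TTCAGCGGTCA / TGACCGCTGAA) around a 4-nt loop,
#: and the AACCA motif at the 3' end.
OL_STEM5 = "TTCAGCGGTCA"
OL_SEQ = "AAAAT" + OL_STEM5 + "TTCG" + revcomp(OL_STEM5) + "CCA"
#: 1-based position in OL_SEQ of the planted stem-breaking A->T substitution
OL_BREAK_POS = 9
assert len(OL_SEQ) == 34 and OL_SEQ[OL_BREAK_POS - 1] == "A"

#: published-style PCG lengths whose printed stop codon is not congruent with
#: the printed length mod 3; the plan keeps the stop and adjusts the length
#: to the nearest consistent value.
_LENGTH_FIXES = {"NAD1": 972, "NAD2": 1041, "ATP6": 684, "NAD3": 354}


@dataclass
class VNTRArray:
    """One control-region tandem array: unit, per-strain copy numbers."""

    unit: str | None  # None: random unit of unit_len drawn at build time
    copies: dict[str, int] | int
    unit_len: int = 0
    spacer_after: int = 25

    def copies_for(self, strain: str) -> int:
        if isinstance(self.copies, dict):
            return self.copies[strain]
        return int(self.copies)

    @property
    def ancestor_copies(self) -> int:
        if isinstance(self.copies, dict):
            return self.copies[STRAIN_NAMES[0]]
        return int(self.copies)


def default_vntr_plan() -> list[VNTRArray]:
    """Four arrays echoing the published control-region architecture:
    a 50-bp unit, a 6-bp unit with ~47–57 copies, a TA microsatellite and a
    9-bp unit, concentrated toward the 3' end of the region."""
    return [
        VNTRArray(unit=None, unit_len=50, copies={"S1": 3, "S2": 3, "S3": 3, "S4": 3}),
        VNTRArray(unit="ACACAT", copies={"S1": 52, "S2": 57, "S3": 48, "S4": 47}),
        VNTRArray(unit="TA", copies={"S1": 37, "S2": 40, "S3": 20, "S4": 34}),
        VNTRArray(unit="TATCATATA", copies={"S1": 6, "S2": 8, "S3": 7, "S4": 6}),
    ]


@dataclass
class PlanEntry:
    name: str
    role: str
    strand: str
    length: int
    spacer_after: int
    start_codon: str | None = None
    stop_codon: str | None = None


def default_gene_plan() -> list[PlanEntry]:
    """Element order/lengths from the packaged published gene table (first
    strain column), with stop-incongruent PCG lengths minimally adjusted and
    overlaps clamped to zero (overlapping reading frames are not simulated)."""
    df = load_gene_table()
    plan = []
    for _, row in df.iterrows():
        length = int(row["HB_len"])
        name = row["name"]
        if name in _LENGTH_FIXES:
            length = _LENGTH_FIXES[name]
        plan.append(
            PlanEntry(
                name=name,
                role=row["role"],
                strand=row["strand"],
                length=length,
                spacer_after=max(0, int(row["HB_ig"])),
                start_codon=row["HB_start"] or None,
                stop_codon=row["HB_stop"] or None,
            )
        )
    return plan


def default_sub_rates() -> dict[str, float]:
    """Per-element substitution probability per site per unit branch length."""
    rates = {"D-loop": 0.036}
    for g in ("NAD3", "NAD4L", "NAD6", "ATP8"):
        rates[g] = 0.016
    for g in ("NAD1", "NAD2", "NAD4", "NAD5", "COX1", "COX2", "COX3", "ATP6", "Cytb"):
        rates[g] = 0.011
    return rates  # everything else (tRNA/rRNA/spacers) falls back to 0.008


@dataclass
class SimConfig:
    seed: int = 0
    gene_plan: list[PlanEntry] = field(default_factory=default_gene_plan)
    per_element_sub_rate: dict[str, float] = field(default_factory=default_sub_rates)
    default_sub_rate: float = 0.008
    ti_tv_ratio: float = 4.0  # transition:transversion odds
    indel_rate: float = 1e-4
    vntr_plan: list[VNTRArray] = field(default_factory=default_vntr_plan)
    branches: dict[str, float] = field(default_factory=lambda: dict(BRANCHES))
    strain_names: tuple[str, ...] = STRAIN_NAMES
    ol_stem_break: bool = True
    ol_break_strain: str = "S4"
    dloop_flank5: int = 600
    dloop_flank3: int = 332

    def rate_for(self, element: str) -> float:
        return self.per_element_sub_rate.get(element, self.default_sub_rate)


@dataclass
class TruthTables:
    """Planted truth for every downstream stage."""

    substitutions: dict[str, dict[str, list[tuple[int, str, str]]]]
    indels: dict[str, dict[str, list[tuple[int, str, str]]]]
    vntr: dict[str, list[tuple[str, int]]]  # strain -> [(unit, copies), ...]
    tree_newick: str
    branches: dict[str, float]
    ol_motifs: tuple[int, int]  # 1-based positions of the 5' and 3' motifs
    ol_stem_bp: int
    ol_break: tuple[str, int] | None  # (strain, 1-based OL position)

    def n_substitutions(self, strain: str) -> int:
        return sum(len(v) for v in self.substitutions[strain].values())


# ---------------------------------------------------------------------------
# Ancestor
# ---------------------------------------------------------------------------

@dataclass
class _Part:
    """Internal building block: an element or spacer in genome order.

    ``seq`` is stored in coding orientation; assembly reverse-complements
    L-strand parts.  The D-loop part keeps its VNTR structure.
    """

    name: str
    role: str  # element role, or "spacer"
    strand: str
    seq: str
    start_codon: str | None = None
    stop_codon: str | None = None
    dloop: dict | None = None  # {"flank5", "arrays":[(unit, spacer_seq)], "flank3"}


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    bases = np.array(list(BASE_PROBS))
    probs = np.array(list(BASE_PROBS.values()))
    return "".join(rng.choice(bases, size=n, p=probs)) if n else ""


_SENSE = [c for c in VERTEBRATE_MITO.codon_to_aa]


def _rand_orf(rng: np.random.Generator, entry: PlanEntry) -> str:
    """Random valid ORF: planned start, base-composition-weighted sense codons,
    planned (possibly incomplete) stop."""
    stop = entry.stop_codon or "TAA"
    tail = stop if len(stop) == 3 else stop  # incomplete tokens kept verbatim
    n_body = (entry.length - 3 - len(tail)) // 3
    if (entry.length - 3 - len(tail)) % 3 != 0:
        raise ValueError(
            f"{entry.name}: length {entry.length} incompatible with stop {stop!r}"
        )
    bases = np.array(list(BASE_PROBS))
    probs = np.array(list(BASE_PROBS.values()))
    codons = []
    while len(codons) < n_body:
        chunk = rng.choice(bases, size=(n_body, 3), p=probs)
        for row in chunk:
            codon = "".join(row)
            if not VERTEBRATE_MITO.is_stop(codon):
                codons.append(codon)
            if len(codons) == n_body:
                break
    return (entry.start_codon or "ATG") + "".join(codons) + tail


def _cap(seq: str) -> str:
    """Flank a spacer with GC-rich caps that break AT-rich repeat patterns,
    so array boundaries are well defined for the detector."""
    if len(seq) < 8:
        return seq
    return "GCG" + seq[3:-3] + "CGC"


def _build_dloop(rng: np.random.Generator, cfg: SimConfig) -> _Part:
    arrays = []
    for arr in cfg.vntr_plan:
        unit = arr.unit or "".join(
            rng.choice(np.array(list("ACGT")), size=arr.unit_len)
        )
        spacer = _cap(_rand_seq(rng, arr.spacer_after))
        arrays.append((unit, arr, spacer))
    dloop = {
        "flank5": _cap(_rand_seq(rng, cfg.dloop_flank5)),
        "arrays": arrays,
        "flank3": _cap(_rand_seq(rng, cfg.dloop_flank3)),
    }
    seq = _assemble_dloop(dloop, STRAIN_NAMES[0], ancestor=True)
    return _Part("D-loop", "control_region", "H", seq, dloop=dloop)


def _assemble_dloop(dloop: dict, strain: str, ancestor: bool = False) -> str:
    parts = [dloop["flank5"]]
    for unit, arr, spacer in dloop["arrays"]:
        copies = arr.ancestor_copies if ancestor else arr.copies_for(strain)
        parts.append(unit * copies)
        parts.append(spacer)
    parts.append(dloop["flank3"])
    return "".join(parts)


def simulate_ancestor(cfg: SimConfig) -> tuple[Mitogenome, list[_Part]]:
    """Build the ancestral circular genome following the gene plan."""
    ss = np.random.SeedSequence(cfg.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(len(cfg.gene_plan) + 1)]
    parts: list[_Part] = []
    for entry, rng in zip(cfg.gene_plan, rngs):
        if entry.role == "PCG":
            seq = _rand_orf(rng, entry)
        elif entry.role == "tRNA":
            seq, _ = build_template_trna(
                entry.length,
                ANTICODONS[entry.name],
                _PyRng(rng),
                with_dhu=(entry.name != "tRNA-Ser(AGY)"),
            )
        elif entry.role == "rRNA":
            seq = _rand_seq(rng, entry.length)
        elif entry.role == "OL":
            seq = OL_SEQ
        else:  # control region
            parts.append(_build_dloop(rng, cfg))
            if entry.spacer_after:
                parts.append(_Part("", "spacer", "H", _rand_seq(rng, entry.spacer_after)))
            continue
        parts.append(
            _Part(entry.name, entry.role, entry.strand, seq,
                  entry.start_codon, entry.stop_codon)
        )
        if entry.spacer_after:
            parts.append(_Part("", "spacer", "H", _rand_seq(rng, entry.spacer_after)))
    genome = _assemble("ancestor", parts)
    return genome, parts


class _PyRng:
    """random.Random-style facade over a numpy Generator (choice on lists)."""

    def __init__(self, rng: np.random.Generator):
        self._rng = rng

    def choice(self, seq):
        return seq[int(self._rng.integers(0, len(seq)))]


def _assemble(strain_id: str, parts: list[_Part]) -> Mitogenome:
    chunks, elements = [], []
    pos = 1
    for part in parts:
        genome_seq = revcomp(part.seq) if part.strand == "L" else part.seq
        if part.role != "spacer":
            elements.append(
                ElementAnnotation(
                    name=part.name,
                    role=part.role,
                    start=pos,
                    end=pos + len(genome_seq) - 1,
                    strand=part.strand,
                    start_codon=part.start_codon,
                    stop_codon=part.stop_codon,
                )
            )
        chunks.append(genome_seq)
        pos += len(genome_seq)
    g = Mitogenome(strain_id=strain_id, sequence="".join(chunks), elements=elements)
    g.validate()
    return g


# ---------------------------------------------------------------------------
# Evolution along the tree
# ---------------------------------------------------------------------------

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G"),
}


def _mutate_seq(
    seq: str,
    p_sub: float,
    p_indel: float,
    rng: np.random.Generator,
    cfg: SimConfig,
    protect_head: int = 0,
    protect_tail: int = 0,
    is_pcg: bool = False,
) -> tuple[str, list, list]:
    """One branch of evolution on one (coding-orientation) sequence.

    Returns (new sequence, substitution events, indel events); events carry
    1-based positions in the *input* sequence.  For PCGs, proposals creating
    an in-frame stop codon are rejected (skipped).
    """
    chars = list(seq)
    subs, indels = [], []
    n = len(chars)
    p_ts = cfg.ti_tv_ratio / (cfg.ti_tv_ratio + 1)
    if p_sub > 0:
        hits = np.flatnonzero(rng.random(n) < p_sub)
        for i in hits:
            if i < protect_head or i >= n - protect_tail:
                continue
            old = chars[i]
            if old not in _TRANSITION:
                continue
            if rng.random() < p_ts:
                new = _TRANSITION[old]
            else:
                new = _TRANSVERSIONS[old][int(rng.integers(0, 2))]
            if is_pcg:
                c0 = (i // 3) * 3
                codon = chars[c0 : c0 + 3]
                if len(codon) == 3:
                    codon[i - c0] = new
                    if VERTEBRATE_MITO.is_stop("".join(codon)):
                        continue
            chars[i] = new
            subs.append((int(i) + 1, old, new))
    out = "".join(chars)
    if p_indel > 0 and not is_pcg:
        hits = np.flatnonzero(rng.random(len(out)) < p_indel)
        for i in reversed(hits):
            if i < protect_head or i >= len(out) - protect_tail:
                continue
            if rng.random() < 0.5 and len(out) > 1:
                indels.append((int(i) + 1, "-", out[i]))
                out = out[:i] + out[i + 1 :]
            else:
                base = "ACGT"[int(rng.integers(0, 4))]
                indels.append((int(i) + 1, "+", base))
                out = out[:i] + base + out[i:]
    return out, subs, indels


def _evolve_part(
    part: _Part, cfg: SimConfig, rng_by_branch: dict[str, np.random.Generator]
) -> dict[str, str]:
    """Evolve one part along the tree; returns per-strain coding sequences."""
    if part.role == "OL":
        out = {s: part.seq for s in cfg.strain_names}
        if cfg.ol_stem_break:
            s = cfg.ol_break_strain
            seq = out[s]
            out[s] = seq[: OL_BREAK_POS - 1] + "T" + seq[OL_BREAK_POS:]
        return out

    rate = cfg.rate_for(part.name if part.role != "spacer" else "spacer")
    indel = cfg.indel_rate if part.role in ("tRNA", "rRNA", "spacer") else 0.0
    is_pcg = part.role == "PCG"
    head = 3 if is_pcg else 0
    tail = 0
    if is_pcg and part.stop_codon:
        tail = len(part.stop_codon)

    if part.role == "control_region":
        return _evolve_dloop(part, cfg, rng_by_branch)

    def step(seq: str, branch: str) -> str:
        b = cfg.branches[branch]
        new, _, _ = _mutate_seq(
            seq, rate * b, indel * b, rng_by_branch[branch], cfg,
            protect_head=head, protect_tail=tail, is_pcg=is_pcg,
        )
        return new

    ab = step(part.seq, "AB")
    return {
        "S1": step(ab, "S1"),
        "S2": step(ab, "S2"),
        "S3": step(part.seq, "S3"),
        "S4": step(part.seq, "S4"),
    }


def _evolve_dloop(
    part: _Part, cfg: SimConfig, rng_by_branch: dict[str, np.random.Generator]
) -> dict[str, str]:
    """Control region: flanks/spacers mutate, arrays change only in copy number."""
    dl = part.dloop
    rate = cfg.rate_for("D-loop")

    def step(pieces: list[str], branch: str) -> list[str]:
        b = cfg.branches[branch]
        out = []
        for piece in pieces:
            new, _, _ = _mutate_seq(
                piece, rate * b, cfg.indel_rate * b, rng_by_branch[branch], cfg
            )
            out.append(new)
        return out

    pieces0 = [dl["flank5"]] + [sp for _, _, sp in dl["arrays"]] + [dl["flank3"]]
    ab = step(pieces0, "AB")
    per_strain_pieces = {
        "S1": step(ab, "S1"),
        "S2": step(ab, "S2"),
        "S3": step(pieces0, "S3"),
        "S4": step(pieces0, "S4"),
    }
    # Arrays are expanded to the strain's copy number and then mutated along
    # the strain's whole root path (repeat arrays evolve mostly by slippage,
    # so their point mutations are modelled as strain-independent).
    root_path = {
        "S1": cfg.branches["AB"] + cfg.branches["S1"],
        "S2": cfg.branches["AB"] + cfg.branches["S2"],
        "S3": cfg.branches["S3"],
        "S4": cfg.branches["S4"],
    }
    out = {}
    for strain, pieces in per_strain_pieces.items():
        chunks = [pieces[0]]
        for k, (unit, arr, _) in enumerate(dl["arrays"]):
            expanded = unit * arr.copies_for(strain)
            mutated, _, _ = _mutate_seq(
                expanded, rate * root_path[strain], 0.0, rng_by_branch[strain], cfg
            )
            chunks.append(mutated)
            chunks.append(pieces[1 + k])
        chunks.append(pieces[-1])
        out[strain] = "".join(chunks)
    return out


def simulate_strains(cfg: SimConfig) -> tuple[list[Mitogenome], TruthTables, Mitogenome]:
    """Generate the four strains plus truth tables (and the ancestor)."""
    ancestor, parts = simulate_ancestor(cfg)
    ss = np.random.SeedSequence((cfg.seed, 1))
    branch_seeds = ss.spawn(len(parts))
    subs = {s: {} for s in cfg.strain_names}
    indels = {s: {} for s in cfg.strain_names}
    per_strain_parts: dict[str, list[_Part]] = {s: [] for s in cfg.strain_names}

    for part, seed in zip(parts, branch_seeds):
        branch_rngs = {
            b: np.random.default_rng(c)
            for b, c in zip(sorted(cfg.branches), seed.spawn(len(cfg.branches)))
        }
        evolved = _evolve_part(part, cfg, branch_rngs)
        for strain in cfg.strain_names:
            new_seq = evolved[strain]
            per_strain_parts[strain].append(replace(part, seq=new_seq))
            if part.role == "spacer":
                continue
            if len(new_seq) == len(part.seq):
                diff = [
                    (i + 1, a, b)
                    for i, (a, b) in enumerate(zip(part.seq, new_seq))
                    if a != b
                ]
                if diff:
                    subs[strain][part.name] = diff
            else:
                indels[strain].setdefault(part.name, []).append(
                    (0, "~", f"len {len(part.seq)}->{len(new_seq)}")
                )

    genomes = [
        _assemble(strain, per_strain_parts[strain]) for strain in cfg.strain_names
    ]
    vntr_truth = {
        s: [
            (unit, arr.copies_for(s))
            for unit, arr, _ in next(
                p for p in parts if p.role == "control_region"
            ).dloop["arrays"]
        ]
        for s in cfg.strain_names
    }
    b = cfg.branches
    tree = (
        f"((S1:{b['S1']},S2:{b['S2']}):{b['AB']},S3:{b['S3']},S4:{b['S4']});"
    )
    truths = TruthTables(
        substitutions=subs,
        indels=indels,
        vntr=vntr_truth,
        tree_newick=tree,
        branches=dict(b),
        ol_motifs=(1, 30),
        ol_stem_bp=11,
        ol_break=(cfg.ol_break_strain, OL_BREAK_POS) if cfg.ol_stem_break else None,
    )
    return genomes, truths, ancestor
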