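"""Report assembly: runs every analysis stage and writes the output bundle.

Outputs (all TSV except the tree) mirror the published tables: gene audit
with intergenic spacers, composition/skew, site classification, RSCU,
per-gene diversity and selection, distances, sliding windows, control-region
repeats, OL hairpin and tRNA variant reports, plus a Newick tree.  Numbers
are printed at the published precision together with full-precision
companion columns.  A failing stage is logged and skipped; the run is then
reported as partial (nonzero exit from the CLI).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .align import ElementAlignment, read_alignment_fasta, star_msa
from .codon_usage import count_codons, rscu, rscu_summary
from .composition import composition_dataframe, element_composition_table
from .diversity import (
    diversity_dataframe,
    gene_distance_table,
    gene_kaks,
    nucleotide_diversity,
    sliding_window_pi,
)
from .genome import Mitogenome, audit_codons, extract_element, intergenic_lengths
from .phylogeny import (
    bootstrap_support,
    concat_distance_matrix,
    distance_matrix_tsv,
    write_newick,
)
from .repeats import cr_report, find_hairpin, find_ol_motifs
from .trna import compare_trnas, fold_cloverleaf, trna_variant_dataframe
from .variation import variation_dataframe, variation_table

log = logging.getLogger(__name__)

PCG_ORDER = (
    "NAD1", "NAD2", "COX1", "COX2", "ATP8", "ATP6", "COX3",
    "NAD3", "NAD4L", "NAD4", "NAD5", "NAD6", "Cytb",
)


@dataclass
class RunConfig:
    out_dir: Path
    seed: int = 0
    window: int = 500
    step: int = 10
    bootstrap_reps: int = 1000
    band: int | None = None
    alignments_dir: Path | None = None  # imported alignments bypass star MSA
    repeat_params: dict = field(default_factory=dict)
    kaks_trim_stop: bool = True


@dataclass
class RunResult:
    outputs: dict[str, Path]
    failed_stages: list[str]

    @property
    def ok(self) -> bool:
        return not self.failed_stages


def build_alignments(
    genomes: list[Mitogenome],
    band: int | None = None,
    alignments_dir: Path | None = None,
) -> list[ElementAlignment]:
    """Per-element alignments across strains, in genome order.

    When ``alignments_dir`` holds ``<element>.fasta`` files those are
    imported verbatim (so published alignments can be reproduced); all other
    elements are star-aligned.
    """
    alns = []
    for el in genomes[0].elements:
        name = el.name
        if alignments_dir is not None:
            path = Path(alignments_dir) / f"{name}.fasta"
            if path.exists():
                alns.append(read_alignment_fasta(path, element=name))
                continue
        seqs = {}
        for g in genomes:
            if any(e.name == name for e in g.elements):
                seqs[g.strain_id] = extract_element(g, name)
            else:
                log.warning("element %s missing in strain %s", name, g.strain_id)
        if len(seqs) >= 2:
            alns.append(star_msa(seqs, element=name, band=band))
    return alns


def run_pipeline(genomes: list[Mitogenome], cfg: RunConfig) -> RunResult:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    failed: list[str] = []

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("mitocomp")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    log.info("mitocomp %s | seed=%d window=%d step=%d bootstrap=%d band=%s",
             __version__, cfg.seed, cfg.window, cfg.step, cfg.bootstrap_reps, cfg.band)
    log.info("strains: %s", ", ".join(g.strain_id for g in genomes))

    def stage(name: str, fn):
        try:
            path = fn()
            if path is not None:
                outputs[name] = path
            log.info("stage %s: ok", name)
        except Exception:
            log.exception("stage %s failed; skipped", name)
            failed.append(name)

    # --- annotation-level tables ------------------------------------------
    def gene_audit():
        rows = []
        for g in genomes:
            spacers = dict(intergenic_lengths(g))
            audits = {a.gene: a for a in audit_codons(g)}
            for el in g.elements:
                a = audits.get(el.name)
                rows.append(
                    {
                        "strain": g.strain_id,
                        "element": el.name,
                        "length": el.length(g.length_bp),
                        "intergenic": spacers[el.name],
                        "start_codon": a.start_codon if a else "",
                        "stop_codon": a.stop_codon if a else "",
                        "complete_stop": a.complete if a else "",
                        "internal_stop": a.internal_stop if a else "",
                    }
                )
        path = out / "table2.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        return path

    stage("gene_audit", gene_audit)

    def composition():
        rows = element_composition_table(genomes)
        path = out / "table3.tsv"
        composition_dataframe(rows).to_csv(path, sep="\t", index=False)
        return path

    stage("composition", composition)

    # --- alignments and everything that consumes them ---------------------
    alns: list[ElementAlignment] = []

    def alignments():
        alns.extend(build_alignments(genomes, cfg.band, cfg.alignments_dir))
        return None

    stage("alignments", alignments)
    by_name = {a.element: a for a in alns}
    pcg_alns = [by_name[n] for n in PCG_ORDER if n in by_name]
    rrna_alns = [a for a in alns if a.element.endswith("rRNA")]

    def variation():
        rows = variation_table(alns)
        path = out / "table4.tsv"
        variation_dataframe(rows).to_csv(path, sep="\t", index=False)
        return path

    stage("variation", variation)

    def rscu_table():
        tables = []
        for g in genomes:
            seqs = [extract_element(g, n) for n in PCG_ORDER
                    if any(e.name == n for e in g.elements)]
            tables.append(rscu(count_codons(seqs), strain_id=g.strain_id))
        df = pd.concat([t.as_dataframe() for t in tables])
        summary = rscu_summary(tables)
        log.info("codons with RSCU>1: %s pooled=%d", summary["per_strain"], summary["pooled"])
        path = out / "rscu.tsv"
        df.to_csv(path, sep="\t", index=False)
        return path

    stage("rscu", rscu_table)

    def diversity():
        pis = [nucleotide_diversity(a) for a in pcg_alns + rrna_alns]
        kaks = [gene_kaks(a, trim_stop=cfg.kaks_trim_stop) for a in pcg_alns]
        dists = gene_distance_table(pcg_alns)
        df = diversity_dataframe(pis, kaks, dists)
        df.to_csv(out / "diversity.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {"gene": k.gene, "ka": k.ka_mean, "ks": k.ks_mean,
                 "kaks": round(k.ratio_mean, 3), "kaks_ratio_of_means": round(k.ratio_of_means, 3),
                 "pairs_defined": k.n_defined}
                for k in kaks
            ]
        ).to_csv(out / "kaks.tsv", sep="\t", index=False)
        outputs["kaks"] = out / "kaks.tsv"
        dm = concat_distance_matrix(
            [a for a in alns if a.element not in ("D-loop", "OL")]
        )
        distance_matrix_tsv(dm, out / "distances.tsv")
        outputs["distances"] = out / "distances.tsv"
        return out / "diversity.tsv"

    stage("diversity", diversity)

    def windows():
        rows = []
        for a in pcg_alns + rrna_alns:
            prof = sliding_window_pi(a, window=cfg.window, step=cfg.step)
            for mid, pi in zip(prof.midpoints, prof.pi_values):
                rows.append({"element": a.element, "midpoint": mid,
                             "pi": round(pi, 3), "pi_full": pi})
        path = out / "windows.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        return path

    stage("windows", windows)

    # --- control region and OL --------------------------------------------
    def repeats_stage():
        crs = {g.strain_id: extract_element(g, "D-loop") for g in genomes
               if any(e.name == "D-loop" for e in g.elements)}
        reports = cr_report(crs, **cfg.repeat_params)
        rows = []
        for r in reports:
            for k, rep in enumerate(r.repeats, 1):
                rows.append(
                    {"strain": r.strain_id, "cr_length": r.length,
                     "cr_pct_AT": round(r.pct_AT, 2), "index": k,
                     "start": rep.start, "end": rep.end, "unit": rep.unit,
                     "unit_len": rep.unit_len, "copies": int(rep.copies),
                     "copies_full": rep.copies,
                     "identity": round(rep.identity, 3)}
                )
        path = out / "cr_repeats.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        return path

    stage("cr_repeats", repeats_stage)

    def hairpin_stage():
        rows = []
        for g in genomes:
            if not any(e.name == "OL" for e in g.elements):
                continue
            seq = extract_element(g, "OL")
            h = find_hairpin(seq)
            motifs = find_ol_motifs(seq)
            rows.append(
                {"strain": g.strain_id,
                 "stem_bp": h.stem_bp if h else 0,
                 "loop_len": h.loop_len if h else 0,
                 "span_start": h.start if h else 0,
                 "span_end": h.end if h else 0,
                 "motifs_found": motifs.both_found}
            )
        path = out / "ol_hairpin.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        return path

    stage("ol_hairpin", hairpin_stage)

    def trna_stage():
        trna_alns = {a.element: a for a in alns if a.element.startswith("tRNA")}
        folds = {}
        for name, aln in trna_alns.items():
            ref_seq = aln.ungapped(0)
            folds[name] = fold_cloverleaf(ref_seq, trna_id=name)
        reports = compare_trnas(trna_alns, folds)
        path = out / "trna_variants.tsv"
        trna_variant_dataframe(reports).to_csv(path, sep="\t", index=False)
        return path

    stage("trna_variants", trna_stage)

    def tree_stage():
        tree = bootstrap_support(
            [a for a in alns if a.element not in ("D-loop", "OL")],
            n_reps=cfg.bootstrap_reps,
            seed=cfg.seed,
        )
        path = out / "tree.nwk"
        write_newick(tree, path)
        return path

    stage("tree", tree_stage)

    if failed:
        log.error("run finished with failed stages: %s", ", ".join(failed))
    else:
        log.info("run finished: all stages ok")
    root.removeHandler(handler)
    handler.close()
    outputs["run_log"] = out / "run.log"
    return RunResult(outputs=outputs, failed_stages=failed)
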