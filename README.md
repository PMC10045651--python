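# mitocomp

Comparative mitogenomics of closely related vertebrate strains, built around
the four-strain analysis of the Chinese soft-shelled turtle
(*Pelodiscus sinensis*): given annotated circular mitochondrial genomes
(13 protein-coding genes, 22 tRNAs, 2 rRNAs, the control region and the
light-strand replication origin OL), the package computes every standard
descriptive and evolutionary statistic of such a comparison, fully offline,
and ships a seeded synthetic-strain generator so the whole pipeline can be
validated against planted truth.

## What it computes

* **Composition and strand skew** per element and genome:
  AT skew = (A − T)/(A + T), GC skew = (G − C)/(G + C).
* **Codon usage**: codon counts over the concatenated protein-coding genes
  and RSCU (relative synonymous codon usage,
  RSCU_i = n_i / (n̄ of the synonymous family)) under the vertebrate
  mitochondrial code (AGA/AGG stops, ATA = Met, TGA = Trp, incomplete T/TA
  stop tokens).
* **Site classification** of per-element multiple alignments: invariable,
  singleton and parsimony-informative columns with complete deletion of
  gap/N columns.
* **Diversity and selection**: nucleotide diversity π (overall and in
  500 bp/10 bp sliding windows), Kimura 2-parameter distances
  d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q), and Nei–Gojobori (1986) Ka/Ks with
  exhaustive substitution-pathway averaging and Jukes–Cantor correction.
* **Control-region structure**: deterministic tandem-repeat detection
  (unit 2–50 bp, consensus refinement, primitive-unit reduction), the
  conserved 5′-AAAAT / AACCA-3′ OL motifs, and exhaustive stem-loop search.
* **tRNA cloverleaf comparison**: template-constrained folding (acceptor,
  DHU, anticodon and TψC arms) and mapping of cross-strain variants onto
  those regions.
* **Distance phylogeny**: K2P on concatenated elements, Saitou–Nei
  neighbor-joining with deterministic tie-breaking, column-resampling
  bootstrap, Newick output.

The published per-strain gene table (element lengths, intergenic overlaps,
start/stop codons), composition table and variation table for the four
*P. sinensis* strains (HB, JB, RB, WB) are packaged as reference data; the
cumulative coordinate walk over the gene table closes the circle at exactly
the published genome lengths (17,116 / 17,182 / 17,235 / 17,219 bp).

## Worked example

Simulate four strains at the default study conditions and run the full
report pipeline:

```bash
mitocomp simulate --seed 7 --out sim/
mitocomp all --fasta sim/strains.fasta \
    -a sim/S1.annotations.tsv -a sim/S2.annotations.tsv \
    -a sim/S3.annotations.tsv -a sim/S4.annotations.tsv \
    --out report/ --bootstrap-reps 1000
```

The simulate step prints

```
wrote 4 strains to sim (431 planted substitutions; seed 7)
```

and the report directory then holds twelve tables plus `tree.nwk` and
`run.log`.  `ol_hairpin.tsv` from that run reads

```
strain  stem_bp  loop_len  span_start  span_end  motifs_found
S1      11       4         6           31        True
S2      11       4         6           31        True
S3      11       4         6           31        True
S4      7        4         10          27        True
```

i.e. the planted 11 bp OL stem-loop is recovered in three strains while the
planted stem-breaking A→T substitution in strain S4 shortens its stem — the
same signature the real RB strain shows.  The tree file contains
`((S1,S2),S3,S4)`-compatible topology with 100% bootstrap support for the
S1+S2 pair, matching the planted phylogeny, and `table4.tsv` reports the
complete-genome percentage of variable sites (≈2.5% at default rates).

The same `all` command runs on real data: a multi-FASTA of strains plus one
annotation table per record (TSV with name/role/start/end/strand or a
GenBank feature table).  Imported per-element alignments
(`--alignments-dir`) bypass the built-in star aligner so published
alignments can be reproduced verbatim.

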