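# Methods

This note documents the models, algorithms, numerical conventions and
design decisions behind mitocomp, and what the synthetic-data validation
does and does not establish.

## Genome model and coordinates

A mitogenome is a circular heavy-strand sequence with ordered element
annotations.  Externally all coordinates are 1-based inclusive (GenBank
convention) so published feature tables round-trip losslessly; slicing
arithmetic is 0-based half-open internally.  `strand='L'` means the element
is reverse-complemented on extraction; in the canonical vertebrate
arrangement this applies to NAD6 and eight tRNAs (Gln, Ala, Asn, Cys, Tyr,
Ser(UCN), Glu, Pro).  A wrap-around element (start > end) is allowed only as
the last element.  The circular origin is normalised to the tRNA-Phe start.
N bases are carried through but excluded from every count; gap/N handling
downstream is complete-deletion for site classification and pairwise
deletion for distances and π.

The packaged reference gene table stores the published per-strain element
lengths, intergenic spacers (negative = overlap with the next element) and
PCG start/stop codons for the four *P. sinensis* strains.  Walking it
cumulatively from tRNA-Phe reproduces the four published genome lengths
exactly, which is why coordinate-level analyses need no sequence download.
Two published inconsistencies are stored, flagged and deliberately not
reconciled: the control-region section lengths differ by exactly 1 bp from
the gene-table D-loop lengths, and several printed PCG lengths are not
congruent mod 3 with their printed stop codon (e.g. NAD1 971/TAG).

## Vertebrate mitochondrial code and codon statistics

AGA and AGG are stops, ATA is Met, TGA is Trp; incomplete stops (T, TA) are
completed to TAA by polyadenylation in vivo, but here the trailing 1–2 nt
are simply dropped from codon-level computations so codon counts stay
integral.  RSCU families are the sense codons per amino acid (Leu and Ser
6-fold, Arg 4-fold after removing AGA/AGG); stop codons are tallied
separately.  Within a family with nonzero total the RSCU values average to
1 exactly; empty families are reported as 0 with an explicit flag.

## Alignment

Pairwise alignment is a Gotoh three-state global DP with affine gaps
(match 1, mismatch −1, open −4, extend −1 by default; a gap of length L
costs open + (L−1)·extend).  Ties are broken diagonal-first, then the
vertical state, so alignments are identical across platforms.  An optional
band restricts |i − j| ≤ band (error if the band cannot connect the
corners); a band of 200 is applied automatically above 2 kb.  The multiple
alignment is a star alignment around the sequence with the greatest summed
pairwise score, merged under "once a gap, always a gap" — adequate for
four conspecific sequences at ≤ a few percent divergence, and exactly
invertible (ungapping any row reproduces its input).  Alignment is always
per element, never whole-genome: elements are orthologous by annotation and
the control-region repeat arrays would otherwise dominate alignment
ambiguity.  Imported aligned FASTA files bypass the aligner.

## Variation, diversity, distances, selection

Site classification excludes any column containing a gap or N from the
totals (complete deletion), matching the convention that makes the
published complete-genome site total smaller than every genome length.
A column is parsimony-informative when ≥2 states each occur in ≥2
sequences; with four sequences this forces a 2+2 pattern over exactly two
bases, a property the tests assert exhaustively.

π is the mean over sequence pairs of (differences / comparable sites).
Sliding windows (default 500 bp every 10 bp, per the study convention) are
computed on alignment columns per element; windows never span element
boundaries.  K2P uses transition = A↔G / C↔T and raises a saturation error
outside the model domain rather than returning NaN.

Ka/Ks follows Nei–Gojobori (1986) under the mitochondrial code: per-codon
synonymous-site fractions count a mutation to a stop codon as
nonsynonymous, making S + N = 3 per codon exactly; multi-difference codon
pairs are averaged over all minimal substitution pathways with
stop-crossing pathways excluded (all pathways are used in the degenerate
case where every pathway is blocked); proportions are Jukes–Cantor
corrected.  Codon pairs containing gaps or N, and observed stop codons, are
wholly excluded.  The per-gene value is the mean of the defined pairwise
ratios (pairs with Ks = 0 excluded, reported as 0.000 when none are
defined); the ratio of mean Ka to mean Ks is kept as an alternative
aggregation because the aggregation used for the published per-gene values
is not stated.

## Control-region repeats and the OL stem-loop

The tandem-repeat detector is deterministic seed–extend–refine, not a
reimplementation of a probabilistic repeat finder, because the claims it
must support reduce to unit length, copy number and span.  For each period
p it seeds at near-periodic windows (≥90% of p matching under a shift of
p — tolerant seeding matters for long mutated units), extends by a running
score (+1 match, −4 mismatch) keeping the score-maximum boundary, then
refines the span against the majority-vote consensus unit (Kadane maximal
subsegment, which trims quasi-matching flank junk), reduces the unit to a
divisor period when that explains the span as well (exactly, or within the
array's own mismatch level — this collapses degenerate long-period
re-descriptions of microsatellites), and canonicalises rotation to the
lexicographically smallest (the original phase is kept alongside).
Overlapping candidates are resolved by identity compared at 0.1 resolution,
then span, then smaller unit; the coarse identity comparison prevents tiny
perfect fragments of a long, slightly mutated array from shattering it.
Fractional copy numbers are floored in reports and kept exact internally.

The hairpin search is an exhaustive inverted-repeat scan over all
(loop position, loop length 3–30) placements, growing the stem outward and
maximising contiguous paired length (Watson–Crick 2, G–T 1 when allowed);
ties prefer the smaller loop, then the 5′-most placement.  It is validated
against a brute-force enumerator on short windows.  Note that stem length
is reverse-complement invariant only under pure Watson–Crick pairing: the
G·T wobble maps to A·C under complementation.

## tRNA cloverleaf comparison

Folding is template-constrained, not thermodynamic, because the question is
which region a variant falls in.  The template is acceptor 7 bp, DHU stem
0/3/4 bp with a 4–12 nt loop, anticodon stem 5 bp with a 7 nt loop,
variable loop 3–23 nt, TψC stem 4–5 bp with a 4–9 nt loop; all layouts
consistent with the sequence length are scored (WC 2, G–T 1) and the best
is kept.  DHU is declared missing below 2 paired positions — the natural
state of mitochondrial tRNA-Ser(AGY).  Fold failure (acceptor < 5 pairs) is
a result, not an exception.  Variants are classified substitution vs indel
from the alignment and assigned to the region of the first strain's fold
(reference), mapped through alignment columns.

## Phylogeny

NJ is Saitou–Nei with the Studier–Keppler criterion and label-order
tie-breaking; it recovers additive matrices exactly (tested on random
4–8-taxon trees and cross-checked against an independent NJ
implementation).  Negative branch estimates are clamped to zero and
logged.  Bootstrap support is column resampling with replacement on the
concatenated element alignment (D-loop and OL excluded by default);
support = % of replicate trees containing the same leaf bipartition.
Bayesian and maximum-likelihood inference are out of scope; the NJ tree is
a deterministic distance-based surrogate.

## Synthetic-strain generator

The generator is first-class, tested code that defines the study
conditions.  An ancestor with the published element order and lengths is
built from AT-biased base frequencies (~63% A+T): protein genes are random
sense-codon ORFs with the published start/stop plan, tRNAs are built from
the cloverleaf template with perfect stems (and verified to re-fold to
their planted layout), the OL is a designed 34-mer carrying 5′-AAAAT, an
11 bp perfectly paired stem around a 4 nt loop, and AACCA-3′, and the
control region carries four tandem arrays echoing the published
architecture (a 50 bp unit, a 6 bp unit at ~47–57 copies, a TA
microsatellite, a 9 bp unit) between GC-capped spacers (the caps keep array
boundaries well defined for the detector).

Two published-table reconciliations are built into the default plan: PCG
lengths not congruent with their printed stop codon are adjusted to the
nearest consistent length (972, 1041, 684, 354/349), and negative
intergenic spacers are clamped to zero because overlapping reading frames
are not simulated (overlap semantics are exercised on the packaged
coordinate fixture instead).

Strains evolve independently along the fixed tree ((S1,S2),S3,S4) with
branch lengths 0.35/0.35 external, 0.30 internal, 0.45/0.55 to S3/S4
(total 2.0).  Substitutions are per-site Bernoulli with per-element rates
(control region 0.036; NAD3/NAD4L/NAD6/ATP8 0.016; other PCGs 0.011;
tRNA/rRNA and spacers 0.008 per unit branch), transition:transversion odds
4; with total tree length 2 the expected 4-strain variable-site fraction of
an element is ≈2× its rate, which places the simulated variation
percentages near the published comparison (control region ~7%, complete
genome ~2.5–2.8%, tRNA/rRNA ~1.6%).  PCG proposals creating in-frame stops
are rejected; the OL is treated as functionally conserved except for an
optional planted stem-breaking A→T substitution in S4 (mirroring the
published RB-strain observation); repeat arrays change copy number
per strain and accumulate point mutations along the strain's root path
(slippage-dominated arrays are modelled as strain-independent), while
their flanks evolve on the tree; 1-bp indels occur at 1e−4 per site per
unit branch outside PCGs, OL and arrays.  All randomness derives from one
seed through numpy SeedSequence spawning in a fixed order, so outputs are
byte-identical per seed.  Truth tables record per-element substitutions
(exact, via diff, for indel-free elements), indel events, per-strain VNTR
copy numbers, the tree and the OL design.

What passing the synthetic validation shows — and what it does not: the
generator produces clean annotations, equal-rate lineages, no
heteroplasmy, no selection (Ka/Ks ≈ 1 up to the stop-rejection bias), no
recombination and no sequencing error, so recovery results certify the
correctness of the analytical engines under the stated model, not their
robustness to annotation error or real base-composition heterogeneity.
Real-data behaviour is anchored separately by the packaged published
tables, whose derived quantities (skews, percentages, genome-length
closure) the package reproduces exactly.

## Problem sizes and determinism

The default validation sweep uses 20 seeds of full four-strain genomes
(~17.1 kb each) for parameter recovery and desk-scale oracle checks
elsewhere (1,000 random alignments, 200 random codon-sequence pairs, 200
random additive trees, all unit sizes 2–50 for the repeat detector);
`scripts/acceptance.py` uses 8 seeds.  These sizes give stable means
(binomial noise well inside the stated tolerances) while keeping the whole
suite fast.  Every stochastic component takes an explicit seed; reruns are
bitwise identical.
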