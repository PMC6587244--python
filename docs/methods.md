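# Methods

This note records the models `cazymine` implements, the defaults it
ships, and the boundaries of what its tests demonstrate.

## Annotation by coverage-filtered homology

A unigene's candidate CAZy families come from tabular homology hits
(outfmt-6 plus query/subject lengths, subject family and lineage). A
hit is retained iff

- e-value ≤ 1e-5,
- bit score strictly > 60 (a score of exactly 60 is excluded), and
- both coverage ratios BCR_Ref = 100·Align/Ref_length and
  BCR_Que = 100·Align/Que_length are ≥ 40% (exactly 40.0 passes, since
  the exclusion rule is "< 40%").

The asymmetric boundary semantics follow the filtering rules as stated
in the protocol this package re-implements; both are asserted directly
in the test suite. Alignment lengths exceeding a sequence length
(possible with gapped tabular output) are clamped to that length with
a warning, keeping BCR ≤ 100. When the query is nucleotide and the
subject protein (blastx-style), the declared dialect divides the query
length by 3 before BCR_Que so both ratios are in amino-acid units;
which convention a given hit file needs is a property of how it was
produced, so the reader exposes both. Per query and family the best
hit is kept, ranked by bits (desc), then e-value (asc), then subject
id (lex) — a total order, so results are independent of input order.
Filtering is per-record and therefore idempotent. Percentages in
printed tables are rounded half-up to one decimal.

## LCA taxonomy

The taxonomy is an explicit rooted tree (two-column edge list + node
metadata) with ranks superkingdom…species. Hits contribute when bits
> 50 and the alignment spans > 25 nucleotides (protein-unit alignments
are converted at 3 nt/aa); all such hits contribute — no
top-percent-of-best-score window, since the re-implemented protocol
changed only those two thresholds from defaults. A hit lineage
resolves to the deepest tree node whose name appears in it; fully
unresolvable lineages are dropped with a warning. The assignment is
the deepest node ancestral to every contributing lineage; an LCA at
the root is reported as unassigned. A min-support parameter (as in
MEGAN) is deliberately not implemented. Assignments at or below phylum
inherit their phylum ancestor's name; anything shallower is pooled as
"unclassified" in the class × phylum summary.

## Quantification

The pseudo-mapper indexes unigene k-mers (default k = 31) and assigns
a read iff every one of its k-mers occurs in exactly one, and the
same, unigene — a deliberately conservative stand-in for alignment
that is exact on error-free reads and abstains on any ambiguity.
Reads are single-end and count one fragment each. FPKM uses the mapped
library size per sample by default (configurable to total input
fragments). Q20/Q30 are percentages of bases at Phred ≥ 20/≥ 30
(offset 33); the FASTQ reader is strict 4-line and reports the line
number of the first malformed record.

## ORF and domain mining

ORFs are maximal stop-free codon stretches ≥ 600 nt, reported in all
six frames with 0-based half-open forward-strand coordinates; the
600-nt minimum includes neither flanking stop and is inclusive at the
boundary. Stretches truncated by the sequence ends are reported
(getorf-default behaviour); a Met-anchored mode trims each stretch to
its first start codon of the chosen genetic code (standard table 1:
TTG/CTG/ATG; bacterial table 11 additionally GTG, ATT, ATC, ATA).
Tables 1 and 11 share sense-codon translations, so the code choice
matters only for start anchoring; the pipeline picks the bacterial
code for unigenes whose LCA superkingdom is Bacteria or Archaea.
Codons containing N or other non-ACGT letters translate to X with a
warning.

Domain screening retains hits with score ≥ the model's gathering
threshold (inclusive — the cutoff is *set to* the threshold) and
merges overlapping same-model hits into the higher-scoring one. Two
routes exist: parsing real HMMER `--domtblout` output (per-domain
score, 1-based alignment coordinates converted to half-open), or
built-in motif models. The built-in models are synthetic
position-specific consensus motifs (match +2 / mismatch −1, GA =
1.25 × consensus length, i.e. ≈25% mismatch tolerance) constructed for
planted-truth testing; they are not Pfam profiles and carry no claim
of sensitivity on real proteins. CBM families indistinguishable at the
model level arrive pooled under a combined label ("CBM4, CBM9").
Signal-peptide annotation, when present, is a pass-through column from
an external predictor's summary file.

## Candidate selection and primers

Pairwise distances between catalytic-domain proteins are
1 − fractional identity over aligned columns of a global BLOSUM62
alignment (gap open −11, extend −1). Trees are built by standard
neighbor joining; NJ on an identity distance is a documented
substitute for the original maximum-likelihood (JTT) tree, chosen
because the exact tree is unreachable without the original sequences
while the downstream contract — clusters plus an unclustered pool —
only needs a consistent additive-tree method. NJ reproduces additive
matrices exactly (property-tested); occasional negative branch lengths
on noisy input are clamped to 0. Clusters are maximal clades (≥ 2
leaves) whose largest internal leaf-to-leaf path is ≤ the height
threshold; all other leaves are "unclustered", and every leaf lands in
exactly one stratum. The protocol's own counts of "nine clusters"
versus "eight clusters plus a non-clustered segment" are reconciled as
8 + 1 strata. Candidate selection samples `per_cluster` members per
stratum from a single seeded PRNG stream.

Primer cores are the ORF's 5′ terminus and the reverse complement of
its 3′ terminus, lengths 18–28 nt chosen to minimise |Tm_f − Tm_r|
(flagged if the window is unreachable); Tm is the Wallace rule
(2·AT + 4·GC) for cores ≤ 14 nt and 64.9 + 41·(GC − 16.4)/N above —
no Tm method is prescribed by the protocol, so these textbook rules
are used and exposed. The 22-nt pET-28a(+) homology tails are
prepended verbatim and excluded from Tm.

## Assay analytics

Standard curves are OLS lines (≥ 3 distinct concentrations; slope ≤ 0
is an error, not a warning). The activity call is positive iff
mean(sample) > 1.5 × (mean(control) + sd(control)), with sd the n−1
sample standard deviation (duplicates suffice); the underlying rule
sentence admits a second reading, mean + 1.5·sd, which is available
behind `alternative_rule` rather than silently chosen. Specific
activity inverts the curve — µmol = (A − intercept)/slope × volume —
then U = µmol/min and U/mg; reaction time, volume and protein mass are
required inputs with no defaults in the analysis layer, because they
are assay-dependent (the DNS endoglucanase and pNP exoglucanase mixes
differ). Optima are argmax with ties resolved to the lower condition
and flagged; residual activity is 100 × activity/baseline with a
monotone-decay flag.

## The synthetic-data generator

The generator emulates the statistical structure of a rumen
metatranscriptome screen, not any particular dataset:

- **Community**: 8 taxa by default from a rumen-flavoured lineage pool
  (Ruminococcus, Prevotella, Fibrobacter, Methanobrevibacter, …),
  Dirichlet(1) abundances, genes assigned to taxa by abundance.
- **Genes**: ORF lengths 660–1497 nt (uniform over codon counts,
  matching the few-hundred-residue range of validated cellulases);
  log-normal(0, 1.2) relative expression so most transcripts sit at
  low FPKM with a long right tail; default family mix dominated by
  GH3/GH5/GH9; 15% of genes carry no CAZyme family; 25% of CAZyme
  genes also carry a CBM. Each CAZyme gene has its family's consensus
  motif spliced into an otherwise random protein, which is
  back-translated with random synonymous codons and embedded between
  in-frame stops and random flanks on a random strand. The flanking
  stop occupies the innermost 3 nt of each flank, so `flank_len=0`
  yields a unigene that is exactly its ORF. A configurable fraction of
  genes is truncated to 180–594 nt of ORF to exercise the length
  filter.
- **Hits**: 2–4 per CAZyme unigene, alignment 90% of the shorter
  sequence, identity N(88, σ) clipped to [60, 100], bits =
  0.5·align·identity/100 (monotone in alignment length at fixed
  identity), Karlin–Altschul-flavoured e-values. Decoy queries each
  fail exactly one named filter (coverage, bits, or e-value) so filter
  sensitivity is attributable per rule.
- **Counts**: negative binomial with mean ∝ expression rate × length,
  normalised to the library size per sample; dispersion r = 0.3 by
  default (Var = µ + µ²/r), Poisson in the r → ∞ option.
- **Plates**: absorbance = intercept + slope·concentration + N(0, σ),
  standards/blanks/negative controls laid out alongside samples;
  sample concentration follows from the planted U/mg through the
  reaction geometry (default 10 min, 0.5 ml, 0.2 µg protein), so the
  analysis layer's inversion recovers the planted activity exactly at
  zero noise.
- Gaussian-bump condition profiles and exponential decay timecourses
  for the optimum/stability analyses.

What it does **not** emulate: sequencing error profiles and quality
artefacts, rRNA contamination, chimeric assembly, strain-level
lineage ambiguity, paralogy (every unigene carries one planted gene),
shared k-mers between transcripts, non-linear standard curves, and
plate position effects. Passing tests therefore demonstrate the
*correctness of the analysis logic* on data matching its assumptions,
not robustness to real-data pathologies.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale by design: 60–80
gene communities, 1000–2000 reads, 50 random 2-kb sequences for the
ORF-scanner oracle, 60 random toy taxonomies for the LCA oracle, 4–8
taxon additive matrices for NJ, 500–1000 Monte-Carlo repetitions for
the optimum-recovery and false-positive-rate checks. The whole suite
completes in seconds. Exact-recovery assertions use set equality;
floating-point comparisons use relative tolerances of 1e-9 (algebraic
identities), 2% (planted-activity round trips, matching the
generator's stated recovery contract) and 3σ bands (sampling-error
checks with exact moment formulas).

## Known limitations

- The NJ/identity tree is not the original ML/JTT phylogeny; cluster
  boundaries on real GH5 sets may differ.
- The built-in motif models cannot assess real Pfam sensitivity; use
  the domtblout route with real HMMER output for that.
- The pseudo-mapper has no error tolerance and no multi-mapping
  rescue; mapping rates on real reads would be pessimistic.
- LCA support thresholds (min-support) and e-value-window heuristics
  of MEGAN are not implemented.
- Bootstrap support, codon optimisation and Michaelis–Menten kinetics
  are out of scope.
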