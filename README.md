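# cazymine

Cellulase mining from rumen metatranscriptomes, re-implemented as a
tested, reusable Python pipeline.

Ruminants digest plant fibre through their rumen microbiome, which is a
rich and largely uncharted source of carbohydrate-active enzymes
(CAZymes), in particular the glycoside hydrolases (GHs) that hydrolyse
cellulose. A metatranscriptomic screen for such enzymes runs, after
assembly, through a fixed chain of analyses; `cazymine` implements that
chain for people who want to run, audit or stress-test it without the
original multi-gigabase read set:

1. **CAZy family annotation** (`cazy_annotation`) — tabular homology
   hits are screened on e-value ≤ 1e-5, HSP bit score > 60 and the
   BLAST coverage ratio on both sides,

   BCR_Ref = Align_length / Ref_length × 100%,
   BCR_Que = Align_length / Que_length × 100%,

   with hits below 40% coverage on either side excluded; surviving hits
   assign one or more CAZy families per unigene (best hit per family).
2. **LCA taxonomy** (`taxonomy`) — each unigene is placed at the
   deepest taxonomy node ancestral to all of its contributing hit
   lineages (hits with bits > 50 and alignment > 25 nt), MEGAN-style,
   and CAZyme classes are cross-tabulated by phylum.
3. **Quantification** (`quantification`) — an exact-k-mer pseudo-mapper
   assigns reads to unigenes and expression is reported as
   FPKM = fragments / ((length/1000) · (library/10⁶)), plus Q20/Q30/GC
   read-quality summaries.
4. **ORF and domain mining** (`orf_mining`) — six-frame stop-to-stop
   ORF prediction at a 600-nt minimum (standard or bacterial genetic
   code according to the unigene's taxonomic origin), then screening of
   the translations for GH catalytic domains and carbohydrate-binding
   modules (CBMs), retaining hits at or above each model's gathering
   threshold, tabulated as per-family ORF and domain counts.
5. **Candidate selection** (`candidate_selection`) — GH5 catalytic
   domains are compared by global alignment identity, agglomerated by
   neighbor joining, cut into clusters, sampled stratified across
   clusters plus the unclustered pool, and given RT-PCR primer pairs
   with 22-nt pET-28a(+) homology tails and Tm-balanced cores.
6. **Assay analytics** (`assay_analysis`) — linear standard curves,
   the activity call (positive iff mean sample signal >
   1.5 × (control mean + control SD)), specific activity in U/mg
   (1 U = 1 µmol product/min), temperature/pH optima and residual
   activity.

Because the raw data of such studies are rarely re-analysable at desk
scale, the package ships a first-class synthetic-data generator
(`synthetic_data`) that plants cellulase ORFs, hit tables, counts,
reads and assay plates with known ground truth — every downstream stage
is tested by exact recovery of what was planted.

## Worked example

```python
from cazymine import synthetic_data as sd
from cazymine.pipeline import run_pipeline

truth = sd.generate_community(n_taxa=8, n_genes=60, seed=1)
unigenes, table = sd.generate_unigenes(truth, seed=2)
hits = sd.generate_hit_table(truth, table, seed=3)
result = run_pipeline(hits, unigenes, truth.taxonomy_tree())

print(len(unigenes), len(hits), len(result.orfs), len(result.domain_hits))
print(result.domain_table.head(3))
planted = {(r.unigene_id, r.family) for r in table.itertuples()
           if r.family and not r.truncated}
print(result.recovered_cellulase_orfs() == planted)
```

prints

```
60 160 55 68
       family kind  orf_count  domain_count
0        CBM2  CBM          4             4
1        CBM3  CBM          2             2
2  CBM4, CBM9  CBM          3             3
True
```

— 60 synthetic unigenes and their 160 homology hits pass through
annotation, LCA and ORF/domain mining; 55 ORFs carry 68 retained domain
hits, the table counts ORFs and domains per family, and the final
`True` confirms that the pipeline recovered exactly the planted
cellulase ORF set (truncated plants are correctly lost to the 600-nt
filter).

The same chain is available from the shell:

```bash
cazymine simulate --seed 5 --outdir out/
cazymine annotate out/hits.tsv --out-annotations out/ann.csv --out-families out/fam.csv
cazymine taxonomy out/hits.tsv --edges out/taxonomy_edges.csv \
    --nodes out/taxonomy_nodes.csv --out out/tax.csv
cazymine quantify out/reads.fastq out/unigenes.fasta --out out/fpkm.csv
cazymine mine-orfs out/unigenes.fasta --out-proteins out/prot.fasta \
    --out-domains out/dom.csv --out-table out/domtab.csv
```

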