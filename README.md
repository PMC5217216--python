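# spudcoex

Cross-platform co-expression consensus analysis for potato tuber
transcriptomics.

## The problem

Candidate regulators of tuber starch biosynthesis can be nominated by
asking which genes are co-expressed with known, strongly tuber-specific
starch genes across *independent* expression platforms.  Integrating an
EST-based 4x44k oligonucleotide microarray, a genome-based 8x60k
microarray and RNA-Seq FPKM data is non-trivial: microarray probes must
first be re-validated against current gene models (probes binding
predicted introns, or matching their transcript at below 85% identity,
measure nothing useful; probes matching duplicated loci are ambiguous),
each platform needs its own normalization, and the probe-level results
must be reconciled to gene identifiers before lists can be compared.

`spudcoex` implements that workflow as a reusable, tested pipeline:

1. **Probe validation** — Smith–Waterman alignment of each probe to the
   spliced transcript (then the pre-mRNA); valid iff identity ≥ 85%
   over the full probe length and no intron overlap; multi-gene matches
   flagged ambiguous.
2. **Normalization** — detection filter, log2, per-chip shift to the
   75th percentile, per-feature median baseline (FPKM passes through).
3. **Tissue specificity** — leaf versus the stolon+tuber+sprout group;
   a gene is tissue-specific when the linear fold-change FC (ratio of
   group means) is strictly above 10 in either direction.
4. **Query selection** — genes tuber-specific on every measurable
   platform and up-regulated from unswollen stolons (stage 1) to small
   tubers (stage 5), ranked by the stage5/stage1 log2 ratio.
5. **Co-expression** — per platform, entities with Pearson correlation
   r ≥ 0.8 (inclusive) against *all* valid probes of each query gene;
   Venn intersection over the query genes; entity→gene mapping; strict
   intersection across platforms gives the consensus list.  Correlation
   significance is flagged at p ≤ 0.1 (two-sided t test,
   t = r√(n−2)/√(1−r²)).
6. **qPCR validation arithmetic** — dCT = CT(target) − CT(reference),
   relative expression 2^(−dCT), stage profiles and the Pearson matrix
   with significance flags.

Because the original raw array/RNA-Seq data are not archived, the
package ships a first-class synthetic-data generator that emulates the
study design — two probe-level platforms with planted defective probes,
an FPKM platform, leaf/stolon/tuber/sprout samples across developmental
stages, planted tissue-specific genes, stage-ramp genes and a planted
latent-factor co-expression module containing the query genes — so the
whole pipeline is testable against known ground truth.  See
`docs/methods.md` for the model and all defaults.

## Worked example

```python
import spudcoex as sc

cfg = sc.SimConfig(n_genes=150, n_chromosomes=3,
                   n_tissue_specific_leaf=6, n_tissue_specific_tuber=6,
                   n_ramp_genes=6, module_size=8)
sim = sc.generate(cfg, seed=11)           # genome, probes, 3 platforms
res = sc.analyze(sim, sc.ParamSet())      # full pipeline, data-driven queries

print("queries:", res["queries"])
print("consensus:", res["consensus"].genes)
print("recovery:", {k: round(v, 3) for k, v in res["recovery"].items()})
```

prints

```
queries: ['gene0035', 'gene0019', 'gene0033']
consensus: ['gene0019', 'gene0033', 'gene0035', 'gene0076', 'gene0116', 'gene0123', 'gene0124', 'gene0137']
recovery: {'precision': 1.0, 'recall': 1.0, 'f1': 1.0, 'n_consensus': 5, 'n_truth': 5, 'n_true_positive': 5}
```

The three selected queries are exactly the planted tuber-specific,
developmentally ramped module genes; the consensus contains the queries
plus the five remaining planted module genes (recall and precision 1.0
against the ground truth, queries excluded from the score).

The same pipeline is available from the shell:

```bash
spudcoex run-all --config cfg.yaml --outdir out --seed 11
spudcoex simulate --outdir sim --seed 1
spudcoex validate-probes --gff sim/genes.gff3 --genome sim/genome.fasta \
    --probes arrayA sim/probes_arrayA.fasta --out probe_table.tsv
```

`run-all` writes every intermediate (probe table, normalized matrices,
specificity and developmental tables, co-expression hits, Venn region
counts, consensus with per-platform support, qPCR profiles and
correlation matrix) plus a `manifest.json` with SHA-256 digests — the
same configuration and seed reproduce every file byte for byte.

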