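# Methods

`spudcoex` re-implements, as a tested pipeline, a cross-platform
co-expression strategy for nominating candidate regulators of tuber
starch metabolism: probe-level measurements from two oligonucleotide
microarray designs and gene-level RNA-Seq (FPKM) data are integrated by
validating probes against gene models, normalizing each platform,
scoring tissue specificity and developmental regulation, selecting query
genes, thresholding Pearson co-expression per platform, and intersecting
the resulting gene lists across platforms.  Because the original raw
data are not archived, the package ships a synthetic-data generator with
planted ground truth; every stage is tested against that truth.

## Probe validation

A probe represents a gene when its best local alignment to the spliced
transcript reaches **85% identity computed over the full probe length**
(number of matched bases / probe length).  Using the probe length rather
than the alignment length as the denominator penalizes partial hits; the
threshold test is integer-exact (`matches * 100 >= min_identity * length`)
so the 85.0% boundary is inclusive and 84.9% is rejected.  Probes that
fail on the transcript are aligned to the unspliced pre-mRNA: a good hit
overlapping a predicted intron by at least 1 bp is discarded as
intron-binding (the threshold of 1 bp is our choice; any overlap
invalidates a transcript-level measurement).  Junction-spanning probes
validate via the spliced transcript, which is checked first.  Probes
validly matching two or more genes — duplicated loci, undistinguishable
isoforms — are retained but flagged ambiguous.

The aligner is Smith–Waterman with match +1, mismatch −1 and a linear
gap cost of −2 per base ('N' never matches).  No scoring scheme is
canonical for this task; this one is fixed in the configuration and the
identity definition above makes the verdicts insensitive to moderate
changes.  Ties are broken deterministically: among best-scoring cells
the lowest target end (then probe end) coordinate wins, and the
traceback prefers diagonal over probe-gap over target-gap moves.  The
matrix fill is JIT-compiled when numba is importable, with an equivalent
vectorized numpy fallback; tests compare both outputs to an independent
cellwise dynamic program.

Aligning every probe against every gene is quadratic, so candidate genes
are nominated by shared 14-mers (both strands).  Only candidates with a
shared exact stretch of ≥ 23 nt, or two separate seed clusters, are
aligned with the full dynamic program; every candidate is also checked
for cheap exact full-length occurrences.  This prescreen is exact for
probes carrying any 23-nt exact stretch and heuristic for probes whose
mismatches are spread so evenly that no such stretch survives — a
documented trade-off that does not affect the planted probe classes.

## Normalization

Probe platforms follow the standard expression-suite chain, in this
fixed order: detection filter (signal ≥ `min_signal` in ≥ 1 sample),
log2 transform with a floor of 1.0, per-sample (per-chip) shift to the
75th percentile, and per-feature baseline correction to the median
across samples.  The percentile uses linear interpolation at index
`(n−1)·q/100` (the numpy/GeneSpring-style default; the exact dialect of
the original software is unknowable, so the choice is recorded here).
Missing values are excluded from percentile and median computation.
After the chain, every sample's 75th percentile and every feature's
median recompute to zero within 1e−9 (asserted in tests).  The FPKM
platform bypasses the chain entirely.

## Differential scoring and query selection

Tissue specificity compares all leaf samples against the pooled
stolon + tuber + sprout group.  On normalized log2 platforms the linear
fold-change is `2^(mean_leaf − mean_tuber)` (difference of log2 means —
the paper-era software reports ratios of normalized means; the log-scale
average is the robust variant and the planted effects make the two
agree); on FPKM it is the ratio of group means with a pseudocount of 0.1
to tolerate zeros.  A gene is tissue-specific when the fold-change is
**strictly above 10** in either direction — exactly 10 does not qualify.
The developmental score is the difference of mean normalized log2 values
between small tubers (stage 5) and unswollen stolons (stage 1).

Query genes must be tuber-specific on *every* platform where they are
measurable and have a mean developmental log2 fold-change of at least
1.0 (default); survivors are ranked by developmental score, ties broken
lexicographically, and the top 3 are returned.  Gene-level values on
probe platforms are the arithmetic mean over the gene's valid,
unambiguous probes (ambiguous-only genes are used but flagged).

## Co-expression and consensus

Within each platform, every valid probe of a query gene is used as a
query feature; an entity co-expresses with the query gene only if its
Pearson correlation reaches the cutoff against **all** features of that
gene (multi-probe Venn reconciliation).  The cutoff is inclusive
(0.8 ≤ r ≤ 1.0) and one-sided — negative correlations never qualify.
The platform core is the central Venn intersection over the query
genes; all 2^k−1 region counts are reported.  Probe-level entities map
to genes through their valid assignments (ambiguous probes contribute
all their genes, flagged), and the cross-platform consensus is the
strict intersection across all platforms, so a gene unmeasurable on any
platform cannot reach the consensus.

Microarray correlations are computed on normalized log2 values.  For
the RNA-Seq platform the default is log2(FPKM + 1): Pearson on linear
FPKM is dominated by the most extreme samples once fold-changes span
orders of magnitude (for jointly lognormal signals the linear-scale
correlation of a high-variance/low-variance pair collapses towards
zero), which would make the gene-level platform structurally unable to
confirm the microarray results.  A configuration switch
(`fpkm_log: false`) restores the raw-scale spreadsheet behaviour.
Correlations use pairwise-complete observations with at least 3 pairs;
zero-variance entities are skipped.

P-values for a correlation r at n paired observations use
`t = r·sqrt(n−2)/sqrt(1−r²)` against Student's t with n−2 degrees of
freedom, two-sided; |r| = 1 gives p = 0.

## qPCR validation arithmetic

Relative expression against the reference gene (the EF1α role) is
`dCT = CT_target − CT_reference`, relative expression `2^(−dCT)`.
Averaging order: technical replicates first, then dCT per biological
replicate, then the biological mean per stage.  The order is a
convention (the alternatives differ only through technical noise) and is
fixed so results are reproducible.  Stage-mean profiles are compared by
pairwise Pearson correlation with two-sided p-values; `n` is the number
of paired stage points, and cells with p ≤ 0.1 are flagged.  Technical
replicates spreading more than 0.5 cycles trigger a warning.

## Synthetic data

The generator emulates the study design end to end.  Gene models (2–5
exons of 120–400 bp, introns of 60–250 bp) are laid out on 12
chromosomes with random intergenic spacers; transcripts honor strand.
Probes are 60-mers drawn from the transcripts (1–3 per gene).  Planted
defects: 10% intron-binding probes (verbatim intron sequence), 10%
low-identity probes (≥ 10 substitutions outside a preserved 24-nt block,
certified with the aligner to stay below 85% best identity — substitution
counts alone do not bound gapped-alignment identity), and 5%
cross-hybridizing probes drawn from exon windows duplicated between
background gene pairs.  Defects only ever replace a gene's second and
later probes, so every gene keeps one valid probe — emulating that the
original study analyzed only genes with accepted identifiers.

Expression follows a log2-scale linear model

    y_gs = μ_g + t_g·1[tuber group] + d_g·rank(stage_s) + λ_g·z_s + ε_gs

with gene baselines μ ~ N(8, 1.5²), per-platform noise ε ~ N(0, 0.5²),
stage ranks stage1…stage5 → 1…5, growing → 6, dormant → 7, and a module
latent factor z shared across platforms (shared biology; each platform
adds its own measurement noise).  Tissue-specific genes carry
t = ±log2(20); decoy ramp genes carry d = ±0.5 (half down-regulated,
emulating genes repressed during tuberization); the 15 module genes
carry λ = 1.5; the 3 query genes are module members that additionally
carry the full tuber program (t = +log2(20), d = +1.5) — that is the
profile they are selected for.  With σ = 0.5 the expected correlation
between two plain module genes is λ²/(λ²+σ²) = 0.9.

The latent factor is `z = w·p + sqrt(1−w²)·η` with η iid standard
normal and `p` the standardized tuber-development program (the query
profile shape), w = 0.9 by default.  This models the module as a
development-tracking regulon — which is what a consensus seeded by
tuber-specific, developmentally ramped queries can recover — while
keeping var(z) = 1, so the module-module correlation above is
independent of w, and a null model with λ = 0 removes all planted
co-expression.  With iid z (w = 0) the queries' own large fixed effects
would dilute query–module correlations to ~0.6 and no consensus could
recover the module at the 0.8 cutoff; the mixing weight is therefore a
modelling choice, not a tuning knob, and it is exposed in the
configuration.

The default sample design has 36 biological samples per platform:
leaves across stages 1–5, stolons (stages 1–3), tubers (stages 4–5 and
growing) and dormant sprouts, 3 replicates each; all three platforms
measure the same biological design.  Microarray intensities are emitted
as `2^y` with a background floor of 1.0 (so the log2 transform is
invertible); FPKM is `fpkm_scale·2^y`.  Probe values add N(0, 0.1²)
measurement noise per probe and sample; planted-invalid probes instead
measure independent hybridization noise around log2 level 5.  The qPCR
generator re-draws the same latent model on an independent sample set
(stages 1, 3, 5, growing, dormant; 4 biological × 2 technical
replicates) with CT = 32 − y and a reference gene at CT 20.

The noise magnitude of the original arrays is unknown; σ = 0.5 log2
units is a typical residual for replicated one-color arrays and is a
free parameter.  What the generator does **not** emulate: sequencing
counts (FPKM is lognormal here, not negative-binomial), batch effects,
probe-specific affinity biases correlated with sequence, or
cross-platform sample mismatches.  Passing tests therefore demonstrate
the correctness and internal consistency of the pipeline under the
stated model, not performance on real arrays.

## Problem sizes and determinism

All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical configuration and seed give
byte-identical outputs, recorded as SHA-256 digests in the run manifest.
The acceptance checks run the default study (2000 genes, three
platforms, 36 samples) over 20 seeds for module recovery and its λ = 0
null control, 20 seeds for query selection at 500 genes, and single
seeds for the probe-verdict and qPCR checks; these sizes were chosen so
the full suite completes comfortably on one CPU.  Known per-seed
fluctuation: because the latent factor is drawn once per biological
sample set and shared across platforms, an unlucky draw lowers
query–module correlations on all platforms simultaneously, occasionally
producing a seed with low recall; the acceptance criterion is
accordingly a 20-seed average.

## Known limitations

* The k-mer prescreen can miss probes whose mismatches leave no 23-nt
  exact stretch (they become `no_hit` instead of `low_identity`); the
  full aligner is available via `assign_probe(..., candidate_genes=None)`.
* Entity-to-gene mapping keeps ambiguous probes, so a duplicated locus
  can carry its twin into the consensus; such genes are flagged.
* The qPCR p-values treat stage means as independent observations
  (n = number of stages), a convention, not a mixed-model analysis.
* The FPKM fold-change pseudocount (0.1) is arbitrary below the scale of
  real FPKM values; ratios of near-zero means remain unstable.
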