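# Methods

`coldtme` implements the computational chain used to relate tobacco-smoke
exposure to a "cold" (leukocyte-poor) tumor immune microenvironment and to
hyperactivation of the NRF2 antioxidant program: signature scoring of bulk
RNA-seq, resampling consensus clustering of patients and genes, cohort
statistics over smoking and KEAP1/NFE2L2 mutation strata, differential
expression/metabolite testing, and metabolite–transcript integration. This
note records the models, the parameter choices that matter, and what the
synthetic-data generators do and do not emulate.

## Value spaces and normalization

Expression matrices carry an explicit value-space tag (`counts`, `linear`,
`log2`) and operations refuse inputs in the wrong space rather than
guessing.

**FPKM-UQ.** For RSEM-style counts with effective gene lengths,
`value[g,s] = counts[g,s] · 1e9 / (length_g · UQ_s)` where `UQ_s` is the
75th percentile of sample *s*'s **nonzero** gene counts. Taking the upper
quartile over nonzero counts follows the TCGA/GDC harmonization dialect;
`include_zeros=True` switches to the all-genes quartile. Percentiles and
quartiles throughout the package (FPKM-UQ, median-IQR, percentile
stratification) use linear interpolation between order statistics, so a
single convention holds everywhere. FPKM-UQ is invariant to global
per-sample count scaling, and within a sample the ratio of two genes'
values equals the ratio of their length-normalized counts.

**log2 offset.** `log2(X + 0.01)` maps linear values (including exact
zeros) into log2 space; the same offset is implied wherever fold changes
are formed as differences of log2 means, so zero-expression features keep
finite fold changes.

**Per-gene Z scores.** Sample-wise Z within each gene, with population SD
(divisor *n*). Ward clustering is invariant to the *n* vs *n−1* choice
(it rescales all coordinates of a gene equally); population SD is used
and recorded. Constant genes cannot be standardized: they are set to zero
and flagged, and flagged genes are excluded from gene-axis clustering.

**Median-IQR (metabolomics).** Peak areas are log2-transformed, then each
*sample* (column) is centered by its median and scaled by its
interquartile range. The per-sample orientation is deliberate: it removes
injection/loading differences before differential testing, while
per-metabolite scaling is a display-time step, not part of the test.
Zero-IQR columns and tables with fewer than 4 metabolites are errors.

## Single-sample GSEA

For one sample, genes are ordered by expression descending, ties broken
lexicographically by gene id so scores are bit-reproducible. With integer
rank weights `R = N..1` and exponent `α` (default 0.75, the common ssGSEA
default), the score is the summed difference between the weighted in-set
running CDF and the unweighted out-of-set running CDF:

    ES = Σ_i [ Σ_{j≤i, j∈S} R_j^α / Σ_{j∈S} R_j^α  −  #{j≤i, j∉S} / (N − |S|) ]

Because the weights are ranks rather than raw magnitudes, linear-space
input determines only the ordering; scores are exactly invariant under
strictly monotone transforms, and for α = 0 reversing the ranking negates
the score. Set genes absent from the matrix are dropped with a warning
(the GSEA convention), an empty effective set or a set covering all genes
is an error. An optional `normalize_scores` flag divides the whole matrix
by its max − min; it defaults to off.

The implementation is vectorized (one ordering per sample, cumulative
sums per set); the test suite checks it against an independent plain-loop
enumeration to 1e-12 on randomized instances.

## Consensus clustering

A Monti-style resampling wrapper around Ward agglomeration on Euclidean
distances. Per resample `b` of `B` (default 250; 0.8 subsampling without
replacement), items are drawn with an RNG seeded from `(seed, b)` — a
counter-derived stream, so enlarging `B` never reshuffles earlier draws —
Ward-clustered, and cut at `k`. The consensus matrix is the ratio of
co-clustering to co-sampling counts (0 with a warning for never
co-sampled pairs); the final partition is Ward linkage on `1 − consensus`
cut at `k`. With fraction 1.0 and `B = 1` the procedure reduces exactly
to plain Ward clustering. Samples are clustered on per-gene Z scores; for
gene modules the *same* Z matrix is transposed without re-standardizing.
The patient-immune clustering defaults to `k = 3` (two hot clusters plus
one cold).

**Choosing k.** `select_k` cuts the same resampling trees at every
candidate k and reports the Monti consensus-CDF area per k. The
*recommendation*, however, is based on the proportion of ambiguous
clustering (PAC: off-diagonal consensus entries in (0.1, 0.9)): the
largest candidate with PAC ≤ 0.1, i.e. the finest partition the
resampling still reproduces crisply, falling back to the smallest
candidate when nothing is crisp. The delta-area rule was evaluated and
rejected during development: with resampled Ward trees the CDF area keeps
growing by more than 5% per k even on structureless Gaussian data
(measured 0.34 → 0.81 over k = 2..6), because an 80% subsample of a fixed
noise cloud still has stable hierarchical structure, so a relative-area
threshold selects the largest candidate regardless of the data. PAC
separates planted from structureless data cleanly (PAC = 0 at the true k
for well-separated clusters; PAC ≥ 0.3 at every k for noise).

## Cohort statistics

**Hot/cold calling.** Signature scores are Z-scored across samples within
each signature; per-cluster mean profiles are averaged over signatures,
and the single cluster with the minimum overall mean is called cold —
everything else is hot. A tie within 1e-9 raises an error demanding
manual assignment rather than an arbitrary call.

**Smoking enrichment.** Pearson χ² on the exposure × phenotype count
table, no continuity correction, expected counts `row·col/total`, upper
tail at `df = (r−1)(c−1)`; any expected cell below 5 raises a flag.
Smoking is dichotomized as exposed = {current, reformed ≤ 15 y} vs
unexposed = {never, reformed > 15 y}; unknown histories are excluded with
a logged count.

**Effect sizes and ANOVA.** Cohen's *d* uses the pooled sample SD
(Cohen's original form, not Hedges' g). The two-factor ANOVA fits a
linear model with interaction and reports Type II sums of squares —
chosen because observational strata are unbalanced and Type II main
effects are invariant to factor order; on balanced designs the
decomposition coincides with the classical one. The companion contrast
(the headline effect size) is factor1 = exposed vs unexposed *within*
mutated samples.

**Mutation geometry.** NFE2L2 mutations are classified motif-proximal if
the protein position falls within a KEAP1-binding degron motif — DLG
(29–31) or ETGE (79–82), human NRF2 coordinates — extended by a vicinity
window of ±5 aa (an explicit quantification of "immediate vicinity";
configurable, inclusive boundaries). Percentile stratification splits
activation scores at an interpolated percentile (default 10th), scores at
or below the cutoff counting as marginal.

## Differential testing and consensus calls

Per feature: two-sided pooled-variance Student's t (Welch by flag),
BH step-up within the experiment over filter-passing features only —
filtering (mean log2 ≥ 2 in at least one group) happens *before* testing,
which changes the BH `m` and is therefore part of the contract.
Zero-variance features get `p = 1` and a flag instead of an undefined
statistic. `log2_fc` is the difference of log2 means and
`fold_change = 2^log2_fc`, i.e. the ratio of geometric means of the
linear values. Cross-experiment consensus counts a gene per experiment
iff it is significant **and** past the fold threshold (≥ 1.3-fold up, or
≤ 1/1.3 down; inclusive), with a call at ≥ 3 experiments by default.
Proteomics-style moderated-t shrinkage is intentionally out of scope;
the plain-t machinery is applied to all feature types.

## Metabolite–transcript integration

Differential metabolites (BH q < 0.25 by default) are mapped to genes
through a user-supplied metabolite→gene table (HMDB-style; kept as an
offline file so results are reproducible without network access;
unmapped metabolites are reported, not fatal). Over-representation of
the mapped genes in pathway collections uses the hypergeometric upper
tail `P(X ≥ k)` with BH across pathways (q < 0.05); enrichment only, no
depletion. The universe defaults to the genes passing the expression
filter of the matching experiment, not the whole genome. Per background,
the overlap signature is DEM-associated genes ∩ upregulated DEGs
(q < 0.1), and the core is the intersection of overlaps across all
backgrounds.

## Synthetic-data generators

All generators are pure functions of parameters + seed and return exact
ground truth.

**Cohort** (`simulate_cohort`). Genes partition into 14 disjoint
leukocyte signatures (30 genes each), one 138-gene Nrf2 signature, and
background. Per-gene baseline log2 means are N(5, 1.5); negative-binomial
counts with dispersion 0.2 (variance μ + 0.2 μ²); uniform effective gene
lengths on [500, 5000]. Hot samples get a +1 log2 infiltration shift on
leukocyte genes; the second hot cluster additionally gets 1.5× the shift
on the second half of the leukocyte sets — without some profile
difference the two hot clusters would be geometrically identical and no
three-way partition could exist. Smoking is assigned by conditional
probability so the cold-vs-hot exposure odds ratio equals the target (4
by default) in expectation, at a base exposure rate of 0.35 among hot
samples. The Nrf2-signature shift is
`β_mut·mut + β_smoke·smoke + β_int·mut·smoke` in log2 units with defaults
(0.5, 0.1, 0.18); β_int was calibrated by pilot simulation so that the
standardized mutated-smoker vs mutated-nonsmoker difference of the Nrf2
ssGSEA score is ≈ 1.0 — the effect-size regime the cohort statistics are
tested in. Mutations (25% prevalence, half KEAP1 / half NFE2L2) carry
protein positions; 80% of NFE2L2 positions fall in the DLG/ETGE vicinity.

**Cell-line exposure** (`simulate_exposure_experiment`). Per line,
treated and sham replicate matrices (default 4 per arm) with Gaussian
noise (SD 0.25) in log2 space around N(6, 1.5) baselines — the
post-normalization regime the differential tests operate in. A shared
set (40 genes) is shifted +2 log2 (4-fold) in every line; each line has
its own up and down sets (30 each). Four replicates are the default
because with triplicates a planted 4-fold shift is detected at BH
q < 0.1 among ~2000 features only ~95% of the time per gene and line,
which makes *exact* multi-line recovery of a named gene set a coin flip
rather than a property of the method.

**Metabolome** (`simulate_metabolome`). Log-normal peak areas (log2 base
N(20, 2), noise SD 0.5, 4 replicates per arm); the same 30-metabolite DEM
set is shifted +2 log2 in the treated arm of every background. The
metabolite→gene map links each planted DEM to decoy genes (`MGENE_*`,
absent from any expression experiment) and each core gene to 3 planted
DEMs — mirroring how a redox enzyme associates with several metabolites
of its pathway. `simulate_integration_study` couples the two generators:
the named core genes (default GPX2, GSR) are placed in the shared
upregulated set of a 3-background exposure experiment and mapped from
planted DEMs, so the pipeline's cross-background core has an exact
expected value.

**What the generators do not emulate.** Read-level sequencing noise,
GC/length bias, batch effects, correlated genes within signatures,
HPV status, missing metabolite values, and mass-spectral artifacts.
Passing the recovery tests therefore demonstrates correctness of the
statistical machinery under its stated model, not robustness to every
real-data pathology.

## Numerical choices and degenerate inputs

- Ties in expression are broken lexicographically by gene id everywhere a
  ranking is formed (bit-reproducibility).
- One RNG convention: `numpy` Generator seeded with `[seed, stream]`
  lists; per-resample streams are counter-derived.
- Constant features: flagged and zeroed (Z scores), `p = 1` + flag
  (t tests), error (median-IQR, Cohen's d) — chosen per operation so
  nothing silently propagates an undefined value.
- χ² with zero-margin rows/columns, empty ORA queries/universes, k
  larger than the item count, overlapping differential groups: all hard
  errors.
- Consensus entries for never co-sampled pairs are 0 with a warning;
  with the default B = 250 at 0.8 subsampling this does not occur for
  realistic cohort sizes.

## Problem sizes used in the recovery checks

The simulation-based checks run at deliberately modest sizes chosen to
make planted effects decisively recoverable: cohorts of 300 samples ×
1000 genes (100 replicates for enrichment power; 500 label-only
replicates for null calibration), effect-size recovery on 800-sample
cohorts (200 replicates), differential nulls of 2000 features × 8
samples (100 runs), and 3-background integration studies at generator
defaults. The same quantities are recomputed from scratch by
`scripts/acceptance.py`.

## Known limitations

- The ssGSEA dialect (integer rank weights, lexicographic ties) is one
  of several in circulation; scores are not numerically interchangeable
  with other implementations, though rank-based conclusions are.
- The consensus wrapper assumes Euclidean/Ward; no other linkage is
  offered for the resampled stage.
- BH assumes independent or positively dependent tests; no
  Benjamini–Yekutieli option.
- The metabolite→gene map is taken at face value; no identifier
  harmonization across HMDB/KEGG/ChEBI vocabularies.
- Hot/cold calling assumes exactly one cold cluster; cohorts with two
  equally cold clusters error out deliberately.
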