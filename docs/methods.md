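# Methods

`chronofield` implements the statistical chain used to compare diurnal
transcriptome dynamics between a field-grown plant and growth chambers that
either reproduce or hold constant individual components of the field
environment (irradiance; air temperature and humidity). This note records
the models, the parameters that matter, what the synthetic generator does
and does not emulate, and the numerical choices that were genuinely open.

## Experimental designs

Two designs are built in. The field experiment (`exp1`) samples five
conditions — FIELD, the full chamber simulation FL/FTH, the square-wave
chamber CL/CTH, and the two partial simulations FL/CTH and CL/FTH — every
2 h for 24 h starting at 19:00 (13 timepoints, the last being 19:00 again
24 h later, written 19:00_2) with 4 replicates: 260 samples. The
chamber-only experiment (`exp2`) covers the four chamber conditions at 17
timepoints from 5:00 to 19:00 with 3 replicates: 204 samples. The exp2 grid
is densified around dawn and dusk (half-hourly 5:00–7:00 and 17:00–19:00,
coarser midday); the published description fixes the endpoints, the count
and the dawn/dusk densification but not every interior point, so the midday
spacing here (8, 9, 10, 11, 13, 15, 16 h) is a package choice.

Time is stored as minutes since midnight plus a day index, so the repeated
19:00 clock time stays distinguishable. All periodic fits use clock time
modulo 24 h.

## Expression units

Raw counts (fractional expected counts from upstream quantifiers are
accepted) are filtered by mean count strictly greater than 10 across all
samples, scaled to reads per million (rpm) per sample after removing an
exclusion list (typically rRNA genes), and log-transformed as
log2(rpm + 1). Operations declare the unit they need and refuse others.

## Molecular timetable method

A gene's periodicity is scored by the best Pearson correlation *r* between
its time course and the family of 24-h cosines
cos(2π(t − φ)/1440), φ scanned over 1440 one-minute candidates; the argmax
φ is the gene's molecular peak time. The period is fixed at exactly 24 h —
no period search. Amplitude is a = SD/mean (sample SD, n−1). Genes with
r ≥ 0.935 and a ≥ 0.15 (the literature cutoffs, both configurable) become
time-indicating genes; every replicate enters the fit as an independent
observation at its clock time.

For any single sample, marker expression is z-scored against the training
mean/SD and the internal time T is the candidate (same 1-min grid)
maximizing the Pearson correlation between z_g and cos(2π(φ_g − T)/1440).
Ties break toward the smallest candidate, making output deterministic.

The grid argmax is not an approximation: for the continuous problem, the
correlation-maximizing phase equals the closed-form harmonic-regression
phase atan2(γ̂, β̂) from fitting α + β·cos + γ·sin (the correlation is
scale-free, so the constrained direction (cos Φ, sin Φ) maximizing it is
the unconstrained least-squares direction). The grid answer is therefore
within half a grid step (0.5 min) of the closed form; the test suite
verifies ≤ 1 min against an independent least-squares oracle.

Marker-set quality is summarized as measurement noise: the SD of residuals
between observed z-scores and the gene's expected cosine at the estimated
internal times, reported per gene and ×100 as a percentage. The expected
cosine carries a per-gene least-squares amplitude by default (the z-score
of an ideal sinusoid is a √2-amplitude cosine, so a unit-amplitude residual
never vanishes even on noise-free data); the unit-amplitude convention
remains available via `amplitude="unit"`. The percentage baseline of
published noise figures is ambiguous, so the convention used here is
stated in the output.

Caveat observed in simulation: on the exp1 grid the duplicated 19:00 clock
time makes the training mean/SD of a cosine slightly phase-dependent, which
can bias single-sample estimates by up to ~15 min at some timepoints. This
is well inside the ~20-min accuracy the method is used at and disappears on
balanced circular designs.

## Differential expression

Between-sample normalization is trimmed mean of M-values (TMM): reference
sample by upper quartile of nonzero relative counts closest to the mean;
gene-wise M (log2 ratio of relative abundances) and A (mean log2 abundance)
over genes nonzero in both; double trimming (30% on M, 5% on A, half per
tail, rank-based); factor = 2^(precision-weighted mean of retained M) with
inverse asymptotic binomial variance weights; factors rescaled to geometric
mean 1.

The test is the negative-binomial conditional exact test with a common
dispersion φ (variance μ + φμ²) estimated by maximizing the conditional
log-likelihood over all genes given the group totals, via bounded scalar
optimization of log φ (fallback: pooled method of moments, with a warning).
Libraries are adjusted to the geometric-mean effective size
(library size × TMM factor) by scaling counts — scaled means rather than
resampled pseudo-counts, a deliberate simplification validated by
calibration: the type-I error at nominal 0.05 stays within [0.03, 0.07] in
the suite's null simulations, and power for 4-fold changes at q < 0.05
exceeds 0.8 at 4 replicates per group. Conditional on the total z = z1 +
z2, the group-1 total follows a negative hypergeometric law; the two-sided
p sums the probabilities of all splits no more probable than the one
observed (log-scale comparison with a 1e-10 tie tolerance). Counts are
rounded to the nearest integer before testing. Tagwise dispersion shrinkage
and GLM-based testing are out of scope.

DEG-elimination normalization runs TMM, flags putative DEGs with the exact
test at a liberal FDR (default 0.1), recomputes TMM on the unflagged genes
and converts the subset factors back to full-library scale via the subset
effective sizes. With no true DEGs this reproduces plain TMM (within 2% in
simulation); with 25% one-directional DEGs it removes most of the
composition bias the DEGs induce. Per-timepoint DEG calling applies the
full chain independently at every timepoint shared by the two conditions
(≥ 2 replicates each), flagging at BH q < 0.05; the per-timepoint design
mirrors how the replicate structure is actually available.

## Environmental-driver classification

At each timepoint a gene carries one DEG flag per comparison of the
baseline condition against the others. An ordered truth table maps flag
tuples to classes; the field-experiment default (baseline FIELD,
comparisons FL/FTH, CL/CTH, FL/CTH, CL/FTH):

| class | FL/FTH | CL/CTH | FL/CTH | CL/FTH | reading |
|-------|--------|--------|--------|--------|---------|
| UNREP | T | – | – | – | differs even from the full simulation |
| LIGHT | F | T | F | T | differs exactly where light is constant |
| TH    | F | T | T | F | differs exactly where temperature/humidity are constant |
| LTH   | F | T | T | T | differs wherever either factor is constant |

Everything else is `none`. UNREP deliberately dominates: a gene the full
simulation fails to reproduce is field-driven regardless of the other
flags. The chamber-only scheme (baseline FL/FTH; three comparisons) has no
UNREP class. Published figure tables of this kind are not always fully
legible from text, so the scheme is data — any alternative table can be
supplied as a mapping (e.g. YAML) — and the defaults are recorded in
pipeline output headers.

Field-specific genes: per condition, replicate means per timepoint are
averaged over all timepoints; a gene is field-up if its FIELD mean is at
least 2× the FL/FTH mean (floor 1e-9 against division by zero) *and* it is
a DEG at one or more timepoints; field-down symmetrically. Cross-study
concordance joins two per-gene log difference vectors on shared genes and
reports the sign-agreement fraction above a magnitude threshold.

## Similarity summaries

Per-timepoint condition similarity is the Pearson correlation over genes
for every replicate pairing (4×4 = 16 values per timepoint by default;
the mean-profile alternative is a flag) on the log2(rpm+1) scale, with
two-sided tie-corrected Wilcoxon rank-sum comparisons between condition
groups and BH adjustment across the tested pairs. Per-gene similarity is
the correlation of replicate-mean time courses, p from
t = r√((n−2)/(1−r²)) on n−2 df, BH across genes; the headline count is
genes with r > 0.7 and q < 0.05. PCA is gene-centred (not scaled) on
log2(rpm+1). Hierarchical clustering uses 1 − Pearson r between sample
profiles with average linkage (configurable) and Newick export.

Multiple-testing adjustment is Benjamini–Hochberg everywhere, via
statsmodels.

## Term enrichment

Fisher's exact test, two-sided, per term, over the universe of annotated
genes (optionally intersected with the analysis gene list); terms with
fewer than 2 universe genes are skipped. The p-value is computed with
exact integer binomial-coefficient weights over the common hypergeometric
denominator, so tie comparison is exact rather than float-tolerant; the
suite checks agreement to 1e-10 with an exact-fraction brute-force
enumeration over all tables with total ≤ 50, and cross-checks SciPy's
implementation. The odds ratio uses a 0.5 continuity correction for
display only. No GO-graph propagation is performed — annotations are
consumed as a flat table.

## Synthetic generator

Counts for gene g in condition c at clock time t are negative binomial
(dispersion ψ, default 0.1) with mean

    L_s · μ_g · (1 + A_g · cos(2π (t + δ_c − φ_g)/1440)) · e_{g,c,t}

with per-sample library factors L_s ~ U(0.7, 1.3), log-normal baselines
μ_g (median 100, ln-scale SD 1.2), rhythm fraction 0.3 with amplitudes
A ~ U(0.2, 0.9) and uniform phases, optional per-condition internal-time
offsets δ_c, and multiplicative class effects e of ±2 in log2 (random sign
per gene) applied, per class, in the conditions whose constant factor
defines the class and at its affected timepoints (temperature effects in
the morning; light effects morning and evening; field-specific effects at
midday). Class fractions default to 5% each of all genes; rhythmicity is
drawn independently. All randomness flows from a single seed; equal seeds
give bit-identical experiments.

What the generator emulates: the two sampling designs, cosine diurnal
profiles with realistic amplitude spread, NB count noise with variable
depth, and driver classes recoverable by the DEG set logic. What it does
not: weather-driven day-to-day differences (each clock time has one true
profile), autocorrelated or weather-dependent noise, gene-gene
correlation, partial or phase-shifting responses (effects are clean
multiplicative shifts at whole timepoints), and transcript-level quirks of
poly(A) selection. Passing recovery tests therefore demonstrates that the
statistical chain is correct and calibrated under its stated model, not
that real field data would classify as cleanly.

Two consequences of the defaults worth knowing: with NB dispersion 0.1 and
4 replicates, the strict marker cutoffs (r ≥ 0.935) select nothing on
simulated counts — marker selection at those cutoffs presumes the lower
noise of real deep RNA-seq averages, and simulation-based tests either use
noise-free profiles or relax r; and with only ~30% of genes rhythmic the
sample dendrogram does not cleanly split into 13 timepoint clusters
(adjacent 2-h timepoints merge) — that separation emerges once diurnal
structure dominates (e.g. 90% rhythmic at low dispersion), which is how
the clustering recovery test is constructed.

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale: 1000-gene
presets for classification recovery, 2000-gene calibration simulations,
150-marker internal-time recovery over 100 probe samples, 500 random
series for the phase-oracle check, and exhaustive Fisher enumeration to
total 50. Grid fits and exact tests are deterministic; ties break toward
the smallest candidate; every stochastic step takes an explicit seed, and
the pipeline writes byte-identical outputs on re-run with an identical
config (provenance headers carry the package version, a config hash and
the seed — no timestamps).

## Known limitations

* Numeric parity with any particular normalization/DEG package is not a
  goal; the implementation is validated by calibration and construction
  truth instead.
* Common dispersion only; at 3–4 replicates per group tagwise estimates
  would be unstable without shrinkage machinery that is out of scope.
* The exact test's library adjustment by scaled means slightly perturbs
  the conditional model when effective sizes are very unequal; calibration
  holds in the regimes tested (factors within ~±30%).
* Internal-time estimates inherit a small grid-design bias on unbalanced
  sampling grids (see above).
* Enrichment treats terms independently — no hierarchy, no overlap
  correction.
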