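# Methods

This note records the statistical models, defaults, and design decisions
behind `httrscreen`, in the spirit of a package vignette: what is
computed, under which assumptions, and where the edges are.

## Data model

A screen is a gene-by-well integer count matrix joined to a validated
plate sheet (barcode, well, treatment, concentration, unit, sample type,
replicate, plate). Vehicle (solvent-only, typically DMSO) wells are the
baseline for every comparison; they are identified by the `sample_type`
column, with a case-insensitive treatment-name fallback. Well labels are
canonicalised (letters = rows, 1-based unpadded columns, so `A01 ≡ A1`);
identifier columns are restricted to `[A-Za-z0-9._-]` because treatment
strings become file names downstream.

## QC and normalisation

**RLE.** Relative log expression is `log2(norm + pc) − median_ref`
per gene, pseudocount 1 by default. Flat, zero-centred RLE distributions
indicate successful normalisation.

**Average CV.** The scalar quality score is the per-gene coefficient of
variation of normalised counts across wells (sample sd / mean), averaged
over genes with mean ≥ 1 (normalised units), computed on vehicle wells
by default. This directly measures the residual spread that RLE plots
display. An alternative reading — the mean per-well sd of RLE values —
is available via `average_cv(..., per_well=True)`. The CV itself is
scale-free; the `min_mean` gate is expressed in absolute normalised
units, so exact invariance to global rescaling holds when `min_mean=0`.

**Gene filtering.** A gene is kept when its aggregated count reaches
`min_count` (default 5) in at least `min_groups` (default 2) sample
groups, a group being a treatment × concentration cell. The default
aggregation is the group sum — at plate-screen depths "5 reads in a
group" reads most naturally as a group total; `per_well_min` is the
stricter alternative.

**Outlier wells** are flagged by explicit thresholds: |median RLE| > 1,
RLE IQR > 2× the cohort median IQR, or fewer than 200 detected genes.
All three are configuration, not estimates.

**Variance decomposition** uses sequential (type-I) sums of squares of a
per-gene linear model over declared metadata factors, in declared order.
For the near-balanced designs of plate screens this is simple and
exactly reproducible; the order is recorded in the output and aliased
factors are reported as NaN with a warning.

**Scaling factors.** Four families are implemented: CPM;
DESeq-style median-of-ratios (median of per-gene ratios to geometric
means, computed on the ratio scale; genes containing any zero are
excluded from the reference, so pre-filtering is advisable and the error
message says so); TMM with M-trim 0.3, A-trim 0.05, inverse-asymptotic-
variance precision weights, and the reference well whose upper-quartile
proportion is closest to the mean; and TMMwsp, which additionally ranks
genes positive in only one well of a pair by count and greedily pairs
them largest-to-largest into surrogate ratios, keeping the factor usable
under heavy zero inflation. TMM-family factors are rescaled to geometric
mean exactly 1. Trimming ranks are tie-broken on the full (M, A, weight)
value triple so factors are exactly invariant to gene order.

**Control-gene correction** (RUV-style) takes the first k right singular
vectors of the row-centred control-gene submatrix as unwanted factors,
regresses every gene on them, and returns residuals plus gene means
(means are preserved exactly because the scores have zero well-mean).
The scores are also exported for use as DE covariates.

## Zero inflation and observation weights

Plate screens with limited input show more zeros than a negative
binomial (NB) predicts. The ZINB model here is a per-gene two-component
mixture: with probability π the observation is a technical dropout
(point mass at zero), otherwise NB(μ, θ). The per-gene EM alternates:

* E-step: dropout responsibility of each zero,
  `z = π / (π + (1−π)·NB0)`, `NB0 = (θ/(θ+μ))^θ`;
* M-step: `π ← mean(z)`; group means by weighted Newton ML and θ by
  ternary search on the weighted profile likelihood, with NB-component
  weights `1 − z`.

Observation weights are `1 − z` at zeros and exactly 1 at positive
counts. The observed-data log-likelihood is non-decreasing across
iterations (each M-step is a coordinate ascent on the EM lower bound);
convergence tolerance 1e-4 on the log-likelihood, at most 100
iterations, θ clamped to [1e-3, 1e6]. π is a single per-gene intercept;
no sample-level latent factors are modelled — the weight formula the DE
engines consume is identical in form, and the latent-factor machinery
adds nothing at 3–19 replicates per group.

Weights enter both dispersion estimation and the GLM/least-squares fits
of the engines that accept them.

## Differential-expression engines

All five engines share one result contract (log2FC, statistic, p,
Benjamini–Hochberg adjusted p, mean normalised abundance) and are
deterministic — no RNG anywhere, so multi-treatment runs are bit-identical
for any worker count. Where an engine family has a published reference
implementation, the implementation here was cross-checked against it
(edgeR, limma and DESeq2 in their current releases) on identical
simulated inputs, and three details proved decisive for matching their
behaviour on zero-heavy data:

1. **The dispersion trend is estimated on the likelihood scale.** Genes
   are sorted by abundance and cut into ~20 bins; each bin's dispersion
   maximises the summed Cox–Reid adjusted profile likelihood of its
   genes. Averaging per-gene estimates instead (e.g. a lowess of
   log-dispersions) compresses the heavy upper tail that dropout zeros
   create, and low-abundance genes then look artificially precise.
2. **The QL engine (`nbql`) fits at the trended dispersion** and lets
   gene-specific variability flow into the quasi-likelihood dispersion,
   which is estimated from the *deviance* (not Pearson residuals — the
   deviance penalises badly fitted observations, dropout zeros above
   all, much harder) and moderated across genes by closed-form moment
   matching of a scaled inverse-chi-square on log variances (trigamma
   inversion; a non-positive moment estimate of the prior df falls back
   to complete shrinkage with a warning). The test is an F on the
   treatment coefficient with moderated denominator df.
3. **The Wald engine (`wald_nb`)** uses median-of-ratios offsets and
   shrinks log-dispersions toward the trend with prior weight 10 —
   except dispersion outliers (gene log-dispersion more than 2 residual
   sd above trend), which keep their own estimate so erratic genes are
   not anti-conservatively squeezed. A Cook's-distance guard
   (`D = r²/p · h/(1−h)²` with GLM leverages, cutoff F(p, n−p) at 0.99)
   refuses to test genes whose coefficient is dominated by a single
   observation; it requires ≥ 3 wells per side and is a gross-outlier
   guard, not a dropout detector.

`voom` computes log2-CPM (prior count 0.5) on TMMwsp effective library
sizes, fits per-gene linear models, smooths sqrt(residual sd) against
mean log2 count by lowess (span 0.5), takes observation weights as the
inverse fourth power of the trend at each fitted log-count, refits by
weighted least squares and applies the moderated t. External ZINB
weights multiply the voom weights. `trend` uses unweighted least squares
on log2-CPM with prior count 3 (the larger prior damps the extreme fold
changes an all-zero group would otherwise produce) and an
intensity-dependent prior variance. `ranksum` is a two-sided Wilcoxon
rank-sum on CPM, exact by enumeration when both groups have ≤ 8 wells
and the gene is tie-free, otherwise the tie-corrected normal
approximation with continuity correction; its fold change is
`log2((mean CPM_t + 1)/(mean CPM_c + 1))`.

Lowess trends sort their inputs by (x, y) before fitting, making every
engine exactly invariant under permutation of gene rows, ties included.

BH adjustment is the step-up rule computed directly; NaN p-values (from
untested genes) propagate and are excluded from the test count.

### What marginal engines cannot see

Two technical dropout zeros among three treated wells are statistically
indistinguishable from genuine strong downregulation for *any* model
that looks at one gene's counts alone — the group coefficient simply
absorbs them. The QL engine's inflated trend dispersion and deviance
dispersion suppress almost all such calls; the Wald and trend engines
(like their reference implementations, which behave near-identically on
the same simulated data) emit an occasional spurious down-regulated gene
under heavy zero inflation. This is the concrete reason the toolkit
ships ZINB weights, and why down-regulated calls from small groups
deserve more scepticism than up-regulated ones.

## Enrichment

ORA is the upper-tail hypergeometric with BH across sets. Preranked
GSEA walks the ranking in decreasing order; hits add `|stat|^p`
(normalised), misses subtract `1/(N−K)`; the ES is the extreme deviation
of larger magnitude (positive wins an exact tie). The null is gene-label
permutation — appropriate for preranked input, unlike phenotype
permutation — with NES = ES / mean |null ES| of matching sign and a
(1+b)/(1+m) permutation p. Sets whose same-sign null has fewer than 10
draws are flagged rather than guessed. Signature scoring takes the top
500 genes of a reference profile as the set and the query's DE statistic
as the ranking.

## Dose–response

The four-parameter logistic `y = lower + (upper−lower)/(1+(EC50/x)^h)`
is fitted on the log10-dose axis by bounded least squares from a grid of
starts (h ∈ {±0.5, ±1, ±2} × dose quantiles); refinement never returns
a worse RSS than the best start, `y(EC50)` is exactly the midpoint of
the asymptotes, and `(lower, upper, h)` ↔ `(upper, lower, −h)` describe
the same curve, so fits are reported up to that equivalence. Vehicle
(x = 0) anchors the response definition (log2FC vs vehicle) and never
enters the fit. EC50 bounds extend 100-fold beyond the dose range with
an in-range flag; flat responses are reported as non-converged.

Pathway-level profiles offer two response scales. The default for EC50
fitting is the **mean log2FC of the set members** per concentration, an
effect-size scale whose midpoint tracks the member genes' EC50s. The
permutation-normalised **NES** is also available but is a detection
scale: it saturates as soon as the coordinated shift is clearly
detectable — typically well below the genes' half-maximal concentration
— so NES-based midpoints are systematically left-shifted. A dedicated
test asserts this left shift.

## Benchmark harness

All procedures are pure functions of (screen, config, seed). The
DMSO-split false-positive estimator partitions the vehicle wells once
(seeded) into two fixed pools of 8 and draws n = 3 per pool per repeat,
reporting genes passing nominal (p, |LFC|) and adjusted (padj, |LFC|)
cuts as mean ± se over repeats. Replicate subsampling compares each
leave-one-out duplicate against the full-replicate reference set.
Control-count sweeps draw c vehicle wells per repeat. Uncertainty is
always the standard error over repeats or subsets.

The yield-vs-controls curve is informative only in the power-limited
regime: with saturating planted effects every control count recovers
everything, and past roughly a dozen controls the yield can decline
slightly as variance estimates stabilise and retract borderline calls.
The packaged shape checks therefore use moderate planted effects
(|log2FC| ≈ 1.3) over 2–12 controls.

## The simulator

`simulate_screen` draws `count[g,j] ~ ZINB(s_j · μ_g · 2^{Δ_g(j)} ·
batch_j, θ_g, π_g)` with per-gene baselines `log2 μ ~ N(3, 2)` scaled to
a target depth of 2×10⁵ reads per well, dispersion trend `1/θ = 0.05 +
2/μ`, dropout `logit π = −1.5 − 0.75·ln(μ+1)` (≈ 2% at μ = 20, ≈ 0.7% at
μ = 100 — dropout concentrated at low abundance, as limited-input plate
data show), library sizes log-normal (sd 0.3), and an optional per-row
batch preset. The default full-plate layout is 384-well: 32 treatments ×
3 replicates, 19 vehicle wells, and two 8-concentration dose compounds
in duplicate. Planted DE is a point-mass ±LFC on a random gene subset;
dose compounds give responsive genes a 4PL-shaped LFC in concentration.
Everything is deterministic given the seed, and the truth object records
planted LFCs, EC50s, size factors and dropout probabilities.

What the simulator does **not** emulate: gene–gene correlation beyond
shared batch factors, UMI collision, position-dependent edge effects
beyond the row preset, compositional shifts from cytotoxic treatments,
and mixed direction-biased signatures. Passing tests therefore
demonstrate correctness of the machinery and calibration under the
stated generative model, not robustness to every artefact of real
plates.

## Problem sizes

The packaged tests and the acceptance script run desk-scale versions of
each experiment: 600–2000 genes, 3 treated vs 19 vehicle wells, 10–20
simulation seeds per stochastic claim, 200–1000 permutations for
enrichment, and 50 seeds for EC50/weighting recovery. These sizes were
chosen so the full suite exercises every claim in a few minutes while
keeping Monte-Carlo error well below the asserted margins.

## Known limitations

* Marginal NB engines on zero-inflated nulls: see above; the QL engine
  is conservative (nominal p < 0.05 rate ≈ 0.025, where its reference
  implementation measures 0.02–0.03 on the same data) and the Wald/trend
  engines occasionally emit spurious down-calls, faithfully to their
  references.
* The EM weights assume dropout is independent of the design; a
  treatment that *causes* dropout (cytotoxicity) will be partially
  absorbed into π.
* Sequential variance decomposition depends on factor order for
  unbalanced designs; the order is recorded in the output.
* The rank-sum engine has essentially no power below ~5 replicates per
  side at screen-scale multiple testing; it is included for parity with
  single-cell-style workflows, not as a recommendation.
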