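# Methods

This note documents the models, estimators and numerical choices behind
`flylife`, and what the synthetic studies do and do not demonstrate.

## Demography

**Lifespan model.** Death times follow the Gompertz law with survival
S(t) = exp(−(a/g)(e^{gt}−1)); `a` (per day) is the baseline hazard, `g`
(per day) the demographic aging rate, MRDT = ln 2/g. Simulated deaths are
drawn by inverse-CDF sampling and rounded **up** to whole days, matching
daily mortality records; stress-assay times live on a 0.5-hour grid.

**Death calling.** Activity monitors report counts in 30-minute bins. A
fly's death is placed at the start of the first bin after the last bin with
non-zero activity; a fly active in the final bin is right-censored at assay
end. An all-zero row is assigned the first bin boundary and logged — the
rule is undefined for a fly that never moved, and flagging beats guessing.

**Quantiles.** Lifespan percentiles use the averaging (type-2) convention:
an even split yields the midpoint of the two straddling order statistics, so
half-day medians (58.5) are representable. With censoring (stress assays
only) the quantile is read off the Kaplan–Meier curve as the first time
survival drops to 1−q. Lifespan assays are treated as fully observed — every
death is recorded.

**Gompertz fitting / MRDT.** The estimator is a death-weighted least-squares
line through ln(hazard) against bin mid-age on a regular age grid (weekly
bins by default; the bin width is exposed because the choice is not
canonical). The per-bin hazard is the actuarial rate −ln(1 − d/n)/Δ, which
corrects for within-bin depletion of the risk set; with constant bin width
the binning bias affects the intercept, not the slope. Fitting requires at
least three bins with deaths. An exponential-lifetime cohort yields ĝ ≈ 0
and MRDT → ∞, reported as infinity rather than an error.

**Tests.** Log-rank uses the standard one-degree-of-freedom statistic with
hypergeometric variance at each distinct death time (via lifelines). The
two-sample Kolmogorov–Smirnov test uses the exact small-sample distribution
when n·m ≤ 10⁴ and the asymptotic one otherwise; it refuses censored input
(the log-rank test is the right tool there). The Wang–Allison test
thresholds at the pooled 90th percentile (averaging convention), builds the
2×2 table of (alive at/after threshold) × group, and applies the two-sided
Fisher exact test by the point-probability method (sum of tables no more
probable than the observed one). Fecundity differences per weekly time point
use the pooled-variance Student t. A "modified" Kolmogorov–Smirnov variant
exists in the survival literature but is not reproducible from available
descriptions; the standard two-sample KS is implemented and documented as
such.

## 3′-degradation bias and its correction

**The phenomenon.** In poly-A-primed libraries, degraded RNA (low RIN)
loses coverage with distance from the 3′ end; empirically coverage collapses
beyond ~750–1000 bp from the 3′ tail while the first 750 bp remain
comparable across samples. Uncorrected, this inflates short transcripts and
deflates long ones in the degraded group.

**Degradation model (simulator).** A fragment at 3′-distance d survives
with probability e^{−d/λ}, λ = λ₀·2^{(RIN−5)}, default λ₀ = 400 bp so RIN
5–8 spans λ 400–3200 bp. The exponential family is a stand-in chosen for its
closed forms (the true decay law is not identified by the empirical
profiles); any monotone family reproducing the collapse beyond ~750 bp would
serve. A transcript of spliced length L keeps the fraction
(λ/L)(1 − e^{−L/λ}) of its reads — degradation costs long genes more — and
surviving reads are placed multinomially over 25-bp 3′-distance bins with
mass ∝ e^{−d/λ}. Columns are then rescaled so that expected column sums
match the per-sample library size (a sequencer delivers fixed depth), which
is exactly what converts absolute read loss into a *relative*,
length-dependent bias between samples. Totals are negative binomial with
variance μ + φμ² (φ = 0.05 by default; φ = 0 degenerates to Poisson).
The 25-bp positional resolution keeps memory at desk scale; it is
configurable.

**Correction pipeline.**
1. *Coverage profile*: per sample, mean coverage by 3′-distance bin over
   transcripts ≥ 1500 bp, each transcript scaled to its own maximum, bins
   beyond a transcript's length excluded.
2. *Dominant isoform*: the most abundant transcript per gene; ties go to
   the longer transcript, then the lexicographically smaller id (a
   deterministic, content-free tie-break).
3. *Truncation*: walk exons from the 3′ terminus (right end on +, left end
   on −) accumulating spliced length to 750 bp, splitting the boundary exon;
   shorter transcripts are kept whole. Internally coordinates are 0-based
   half-open; GTF I/O converts to 1-based inclusive.
4. *Truncated counting*: sum positional counts with 3′ distance below the
   truncated length. Under the exponential model the expected truncated
   count is baseline·(λ/L)(1 − e^{−750/λ}) — the residual degradation factor
   no longer depends on L, which is why truncation plus a per-sample scale
   correction removes the length bias.
5. *Binned TMM*: genes are split into 10 equal-count quantile bins by
   **original** (pre-truncation) transcript length — after truncation the
   truncated lengths are nearly all exactly 750 bp and would tie massively;
   quantile bins on the original length are what guarantee populated bins.
   Within each bin the reference sample is the one whose upper-quartile
   relative abundance is closest to the mean (the standard TMM reference
   rule), per-sample factors are trimmed weighted means of M-values (trim
   30% on M, 5% on A, precision weights from delta-method binomial
   variances), factors are rescaled to geometric mean 1 within the bin, and
   counts are divided by their bin's sample factor. A second pass repeats
   the procedure on 10 average-CPM bins to remove expression-level-dependent
   residuals; the order (length-first by default) is configurable because
   the two-pass composition is not exactly commutative. Finally columns are
   rescaled to the original library sizes so downstream CPM stays
   interpretable (preserved to well within 0.5%).

The single-pair TMM factor reproduces edgeR's `calcNormFactors` to ~1e-8 on
random matrices (cross-checked against R in the test suite) and an
independent sort-based reimplementation to 1e-10.

## Differential expression

**Filter.** CPM > 1.0 in at least ⌈0.5 · n_smallest-group⌉ samples,
counted over all samples.

**Dispersion.** A single common φ maximizes the conditional NB
log-likelihood given group totals, Σ_g [Σ_i lnΓ(y_i + 1/φ) − n lnΓ(1/φ) +
lnΓ(n/φ) − lnΓ(s + n/φ)], after linear scaling of every column to the
geometric-mean library size. The maximization runs bounded on log₁₀φ ∈
[−6, 1]. Without replication the likelihood is flat; a configurable fallback
is returned with a loud warning. Tagwise shrinkage is deliberately out of
scope: the exact test below is defined for a common dispersion.

**Exact test.** Conditional on the total s of the two group sums, the
group-A sum is beta-binomial with shapes n_A/φ and n_B/φ (binomial(s,
n_A/(n_A+n_B)) at φ = 0). The two-sided p-value sums the probabilities of
all outcomes no more likely than the observed one (no doubling). Unequal
library sizes are equalized by linear scaling to the geometric mean and the
scaled sums rounded to integers; the approximation is benign for the ±20%
library-size spread simulated here, and the implementation matches edgeR's
`exactTest(rejection.region="smallp")` to ~1e-4 on NB data. Fold changes are
log₂ of the 0.5-prior-smoothed per-sample group means. Where counts have
not passed through the binned TMM adjustment, TMM-effective library sizes
(whole-matrix factors) guard against composition bias from genuinely
differential genes.

**FDR and tiers.** Benjamini–Hochberg step-up (via statsmodels). DEG tiers:
p < 0.05; p < 0.05 and |log₂FC| > 1; FDR < 0.05 and |log₂FC| > 2 (the "most
differentially expressed" tier), each labeled up/down by the sign of the
fold change.

**Enrichment.** One-sided hypergeometric upper tail of a gene set's overlap
with a top-N DEG list, evaluated over N ∈ {50, 100, 200, 500, 1000}, merged
by minimum p (recording the N), BH-adjusted across sets. Flat sets from GMT
files only; no ontology-graph weighting.

## What the validation studies show — and what they don't

The package validates itself on simulations with known truth
(`flylife.benchmarks`, also driven by `scripts/acceptance.py`):

- **Bias removal** (2000 single-isoform genes, log-uniform lengths
  0.4–8 kb, 3+3 samples, RIN 5–6 vs 7–8 confounded with genotype, no true
  DE): before correction the log₂FC-vs-log-length regression slope is
  overwhelmingly non-zero and per-length-decile rejection rates at α = 0.05
  vary ~17-fold; after truncation + binned TMM the slope is statistically
  indistinguishable from zero, deciles are homogeneous (χ² p ≫ 0.01), and
  the overall type-I error sits near the nominal 0.05.
- **Recovery**: ĝ within 10% of truth at n = 5000 (weekly bins), MRDT =
  ln 2/ĝ; φ̂ within [0.08, 0.12] for truth 0.10 at 1000 genes × 6 samples;
  planted ±2 log₂FC in 200 of 2000 genes detected with sensitivity > 0.95
  at observed FDR ≲ 0.07.
- **Null calibration** (1000 pairs of identical Gompertz cohorts, 300
  flies/group — the scale of pooled lifespan cohorts): rejection rates at
  α = 0.05 of ~0.05 (log-rank), ~0.03–0.04 (KS and Wang–Allison; both are
  genuinely conservative here — KS because daily recording ties its exact
  and asymptotic null distributions, Wang–Allison through Fisher-exact
  discreteness). Replicate streams use `SeedSequence.spawn`, numpy's
  recommended construction for independent replicates.

Problem sizes were chosen to make these studies precise at interactive
runtimes (the full acceptance sweep takes ~30 s on one CPU); all are
arguments, so larger sweeps are one call away.

The simulator emulates the *structure* of a real study, not its full
messiness: no isoform switching between conditions, no GC or positional
sequence bias, no batch effects beyond RIN, a single global decay family,
and NB noise with common dispersion. Passing these studies therefore shows
the pipeline removes the specific bias it models and is calibrated under its
own noise assumptions — it does not certify performance on real libraries,
and reproducing a particular study's DEG counts would require the original
sequencing data.

## Degenerate inputs and tie-breaks (summary)

- TMM: genes zero in either sample are excluded; < 3 genes surviving the
  trim → factor 1 with a warning; all-M-below-1e-6 → factor 1.
- Quantile binning with massive ties merges adjacent bins with a warning.
- Wang–Allison with an empty table margin → p = 1 with a warning.
- Zero-variance equal-mean t-test → p = 1.
- Exact test with total 0 → p = 1.
- Config files with unknown keys are rejected, listing every violation.
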