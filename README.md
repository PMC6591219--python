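# flylife

Demographic statistics and 3′-degradation-aware differential expression for
*Drosophila* longevity studies — with a ground-truth simulator of the whole
study design.

## The problem

Longevity experiments in flies produce two kinds of data that need careful
statistics:

1. **Demography.** Lifespan tables (deaths recorded daily), stress-resistance
   assays read out by activity monitors in 30-minute bins, and weekly
   fecundity counts. The standard summaries are the median lifespan *M*, the
   age of 90% mortality, and the mortality-rate doubling time
   MRDT = ln 2 / *g* under the Gompertz hazard *h(t) = a·e^{gt}*; the
   standard comparisons are the log-rank test (survival curves), the
   two-sample Kolmogorov–Smirnov test, the Wang–Allison 2×2 Fisher test
   (maximum lifespan), and Student's *t* (fecundity).

2. **Bulk RNA-seq with unequal RNA integrity.** When samples differ in RIN
   (RNA integrity number), degraded samples lose read coverage with distance
   from the 3′ end of each transcript, and the loss grows with transcript
   length. Comparing a degraded group against an intact one then yields
   spurious fold changes that track transcript length: short transcripts look
   overexpressed, long ones suppressed. `flylife` implements the correction:
   keep each gene's dominant isoform, truncate it to the **750 bp nearest its
   3′ end** (strand-aware, exon-splitting), re-count reads over that
   territory, then apply **TMM normalization separately within 10
   transcript-length bins** and again within 10 average-CPM bins. The
   adjusted pseudo-counts feed a **negative-binomial conditional exact test**
   (common dispersion by conditional maximum likelihood; the test reduces to
   the exact binomial test at zero dispersion), Benjamini–Hochberg FDR, and
   hypergeometric enrichment of top-*N* DEG lists against GMT gene sets.

Because the package is meant to be validated end to end, it ships a
first-class simulator: Gompertz lifespans, activity matrices with death
calling ("death at the start of the first 30-minute bin after the last
movement"), NB fecundity, and positional RNA-seq counts whose 3′ coverage
decays as exp(−d/λ) with λ = λ₀·2^(RIN−5). Every simulation records its
ground truth, so bias removal, power, FDR and parameter recovery are all
measurable.

## Worked example

```bash
cat > demo.yaml <<EOF
seed: 42
simulate: {n_genes: 1000, cohort_n: 100, n_de: 30, stress_n: 16, n_females: 20}
EOF
flylife full --config demo.yaml --outdir demo
```

```
INFO flylife.pipeline: simulate: 1000 genes, 6 samples, 6 cohorts
INFO flylife.pipeline: biascorr: 1000 genes adjusted, factor range [0.887, 1.143]
INFO flylife.detest: common dispersion estimate: 0.0510
INFO flylife.pipeline: detest: 1000 genes tested, 36 below FDR 0.05
INFO flylife.pipeline: survival: 6 cohorts summarized, 1 contrasts tested
done: 15 files in demo (config 12c2a854115b)
```

The run simulates a two-genotype, three-replicate study (RIN drawn in 5–8),
corrects the degradation bias, tests mutant vs control, and summarizes the
lifespan cohorts. `demo/lifespan_summary.tsv` holds per-cohort rows such as

```
cohort          n   median  q90   MRDT
E(z)/w:male:r1  100 47.0    63.0  9.02
```

(median and 90%-mortality age in days; MRDT from the death-weighted
log-hazard regression). `demo/survival_tests.tsv` gives the pooled contrast —
here `dM_percent=6.8`, `logrank_p=0.048` — and `demo/de_results.tsv` the
per-gene table. Of 30 planted fold changes (|log₂FC| = 2) the run recalls 17
in the top tier (FDR < 0.05 and |log₂FC| > 2), e.g.

```
gene_id   logFC   logCPM  p       FDR     tier
gene0331  2.478   10.75   ~0      ~0      top
gene0355  -2.455  9.86    ~0      ~0      top
```

`demo/manifest.json` records the config hash, seed and a checksum per output;
re-running with the same config and seed reproduces the checksums bit for bit.

The same machinery is available as a library:

```python
from flylife import GompertzParams, simulate_lifespans, fit_gompertz
s = simulate_lifespans(GompertzParams(a=0.001, g=0.1), 5000, seed=1)
fit_gompertz(s).mrdt          # ~6.9 days = ln2/0.1
```

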