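# pneumotyper

Compositional state typing and transition dynamics for longitudinal,
low-biomass 16S rRNA microbiota profiles — built for bronchoalveolar
lavage fluid (BALF) cohorts such as post-transplant lung surveillance
series, where bacterial load spans five orders of magnitude and relative
abundances alone are misleading.

## What it does

Given an OTU count table, per-sample metadata (patient, months
post-transplant, qPCR 16S copies/ml, a host-gene expression panel,
anellovirus loads) and an optional contaminant blocklist, the pipeline:

1. **Filters and rarefies** — drops OTUs without a phylum assignment,
   blocklisted OTUs, and samples with < 10⁴ reads or no load
   measurement; subsamples every sample to the minimum depth
   (multivariate hypergeometric).
2. **Quantifies diversity** — Hill numbers H₀ (richness),
   H₁ = exp(Shannon), H₂ (inverse Simpson), H∞ = 1/max pᵢ (inverse
   Berger–Parker; its reciprocal is the dominance of the top taxon);
   Bray–Curtis, Sørensen and Morisita–Horn dissimilarities; one-factor
   PERMANOVA (pseudo-F under label permutation) with pairwise
   Benjamini–Hochberg-corrected contrasts.
3. **Discovers pneumotypes** — partitioning around medoids (PAM) on the
   Bray–Curtis matrix, with the number of states k chosen by maximum
   average silhouette width s̄, s(i) = (b−a)/max(a,b). Absolute
   abundances aᵢ = pᵢ × load recover the biomass axis.
4. **Tests enrichment** — aligned rank transform (ART) ANOVA contrasting
   each state against the other states combined over the 30 most
   dominant taxa, with per-taxon rank contrasts and FDR control.
5. **Links states to host genes** — a randomized-forest learner with
   repeated-CV tuning of mtry/ntrees, Boruta shadow-feature selection
   (importance Z vs shadowMax, binomial hit test, tentative rough fix),
   percentile importance confidence intervals over refits, and
   stepwise-AIC linear models for bacterial/viral loads.
6. **Models dynamics** — per-patient state sequences feed a first-order
   Markov chain: MLE transition matrix P̂, patient-bootstrap percentile
   CIs, structural properties (communicating classes, periodicity,
   recurrent/absorbing states, stationary distribution), plus chi-square
   checks of memorylessness and time-homogeneity.

A first-class synthetic cohort generator (`pneumotyper.synthetic`)
emulates the assumed data structure — four latent state archetypes
(balanced core community, two pathogen-dominated, one
microbiota-depleted with ~100× lower loads), Dirichlet-multinomial
composition noise, state-shifted gene expression and viral loads, and a
ground-truth Markov chain — so every stage can be validated against a
recoverable truth.

## Worked example

```python
from pneumotyper import AnalysisConfig, generate_cohort, run_pipeline

cfg = AnalysisConfig(k_range=(2, 10), n_permutations=999,
                     boruta_max_iter=50, ntrees=300)
table, info, truth = generate_cohort(seed=11)   # 64 patients, 282 samples
report = run_pipeline(cfg, table, info)
print("\n".join(report.log))
print(report.markov_model.to_frame().round(3))
```

prints

```
seeds: rarefaction=7001 permanova=7002 boruta=7003 markov=7004
filter: kept 282 samples / 57 OTUs; dropped 0 samples, 3 OTUs
rarefy: depth 11412
cluster: k=4 ASW=0.4948
hostmodel: Boruta confirmed ['IFNLR1', 'IL10', 'IL1RN', 'LY96', 'MRC1', 'PDGFD'] in 29 iterations
hostmodel: stepwise-AIC load model terms ['IFNLR1', 'IL10', 'IL1RN', 'MRC1', 'PDGFD'] (AIC -149.19)

       0      1      2      3
0  0.651  0.094  0.085  0.170
1  0.423  0.231  0.038  0.308
2  0.400  0.100  0.350  0.150
3  0.394  0.076  0.091  0.439
```

Silhouette selection recovers the four planted states (k=4); Boruta
confirms exactly the six genes given nonzero state shifts by the
generator; and the fitted transition matrix shows the balanced state
(cluster 0 here) as the most stable, with a 65% recurrence probability
and frequent returns to it from every other state.

The same stages are available from the shell:

```bash
pneumotyper simulate --seed 11 -o demo/
pneumotyper run --counts demo/counts.tsv --meta demo/metadata.tsv \
    --taxonomy demo/taxonomy.tsv -o results/
pneumotyper cluster --counts demo/counts.tsv -o labels.tsv   # k=4 ASW=0.4959
```

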