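# Methods

## Data model and preprocessing

The pipeline joins a samples × OTUs read-count matrix (with per-OTU
taxonomy down to genus) to per-sample metadata: patient identity,
months post-transplant, total 16S rRNA gene copies per ml BALF (qPCR),
a 31-gene host expression panel on the log2-fold scale relative to a
reference gene, anellovirus loads (log10 genome copies), and
categorical clinical flags. Sampling times are binned into five
ordinal windows with default month boundaries (0, 1.5], (1.5, 6],
(6, 12], (12, 24], (24, ∞). These boundaries are configuration, not a
constant: the window grid is anchored on the early post-transplant
period in which viral loads peak, and analyses should not be sensitive
to the exact cut points.

Filtering removes OTUs with no phylum assignment, OTUs on an optional
contaminant blocklist (a helper derives one as "≥ min_count reads in at
least one negative-control sample", default min_count = 1), and samples
with fewer than 10⁴ reads or without a load measurement. Rarefaction
subsamples each remaining sample without replacement (multivariate
hypergeometric) to the minimum per-sample total; prevalence is computed
on the rarefied table (presence = count > 0), a choice exposed as a
flag because computing it pre-rarefaction is equally defensible.
Absolute abundance is aᵢ = pᵢ × load, so per-sample absolute rows sum
to the measured load exactly.

## Diversity

Hill numbers are computed in closed form: H₀ = #{pᵢ > 0},
H₁ = exp(−Σ pᵢ ln pᵢ), H₂ = 1/Σ pᵢ², H∞ = 1/max pᵢ; dominance is 1/H∞.
Generic orders q are exposed (`renyi_diversity`) but only
q ∈ {0, 1, 2, ∞} are exercised by the tests. Beta diversity offers
Bray–Curtis Σ|x−y|/Σ(x+y), Sørensen (Bray–Curtis on presence/absence)
and Morisita–Horn 1 − 2Σxᵢyᵢ/((d_x+d_y)·X·Y), which is invariant to
per-sample scaling.

PERMANOVA is one-factor: SS terms are built from squared
dissimilarities, pseudo-F = ((SS_T − SS_W)/(k−1))/(SS_W/(n−k)), and the
Monte-Carlo p-value uses the +1-corrected estimator
(1 + #{F_perm ≥ F_obs})/(n_perm + 1) with ties resolved conservatively
(≥). An exact mode enumerates every label permutation for small n.
Longitudinal samples are treated as exchangeable units — there is no
strata or repeated-measures adjustment, mirroring common field
practice; p-values should therefore be read as descriptive when
patients contribute multiple samples.

## Pneumotype discovery

Clustering is k-medoids on the Bray–Curtis matrix of relative
abundances (an absolute-abundance flag exists; phylum-level runs are
supported by pre-aggregating counts). Instances with at most 10,000
candidate medoid subsets are solved exactly by enumeration, making
small problems provably optimal; larger instances use the canonical
BUILD + SWAP heuristic with steepest-descent swaps and lexicographic
tie-breaking, which is deterministic and matches the behaviour of the
standard reference implementations (heuristic PAM is a local search
and can sit slightly above the global optimum on adversarial
instances). k is selected over a configurable range (default 2–10) by
maximum average silhouette width, ties to the smaller k; a best ASW
below 0.3 flags "weak structure". Silhouettes follow the usual
convention s(i) = (b−a)/max(a,b) with s = 0 for singleton clusters.

## Enrichment

Each state is contrasted against the remaining states combined in a
two-factor layout (group × taxon) over the 30 taxa with the largest
summed absolute abundance. The response is log10(absolute
abundance + 1); since inference is rank-based downstream, the exact
monotone transform matters only through the alignment step (see
below). The aligned rank transform computes, per effect, aligned
responses Y′_A = y − μ̂ᵢⱼ + μ̂ᵢ, Y′_B = y − μ̂ᵢⱼ + μ̂ⱼ,
Y′_AB = y − μ̂ᵢ − μ̂ⱼ + μ̂, where marginal and grand means are
unweighted means of cell means, so the alignment strips the other
effects exactly in complete proportional layouts (each sample
contributes one observation per taxon, so the layout here is always
proportional). Aligned responses are ranked (average ties, after
collapsing float dust at 1e-10 relative) and submitted to a Type-II
factorial ANOVA implemented on least-squares residual differences and
cross-checked against statsmodels. One caveat discovered during
validation: the ART F statistics are *not* invariant to monotone
transforms of the response, because alignment subtracts means; only
the post hoc rank contrasts are.

Post hoc, per-taxon contrasts are differences in mean global rank
between target and rest, with a normal approximation using the
within-stratum rank variance, and Benjamini–Hochberg correction across
taxa. Incidence percentages in target vs rest are reported alongside.

## Host-gene models

The forest learner is bagged decision trees with per-split random
feature subsetting of size mtry (bootstrap rows, OOB estimates) — the
Breiman random-forest contract. Importance is the per-tree out-of-bag
permutation importance normalized by its standard deviation across
trees (a Z score); mean-decrease-impurity is exposed but not default.
Tuning is repeated stratified k-fold CV (default 10 × 3) over an
(mtry, ntrees) grid, scored by accuracy (classification) or RMSE/R²
(regression).

Boruta appends a column-shuffled shadow copy of every gene each
iteration, fits the forest on the doubled matrix, and scores a hit when
a real gene's Z exceeds the iteration's shadowMax. Hits accumulate
against Binomial(iters, ½): a two-sided test at α (default 0.01, from
iteration 5 onward) confirms or rejects; undecided genes after
max_iter (default 100; early exit once all are decided) are Tentative
and resolved by comparing their median Z to the median shadowMax.
Importance confidence intervals are percentile intervals (default 99%)
of Z over repeated refits with distinct seeds, reported with OOB
accuracy/per-class recall or OOB percent variance explained.

Stepwise model selection minimizes AIC = n·ln(RSS/n) + 2(k+1)
bidirectionally from the intercept-only model; the final model is refit
by OLS for coefficients and t statistics. Note that AIC's penalty of 2
admits a lone spurious regressor with probability P(χ²₁ > 2) ≈ 0.16 —
selection "consistency" expectations are calibrated accordingly. Radar
summaries use per-gene median normalization: each gene's state medians
are divided by their maximum, which becomes exactly 1; genes with a
non-positive maximum are emitted as missing.

Samples with missing gene values are dropped per-model with a logged
count.

## Markov dynamics

Per patient, samples sorted by (window, months, sample-id) define
transitions between consecutive samples regardless of gap length (a
documented simplification); a `graft_id` flag starts a new sequence at
re-transplantation. P̂ is the row-normalized pooled count matrix; rows
with no outgoing transitions are flagged undefined rather than
smoothed (optional Laplace +α exists, default off). Bootstrap
resamples *patients* with replacement — transitions within a patient
are dependent, so the sequence is the exchangeable unit — and CIs are
percentile intervals (default 95%, 100 replicates).

Structural properties come from the support digraph: communicating
classes are strongly connected components (networkx), recurrent classes
are the closed ones, a state is absorbing iff its self-probability is
1, class periods use the BFS-level gcd construction, and the stationary
distribution is obtained by power iteration to 1e-12 when the chain is
irreducible and aperiodic. The property classifier is verified against
an independent matrix-power path-enumeration oracle on every 4-state
support graph with defined rows (15⁴ graphs).

The memorylessness check compares observed (previous, next) tables
within each stratum of the middle state to the first-order expectation,
summing per-stratum Pearson χ² with df Σ(r−1)(c−1); expected cells
below 5 raise a warning rather than being pooled (pooling rules are
ad hoc, and at the cohort sizes used for calibration the asymptotic
approximation is adequate — type-I error is 0.043–0.048 at 300
patients × 6 samples). Time-homogeneity is a standard state × window
contingency χ² without continuity correction. Both are this package's
constructions of the informal "chain property" checks common in the
field.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
with defaults chosen as the study conditions:

* **Panel**: 22 core OTUs with geometrically decaying weights (genera
  drawn from the oropharyngeal taxa typical of BALF), two designated
  pathogen OTUs (*Staphylococcus*-like, *Pseudomonas*-like), 33 rare
  background OTUs and 3 taxonomically ambiguous OTUs (filter fodder).
* **States**: balanced (0.93 core + 0.07 rare, Dirichlet concentration
  80, load 10^N(4.5, 0.35)); two dominated states (0.75 mass on the
  designated OTU, concentration 60, load 10^N(5.3, 0.4)); depleted
  (0.08 core + 0.92 uniform, concentration 40, load 10^N(2.4, 0.45) —
  a median ~125× below balanced — and lower sequencing depth).
  Within-state dispersions are Dirichlet-multinomial and are set so
  that silhouette-based selection recovers k = 4; they are a design
  choice of the generator, not estimates from any cohort.
* **Covariates**: 31 named immune/remodeling genes; six carry additive
  state shifts of |1.0–1.4| log2 units against N(0, 0.5) noise (an
  SNR ≥ 2 planted-feature regime); three anellovirus genera have
  state-dependent log10 means, lowest in the depleted state.
* **Dynamics**: 64 patients with 1–8 samples each over 49 months; state
  sequences follow a ground-truth chain whose diagonal encodes high
  balanced-state recurrence (0.63), intermediate depleted recurrence
  (0.42), and near-disconnection between the two pathogen states, with
  initial distribution (0.49, 0.08, 0.33, 0.10) matching the intended
  state frequencies.

What the generator does **not** emulate: compositional correlations
between taxa beyond the Dirichlet, contaminant structure, antibiotic
or clinical feedback on transitions, time-inhomogeneity, and
measurement error in qPCR loads. Passing recovery tests therefore
demonstrates internal consistency of the inference chain under its own
assumptions, not performance on real BALF data.

## Problem sizes and numerical choices

Simulation-based checks use: 1000 replicates for type-I calibration of
PERMANOVA (n = 16, 199 permutations), ART-ANOVA (2 × 5 layout, n = 60)
and the memorylessness test (300 patients × 6 samples); 200 replicates
of 500 patients × 6 samples for transition-matrix recovery (median
max-entry error is the reported statistic — a single draw has ~0.033
standard error in the rarest rows) and bootstrap coverage; 100 random
instances for PAM oracle equivalence. All randomness flows through
named seeds; reruns are byte-identical, which the test suite asserts
on the full pipeline's TSV outputs. Ties in permutation tests are
counted conservatively (≥ with +1 correction); BH adjustment uses
statsmodels; silhouettes of singletons are 0; empty samples propagate
as explicit missing values with warnings rather than NaN surprises.

## Known limitations

* PERMANOVA ignores within-patient dependence (see above).
* The importance Z scale is this package's own; thresholds quoted on
  other implementations' importance scales are not transferable.
* Heuristic PAM above the exact-search size bound is a local search.
* The memorylessness χ² is asymptotic; at small cohort sizes its
  expected-cell warning should be taken seriously.
* Bootstrap CIs for transition rows visited rarely can be wide and
  slightly anti-conservative at extreme entries (0 or 1).
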