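# Methods

`orofaecal` implements the statistical workflow for comparing the microbiota
of two gastrointestinal-tract regions — the oral cavity and the distal gut
(faeces) — sampled non-invasively from the same wild bird population, with a
subset of individuals sampled in both regions. This note records the models,
the numerical choices, and what the synthetic benchmark does and does not
establish.

## Data model and filtering

The central object is an integer samples × OTUs count table (OTU = 16S
cluster at 97% identity). Two filters precede analysis:

* **Contaminant filter.** OTUs whose class or order label is `Chloroplast`
  or `Streptophyta` (case-insensitive) are treated as diet-derived plant
  material; OTUs with no phylum assignment are treated as sequencing
  artefacts. Both are removed. Samples emptied by filtering are dropped (a
  zero sample has no defined dissimilarity to anything), with a logged
  warning.
* **Prevalence filter** (differential-abundance scan only): OTUs detected in
  fewer than 5 samples (configurable) are excluded; the retained read
  fraction is logged.

Rarefaction subsamples every sample without replacement to a common depth
(default: the smallest post-filter sample total) via multivariate
hypergeometric draws — zeros stay zero, row sums are exact, and a single
draw is used rather than an average over draws. All diversity,
ordination and community tests run on the rarefied table. The
differential-abundance scan runs on the *unrarefied* (filtered) table: its
model carries sequencing depth as an explicit offset, which is informative
only when totals vary.

## Alpha diversity and its contrasts

Per sample: observed richness, Shannon entropy in nats
(−Σ p ln p; base switchable), and bias-corrected Chao1
(S_obs + F1(F1−1)/(2(F2+1)); the classic F1²/(2F2) variant is available but
is infinite when singletons exist without doubletons). The oral/faecal
contrast is a likelihood-ratio test between random-intercept linear mixed
models fitted by maximum likelihood (not REML — the compared models differ
in fixed effects):

    metric ~ region + (1 | individual)   vs.   metric ~ 1 + (1 | individual)

with χ² on 1 df. Group means ± SE are purely descriptive (sd/√n per
region). Sex is tested per region by one-way ANOVA, body condition by a
single-slope regression on the scaled mass index (below).

## Beta diversity

Four pairwise indices: Bray–Curtis (Σ|x−y| / Σ(x+y)), binary Jaccard
(1 − shared/union on presence–absence; the quantitative variant exists
behind a flag), and unweighted / weighted UniFrac on a rooted OTU
phylogeny. Unweighted UniFrac is the fraction of branch length leading
exclusively to one community's OTUs among branch length leading to either;
weighted UniFrac is Σ l_b |p_b(x) − p_b(y)| over branches, normalised by
default by Σ_j d_j (p_j(x)+p_j(y)) over tips (root-to-tip distance d_j),
bounding it to [0, 1]. Unrooted input trees are midpoint-rooted with a
logged notice. UniFrac is evaluated through a branch × OTU incidence matrix
built once per distance-matrix call, so all sample pairs are vectorised
branch sums.

PCoA is classical scaling: Gower double-centering of −½d², symmetric
eigendecomposition, axes sorted by eigenvalue. Negative eigenvalues (normal
for Bray–Curtis/Jaccard) are reported untouched — no Cailliez/Lingoes
correction — and variance proportions are relative to the positive
eigenvalue sum.

## Community-level tests

**PERMANOVA** partitions squared dissimilarities: SS_total = Σ_{i<j} d²/n,
SS_within pooled over groups, pseudo-F = (SS_A/df_A)/(SS_W/df_W). Because
paired samples from one bird are not independent, the null permutes region
labels only *within* an individual (strata). For the study layout — 8
individuals with both samples plus singletons — this space holds exactly
2⁸ = 256 permutations; whenever the distinct count is below the requested
number of permutations the space is enumerated completely and
p = #{F* ≥ F}/N over the full enumeration, identity included (ties count).
Monte-Carlo sampling otherwise, with p = (1 + exceedances)/(1 + draws).
Note that tiny designs are intrinsically granular: with two groups of
three, the observed labelling and its group swap always tie, so exhaustive
p can never fall below 2/20 — calibration claims about the 5% level are
only meaningful on designs with enough distinct partitions (the test suite
uses 6+6).

**Dispersion contrast** (homogeneity of multivariate dispersion): samples
are embedded by PCoA keeping negative-eigenvalue axes as imaginary
coordinates; squared distance to the own-group centroid is the positive-axis
sum minus the negative-axis sum, floored at zero; group centroids (not
spatial medians) and a parametric one-way ANOVA on the distances give one F
and p per metric, mirroring the table layout the workflow reports.

**Mantel test**: Pearson r on strictly-lower-triangle entries, null by
jointly permuting one matrix's rows and columns; one-sided ("greater") by
default.

## Within-individual concordance

For individuals sampled in both regions: Pearson correlation of paired
alpha-diversity values; a Mantel comparison of the oral and faecal distance
sub-matrices (both reindexed by individual); and per-OTU Spearman rank
correlations of relative abundances across pairs, restricted to OTUs
detected in both regions of the paired subset. Ties get average ranks; an
OTU whose oral or faecal vector has fewer than three distinct values is
reported as missing rather than zero. The summary is the mean and
interquartile range of the defined correlations.

## Differential abundance: permutation mixed-model scan

Per OTU, counts are Box-Cox transformed (shift +1 to admit zeros; λ chosen
by Gaussian profile likelihood on [−2, 2]) and modelled as

    boxcox(count + 1) − boxcox(depth) ~ intercept + region + (1 | individual)

The depth offset enters with coefficient fixed at 1, i.e. subtracted from
the response. **One λ — the response's estimate — is used for both terms.**
An offset constrained to coefficient 1 is only meaningful on the response's
own transformed scale; profiling a second λ on the ~37 sample depths is so
noisy (replicate surveys of one process gave estimates between 0.05 and
0.75) that the un-cancelled depth term behaves as an arbitrary survey-wide
covariate, and simulations showed per-survey false-positive rates swinging
between 0 and 4× the nominal level. With the shared λ the level is held.
Separate estimation remains available (`shared_lambda=False`).

The statistic is the ML deviance change when the region term is dropped
(Δdev ≥ 0 for nested fits, asserted). Significance is by permutation: the
per-sample (count, depth) pairs are jointly reshuffled across samples —
preserving the count–depth coupling while breaking any region association —
with the design held fixed, both models refitted per draw, and
p = (1 + #{Δdev* ≥ Δdev}) / (1 + n_perm). Permutations are unrestricted
across samples (strata apply to the community-level tests, not here);
resampling with replacement is available behind a flag. Default
n_perm = 10,000; the test suite uses 99–499.

The mixed model itself is fitted by profiling: for a single random
intercept, given the variance ratio λ_v = σ²_ind/σ²_res, the GLS fixed
effects and the residual variance have closed forms through per-group sums,
leaving a 1-D maximisation in λ_v (coarse log-grid, golden-section
refinement, explicit boundary check at λ_v = 0). All permutation replicates
share the design, so the likelihood evaluations are vectorised across
replicate response vectors; a 10⁴-permutation null costs a few hundred
vectorised evaluations. The fitter is validated against a dense-covariance
variance-grid oracle (1e-4 deviance agreement) and statsmodels' ML MixedLM.

Multiplicity is handled with q-values: π̂0 is the λ-grid estimator on
λ = 0.05…0.95 smoothed by a cubic least-squares polynomial evaluated at
λ = 0.95 (a low-order polynomial is the stable choice on a fixed 19-point
grid; the raw grid maximum, clamped to (0, 1], is the fallback), and
q_i = π̂0 · min_{p_j ≥ p_i} m p_j / rank_j — with π0 = 1 this is exactly
Benjamini–Hochberg. An OTU is called significant when **both** its
permutation p and its q fall below 0.05; the direction flag (+oral /
+faecal) is the sign of the fitted region contrast. Per-OTU failures are
recorded and the scan continues. For the heatmap companion file,
significant OTUs are written as log10(count+1) rows ordered by the sheared
phylogeny's leaf order, together with the subtree in newick.

A structural interaction worth knowing: the smallest attainable q is
π̂0 · m / (n_perm + 1) / K, with K the number of p-values tied at the
permutation floor. With m in the hundreds, the joint p-and-q rule needs
either n_perm in the thousands (the default 10,000 gives a q floor around
0.02/K) or a large simultaneous floor count. Scans run with only a few
hundred permutations cannot produce q < 0.05 discoveries unless dozens of
OTUs hit the floor at once — a property of the q-value floor, not of the
effect sizes.

A related caveat for the diversity contrast: the likelihood-ratio χ²₁ test
for the region fixed effect is asymptotic, and at survey sample sizes
(37 samples, 29 individuals) ML fixed-effect LRTs in mixed models are
known to be slightly anticonservative — the package's own null calibration
measures an empirical level around 0.07 at nominal 0.05, and an
independent mixed-model implementation reproduces it. The permutation
tests (PERMANOVA, dispersion, Mantel, the OTU scan) hold their level
exactly, which is the argument for permutation inference wherever the
workflow offers it.

## Scaled mass index

Body condition is mass standardised to a reference tarsus length L0:
SMI = mass · (L0/tarsus)^b, where b is the standardised major axis slope of
ln(mass) on ln(tarsus) (OLS slope divided by |r|; equivalently the sd ratio
signed by r). L0 defaults to the mean tarsus of the analysed sample;
samples missing either measurement are excluded.

## Synthetic data generator

The generator draws paired two-region surveys with the statistical
structure the analyses assume. Defaults are fixed at the study design and
are not resampling knobs:

| parameter | default | rationale |
|---|---|---|
| individuals / paired | 29 / 8 | 20 oral + 17 faecal samples, 8 birds in both |
| OTUs | 1127 | survey-scale richness |
| OTU pools | 34% shared, 48% oral-only, 18% faecal-only | observed region overlap |
| baseline log-abundance sd | 1.2 | realistic abundance heterogeneity |
| individual intercept sd | 0.6 (log scale) | moderate repeatability, shared across a bird's two samples |
| Dirichlet concentration | oral 150, faecal 60 | faecal communities more overdispersed |
| depth | LogNormal(ln 6000, 0.4) | uneven depth, minimum ≈ 2000 |
| differential OTUs | 30 at 4-fold (log2 = 2), balanced ± | detectable but not trivial |
| contaminants | 7% chloroplast + 4% unassigned phylum | exercises the filter |
| sex / body-size effects | none | null covariates, switchable |

Composition is drawn Dirichlet-multinomial: per sample,
Dirichlet(c_region · softmax(baseline + region shift + individual
intercept)), then a multinomial at the sample's lognormal depth. Region
exclusivity is a −7 log-unit penalty in the other region. The random tree
is sequential coalescence with Exponential(1) branch lengths. Everything is
deterministic given the seed (byte-identical files).

What the generator does **not** emulate: real phylogenetic signal in
abundances (tree and abundances are independent), taxonomic correlation
structure, chimeras/contamination gradients, and batch effects. Passing
tests therefore demonstrate correctness of the statistics under the assumed
sampling model, not robustness to those real-data features.

Two benchmark configurations deviate deliberately from the survey preset,
because they measure different things. The *recovery* benchmark (spiked
differential OTUs scored against ground truth) disables the region pools
and equalises the two concentrations: exclusive-pool OTUs and dispersion
differences are genuine region signals, and counting them as false
positives would make the FDR meaningless. The *effect-size consistency*
check uses high concentrations and a small individual sd, since it
validates the planted fold change, not survey noise.

## Numerical conventions and edge cases

* Permutation p-values: (1 + exceedances)/(1 + draws) for Monte-Carlo,
  plain fraction over the complete enumeration (identity included) when the
  strata space is exhausted; ties always count as exceedances.
* Master seed split per pipeline stage through `numpy` seed sequences;
  per-OTU streams are keyed on the OTU id, so results are invariant to
  column order.
* Constant transformed response in the scan → Δdev = 0, p = 1 with a
  warning. Spearman with <3 distinct values → missing. Chao1 with no
  doubletons → bias-corrected form stays finite.
* All file outputs are UTF-8, LF, tab-separated, full float precision.

## Problem sizes used by the test and acceptance runs

Simulation-based checks are sized for a single CPU: type-I calibrations use
500–1000 replicates at the smallest designs that make the 5% level
measurable; the recovery benchmark uses 10 replicate surveys of 240 OTUs at
199 permutations; the acceptance script runs the full pipeline at the
survey preset with 600 OTUs, 1999 scan permutations and the exhaustive
256-permutation community tests.
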