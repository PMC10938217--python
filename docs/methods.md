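# Methods

## Scope

`cadmb` implements the downstream statistics of a cross-sectional
microbiome–CAD cohort analysis: everything from an ASV count table,
taxonomy, phylogeny and clinical metadata to diversity, differential
abundance, a dysbiosis index, metabolite ranking and association models.
Upstream read processing (demultiplexing, denoising, contaminant
filtering) and the wet-lab assays that produce ImP and IL-6 measurements
are out of scope; their outputs are inputs here.

## Synthetic cohort model

The generator emulates the data structure of a 254-participant HIV cohort
stratified by coronary CT-angiography (114 no CAD / 80 nonobstructive /
60 obstructive). It is the package's only data source and is treated as
first-class, tested code.

**Community model.** Each cohort draws genus base proportions once: the
twelve dysbiosis-index genera receive fixed prevalent shares (2% each for
the three enriched genera, 3% each for the nine depleted genera — these
are common gut taxa, and the analysis presumes they are detectable),
while the background genera split the remaining share by a symmetric
Dirichlet with concentration 0.3, giving realistic long-tailed sparsity.
In the obstructive group the numerator genera are multiplied by
`effect_up` (default 3.0) and the denominator genera by `effect_down`
(default 0.3), then proportions are renormalised. Per sample, genus
shares are additionally perturbed by i.i.d. lognormal factors with log-SD
`genus_log_sd` (default 1.0) — inter-individual taxon abundances in real
gut data vary over orders of magnitude, and without this layer a
12-genus log-ratio index would separate the groups essentially perfectly
— followed by a Dirichlet draw with concentration
`sample_concentration` (default 300) and multinomial read sampling.
ASVs are allocated to genera proportionally to genus abundance and split
within genus by stick-breaking, so abundant genera carry more ASVs.
Sequencing depth is negative-binomial with mean `depth_mean` (default
20 000) and dispersion 15, floored one read above the default rarefaction
depth so that no sample is lost in a default run.

**Phylogeny.** A random bifurcating topology over the ASVs (successive
random pair joins) with Exp(0.1) branch lengths. It carries no biological
signal; it exists so that Faith PD is computable and its conventions
testable.

**ImP.** log ImP = 2.71 + `imp_coupling` × z + N(0, `imp_noise_sd`),
where z is the standardised summed relative abundance of the producer
genera (Veillonella, Ruminococcus gnavus group). The baseline puts the
noise-free median near 15 nM, the right order of magnitude for
circulating ImP. Default coupling 0.6 and noise 0.6 yield roughly a
threefold median ImP elevation in the obstructive group — strong enough
for the ranking stage to find, without making ImP a perfect proxy for
the index.

**Covariates.** Age, Framingham score and HIV duration are Gaussian with
group offsets proportional to `confounding_shift` (in SD units; default
1.0 reproduces the gradient typical of CT-angiography HIV cohorts —
obstructive participants older, higher Framingham, longer infection).
IL-6 is lognormal with the same pattern; binary covariates (MSM, CD4
nadir < 200, statins, abacavir, antibiotics, male sex) are Bernoulli with
group-specific rates that collapse to a common rate when
`confounding_shift = 0`. With all effect knobs at null
(`effect_up = effect_down = 1`, `imp_coupling = 0`,
`confounding_shift = 0`) the three groups are exchangeable by
construction; the test suite uses this for type-I-error calibration of
every downstream stage.

**Seeding.** One master seed fans out through named `SeedSequence`
streams (counts, tree, covariates, ImP, depths), so cohorts are
bit-reproducible and stages can be regenerated independently.

**What the generator does not emulate.** Read-level error, chimeras and
contaminants; realistic phylogenetic signal; correlation between
covariates and the microbiota (confounding here affects outcome and
covariates, not community composition); any attempt to match a real
cohort's abundance spectra. Passing tests therefore demonstrate that the
statistics are implemented correctly and calibrated, not that the
biological effect sizes of any real cohort are recoverable.

## Ecology stage

- **Rarefaction** is true without-replacement subsampling (multivariate
  hypergeometric), one draw per analysis at depth 6247, seeded; samples
  below depth are dropped and itemised in a warning. Repeated-rarefaction
  averaging is deliberately not offered.
- **α diversity**: observed ASVs; Shannon entropy with natural log
  (configurable base); Faith PD via scikit-bio, root-inclusive (the stem
  from the root to the observed subtree counts). The convention is stated
  because toolkits differ; an empty sample has PD 0.
- **β diversity**: Bray-Curtis, 1 − 2·Σmin/(Σx+Σy), computed on the
  rarefied table (the paper trail for whether β diversity used rarefied
  counts is ambiguous in this literature; rarefied is the package's
  default substrate for everything downstream of rarefaction).
- **PCoA** is the classical double-centred eigendecomposition. Negative
  eigenvalues (Bray-Curtis is non-Euclidean) are reported but excluded
  from both the coordinates and the proportion-explained denominator; no
  Cailliez correction.
- **PERMANOVA** uses Anderson's pseudo-F on squared distances, one factor
  only. p-values use the add-one permutation estimator
  (1 + #{F* ≥ F})/(1 + n_permutations), which cannot return 0; for
  two-group designs where C(n, n1) does not exceed the requested
  permutation count the null is enumerated exhaustively instead and the
  exact fraction is returned. F-statistic ties are compared with a
  relative tolerance of 1e-12 so that enumeration is not at the mercy of
  floating-point noise.

## Differential abundance

A two-stage LEfSe-style procedure at genus level: Kruskal-Wallis screen
at raw α = 0.05 (no FDR — the original method's convention; constant
taxa get p = 1), then a linear-discriminant effect size on the passing
taxa. Abundances are scaled to parts-per-million; for each of 30
bootstrap rounds a two-thirds subsample of each class feeds a
ridge-regularised Fisher discriminant (ridge 1e-6 × mean diagonal,
logged); the per-taxon effect is the average of the raw class-mean
difference and the taxon's share of the projected class-mean difference,
and the reported score is sign·log10(1 + |mean effect|), thresholded at
2.0. Comparisons are one-vs-one between named groups; there is no
subclass (within-class) stage because the study design has none, and no
multi-class cladogram.

## Dysbiosis index

ln((Σ numerator + ε)/(Σ denominator + ε)) on the rarefied genus table,
ε = 1e-6 (keeps sparse samples finite while perturbing typical values by
< 1%). Genus matching is by a normalisation pass that collapses case,
punctuation, brackets and common family-name misspellings, so SILVA
variants like "Ruminococcacea UCG 005" resolve to "Ruminococcaceae
UCG-005"; absent genera are treated as zero columns with a warning.
Quantiles use linear interpolation between order statistics (the numpy
default) and elevation is strictly above the 75th percentile — with ties
at the threshold this flags at most ⌈n/4⌉ samples. Published
cohort-specific thresholds (an index cut of −1.06, an ImP cut of
25.1 nM) are properties of one cohort's empirical quartiles, not
recomputable constants, and are not targets here.

## ImP taxa ranking

For each of 200 bootstrap resamples: fit a random-forest regression of
ImP on genus abundances (200 trees, mtry = p/3; 200 trees rather than a
larger forest keeps the 200-resample procedure tractable on a single
workstation, and on planted fixtures the top-k membership is unchanged
versus larger forests), score taxa by permutation importance evaluated
on the rows left out of the bootstrap draw (an out-of-bag set at the
resample level), split taxa into positive/negative by the sign of their
marginal Spearman correlation with ImP in the draw, and record the
top-20 by importance within each direction. Taxa are ranked by selection
frequency, ties broken by mean importance. Per-taxon permutation seeds
derive from the taxon name and features are processed in name-sorted
order, so the ranking is invariant to input column order. Raw relative
abundance is the default substrate; a log10 option exists because
heavy-tailed responses/features can otherwise dominate squared-error
importances.

## Association models

The outcome is always obstructive CAD versus the combined reference
(nonobstructive + no CAD). Exposures enter as highest-quartile flags
(computed by the same quantile convention as above). Model 1 adjusts for
Framingham score, HIV duration per 5 years, MSM, CD4 nadir < 200,
statins, abacavir, antibiotics and IL-6; model 2 adds age and sex.
Framingham, IL-6 and age enter standardised per SD: their native scales
are heterogeneous and a per-SD coding makes the odds ratios comparable
across cohorts (published per-unit ORs for such terms depend on an
unstated scaling; per-SD is this package's documented choice).
Fits are maximum likelihood (statsmodels) with Wald 95% CIs — chosen
over profile likelihood for determinism and speed. Quasi-complete
separation is detected (failed convergence or |coef| > 15) and raised as
an explicit `SeparationError`, never returned as silent output.

ROC curves use trapezoidal integration with half-credit ties, which
makes the AUC exactly the Mann-Whitney concordance probability (asserted
to 1e-10 in tests).

Mediation (index → ImP → obstructive CAD) uses the product-of-
coefficients estimator on linear regressions, with the binary outcome in
linear-probability form — mirroring the behaviour of the classical
psychology-toolbox estimator this analysis style descends from — so that
total = direct + indirect holds exactly on every draw. CIs and two-sided
p-values come from a percentile bootstrap over rows (default 1000
draws; the p uses the add-one estimator). A caveat documented here and
pinned by tests: under the *complete* null (no x→m and no m→y path) the
product statistic is degenerate and its bootstrap p is conservative, not
uniform; uniformity holds under the no-mediation null in which x drives
the mediator but the mediator carries nothing.

## Pipeline and reproducibility

`run_all` chains every stage, records a manifest (full configuration,
named per-stage seeds, package version, per-stage shapes and timings)
and aborts on any stage failure naming the stage. Reruns with the same
configuration are bit-identical. The cohort summary table reports median
(IQR) with Kruskal-Wallis p for continuous variables and n (%) with
Fisher's exact test (2×2) or chi-square (larger tables — SciPy provides
no exact R×C test) for categorical ones.

## Problem sizes used in the test suite

Calibration batteries run on reduced problem sizes chosen once: null
cohorts use 60 ASVs in 15 genera at mean depth 8000 (group sizes stay
114/80/60); mediation recovery uses 200 bootstrap draws per replicate;
the RF planted-signal unit test uses 30 resamples on 80 taxa, with the
full 200-resample configuration exercised on the default cohort in the
acceptance suite. The acceptance script runs the complete default
configuration, including 200 RF resamples and 1000 mediation draws.

## Known limitations

- One-factor PERMANOVA only; no covariate-adjusted or multi-factor
  designs, and no UniFrac.
- The LDA effect size has no subclass stage and no multi-class mode.
- The default mediation estimator is the linear product-of-coefficients
  form, whose linear-probability approximation degrades for extreme
  outcome prevalences; the `outcome_model="logit"` option replaces the
  outcome regressions with a logistic fit reported as probability-scale
  average marginal effects, but is not a full counterfactual
  (simulation-based) estimator.
- The synthetic cohort's planted effects (3×/0.3×) are deliberately
  strong — chosen for unambiguous planted-signal recovery, not as
  estimates of any real cohort's effect sizes, which this study design
  cannot identify without the original data.
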