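# Methods

## The model

Plasma testosterone concentrations of known-sex hatchlings are modelled as
sex- and challenge-status-specific lognormal random variables: within each
group, `ln X ~ Normal(meanlog, sdlog²)` with concentrations in pg/mL and
parameters on the natural-log pg/mL scale. The lognormal was chosen over
gamma and Weibull because it fits every group acceptably (K–S test) and its
parameters are directly interpretable as log-scale means and SDs; the
`compare_families` helper reproduces this screening on any panel. The
packaged point estimates and 95% bootstrap CIs (`hatchsex.constants`) are:

| group | n | meanlog (95% CI) | sdlog (95% CI) |
|---|---|---|---|
| naive female | 6 | 2.46 (2.23–2.70) | 0.29 (0.11–0.43) |
| naive male | 18 | 5.69 (5.44–5.94) | 0.53 (0.35–0.69) |
| challenged female | 9 | 3.45 (3.01–3.90) | 0.68 (0.34–0.95) |
| challenged male | 22 | 6.54 (6.20–6.90) | 0.85 (0.58–1.08) |

### Fitting

The lognormal MLE has closed form: `meanlog` is the mean of the log values
and `sdlog` the RMS deviation with divisor *n* (the true MLE). At n=6 the
n vs n−1 choice shifts σ̂ by ~9%, so it is worth being explicit. Bootstrap
intervals are percentile (2.5, 97.5) intervals of case-resampled refits; BCa
was not used because the percentile interval is the default of standard
distribution-fitting tooling and the downstream Monte Carlo consumes the
interval only as a uniform sampling box. Refits that fail (degenerate
resamples, non-convergence for gamma/Weibull) are dropped and counted;
more than 50% failures aborts with an error. The K–S p-value treats the
fitted parameters as known; with estimated parameters it is
anti-conservative (Lilliefors-type corrections are not applied, matching
the original analysis). Samples outside the assay's quantifiable band are
retained for fitting.

## Sex assignment

**Probabilistic rule.** The relative probability of male at concentration
`x` is the male density mass over the bin `[x − 0.05, x + 0.049]` divided by
the male-plus-female mass over the same bin. The asymmetric upper offset
(+0.049, not +0.05) is kept exactly as published, with a symmetric-bin
option; the two differ by less than one grid step everywhere. Where both
masses underflow in deep tails, the pointwise log-density ratio is used —
it agrees with the binned ratio far beyond reporting precision. The density
ratio implies equal (1:1) class priors; other priors are out of scope.

**Thresholds.** Reported on a 0.1 pg/mL grid: the female upper bound is the
largest grid value below the density crossing with P(F|x) ≥ the certainty
level; the male lower bound is the smallest grid value above it with
P(M|x) ≥ the level. At certainty 0.5 the single threshold is the grid value
nearest the exact crossing — this is the convention that reproduces both
published single thresholds (37.7 naive, 129.7 challenged), whereas
"largest grid value with P(F) ≥ 0.5" would give 129.6 for the challenged
status. Because the male log-scale spread exceeds the female's, the density
ratio has a second, spurious crossing at a very low concentration
(≈0.23 pg/mL for naive parameters) where the male density re-dominates; the
solver locates the crossing between the two distribution modes by root
bracketing and scans outward from it, so the spurious root is never
returned. The default search range [0.1, 10,000] pg/mL brackets the assay's
working range. One known irreproducibility: the published challenged
99.99% male bound (423.2 pg/mL) corresponds to ≈99.9% certainty under both
the binned and pointwise ratio; the solver returns 605.3 for 99.99%.

**Empirical range rule.** With disjoint observed ranges (naive: female max
20.8, male min 125.4 pg/mL), assignment is inclusive at both extrema.
With overlapping ranges (challenged: 114.8–139.0 pg/mL), the default
assigns F strictly below the male minimum and M strictly above the female
maximum, i.e. printed bounds (male min − 0.1, female max + 0.1); the
alternative of using the first extrema *outside* the overlap (68.1, 198.1)
is available as a constant for callers who prefer a rule with no unknown
band inside the overlap.

## Misidentification Monte Carlo

Each replicate fixes a true sex, draws (meanlog, sdlog) independently and
uniformly within that sex's 95% CIs, draws one concentration from the
resulting lognormal, and assigns a sex. 10,000 replicates per sex by
default, all female replicates then all male from a single seeded
generator. Misidentification is per true sex with unknown assignments
excluded from the denominator; the Monte Carlo SE accompanies each rate.
The assigned F:M split over all replicates is tested against 50:50 with a
1-df chi-square with Yates continuity correction (the squared
continuity-corrected Z).

Decision thresholds are **fixed** from the point-estimate fits by default.
An `adaptive` option instead recomputes the certainty bounds inside every
replicate from the CI-sampled parameters (via the closed-form quadratic
roots of the pointwise log-density ratio, which match the binned grid
search to within one grid step). Both are provided because the original
description reads as fixed thresholds while some published rates sit closer
to the adaptive behaviour; the generation/assignment parameter linkage of
the original code is not recoverable, so the package reports either variant
rather than forcing agreement. The closed-form oracle
(`misid_closed_form`) gives exact rates at zero parameter uncertainty and
anchors the engine in tests.

## FSH response

The design is a split plot: sex between subjects, challenge status (two
levels) within. For a two-level within factor the mixed ANOVA reduces
exactly to one-way analyses of per-subject difference scores (interaction
and status effects) and mean scores (sex effect), which is how it is
implemented; the interaction F carries df (1, n−2). The status main effect
uses the unweighted average of the two sexes' mean changes (Type III
behaviour), chosen because the real groups are unbalanced; it therefore
differs from weighted-SS software under imbalance, while the interaction
and sex effects match a general mixed-ANOVA implementation exactly (tested
against one). Concentrations are log-transformed by default. Levene's test
(median-centred) on the four cells and Shapiro–Wilk on cell-centred
residuals report assumption checks. Zero-residual degenerate designs yield
F = ∞ (nonzero effect) or 0 rather than an exception. Individuals lacking
either sample are dropped with a warning.

The permutation test statistic is the M−F difference in mean per-individual
change (absolute pg/mL or percent); sex labels are permuted, and the
two-sided p includes the observed labelling in numerator and denominator,
so p ≥ 1/(n_perm+1) and lies on that grid.

## ELISA

The 4PL is parameterised on the log-concentration axis, so `b` is the slope
at the inflection and `e` the ED50; this makes parallelism a statement
about `b` and `e` alone. Parallelism is tested with Gaussian-likelihood
ratio tests assuming constant error variance:
`χ² = n·ln(RSS_restricted / RSS_full)`, where the full model shares the two
asymptotes and frees slope and ED50 per series (df = 2 against the
all-shared reduced model; the slope-only and ED50-only intermediates give
1-df tests). Richer models are seeded from the reduced fit so nesting
(RSS_full ≤ RSS_restricted) holds numerically. QC follows assay practice:
duplicate CV = 100·SD/mean (divisor n−1, single replicate → 0), strict
quantification window 20–80 %B/B0, permissive 10–90%, rerun flag on CV >
20% or a strict-window failure. Interplate CV uses per-plate control means;
intraplate CV averages within-plate replicate CVs. The extraction
efficiency determined on a congeneric species (94.1% ± 16%) is carried as
metadata and never applied as a correction.

## Synthetic data

The generator's defaults are the study conditions: panel sizes 6 F / 18 M
(naive) and 9 F / 22 M (challenged), 23 paired individuals, 48-animal wild
cohorts, Table-parameter lognormals, and FSH shifts equal to the
challenged-minus-naive log-means (δ_F = 0.99, δ_M = 0.85) — i.e. nearly
parallel responses, matching the finding that FSH elevates both sexes about
equally. The individual FSH response is additive on the log scale with
Gaussian noise (SD 0.5 by default, chosen so the implied challenged
marginal spread is of the observed order); a challenged marginal generated
through the shift model therefore has sdlog `sqrt(sdlog² + 0.5²)`, while
the `challenged_panel` preset instead draws directly from the fitted
challenged parameters when exact published marginals are wanted. Wild
cohorts are latent-sex Bernoulli mixtures whose true sex is stored in a
clearly named `latent_sex` column that the classifier path never reads.
ELISA plates are twofold dilution series from the assay's top calibrator
(500 pg/mL, 8 steps, duplicates) with additive Gaussian response noise
(SD 2 %B/B0); at least 5 dilution steps are required so the 4 parameters
are identifiable.

What the generator does **not** emulate: assay measurement error on
testosterone (concentrations are drawn directly from the group
distribution), clutch/maternal random effects (reported as plausible in
this system but with no published generative form), heparin dilution
effects, and non-constant ELISA error variance. Tests passing on synthetic
data therefore validate the statistical machinery under the stated model,
not robustness to those real-data features.

## Numerical choices and problem sizes

Thresholds use brentq root bracketing (xtol 1e-9) plus vectorised grid
scans. The test suite scales stochastic checks to sizes that keep the whole
suite fast while leaving comfortable power: 500 seeds for the ANOVA and
parallelism null calibrations (nominal 5% rejection ± 2 pp), 200 seeds for
ED50 recovery, 10⁵ replicates per sex for Monte-Carlo-vs-oracle agreement
(within 3 Monte Carlo SEs), and 300 outer replicates of n=100 samples at
1,000 bootstrap iterations for CI coverage (95% ± 3 pp). Seeds are fixed
throughout; identical seed and configuration give byte-identical outputs.

## Known limitations

Fitted-parameter uncertainty is propagated as independent uniforms on the
CI box (as published), ignoring the μ–σ sampling correlation; model-form
uncertainty is not propagated. The K–S p-values are optimistic for fitted
parameters. Population transferability of the fitted distributions is
unknown — thresholds derived here apply to populations exchangeable with
the source panels. Published misidentification percentages under the
probabilistic rules are only qualitatively reproducible (orderings and
magnitudes), for the parameter-linkage reason above.
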