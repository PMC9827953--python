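# Methods

## Effect sizes

The response ratio compares mean abundance at a disturbed site with its
paired control. We use the natural log of that ratio with the second-order
delta-method bias correction, which matters because many field studies
have 2–6 replicates per site. Both the ratio and the correction terms are
evaluated on truncated means Ã: a zero sample mean is replaced by
1/(2 n D), half the smallest observable abundance given n samples at
reporting scale D (e.g. D = trap-nights for per-trap-night rates). Using Ã
throughout (rather than only in the variance) is required for the ~20–26%
of comparisons with a zero mean, where the raw ratio is undefined.

Zero reported SDs are treated as missing and imputed before effect sizes
are computed. The default imputation assumes count-like (Poisson)
dispersion, SD = √Ã. Two sensitivity methods are provided: the Bracken
ratio (missing SD = Ã × pooled SD/mean ratio of complete cases) and
hot-deck nearest-neighbour draws. For hot-deck we use k = 5 donors nearest
in |Ã|, restricted to the same taxonomic class so that abundance metrics
stay comparable, with ties broken by record order; the donor pool and k
are this package's choices. Multiple hot-deck completions are summarized
by the median and 2.5/97.5 percentiles of the per-completion estimates
rather than Rubin's rules, matching how such runs are usually compared.

Effect sizes that divide different distances by the same control are
correlated; the assembled variance–covariance matrix carries the
first-order shared-control term SD²_c/(n_c Ã²_c) on the off-diagonal.
The second-order delta contribution of the shared control is *not* added:
the standard construction for shared-control log-ratios provides the
first-order term, and the second-order piece is negligible at the
variances where the approximation is trustworthy anyway.

Geary's screen `(Ã/SD)·4n^{3/2}/(1+4n) ≥ 3` (applied to both sides, using
imputed SDs where the original was missing) marks effect sizes whose
denominators are too close to zero for the log-normal approximation; the
pipeline offers it as a sensitivity subset, never as a default filter.

## Design and random effects

Distance enters as x = log₁₀(metres) clamped at 1 m, so a "prediction at
1 m" is exactly the model intercept and 0 m records remain usable; this
clamping (rather than a +1 m offset) is the package's decision and is what
makes printed coefficient tables directly interpretable at 1 m. Body mass
is log₁₀ grams, diet a raw percentage (0–100). Habitat and infrastructure
type are treatment-coded against `closed` and `non_traffic`; power lines
are a separate level only for birds (collision risk), otherwise folded
into non-traffic. Continuous moderators are deliberately uncentered so
that predictions and effect zones can be reproduced from published
coefficient tables alone.

Moderator sets must respect marginality (interactions require their main
effects; quadratic terms require linear ones). Candidate enumeration
produces every marginality-respecting subset of a per-taxon term menu;
because that menu yields ~200 candidates for mammals and birds, the
pipeline's default candidate list is the distance ladder (intercept-only,
distance, distance + distance²) plus the published best structure, with
full enumeration behind a flag.

Random effects are five Gaussian components: observation-level residual
heterogeneity, clade (order for mammals and birds, family for reptiles
and amphibians, where orders are too few and mass varies within them),
species nested in clade, publication (source), and study nested in
source.

## REML engine

The marginal covariance is M = V + Σ σ²_k Z_k Z_kᵀ with V known. The
restricted likelihood is maximized over log σ² by bounded L-BFGS-B with
an analytic gradient and three starts (near-zero, a method-of-moments
heuristic, large), relative tolerance 1e-8; components ending at the
lower bound are snapped to exactly zero. Because effect sizes are
log-ratios, heterogeneity variances live on an O(1) scale, and the
optimizer uses absolute bounds [1e-10, 1e4] — this keeps the search
robust to the very heavy-tailed sampling variances that truncated
zero-mean records produce. Zero diagonal entries of V (possible only if
imputation is skipped) are floored at 1e-8 with a warning. Fixed effects
are GLS at the estimated M with Wald (normal) CIs; no Knapp–Hartung
adjustment is applied, matching the symmetric intervals of standard
multilevel meta-analysis output. The engine is cross-checked in the test
suite against metafor's `rma.mv` on a five-component shared-control
fixture (agreement to ~1e-4; note metafor's restricted log-likelihood
differs by the constant ½log|XᵀX|).

Q_E is computed from the V-weighted fixed-effects fit (the weighted
least-squares extension of Cochran's test); computing it at the
multilevel fit instead was the open alternative, and the fixed-effects
form is this package's choice. Q_M is a Wald chi-square on a coefficient
subset; when a tested main effect participates in untested interactions
the model is refit without those interactions first (the distance main
effect owns both its linear and quadratic columns and their
interactions). AICc uses the *full* likelihood evaluated at the REML
estimates with k = fixed effects + free variance components; counting the
variance parameters in k is this package's reading of the small-sample
correction. R² uses var(Xβ̂) as the fixed-effects variance and the
Higgins–Thompson "typical" sampling variance
s² = (n−1)Σw / ((Σw)² − Σw²), w = 1/V_ii — the exact form of s² was an
open choice and this is the standard one. Variance proportions divide
each σ²_k by (Σσ² + s²).

Profile likelihoods fix one component on a grid and re-optimize the rest;
a component is declared identifiable when the profile has a unique
interior maximum and drops by ≥ 1.92 log-likelihood units (the 95%
chi-square half-width) towards both grid ends. The Egger screen regresses
meta-analytic residuals on precision 1/SE by OLS; a non-zero intercept at
p < 0.05 flags funnel asymmetry.

## Effect zones

Predictions are quadratic in x = log₁₀(distance); the zone boundary is
the smallest sign-changing root in [1 m, d_max], found in closed form
(d_max defaults to 100 km, far beyond the 4.5 km maximum of observed
data; crossings beyond it are reported as undefined). A curve that never
crosses zero within range — e.g. non-carnivorous birds in closed
habitats, negative at 1 m and declining — has an undefined zone. When the
prediction at 1 m is exactly zero the zone is 1 m with the sign taken
from the slope. Confidence bounds are the first crossings of the
pointwise 95% envelope (bisection on a 512-point log-spaced scan): the
envelope on the zero side of the curve gives the lower bound (0 m when it
is already across at 1 m), the other envelope the upper bound, which is
reported as unbounded when it never crosses — reproducing the one-sided
intervals typical of published zone tables. The envelope construction is
this package's choice; the original analysis does not state its interval
method. Zone tables evaluate models with an infrastructure-type term at
paved roads (the dominant class) and collapse trait dimensions absent
from the model.

Bundled with the package are the published final coefficient tables for
the four vertebrate classes (two-decimal precision). Derived quantities
inherit that rounding: zones reproduce published values to the metre
except where the printed precision itself moves the root by ~0.2% (large
non-carnivorous mammals in open habitat: 604 m here vs 603 m at full
precision), and one published amphibian zone (27 m) is not recoverable at
all because the rounded quadratic has no real root.

## Synthetic data

The generator emulates the published database's structure: sources
containing 1–3 studies, studies sampling 1–6 species at 2–5 log-uniform
distances up to 4.5 km, the farthest site serving as the species'
shared control; 10% of studies include a 0 m site. True log response
ratios are design-row × true coefficients plus the five Gaussian random
effects. Observed site means are normal around the truth with
coefficient of variation drawn from a Gamma(shape 4) distribution,
censored at zero and rounded to the count resolution 1/(nD); reported
SDs track the reported level (dispersion proportional to the observed
mean, with chi-distributed sampling noise) and are withheld at the
published per-taxon missing rates (22–63%). The mean CV is calibrated
once from the published zero-mean fractions (20–26%) via the censoring
probability Φ(−√n/cv); per-taxon presets match the published record
counts (863/2471/362/216) and use the published coefficients as the
default truth. A negative-binomial count mode is available behind a
switch for users who want integer-count realism.

What the generator does *not* emulate: real spatial autocorrelation,
digitization error, heterogeneous reporting metrics within a study, and
publication selection. Passing recovery tests therefore demonstrates the
estimator's correctness under its own assumptions, not robustness to
every feature of field data.

Recovery experiments refit the generating specification after imputation
and effect-size assembly. The default validation regime uses a site CV
of 0.4 and 4–8 replicates per site: at the database's own zero-mean
rates the implied CV is ≈1.6, where the log-normal delta approximation
for the sampling variance degrades and the surplus noise is absorbed by
the observation-level component — a property of the effect-size family,
not of the fitting engine, so engine validation uses the regime where
the variance model holds. Acceptance-scale runs use ~380 effect sizes
per replicate and 200 replicates, completing in a few minutes on one
core.

## Known limitations

- Wald intervals can undercover when a variance component is estimated
  at the boundary; no profile-likelihood CIs for fixed effects.
- The shared-control covariance ignores the second-order delta term (see
  above); at variances where this matters the log-ratio itself is
  unreliable.
- AICc comparisons across fixed-effects structures under REML carry the
  usual caveat; a maximum-likelihood selection switch is provided.
- Hot-deck imputation assumes at least one complete case in the taxon.
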