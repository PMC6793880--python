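# Methods

This note documents the statistical models implemented in `isoniche`,
the defaults they ship with, what the synthetic-data generator does and
does not emulate, and the numerical choices that were genuinely open.

## Species niche model: Bayesian standard ellipse areas

Each species × area group's (δ¹³C, δ¹⁵N) values are modelled as
bivariate normal with unknown mean μ and covariance Σ. The isotopic
niche width of the group is the standard ellipse area — the area of the
1-σ ellipse (≈40% coverage in two dimensions):

    SEA  = π √(λ₁ λ₂) = π √(det Σ)        [‰²]
    SEAc = SEA · (n − 1)/(n − 2)           (small-sample correction)

The coverage fraction of the "standard" ellipse is a convention; the
1-σ ellipse is the one used throughout this field and is what the
correction factor (n−1)/(n−2) is derived for.

Inference uses the conjugate normal–inverse-Wishart family with exact
joint draws:

    Σ | data ~ InvWishart(ν₀ + n, Ψ + S + κ₀n/(κ₀+n)(x̄−μ₀)(x̄−μ₀)ᵀ)
    μ | Σ, data ~ N(μₙ, Σ/(κ₀ + n))

where S is the scatter matrix about the sample mean. Exact conjugate
sampling targets the same posterior as the MCMC used by the standard
ellipse-fitting packages, with no convergence diagnostics needed, and is
bit-reproducible given a seed. SEA and SEAc are evaluated on every draw,
giving each group a full posterior of its niche width.

**Prior defaults and their rationale.** κ₀ = 10⁻³ (prior mean weight ≈
1/1000 of one fish; the prior mean defaults to the group sample mean, so
it has no practical pull), ν₀ = 3 (the minimum proper degrees of freedom
for a 2×2 covariance), Ψ = I ‰² (the conventional unit scale used by
Bayesian ellipse fitters). Two properties of Ψ are worth knowing:

- *Properness*: Ψ full rank keeps the posterior proper even when a
  group's points are exactly collinear (the fit flags such groups).
- *Calibration*: the inverse-Wishart posterior determinant is biased
  slightly low at small n (posterior df ν₀ + n vs the n − 1 degrees of
  freedom in S). At typical within-group isotope variances
  (0.3–0.6 ‰²) the unit prior scale offsets this bias: with Ψ = I the
  central 95% SEAc interval covers the true corrected area in ≈95% of
  replicate simulations at n = 25, versus ≈83% with a near-zero Ψ.
  The price is scale-dependent prior sensitivity: doubling Ψ moves the
  posterior median SEAc by well under 2% for well-dispersed groups
  (group SD ≳ 1.5 ‰) but by a noticeable fraction of the (wide)
  posterior spread for small, tight groups. Within this conjugate
  family one cannot make the prior simultaneously scale-free and
  coverage-calibrated; the default favours calibration, and both
  properties are measured in the test suite at the scales stated here.

Groups need n ≥ 3: the covariance of two points is degenerate and the
correction divides by n − 2. Species × area cells below that are
dropped from ellipse fitting and from their area's community with a
logged warning.

## Community metrics

Four community-wide descriptors are computed per area over the species
positions in isotope space: TA (convex hull area, ‰²), NR and CR
(δ¹⁵N and δ¹³C extents, ‰), and CD (mean Euclidean distance to the
centroid, ‰). The Bayesian versions evaluate all four on each joint
posterior draw of the species mean vectors, so per-species uncertainty
(including small-n species) propagates into the community posteriors.

The hull is built over species posterior means per draw — the
"community as species constellation" reading. CD is ambiguous in the
literature (species means vs individuals); both variants are
implemented (`cd_mode="species_mean"` default, `"individual"` option)
and the deterministic summaries report the individual-based CD whenever
it differs from the species-mean version by more than 10%.

The hull is computed by Andrew's monotone chain with the shoelace area
formula; collinear input yields area 0. NR/CR are computed from the raw
species points and asserted at run time to equal the hull-vertex
extrema. Two exact invariants are enforced on every draw: TA ≤ NR·CR
(the hull sits inside its bounding box) and all metrics ≥ 0.

## Exceedance probabilities

Evidence for niche expansion is the posterior exceedance percentage

    P(a > b) = 100 · (1/n) Σᵢ 1[Xₐ,ᵢ > X_b,ᵢ]

between the draw vectors of any two groups. Draws are paired by index by
default (groups are fitted on disjoint data, so this is just a Monte
Carlo coupling; an all-pairs mode is available and agrees within Monte
Carlo error). Ties are counted separately, never split, so
P(a>b) + P(b>a) + P(tie) = 100 exactly. Reports orient community
comparisons protected-over-fished.

**Calibration caveat.** Under a true null (identical group parameters),
P(a > b) computed from one dataset is approximately *uniformly*
distributed across replicate datasets — that is what a calibrated
posterior implies. A single replicate can legitimately produce values
like 15% or 85% with no real effect present. The calibrated property is
distributional: across replicates the exceedance values centre on 50%
with no directional bias, which the test suite verifies over 20
replicate null datasets. Single-dataset exceedance values should be
read as evidence strength, not as error-controlled tests.

## Diet: index of relative importance

For prey taxon i within a predator group, over non-empty stomachs:
%N (count share), %M (mass share), %FO (fraction of stomachs containing
the taxon), combined in the Pinkas form IRI = (%N + %M)·%FO and
normalised to %IRI. If a group's total prey mass is zero while counts
are positive, a count-only fallback IRI = %N·%FO is used and flagged.
Prey richness is compared across groups by rarefying to a common
stomach count (seeded resampling without replacement); the resampled
mean matches the closed-form hypergeometric expectation.

## δ¹⁵N ~ length × protection: model selection

The candidate set for δ¹⁵N regresses on 2-SD-standardised body length,
protection status, and their interaction (always with its main
effects), plus a random site intercept for the nested design. The mixed
model profiles the likelihood down to the single variance ratio
λ = σ²_site/σ²_resid and maximises it by bounded 1-D optimisation
(log-λ in [−12, 8], boundary λ = 0 checked explicitly and flagged) —
exact for this family. ML fits feed model selection; REML is available
for variance-component reporting but REML likelihoods are never
compared across fixed-effect structures.

Models are ranked by AICc; ΔAICc ≤ 2 flags well-supported models and
ΔAICc < 4 defines the averaging set. Averaged coefficients use the
natural (conditional) convention with Buckland unconditional variance;
RVI sums the Akaike weights of all candidate models containing a
predictor. K counts all estimated parameters including variance
components; because published tables sometimes count K one higher, the
selection table also accepts raw (logLik, K, n) triples so either
convention can be reproduced, and externally fitted models (e.g.
Poisson count GLMMs) can enter the same table.

## Synthetic data generator

The generator emulates the nested survey: 3 areas (two fished, one
protected) × 3 sites, 5 rockfish species, 2 fish per species × site
(90 fish; the original survey analysed 87 across the same structure),
62-ish non-empty stomachs, belt transects with habitat covariates.

Generative model per fish: length L ~ logNormal(log 30 cm, 0.25);
δ¹⁵N = μN(species, area) + slope(area)·(L − E[L]) + site intercept +
noise; δ¹³C drawn conditionally on δ¹⁵N so that each species × area
cell hits its target carbon variance (0.30 ‰²) and C–N covariance
(0.08 ‰²) exactly, with the δ¹⁵N variance implied by the length model
(slope²·Var L + σ²_site + σ²_resid). Every dataset ships with a truth
manifest (JSON) holding the implied cell means, covariances and slopes;
recovery tests read truth only from the manifest.

Default coefficients, chosen once for realism at the study scale:
fished slope 0.03 ‰/cm, protection adds 0.05 ‰/cm (overall
relationship ≈ 0.05 ‰/cm with R² ≈ 0.2, matching the scale reported
for such data), status shift +0.5 ‰, site SD 0.25 ‰, residual SD
0.40 ‰. The three scenario presets encode the competing hypotheses as
parameter patterns: H1 spreads species δ¹³C means 2 ‰ wider in the
protected area, H2 spreads δ¹⁵N means 2 ‰ wider and keeps the steeper
protected slope, H3 nulls every protection effect. The 2 ‰ spreads are
fixture conventions (clearly detectable at this sampling scale), not
field estimates.

For the model-selection recovery experiment the interaction is
generated at 0.10 ‰/cm ≈ 3 interaction-SEs at n ≈ 90 across 9 sites.
At that strength the interaction model tops the AICc ranking in ≥80% of
replicates; at exactly 2 SEs the theoretical ceiling of the top-rank
rate is ≈65% (the AICc penalty admits the extra parameter only when the
deviance improvement clears ≈2.3, an event of probability ~0.65 under a
noncentral χ²₁ with ncp 4), so the experiment is run comfortably inside
the detectable regime.

What the generator does **not** emulate: predator (lingcod) behaviour or
movement, prey-base differences between geographic areas unrelated to
protection, measurement error in δ values (laboratory SD ~0.2–0.3 ‰ is
absorbed into the residual), unbalanced catch per site, or empty
stomachs. Passing recovery tests therefore show the estimators work
when their assumptions hold, not that the assumptions hold in any field
dataset.

## Numerical choices

- Covariance validation tolerates eigenvalues down to −10⁻¹⁰ (relative).
- Exceedance ties are reported, not split; strict inequality throughout.
- Per-group posterior seeds are derived from the run seed and the group
  label (SHA-256, < 2³¹), so adding or removing a group never changes
  another group's draws.
- CSV artifacts are written with `%.10g` float formatting; a rerun with
  identical inputs, config and seed is byte-identical (hash recorded).
- Problem sizes in the test suite (replicate counts, draw counts) are
  chosen to hold Monte Carlo error well below each asserted tolerance:
  10⁴ draws for exceedance checks, 100–200 replicates for coverage and
  recovery rates, 1000 random instances for the hull-area oracle.

## Known limitations

- The bivariate-normal niche model ignores within-group structure
  (size-dependent δ¹⁵N within a species inflates SEA rather than being
  modelled per species).
- Community TA over species means ignores within-species spread by
  construction; the individuals-based hull variant is provided but not
  the default.
- The mixed model supports a single random intercept (site); crossed or
  nested-deeper structures are out of scope.
- Exceedance percentages are not error-controlled tests (see the
  calibration caveat above).
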