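# Methods

## The partition

The net biodiversity effect of a mixture plot-year is the observed
total yield minus the expectation formed from sown proportions and
monoculture yields, NBE = Σ Yᵢ − Σ RYₑ,ᵢ·Mᵢ. It decomposes additively
into a complementarity effect CE = n·mean(M)·mean(ΔRY) and a selection
effect SE = n·cov(M, ΔRY), where ΔRYᵢ = Yᵢ/Mᵢ − RYₑ,ᵢ and all sums,
means and the covariance run over the sown species only. We use the
population covariance (divisor n): with the sample covariance
(divisor n−1) the identity NBE = CE + SE holds only approximately,
while with divisor n it is exact algebra, which is what makes the
identity usable as a machine-precision invariant in tests. The SE
notation is sometimes printed with a barred M inside the covariance;
the only dimensionally coherent reading is the species-wise covariance
between Mᵢ and ΔRYᵢ, which is what we implement.

Monoculture references M are means over replicate monoculture plots
within a matching group. The default group is study × year ×
treatment arm, where the arm is identified by the experimental N rate
(a binary fertilised/ambient key would pool monocultures across
distinct rate arms in studies that apply several nonzero rates).
Fallback policies (study × arm pooled over years; study × year pooled
over arms) are selectable. A constant c (default 1 g/m²/yr,
configurable, ≥ 0) is added to every monoculture yield because
relative yields diverge as M → 0. A mixture plot-year whose sown
species lacks a reference in its group is dropped and flagged
`missing_monoculture`, never imputed — imputation would silently
change the statistic. Unsown species found in a mixture (invaders) are
excluded from the algebra, because RYₑ is undefined for them, and the
plot is flagged `unsown_invader`; a sown species that failed enters
with Y = 0 and ΔRY = −RYₑ. When all species in a plot share the same
M, the covariance is exactly zero and SE = 0 with no special-casing.

Multiple harvests within a year are summed to an annual productivity
(g/m²/yr) before any partitioning. Validation enforces the inclusion
rules as data checks: species-level biomass present, monocultures
present in the study, sown proportions summing to 1 per plot-year, and
first-year observations excluded (establishment-year yields are not
comparable across plots).

## Nitrogen exposure

Every plot's annual N input is the experimental rate plus a static
site-level atmospheric deposition rate (kg/ha/yr); ambient plots still
receive deposition, which keeps log-rate models defined for them.
Cumulative exposure through year t sums annual inputs over years 1..t,
counting the measurement year's input in full, so constant rates give
rate × years (40 kg/ha/yr over 23 years → 920 kg/ha). Deposition
accrues from experiment start, not site history. Three accounting
modes — experimental only, deposition only, both — share the identity
cum(both) = cum(experimental) + cum(deposition). No loss terms
(leaching, biomass removal) are modelled.

## Synthetic experiments

The generator emulates the design features the analysis relies on: 15
studies, one running 23 years (the long-term analogue used for the
time model) and the rest 3–5 years; sown richness on a log2 ladder up
to 16 from pools of up to 20 species; experimental rates 0–500
kg/ha/yr with some studies lacking ambient plots; per-study deposition
6–15 kg/ha/yr; monoculture plots for every pool species; and AR1 plot
noise across years. The default design yields ≈1500 mixture plot-years,
matching the scale of the motivating synthesis.

Rather than simulating competition mechanistically, target CE and SE
are injected by inverting the partition in closed form:
ΔRYᵢ = CE/(n·mean(M)) + β(Mᵢ − mean(M)) with β = SE/(n·var(M)), and
Yᵢ = (RYₑ,ᵢ + ΔRYᵢ)·Mᵢ. Partitioning noise-free output therefore
recovers the targets exactly (machine precision), which turns
parameter recovery into a sharp test. Yields are clipped at zero and
the plot flagged when a target would demand a negative yield; default
magnitudes make clipping rare (<1%). Because β divides by var(M),
species pools are drawn as stratified (jittered, shuffled) lognormal
quantiles — every pool spans the productivity range, as real pools do,
and compositions are redrawn when the sampled species are too similar
(sd(M) < 0.2·mean(M)).

Target functions receive (year, total annual rate, richness,
fertilised flag). The richness argument extends the minimal
(time, rate) signature because one recovery scenario requires a
richness × treatment structure in CE. Presets: `interaction` (CE
convex in log cumulative N, 120 − 36x + 3.2x²; SE rising −30 + 7x,
crossing zero — the shift from complementarity to selection),
`additive` (independent time and rate effects), `richness_shift`,
`rate_decline`, `time_divergence`, and `null`. Magnitudes are tens of
g/m²/yr, the scale reported for temperate grassland biodiversity
effects.

Noise model: mixture targets are perturbed by stationary AR1 series
per plot (marginal sd `noise_sd`, default 15 g/m²/yr; lag-1 correlation
`ar1_rho`, default 0.4); monoculture yields carry multiplicative
lognormal AR1 noise (log-sd 0.05). Real-data noise magnitudes for
CE/SE are not well documented; these defaults were chosen once, at the
scale of the injected effects, to give the recovery tests realistic
but non-trivial power. What passing tests show is that the estimation
machinery recovers known structure under this noise model; they do not
show that real grassland noise is this tame, nor do they capture
species-composition turnover, density dependence, or N-loss dynamics.

Monoculture productivity responds multiplicatively to annual N
(default 1 + 0.0012·rate, i.e. +60% at 500 kg/ha/yr) and is otherwise
flat in time.

### Conceptual curves

`conceptual_trends` builds a cumulative-N curve from a time trend f and
a rate trend g. In additive mode the curve is the raw product surface
f(t)·g(r) traced against cum N = t·r; in multiplicative mode the
products are treated as data and a quadratic in log(cum N) is fitted
and returned. Points with non-positive cumulative N are omitted (log
scale). The fitted quadratic's leading coefficient summarises
curvature. A rising time trend times a falling rate trend — the
no-interaction null for complementarity — is necessarily *concave*
against log cumulative N: pointwise in the shared log coordinate the
product of an increasing and a decreasing linear trend is a downward
parabola, and the grid construction inherits the sign (verified against
dense numerical evaluation). Convex curvature is therefore diagnostic
of a time × rate interaction, and the `interaction` preset produces it.

## Models

All models are linear mixed models (statsmodels MixedLM) estimated by
maximum likelihood so that AIC = 2k − 2·logLik is valid for comparison;
k counts fixed effects, covariance parameters and the residual
variance. Optimisation uses the default scorer with Powell/CG
fallbacks, keeping the best finite likelihood.

- **Binary treatment (H1a).** response ~ treatment × study, restricted
  to studies containing both ambient and fertilised plots (elsewhere
  the interaction is collinear). Default random structure: plot-level
  random intercepts with AR1 residual correlation across years.
  MixedLM cannot combine random effects with an AR1 residual process,
  so the AR1 is applied by two-stage quasi-differencing
  (Prais–Winsten): estimate ρ from the pooled within-plot lag-1
  autocorrelation of stage-1 residuals, transform response and design
  within plots, refit. The transform leaves the fixed-effect scale
  unchanged; ρ and the approximation are recorded in the fit metadata.
  The literal "plot within year" variance-component structure is also
  selectable (`nesting="plot_in_year"`), intended for small data — the
  plot dummy expansion is expensive. Marginal means average the fixed
  predictions over observed study levels with equal weights.
- **Richness interaction (H1a).** response ~ treatment ×
  log2(richness), random intercepts for study and for richness within
  study; refuses tables with fewer than three mixture richness levels.
  Richness enters on log2 because the sown gradients are log2 ladders.
- **Rate (H1b).** response ~ log(total annual rate), random intercepts
  and slopes by study; ambient plots included or excluded by flag;
  zero-rate rows dropped with a logged count. Natural log for rates,
  as for cumulative N.
- **Time (H2).** One long-running study: response ~ treatment × year
  with richness-level random intercepts; needs ≥3 distinct years.
  Year-by-year series within a plot are strongly autocorrelated, and a
  naive fit understates the interaction's standard error by half or
  more, so the same two-stage AR1 quasi-differencing is applied here.
- **Cumulative N (H3).** response ~ log(cum N) + log(cum N)², random
  intercepts and slopes (on the linear term) by study, for any of the
  three accounting modes; the quadratic sign labels the relationship
  convex or concave. The additive alternative (log rate + year, same
  random structure) is provided for the AIC comparison, which requires
  identical observation sets and responses.

Significance labels use p < 0.05 (significant) and p < 0.10
(marginally significant) for description only; nothing is filtered on
them.

## Numerical choices and limitations

Proportion sums are checked to 1e-9 (typed observations) or 1e-6 (CSV
validation); additivity is asserted at 1e-9 relative tolerance; AR1 ρ
estimates are clipped to ±0.95; marginal-mean grids use observed
factor levels. Degenerate designs raise rather than guess: mixtures
with n < 2, constant richness columns, single-treatment tables,
all-zero cumulative columns. Evaluation experiments (recovery rates,
AIC regime preference) use 100 generator replicates at the default
≈1500-plot-year scale, the package's standing choice for
power-versus-runtime.

Known limitations: the two-stage AR1 is an approximation, not a joint
likelihood; recovery guarantees are conditional on the generator's
additive-noise world; the pipeline models yearly totals only (no
within-season dynamics); and no correction is applied across the
model hierarchy's multiple tests.
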