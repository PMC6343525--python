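# Methods

This note documents the models and procedures implemented in
`heliastress`, the assumptions behind them, the defaults they use, and
what the synthetic-data experiments do and do not demonstrate.

## 1. Pot water status and the irrigation controller

A potted plant's water status is expressed as the fraction of
transpirable soil water,

    FTSW = (W - W_min) / TTSW,        W_min = W_max - TTSW,

where `W_max` is the pot weight at full soil water capacity (weighed
after saturation and drainage) and TTSW the total transpirable soil
water, both in kilograms. FTSW is clamped to [0, 1]; the raw value is
retained in a diagnostic column because weighing noise can push it
outside the physical range. TTSW is a per-pot calibration input — we do
not estimate it from a dry-down endpoint, and the controller assumes a
fixed calibration for the whole experiment.

The controller converts a target FTSW `f` to a target weight
`W_min + f * TTSW` and, at each robot visit, adds
`max(0, target - observed)` kilograms of water, capped so the pot never
exceeds `W_max`. Water is only ever added. Transpiration between two
visits is estimated as (previous post-irrigation weight minus current
pre-irrigation weight) / elapsed days; negative rates caused by noise
are floored at zero and counted.

The cumulative deficit indicator SFTSW is the trapezoidal integral of
(1 - FTSW) over a window, on the observation timestamps (visits are 1-4
per day and need not be equally spaced). It is non-negative, additive
over adjacent windows, and zero exactly when FTSW is 1 throughout.

**Controller scenario conditions.** A weigh-and-refill controller can
only approach a target from above, so its tracking band is set by the
water lost between visits: amplitude ~ demand x r(FTSW) x dt / TTSW.
The standard scenario used in the tests and the acceptance run —
TTSW = 6 kg, plant demand 1.1 kg/day at full water, 4 visits/day —
keeps that saw-tooth below 0.05 FTSW while still drying a saturated pot
to FTSW 0.2 within 5 days. Both constraints bound the admissible
demand; a much thirstier plant would overshoot the band at this visit
frequency, and a much smaller one could not reach the lowest target in
time. Plant fresh-biomass gain is neglected in the weight balance over
the scenario window (caps prevent rain and limit evaporation, so
transpiration dominates).

## 2. Drought response curves

The response of a daily process (transpiration TR or leaf expansion LE)
to water deficit is the regression of the stressed/control ratio on
FTSW. Each stressed plant-day is normalized by the mean of the control
plants on the same day; days whose control mean is ~0 are dropped and
counted. The curve is the one-parameter logistic

    r(FTSW; a) = -1 + 2 / (1 + exp(a * FTSW)),   a < 0,

which is 0 at FTSW = 0, strictly increasing, bounded in [0, 1), and
approaches a step at FTSW = 0 as `a -> -inf`. A more negative `a` means
the genotype maintains the process deeper into the deficit. This
functional form is an implementation assumption: the parameter
magnitudes used throughout (-2.15 ... -13.98 for the four contrasting
hybrids) are consistent with it, and each genotype is summarized by the
single scalar `a`. Fitting is nonlinear least squares over
a in [-30, -0.01] with five fixed starts; a fit pinned at -30 is
flagged "no regulation detected" (ratios never fall below 1 on the
observed range). The reported `se(a)` is the usual asymptotic standard
error from the Jacobian. TR ratios are not additionally normalized by
evaporative demand; the control-plant ratio is the sole normalization.

The yield dose-response along the SFTSW gradient is the polynomial
ratio model

    Y = (a + b S) / (1 + c S),

fit by nonlinear least squares (the product variant `(a+bS)(1+cS)` is
available behind `form="product"` for sensitivity checks; the rational
form is the primary reading). Fit quality is reported as
rRMSE = 100 x RMSE / mean(observed) — the denominator convention is the
mean of observations.

**Design-precision experiment.** Dense daily dry-down coverage
(FTSW 0.02-1) is compared with sparse three-visit sampling
(FTSW 0.45/0.7/1.0) at equal point noise and point count. Information
about a steep response parameter is concentrated at low FTSW, which only
the dry-down reaches, so the dense design yields a strictly smaller mean
`se(a)`; this is a qualitative ordering, not a numeric reproduction of
any measured precision.

## 3. Interaction traits and the multi-locus mixed-model scan

### Trait decomposition

Per-plant thousand-kernel weight in the two-treatment trial is modeled
as

    TKW = mu + gamma_i + (beta + alpha_i) * SFTSW + eps,

with sum-to-zero constraints on the line intercept deviations `gamma_i`
and line slope deviations `alpha_i` (the constraints are an
identification choice; the decomposition is otherwise not unique).
`beta` is the average TKW response to cumulative deficit and `alpha_i`
each line's interaction deviation. The model is fit by ordinary least
squares on the plant-level table (a two-stage reading: residuals are
absorbed into the line estimates, not modeled hierarchically); lines
missing a treatment are excluded with a warning, and a constant SFTSW
makes the slopes unidentifiable and is rejected. The scan phenotypes
are `alpha_i` (interaction effect) and `gamma_i + alpha_i` (total
genetic effect, taken literally at one SFTSW unit — not scaled by the
mean stress). Per-plant realized SFTSW is the covariate.

### Marker handling

Markers are kept when the recurrent parent assay shows < 10%
heterozygous-or-missing calls and the population heterozygote frequency
lies in [0.40, 0.60] (the backcross expectation is 0.5). Markers with
identical call vectors are merged into bins — by exact equality
including missing values by default, or greedily with missing-as-
wildcard behind a flag — and the left-most marker of each bin by
(linkage group, bp) represents it. Exact-duplicate binning cannot
change scan results; this is asserted in the tests.

### Mixed model

Kinship is `K = Z Z' / m` on column-standardized, mean-imputed calls.
Variance components of y ~ N(Xb, sigma_g^2 K + sigma_e^2 I) are
REML-estimated by profiling to a one-dimensional search over
delta = sigma_e^2 / sigma_g^2 on the spectral decomposition of K (grid
plus bounded refinement, delta in [1e-6, 1e6]); boundary optima are
flagged, and a K proportional to I (only the total variance
identifiable) is flagged "unidentifiable". The scan holds the cofactor
model's variance components fixed for all candidates within a step and
tests each marker by a GLS F-test after whitening — the standard
approximation that keeps a step linear in the number of markers.
Candidates collinear with the cofactors get p = 1 and a flag.

The forward walk adds the smallest-p marker each step (ties broken by
map order), re-estimates variance components, and stops when the
cofactor model's pseudo-heritability sigma_g^2/(sigma_g^2+sigma_e^2)
drops below `h2_stop` (default 0.01) or after `max_steps` (default 10).
The reported model is chosen by the mbonf rule only: the largest step at
which every included cofactor's re-estimated p-value passes 0.05 / m
(no extended-BIC criterion is implemented). Allelic effects in the
report are re-estimated jointly in the final mixed model.

## 4. The daily crop simulator

The simulator keeps the structure of a process-based sunflower model —
thermal-time phenology, one soil water bucket, light interception and
radiation-use efficiency, a nitrogen dilution balance, temperature
response, and the two genotype-dependent FTSW response curves — while
staying small enough to verify in closed form. It makes no claim of
numerical fidelity to any published full model; its acceptance surface
is limits, orderings and balances. A genotype is eight parameters:
`a_TR`, `a_LE`, thermal time to flowering and maturity (850 / 1600
degree-days), potential LAI (3), extinction coefficient k (0.9),
radiation-use efficiency (3 g/MJ) and harvest index (0.4). The
temperature response is a trapezoid on cardinals (4.8, 20, 28, 37) C,
the nitrogen dilution curve is %N = 4.53 x biomass^-0.42, base oil
content 55%. These are conventional values chosen by the implementer,
not measurements.

Daily order of computation: (1) FTSW = ATSW/TTSW; (2) transpiration =
PET x (1 - exp(-k LAI)) x r(FTSW; a_TR); (3) green-LAI growth =
potential logistic rate x normalized r(FTSW; a_LE) x min(1, NNI), with
linear thermal-time senescence from flowering to maturity; (4) biomass
+= RUE x radiation x interception x temperature factor x water factor;
(5) bucket update with precipitation, optional refill irrigation and
bare-soil evaporation (0.1 x PET x (1 - interception) x FTSW), clamped
to [0, TTSW] with the clamped amount tracked so the balance closes to
1e-9; (6) nitrogen uptake chases the critical-dilution demand, limited
by the mineralization supply. Root growth is collapsed into a fixed
TTSW = depth x AWC available from day 0. The emerging crop starts at
the critical N status of the dilution curve's biomass floor (limited by
the initial soil pool) so a just-sown plot does not register a spurious
nitrogen deficit.

Two normalizations are deliberate. The *stress factors* recorded for
envirotyping are scaled to equal 1 in the absence of stress: the water
factor is r(FTSW; a_TR) / r(1; a_TR) (the raw curve is 0.9999 at
FTSW = 1, which would otherwise leak a false permanent deficit), and
the temperature trapezoid is split into its rising limb (low-T factor)
and falling limb (high-T factor), so a day is below-optimum or
above-optimum but never both. Yield is biomass at maturity x harvest
index x mean post-flowering water factor, and oil content is a declared
proxy: 55% minus 10 x mean post-flowering water deficit. With no
stress, yield therefore equals the closed form
HI x RUE x sum(intercepted radiation) exactly.

The four stress indicators are daily trapezoidal integrals of the
deficits over the cycle: SFTSW = integral(1 - FTSW), SNNI =
integral(1 - min(1, NNI)), SLT and SHT the integrals of the two
temperature-limb deficits. The deficit reading of SFTSW (1 - FTSW, not
FTSW itself) is used everywhere for consistency: it makes the indicator
zero in the unstressed limit like the other three.

A known structural consequence of thermal-time phenology: cooling
lengthens the cycle and can *raise* yield through extra intercepted
radiation even as the low-temperature deficit grows. Yield
monotonicity is therefore asserted on drying-precipitation and warming
ladders, where cycle-length and stress effects point the same way.

## 5. Climate archetypes and soils

Each weather variable is a seasonal sinusoid (peak at day-of-year 200)
plus AR(1) Gaussian noise (coefficient 0.6), truncated at zero for the
non-negative variables: temperature 17 +/- 8 C, radiation 14 +/- 8
MJ/m2, PET 3 +/- 2.5 mm, precipitation 1.2 x the PET sinusoid. The
archetypes are deliberate caricatures: `drought` suppresses 95% of
summer precipitation (Gaussian window, sd 55 days) and scales PET by
1.3; `heat`/`cold` shift temperature by +/-7 C; `nitrogen` pairs an
otherwise optimal climate with a low-mineralization soil (0.05 vs 3.0
kg N/ha/day, initial N 5 vs 120 kg/ha); `optimal` changes nothing. The
default soil is 1000 mm deep with AWC 0.13 (TTSW 130 mm). Sowing is
day-of-year 135, when the optimal-archetype temperature enters the
photosynthesis plateau, so the unstressed cycle stays inside it. These
choices make the five archetypes separable by their own indicator;
passing the recovery tests shows the chain can classify environments
whose stresses genuinely differ, not that real European weather would
cluster this way. No attempt is made to mimic real weather statistics
or geography.

The synthetic plant-level generators follow the same philosophy: the
backcross panel codes calls {0 = homozygous recurrent parent,
1 = heterozygous} (the only states the breeding scheme allows), uses
the Haldane map function with no interference on a 1 cM/Mb synthetic
map, and plants exact-copy markers as binnable redundancy; the TKW
generator adds kinship-distributed polygenic terms
(sd 1.5 g on gamma, 0.03 on alpha) and residual sd 2 g around a 50 g
mean with four replicates per condition — stated here as simulation
defaults, not as any trial's measured variances. The truth objects
returned (bin map, per-line gamma/alpha, archetype labels) are
sufficient to score recovery without re-deriving anything.

## 6. Envirotyping

Environments are summarized by the genotype-averaged 4-vector of
indicators (the per-genotype variant — one row per genotype x
environment — can be clustered by passing the unaveraged table).
Columns are standardized, PCs covering >= 95% of variance retained, and
Ward-linkage hierarchical clustering applied to the scores. `k` is
fixed or chosen automatically in [2, 8] by the largest ratio of
successive within-inertia gains (an elbow rule in the spirit of
cutting a hierarchical tree on PC scores). Everything is deterministic
given the input row order.

Clusters are named by their dominant standardized centroid indicator
when it exceeds +0.5 SD, else "Optimal"; naming collisions are resolved
in favour of the larger centroid, the loser falling back to its
next-largest indicator. The threshold rule is an explicit convention of
this implementation.

Genotype profiling first removes each genotype's mean yield across
environments, ranks genotypes on the centered index within each
environment (rank-1 ties split fractionally so frequencies stay on the
simplex), and reports the per-cluster frequency of holding rank 1. Note
that after mean-centering no genotype can dominate every environment —
the index is relative by construction. Location summaries report the
frequency of each environment type across a location's years; rows sum
to 1.

## 7. Problem sizes and numerical conventions

The canonical experiments (in `heliastress.experiments`, shared by the
tests, the analysis scripts and `scripts/acceptance.py`) use: 7
controller targets x 20 days x 4 visits; 200 replicates x 4 truth
values x 60 points for response recovery; a 20 x 30 instance for the
scan oracle; 100 replicates of n = 200 lines x 500 markers for null
calibration and model-selection error; 50 replicates of 90 lines x 255
markers (17 groups x 15, 10% duplicates, alpha-QTL effect 0.15 — about
half the interaction-trait variance at the default noise) for
end-to-end QTL recovery; and 20 seeds x 50 environments x 2 genotypes
for archetype recovery. The full factorial design (4 genotypes x 42
locations x 21 years) is enumerated exactly; the envirotyping runs use
the scaled network because the archetype-recovery question does not
need 882 environments. Random streams derive from a single seed
per experiment via `numpy.random.default_rng`; ties and orderings are
broken deterministically (map order for markers, input order for
environments).

## 8. Known limitations

- The response-curve functional form and the eight-parameter genotype
  reconstruction are assumptions, documented above.
- The crop model is structural, not calibrated; absolute yields and the
  oil proxy have no predictive claim.
- The weather generator produces near-daily drizzle rather than
  realistic event statistics; archetype separability is engineered.
- The scan assumes line-level traits with a single kinship random
  effect; no population-structure covariates, haplotype or epistasis
  models, and no genetic-map estimation.
- Controller tracking guarantees hold for the documented demand window;
  a plant transpiring faster than ~0.3 x TTSW per visit interval cannot
  be held within +/-0.05 FTSW by top-up irrigation alone.
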