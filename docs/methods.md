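# Methods

## The task and what the model explains

Observers memorize three dots, each defined by two circular features: a hue on
a 360-degree colour wheel and an angular position on an invisible circle
around fixation.  After a delay they reproduce the array in one of four probe
regimes — cued by colour, cued by location (the cue dimension is selected
among the three displayed values, the other dimension is recalled), or free
whole report with either location or colour reproduced first (L→C, C→L).  In
whole report all six angles are reproduced in an order the observer chooses.

The analysis question is what a "misbinding" is made of.  A reported colour
near a non-target colour can arise from a genuine *symmetric* exchange of two
features between two objects, or from an *asymmetric misattribution*: the
feature migrated one way and the displaced feature was guessed (one feature,
or the whole donor object).  Single-feature cued recall cannot distinguish
these; the joint six-dimensional report can.

## Generative model

Per trial, with parameters specific to the subject and condition group:

1. **Report order.**  A permutation of the three objects onto the three
   response slots, drawn from a categorical distribution over all six orders
   (the report-order weights, one model parameter).  In cued trials the
   observed cue selections fix this mapping, so it is data, not a latent.
2. **Error structure.**  With probability `P_swap` one of the three object
   pairs (uniform) exchanges its feature on one dimension; with probability
   `P_cyclic_swap` the three features rotate (one of two directions,
   uniform); otherwise the mapping is veridical.
3. **Guessing.**  Per object, an object guess (both features jointly lost,
   one Bernoulli) or, failing that, independent feature-guess Bernoullis.
   The rates depend on stage 2: baseline `G_feature`/`G_object` on veridical
   trials; `G_*_swap_swp` for the two swapped objects versus `G_*_swap_non`
   for the bystander on swap trials; `G_*_cyclic` on cyclic trials.
4. **Emission.**  Guessed features are uniform on the circle; everything
   else is von Mises around the assigned source feature, with one
   concentration per dimension (`kappa_colour`, `kappa_location`).  In cued
   trials the cue dimension is a forced choice among the three displayed
   features and is copied exactly.

That is 13 free parameters per condition group: two concentrations, two
error-structure rates, eight guess rates, and the report-order distribution.

Two representational choices matter and are deliberate:

* **Canonical swap dimension.**  For two-feature objects, exchanging the
  colours of a pair is observationally identical to exchanging their
  locations (the colour–location pairings are the same).  Swaps and cyclic
  rotations are therefore represented on a single canonical dimension — the
  colour dimension in whole report, the freely reported dimension in cued
  trials — so the latent space contains no non-identifiable duplicate states
  and no probability mass is double-counted.
* **Guess semantics.**  A guessed feature is drawn from the uniform even if
  it happens to land near a true feature, and a correctly-reported feature
  that appears twice is attributed to guessing.  The object-guess route and
  the two-independent-feature-guess route both produce an object with both
  features guessed; they are distinct latent states with different priors
  (and different error-type labels) but identical emissions.

## Likelihood

The per-trial likelihood marginalizes the six-dimensional response density
over every latent state exactly: 6 permutations x 6 error structures x the
per-object guess layer.  Conditional on permutation and error structure the
three objects are independent, so the guess layer is summed per object (four
flag configurations) rather than enumerated across objects; the result is
identical to full enumeration (tested to 1e-14) at a fraction of the cost.
The batch evaluator works in scaled linear space — per-trial offsets keep
every factor at most one, so products of six densities cannot overflow — and
memoizes the von Mises factor matrices per concentration value, since most
sampler updates touch only mixture weights.  An explicit enumeration path
(`enumerate_latents` + `state_loglik`) serves trial classification and
transparency.

Cued trials contribute likelihood only on the report dimension; a latent
state claiming a slot-to-object mapping different from the observed cue
selections has likelihood zero.

## Hierarchical estimation

Subject-level parameters live on transformed scales: log for concentrations,
logit for probabilities, with the swap/cyclic pair stick-broken
(`logit(P_swap)`, `logit(P_cyclic/(1-P_swap))`) so the two rates can never
sum above one.  On each transformed coordinate, subjects are Normal around a
population mean with a population SD.  Hyperpriors are weakly informative:
Normal(0, 1.5) on population means (log-concentrations centred at log 5,
i.e. a broad prior around moderate precision) and half-Normal(1) on
population SDs.  Report-order weights get a fixed flat Dirichlet(1) prior
per subject and no population hierarchy — the data per subject are ample for
a 6-cell categorical, and the flat prior adds no sharing assumptions.

Sampling is Metropolis-within-Gibbs with the discrete latents summed out of
the likelihood: per-coordinate Gaussian random walks for subject parameters,
a 5-dimensional random-walk block in additive-log-ratio space for the order
weights, a conjugate Gibbs draw for each population mean, and a random walk
on each log population SD.  Proposal scales adapt during warm-up
(Robbins–Monro towards 44% acceptance for scalars, 25% for the block) and
freeze afterwards.  Chains run sequentially from seeds spawned off one
master seed; runs are bit-reproducible.  Split R-hat and effective sample
sizes of the population means are computed with arviz and attached to every
fit; values above 1.1 are flagged, never dropped.

The reference configuration is 5000 adaptation steps, 10,000 retained
iterations and 4 chains (40,000 draws), with per-subject posterior means
taken over all retained draws on the natural scale.  `McmcConfig.quick()`
(500/1000/2) is the package's desk-scale configuration used throughout the
tests and the acceptance script; at the problem sizes below it recovers
generating parameters and reproduces the model-comparison ordering.

## Model variants and comparison

`build_variant` defines the compared models: `full`; `null` (all swap and
guess rates frozen at zero — precision and report order only);
`no_asymmetric` (the six within-swap/cyclic guess rates frozen, so a swap is
always symmetric); `collapse_order` (the two whole-report conditions share
parameters); `collapse_cue_uncued` (one shared set for all conditions).
Comparison uses WAIC with the variance-form penalty computed from the
(trials x draws) pointwise log-likelihood matrix, reported on the deviance
scale with a trial-wise standard error, and ΔWAIC relative to the best
(lowest) model, whose Δ is exactly zero.

## Decomposition and statistics

Conditional on a swap, each swapped object escapes the object guess and the
swapped-dimension feature guess with probability `(1-G_obj)(1-G_feat)`, so

* symmetric fraction: `((1-G_obj)(1-G_feat))^2`,
* asymmetric via object guess: `1-(1-G_obj)^2` (any object guess dominates
  the label),
* asymmetric via feature guess: the remainder.

Guesses on the bystander object leave the label unchanged.  Per-trial
error-type posteriors (`classify_trials`) sum prior x likelihood within each
class over the full enumeration, by default at the per-subject posterior
means (flagged in the output metadata).

Report-order bias uses the convention that 90 degrees points up and 180
degrees left (mathematical angles, configurable); the first-reported object
is taken from ground truth when present, otherwise by nearest joint match of
the slot-0 responses, with ties to the lowest object index.  Raw absolute
error is the unsigned circular difference between each response and the
same-slot target, ignoring latent structure.

Bayes-factor t tests use the JZS construction (Cauchy prior on the
standardized effect, default scale 0.707) computed by adaptive quadrature of
the noncentral-t marginal; correlations use a stretched-beta prior on the
population correlation with Fisher's exact sampling density of r.  Evidence
bands follow the conventional 3/10/30/100 cutpoints, mirrored for the null.
Within-subject error bars follow Loftus–Masson normalization (subject means
removed, grand mean restored, SEM per condition).

## Synthetic data: what it emulates and what it does not

The task generator reproduces the stimulus statistics of the experiment:
uniform hues with at least 5 degrees pairwise separation; uniform positions
on a 6.5-dva circle with dot centres at least 1.4 dva apart, enforced as the
equivalent central angle of 12.36 degrees (whether the original constraint
additionally accounted for dot radius is unknowable from the task
description; centre distance is used).  Rejection sampling caps at 10,000
attempts and reports infeasible constraints.

Default simulation conditions are chosen to be realistic for three-item
multifeature report: population means of `P_swap` 0.06, `P_cyclic` 0.01,
`G_feature` 0.12, `G_object` 0.05, within-swap guess rates 0.20/0.15
(feature/object), `kappa_colour` 10, `kappa_location` 15, a report-order
preference of 0.4 for the first-encoded object, between-subject SD 0.3 on
the transformed scales, 60 trials per subject and condition (240 per
subject; the experiment's exact per-condition count is not stated in the
task description).  Simulated observers have no output interference (later
reports are as precise as earlier ones), no serial-position structure at
encoding, no lapses of the cue-selection process, and no response
correlations beyond those the model itself generates — so passing tests
certify the estimation machinery, not the behavioural completeness of the
model.

## Numerical choices and scales

Angles are degrees in [0, 360) externally and radians inside density code;
the exact 180-degree antipodal difference resolves to +180.  Densities are
per radian; von Mises normalization uses the exponentially scaled Bessel
function so concentrations up to 1e8 are safe.  Zero-probability latent
states are dropped before log-sum reductions.  The recovery study in the
tests and acceptance script uses 12 subjects x 120 whole-report trials; the
model-comparison study uses 15 subjects x 150 trials with `P_swap` 0.15 and
`G_obj_swap_swp` 0.5 — sizes at which the posterior is informative while a
full study runs on a single core in minutes.

## Known limitations

* The sampler is random-walk based; weakly identified rates (for example
  bystander guess rates when swaps are rare) mix slowly and show elevated
  R-hat at the quick settings.  The pluggable likelihood makes an HMC
  backend possible but none is included.
* Cued trials cannot separate `G_feature` from `G_object` (only the report
  dimension is guessable), and swap estimates in cued conditions are
  structurally inflated relative to whole report — a property of the probe,
  not a bug.
* `collapse_*` variants share whole parameter sets; partial sharing (for
  example, only precisions) is not expressible.
* Real-data ingestion is limited to the package's own CSV trial table; an
  adapter for external deposits is out of scope.
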