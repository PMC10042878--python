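# Methods

## The statistical problem

Society-level traits are doubly non-independent: related societies inherit
traits from common ancestors, and neighbouring societies exchange them.
Regressing one coded trait on others without accounting for this overstates
the evidence (Galton's problem).  The pipeline treats both sources as
covariance-structured random effects in a Bernoulli regression and reads
effects from the full posterior rather than point estimates.

## Coding rules

Raw ethnographic variables are ordinal: 0 (enough information to judge the
trait absent), 1 (present, rare), 2 (present, frequency unknown), 3
(present, common), NA (insufficient information).  Analysis uses collapsed
occurrence: 0 → absent; 1, 2, 3 → present; NA → missing.

* **Carry merge.** Pack-animal and sled-pulling codes merge into one carry
  function: present if either is present; missing only if both are missing.
  The mixed case (one absent, one missing) is scored absent: one carrying
  role is affirmatively absent and absence of the other is the only state
  consistent with the any-present rule.  The merge is commutative and
  monotone.
* **Composites.** A relationship dimension (positive care: ten caregiving
  variables; negative treatment: six abuse/neglect/culling variables;
  personhood: five variables — naming, talking to, burial, mourning, kin
  treatment) is present if any component is present.  Otherwise it is
  absent if at least one component is affirmatively absent, and missing
  only when every component is missing — a single recorded absence is
  "enough information to evaluate" the dimension.  For personhood, silence
  in the record is read as absence of the behaviour, so missing components
  count as absent and the composite is never missing.
* **Counting and filtering.** The number of roles is defined only for
  societies with all five main functions coded (0–5, the count of
  presences).  Filters: at least one main coded; all mains coded; all
  dimensions coded.  The single/multi/zero-function split in count reports
  tallies presences among societies with at least one coded main.

## Covariates

Subsistence dependence (gathering, hunting, fishing, agriculture) arrives
as coarse percentage intervals.  *Farming propensity* samples one integer
uniformly per interval, runs a PCA on the sample covariance of the four
raw columns (no standardisation, no log-ratio transform by default — a
centred-log-ratio variant sits behind `clr_transform=True`), sign-aligns
PC1 so agriculture loads positively, and repeats 500 times; the covariate
is the per-society mean PC1 score.  The across-run standard deviation of
the score is reported for convergence checks.  Animal husbandry dependence
is the interval midpoint.  Temperature and the count of dog-related
paragraphs pass through unchanged; the paragraph count enters the models
because better-documented societies are more likely to have rare
behaviours recorded.  Continuous covariates are z-scored before the
regression (stabilises the sampler and makes the fixed-effect prior scale
meaningful); function indicators stay 0/1.

## Covariance structures

* **Phylogenetic.** Under Brownian drift along the language tree, the tip
  covariance is C(i,j) = root-to-MRCA path length, diagonal = tip depth.
  Requires a rooted tree with non-negative branch lengths; pruning to the
  analysis set preserves tip-to-root path lengths.
* **Spatial.** Matérn kernel over coordinates,
  C(d) = σ²·2^{1−κ}/Γ(κ)·(d/φ)^κ·K_κ(d/φ), with κ = σ² = 1 fixed.  The
  range φ is not pinned by the design; it defaults to 1 and is exposed in
  config and CLI (`--phi`).  Analyses in this repository use φ = 20 on
  Euclidean degrees — of the order of the distance between neighbouring
  cultural regions — and the CLI accepts a haversine/km metric
  alternative.
* Both matrices are divided by their largest diagonal entry before
  entering the model so that the two random-effect scales are comparable,
  and a 1e−8 nugget keeps Cholesky factorisations stable (coincident
  coordinates are allowed).

## Model and sampler

y_i ~ Bernoulli(logit⁻¹(x_i'β + u_i + v_i)), u ~ MVN(0, σₚ²Cₚ),
v ~ MVN(0, σₛ²Cₛ), β ~ N(0, 5²) on standardised predictors,
σₚ, σₛ ~ Exponential(1).  The Normal(0,5) fixed-effect prior is proper and
weakly informative — wide enough to be flat over the plausible log-odds
range while keeping quasi-separated data sampleable; the Exponential(1)
rate on the random-effect standard deviations is the conventional
weakly-informative default for group-level scales.  Both are
config-exposed.

Sampling is plain Hamiltonian Monte Carlo with analytic gradients on the
non-centred parameterisation (u = σₚ L_p z, C = L L'), which removes the
funnel between scales and effects.  Warmup uses dual averaging to a 0.8
target acceptance rate plus a diagonal mass matrix estimated from an
internal warmup window; the number of leapfrog steps is drawn uniformly
from 1..20 per iteration to avoid resonance.  Defaults: 4 chains × 2000
iterations, first half warmup.  Non-finite or absurd states (|log σ| > 30)
reject the trajectory.  Convergence is summarised by split R-hat and ESS
(via arviz); fits report a diagnostics block rather than failing hard.
Identical seed and config give bit-identical draws.  The implementation is
cross-checked in the test suite against an independent JAGS fit of the
same model (different language, density code and sampler) to within 0.1
posterior standard deviations on a 40-society dataset.

Effect flags: posterior mass above zero per coefficient;
`substantial_increase` at ≥ 0.95, `substantial_decrease` at ≤ 0.05.
Variance components report posterior summaries of σₚ², σₛ² and the paired
posterior probability that the phylogenetic variance is strictly smaller
(ties count as false).  Bayesian R² is computed per posterior draw on the
probability scale, R² = Var(p̂)/(Var(p̂) + mean(p̂(1−p̂))) with population
variance across societies; the marginal scope uses fixed effects only, the
conditional scope adds both random-effect draws.  A latent-scale variant
was considered and rejected: the probability-scale form matches the
verbal definition used in the study design and has an exact hand-checkable
oracle.  Note the definition does not mathematically force conditional ≥
marginal; with near-deterministic outcomes the two coincide and the
ordering can invert by a few thousandths (observed once on the synthetic
reference data, where outcomes are assigned deterministically — see
below).

Rows with a missing response or missing covariates are dropped, not
imputed.  All three response models share the same covariate set
(farming propensity, husbandry, temperature, paragraph count).

## Synthetic data

`simulate_dataset` emulates the generative structure the model assumes:
pure-birth trees conditioned on the tip count, clustered coordinates (six
Gaussian clusters over the habitable latitudes), correlated function
indicators via a Gaussian copula (ρ = 0.4 — societies that herd also tend
to guard herds), EA-binned subsistence intervals from a latent
forager–farmer axis (agriculture share Beta(0.8, 0.8), remainder split
Dirichlet(2,2,1) among gathering/hunting/fishing), husbandry coupled to
the latent axis, temperature a noisy function of latitude, paragraph
counts negative-binomial with mean ≈ 20, and outcomes drawn from the
logistic model with σₚ = 0.5, σₛ = 1 (spatial clustering stronger than
linguistic, matching the analysis setting) and Matérn range 20.  Raw codes
are emitted by inverting the collapse rules (presence becomes 1/2/3 with
probabilities 0.25/0.45/0.30), with configurable completely-at-random
missingness and an optional clustered-missingness stress mode.  Defaults
use 100 societies, the scale of the real analysis sample.

`synthetic_reference_dataset` additionally reproduces, by deterministic
construction, the published marginal structure of the original 124-society
sample (counts 108/97/114/77, 54/48/6 single/multi/zero, 81 hunting, 55
defence, 32 with both care and negative treatment, 21 with all three,
model-ready n = 80/61/81).  Relationship outcomes are assigned by ranking
societies on a true linear predictor whose coefficient signs encode the
reported effect directions, under the exact count constraints.  What
passing tests on this stand-in show: the pipeline recovers counts,
directions and magnitudes that are true by construction at realistic
scale.  What they do not show: anything about the real ethnographic
record, which the stand-in does not contain.

## Calibration, and two measured limitations

Simulation studies in the test suite and acceptance script measure, at
n = 100 with 100 replicates and reduced-iteration chains (problem sizes
chosen to keep a full run in minutes on one core):

* **Interval calibration** (truths drawn from the model's own priors):
  95% credible intervals cover the truth at 0.945 pooled — nominal within
  Monte-Carlo error.
* **Null flag rates** (all effects zero): per-coefficient substantial-flag
  rates run ~0.12–0.18, above the 0.10 that two one-sided 5% rules would
  suggest.  This is a property of the study conditions, not the sampler:
  the generator makes temperature a function of latitude while the noise
  is spatially structured, so a stationary spatial kernel cannot fully
  absorb a latitudinal trend, and residual dependence mildly inflates all
  coefficients (a frequentist Wald test on the same designs inflates
  more).  Practically: posterior-mass flags on spatially patterned
  covariates should be read with this inflation in mind.
* **R² ordering**: conditional ≥ marginal holds on five of the six
  reference models; the exception (−0.003) arises from the deterministic
  outcome assignment in the stand-in, as discussed above.

Other known limitations: the Matérn range is a free parameter the design
does not pin down; `ethnophylo fit --phi-sens` refits across a grid of
ranges and reports how the substantial-effect flags change, and
variance-component magnitudes in particular should not be compared across
different ranges.  Also: the
eHRAF-side coding conventions (e.g. the more-than-two-paragraphs rule for
assigning absence) live upstream of this pipeline, which consumes coded
tables as given; and minor dog functions beyond the five mains pass
through uncoded.
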