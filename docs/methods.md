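# Methods

## The growth model

A component growth process follows the Pütter / von Bertalanffy energy
balance: mass grows at `dm/dt = H·s − K·m`, anabolism `H` (g of synthesized
mass per cm² of absorbing surface per year) scaling with the intestinal
surface and catabolism `K` (yr⁻¹) scaling with mass.  The body segment is a
cylinder whose radius tracks height through the allometric law `r = h^q`
with `q ∈ (0, 1)`; its absorbing surface is `2πrh` and its mass `Dπr²h`
with tissue density `D` (1 g·cm⁻³ by default).  Substituting gives the
height ODE

    dh/dt = h^(1−q) · ( 2H / (D(1+2q)) − K h^q / (1+2q) )

with closed-form solution (for `t ≥ i`, `t` in total years since
conception, `i` the initiation age)

    h(t) = [ (2H/(DK)) (1 − e^{Kq/(1+2q)·(i−t)}) ]^(1/q),
    m(t) = Dπ h(t)^(1+2q).

A person's stature is the sum of five such processes gated by `[t ≥ i_x]`,
labelled by the ontogenetic phase each dominates (in utero, infancy, early
childhood, mid childhood, puberty); the first initiates at conception
(`i₁ = 0`) and initiation ages are ordered.  The component asymptote is
`(2H/(DK))^(1/q)`; velocities follow from the ODE with each component
evaluated at its own height.  Parameter constraints are enforced strictly
(`H, K > 0` rather than `≥ 0`, so asymptotes, reciprocals and log
transforms stay finite; a degenerate process is represented by tiny `H`).
Velocity at `t = i` is defined as its limit value 0 (valid since
`1 − q > 0`), and the solution bracket is clamped at zero to absorb
floating-point underflow at `t ≈ i`.

## Measurement model and data conventions

Observed height (cm) and weight (g) are lognormal around the trajectory
with egg-cell offsets inside the log:

    ln h_obs ~ Normal( ln(0.012 + h(t)),      σ_η )
    ln m_obs ~ Normal( ln(1.02e−6 + m(t)),    σ_μ )

All ages are total ages since conception; ages since birth are shifted by a
gestation of 0.75 yr (configurable).  Preparation adds, per person, one
*conception anchor* (a pseudo-observation of 0.012 cm / 1.02e−6 g at
`t = 0`) that enters the likelihood like any record, and — for dense
longitudinal designs only — duplicates the last observed height/weight at
yearly intervals to age 26 since birth to stabilize the adult plateau.
Carrying a sparse person's single childhood measurement into adulthood
would poison the likelihood, so `prepare_study` applies carry-forward only
to dense-design groups.  Raw measurements are never smoothed or modified.
Weight is fit to total modelled mass times a configurable scalar fraction
(default 1); a skeletal-weight mapping can be emulated through that scalar.

## Multilevel structure and priors

On the transformed scale — `log H`, `log K`, `logit q` per process, and log
increments of the initiation ages (`i_x = i_{x−1} + exp(·)`, which enforces
the ordering and removes label switching) — person `j`'s 19-vector is

    θ_j = μ + γ_{g(j)} + u_j,     u_{j,f} ~ MVN(0, Σ_f)

with one covariance per parameter family (H, K, q: 5×5; i-increments:
4×4): offsets covary across processes within a family but not across
families (the minimal reading of cross-process covariation).  The first
group in the data is the baseline (`γ = 0`).

Priors (all package defaults, configurable via `PriorConfig`):

* baseline means: independent normals centered on the reference-like preset
  with SD 0.3 — informative priors anchored on a reference population, the
  same priors-from-reference-children logic the estimation design assumes;
  a ±35% band on each rate and increment;
* group offsets: Normal(0, 0.5²) per coordinate;
* family covariances: inverse-Wishart with `df = dim + 3` and scale chosen
  so the prior mean is `0.1² I` (conjugate stand-in for a
  scale-plus-correlation prior; see "Sampler");
* measurement SDs: half-normal, scale 0.05 for σ_η and 0.25 for σ_μ.  The
  asymmetry is deliberate: the cylinder-with-shared-q body model cannot
  represent soft-tissue weight variation, so the fit is steered to honour
  height more closely than weight.

Females and males are fit with fully separate models; `build_model`
rejects mixed-sex data.

## Sampler

No gradient-based probabilistic-programming backend is part of the
package's dependency set, so the posterior is explored by an adaptive
Metropolis-within-Gibbs scheme designed for this hierarchy:

1. **Person blocks.**  For each family, all persons' blocks are updated
   simultaneously by random-walk Metropolis with proposal covariance
   `step_j² · Σ_f` (per-person step sizes Robbins–Monro-adapted to ~0.30
   acceptance during warmup).  The likelihood factorizes over persons, so
   the update is a handful of vectorized array operations; six passes per
   sweep (the `mh_steps` knob) keep person-level autocorrelation down.
2. **Location moves (interweaving).**  Centered Gibbs mixes poorly when
   many persons carry one or two measurements, so each sweep also proposes
   *rigid shifts*: translate `μ_f` (or a group's `γ_{g,f}`) together with
   every affected person's `θ`, holding individual offsets fixed.  Scalar
   step sizes adapt to ~0.25 acceptance.
3. **Conjugate draws.**  `μ_f` and `γ_{g,f}` have exact multivariate-normal
   conditionals; `Σ_f` is drawn from its inverse-Wishart conditional.  The
   inverse-Wishart replaces an LKJ-plus-half-normal factorization precisely
   to keep this step conjugate.
4. **Measurement SDs.**  Metropolis on `ln σ` against the residual sums of
   squares under the half-normal priors.

Chains are seeded through `numpy.random.SeedSequence.spawn`, so a fixed
seed reproduces draws bit-for-bit.  Diagnostics (split R-hat, bulk ESS via
arviz, acceptance rates) attach to every posterior.  At the reduced chain
lengths used in the test suite (2 × (500 + 500)) population-level R-hat
values are still well above 1: population means decorrelate slowly in this
parameterization, and the reported intervals at that scale are somewhat
conservative.  Production analyses should run several thousand draws per
chain and check `posterior_.diagnostics`.

## Synthetic data

The generator draws persons from exactly the multilevel structure above
(back-transforming to natural scale), then simulates the lognormal
measurement process on one of two schedule designs:

* **dense** — a fixed grid per person: birth (total age 0.75), quarterly
  1.00–2.75, annually 3.75–18.75 (~25 measurements; ~33 after
  carry-forward to 26), emulating an annually-measured longitudinal cohort;
* **sparse** — 1–3 measurements at distinct integer ages since birth drawn
  uniformly from 1–24, counts from the mixture P(1,2,3) = (0.70, 0.29,
  0.01).  The mixture is the unique 3-point distribution matching a 70%
  singleton share, a maximum of 3 and a mean of ≈1.3 measurements per
  person simultaneously.

Defaults: measurement SDs σ_η = 0.03, σ_μ = 0.08 (log scale, fixture
choices — plausible stadiometer/balance error; no published estimates are
packaged); individual-offset SDs 0.04 (H, K), 0.04 (logit q), 0.05 (log
increments), giving an adult-height CV of roughly 4–6%, in the range of
real populations.  The reference-like preset produces a 165 cm adult
female (176 cm male) with a pubertal velocity peak of ~7 cm/yr near age 12
(13.7) since birth; preset values are calibrated against textbook growth
shapes and are package fixtures, not empirical claims.

What the generator does *not* emulate: age mis-recording, secular trends,
manual smoothing of source data, soft-tissue (fat/muscle) weight
variation, or any real population's parameter values.  Passing recovery
tests therefore demonstrates internal consistency of generator + estimator
under the model's own assumptions, not fidelity to any real cohort.

## Posterior summaries

* **Age-weighted parameter trajectories.**  At age `t`, process weights are
  `w_x = h_x(t) / Σ h_y(t)`.  The allometric summary is
  `q̄ = Σ w q / Σ w`; the metabolic summaries additionally weight by an
  activity `a_x = 1 − ρ·h_x/h_{∞,x}` declining linearly in relative
  component height from 1 at initiation to `1 − ρ` at the asymptote
  (`ρ = 0.75` by default, modelling replacement of metabolically active red
  marrow by marrow fat; the linear form is the simplest curve satisfying
  both endpoints).  `K̄ = Σ w a K / Σ w a`, and H̄ uses the same
  denominator, a symmetric treatment chosen for interpretability.  Ages
  with zero composite height are reported missing.  All weighted values
  are convex combinations of the five process values.
* **Trajectory descriptives.**  Maximum achieved height is read at a
  reference adult age (26 since birth, matching the augmentation horizon)
  rather than at the asymptote; peak pubertal velocity and its age are
  located on a 0.01-yr grid over a since-birth window of [5, 20]
  (configurable — the lower edge excludes the infancy velocity peak) and
  refined by parabolic interpolation, earliest age on ties; draws whose
  maximum sits on the window edge are flagged degenerate.
* **Contrasts.**  Group differences are summarized by the elementwise
  difference of draws and the rule that a 90% HPDI excluding zero marks a
  detectable difference.  The HPDI is the shortest sorted-draw window
  spanning at least the requested mass (`ceil(mass·(n−1)) + 1` points,
  earliest window on ties).

## Interventions

An intervention substitutes group-level metabolic parameters (H, K only —
allometry q and timing i are excluded by construction) of a target group
with the reference group's estimates, on the transformed scale.  Two modes:
replace with the reference posterior *mean* (default) or with the
reference value in the same draw (propagating reference uncertainty).
Person-level offsets of the target group are retained, so the intervention
models a population-level shift that preserves inter-individual variation.
Presets: `full_metabolic` (all ten H/K slots), `targeted_female` (K2, H3),
`targeted_male` (K2, K3).  Because each component's shape depends on H and
K, a pure-metabolic substitution changes the *weighted* q̄ trajectory and
the age at peak velocity even though every q and i draw is untouched —
the emergent-allometry effect the intervention machinery is designed to
expose.  These simulations are idealized: real interventions cannot move
each H and K independently.

## Numerical and design notes

* Exponential arguments are clamped at 0 before `exp` for gated
  (pre-initiation) ages, preventing overflow without branching.
* The ODE test oracles integrate from 0.1 yr after initiation with the
  closed form as the initial condition: both ODEs are non-Lipschitz at
  zero size, so integrating through the singular point is ill-posed.
* `hpdi` requires ≥2 draws; constant draw vectors yield zero-width
  intervals and are flagged undetectable in contrasts.
* Unequal draw counts in `contrast` are strided down to the shorter count
  (logged).
* Empirical HPDIs *narrow* as draws are thinned (tail under-representation
  dominates), so the band sanity test checks that thinning inflates the
  variability of the estimated endpoints rather than the width itself.
* Reduced problem sizes in the test suite (e.g. 30 dense + 60 sparse
  persons, 2 × (500 + 500) MCMC; 3-replicate sign-recovery smoke study)
  were chosen to keep the full suite self-contained and quick while still
  exercising every inferential path at a scale where coverage and sign
  recovery are meaningful.

## Known limitations

* Metropolis-within-Gibbs mixes population-level parameters slowly on this
  posterior's ridges (H–K–q trade-offs in each component); short chains
  under-resolve them.  A gradient-based sampler (NUTS) on the same model
  would be preferable when available.
* The five-component composite is weakly identified from sparse data alone;
  informative priors (here, anchored at the reference preset) are load-
  bearing, and group contrasts in individual parameters are attenuated
  when the data cannot separate a shifted K from a compensating H or q.
* The shared-q cylinder cannot represent body-composition change; weight
  fits are deliberately looser than height fits.
* No temperature dependence, reserve dynamics, supply-network scaling, age
  uncertainty or secular-trend modelling.
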