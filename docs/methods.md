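# Methods

This note records the model `accelwalk` implements, the estimation and
extraction procedures, the synthetic data the package is validated on,
and the numerical and design choices made where more than one reasonable
option existed.

## 1. The kick model

A trip of duration *t* (hours) is a speed profile over a hierarchy of
transport layers with speeds v_k = v₀ + k·δv.  The profile has an
accelerating first half and a decelerating second half; layer jumps
("kicks") arrive as a Poisson process with probability per unit time *p*
in both phases.  The mid-trip kick count is then Poisson with mean
p·t/2, the peak speed is v_m = v₀ + k(t/2)·δv, and the triangle
approximation v̄ ≈ (v₀ + v_m)/2 yields the linear mean-speed law
v̄(t) = v₀ + p′δv′·t with the *primed* parameters p′ = p/2 and
δv′ = δv/2.  The primed pair is canonical throughout the package
(`KickModelParams.p_half`, `.dv_half`) because it is what the
conditional-speed law is parameterised by and what gets fitted; the
unprimed values are derived views.  This avoids a whole class of silent
factor-of-two errors.

Internal units are fixed: km, hours, km/h.  I/O converts at the
boundary.

**Conditional speed law.**  Writing k = (v̄ − v₀)/δv′ and λ = p′t, the
mean speed given duration follows the Poisson weight continued to real k
through Γ(1+k):

    P(v̄ | t) ∝ exp(−λ) λ^k / Γ(1+k),   v̄ ∈ [v₀, v_max].

The law has no closed-form normalizer on the truncated support; it is
normalized numerically (trapezoid on a grid that resolves both the
0.1 km/h convention and the weight's own scale δv′·√λ — the latter
matters in the δv′ → 0 limit).  The weight is always evaluated in log
space; λ^k/Γ(1+k) overflows for quite ordinary λt otherwise.

Two facts about this continuous density are worth stating because they
are easy to get wrong:

* its *mode* tracks the Poisson mode, but its *mean* exceeds the linear
  law v̄(t) by a λ-dependent amount below δv′/2 — the exact mean identity
  belongs to the integer Poisson count, which is what the linear law is
  derived from;
* at the lattice points v̄ = v₀ + kδv′ (integer k) it is proportional to
  the ordinary Poisson pmf, which makes the integer-lattice restriction
  of the law the exact distribution of the reduced sampler below.

**Displacement law.**  With travel times P(t) = (1/t̄)exp(−t/t̄) and the
constraint Δr = v̄t,

    P(Δr) = ∫ P(t) · P(v̄ = Δr/t | t) · dt/t,

supported on t ∈ [Δr/v_max, Δr/v₀].  The integral is evaluated by
adaptive quadrature **after substituting k = (Δr/t − v₀)/δv′**: in
t-space the integrand's support collapses to a near-delta as δv′ → 0 and
adaptive rules miss it, while in k-space the integrand always varies
over order-one scales.  Absolute tolerance 1e−9.  In the single-layer
limit δv′ → 0 the law reduces to the exponential
(1/v₀t̄)·exp(−Δr/v₀t̄), which the tests verify to sup-norm < 1e−4.

The mixture optionally uses the exponential law *conditioned on
t ≥ t_min* with unchanged mean (`t_min=5` min by default in the
prediction workflow): simulated and extracted populations are filtered
at 5 minutes, and a Monte-Carlo histogram of such a population can only
be compared against the mixture over the same duration law.  The
unconditioned analytic form is `t_min=0`.

**Tail.**  Mixing a Gaussian displacement kernel over exponential travel
times and applying the Laplace (saddle-point) method gives a stretched
exponential tail

    P(Δr) ∝ Δr^(−δ) exp(−C·Δr^γ).

For a kernel variance growing as t^a the saddle point sits at
t* ∝ Δr^(2/(a+1)) and γ = 2/(1+a): a plain diffusive kernel (a = 1)
gives γ = 1, the integrated Brownian velocity (a = 3) gives γ = 1/2, and
the vehicular tail exponents γ = 3/4, δ = 1/2 correspond to an effective
a = 5/3.  `saddle_tail_exponent` performs the computation numerically —
inner minimization of the exponent per Δr, then a log–log regression —
and deliberately takes the kernel as a parameter (a power, or an
arbitrary variance callable), with the closed forms above serving as its
oracles; its default kernel is the one whose saddle point reproduces the
vehicular exponents.  δ is implemented as the standard power-law
prefactor Δr^(−δ).

## 2. The Brownian-velocity null model

The null model lets the velocity itself diffuse: dv = √D·dW from
v(0) = v_drift, so Var[v(t)] = D·t and the displacement (the time
integral) has variance D·t³/3.  It predicts ⟨|v̄|⟩ ∝ t^(1/2) — the
signature the linear empirical v̄(t) rules out — and, mixed over
exponential travel times, a displacement density computed here by
brute-force quadrature (folded Gaussian kernel; the density diverges
integrably like Δr^(−1/3) at the origin).  Simulation is Euler–Maruyama
with default step t/10⁴ (weak error far below Monte-Carlo error at the
rep counts used); a vectorized many-trip variant with 200–400 steps
serves the scaling tests, where the O(1/n_steps) variance bias is an
order of magnitude below the binomial noise.

## 3. Estimation pipeline

Given a trip table (duration, mean speed, path length), `KickModel.fit`
runs:

1. **Travel time** — durations are modelled as exponential conditioned
   on t > 5 min; the MLE of the shifted scale is the mean excess, and
   the reported t̄ is the mean of the filtered sample (the convention
   under which the population mean is quoted and fed to the displacement
   prediction).  By memorylessness the two differ by exactly the 5-min
   floor.
2. **Base speed** — mean speed per 5-minute duration bin, weighted least
   squares against the *within-bin mean duration* for bins with centres
   in [0, 2] h; the intercept is v₀, the slope the effective
   acceleration.  Two deliberate choices: bin means as the abscissa
   (the 5-min bin is half-censored by the trip filter, so its centre
   misstates its duration by ~1.1 min and would bias the intercept by
   ≈ +0.4 km/h) and trip-count weights (bin means are heteroscedastic;
   the far bins carry a handful of trips).
3. **Speed surface** — speeds binned at integer km/h centres
   (half-open [v−0.5, v+0.5), top edge closed at v_max = 130 km/h;
   lowest edge at ceil(v₀)−0.5 so that data marginally below an
   *estimated* v₀ are not dropped), durations in half-open 5-minute
   bins centred at 5, 10, …, 180 min; each populated duration bin is
   normalized to a relative-frequency curve.
4. **Kick parameters** — p′ and δv′ minimize the summed squared error
   between all binned curves and the model law simultaneously.  The
   model column is the conditional density integrated over each speed
   bin and normalized on [v₀, v_max] (pdf-at-centre available as an
   option).  Duration bins are count-weighted by default, for the same
   heteroscedasticity reason as above.  Optimization: 16 Latin-hypercube
   starts, L-BFGS-B within p′ ∈ (0, 10] /h, δv′ ∈ (0, 60] km/h, best
   objective wins, ties to the smaller p′.

**Lattice-valued speeds.**  When the trips come from the reduced Poisson
sampler (below), the observed speeds live on the lattice v₀ + kδv′ and
the continuous-density objective is not a consistent estimator — a
smooth curve cannot chase frequency atoms.  `model_eval="lattice"`
replaces the model column by the sampler's exact induced bin mass (the
Poisson mass of each lattice point falling in each integer bin, with the
above-cap tail clipped into v_max).  That objective is smooth in p′ but
piecewise constant in δv′ (atoms change bins only at edge crossings), so
it is minimized by a deterministic δv′ grid scan with p′ profiled out by
bounded line search, reporting the midpoint of the minimizing plateau.
Self-consistency and million-trip recovery tests pin both modes:
noise-free surfaces reproduce their generating parameters to < 0.1%, and
the simulate-and-refit experiment returns p′ and δv′ to well within 5%.

**Prediction.**  `predict_displacement_curve` evaluates the displacement
mixture on a log-spaced 0.5–500 km grid from a complete parameter set —
parameters in, P(Δr) out, no refitting.

**Tail families.**  `fit_tail_model` fits descriptive families by
maximum likelihood on [x_min, ∞) with numerically computed
normalization: exponential, pure power law (both closed-form MLEs),
truncated power law (Δr+Δr₀)^(−β)·e^(−Δr/κ), and stretched exponential
Δr^(−δ)·e^(−C·Δr^γ) with δ held at 1/2.  The truncated-power-law
likelihood is flat along a (β, Δr₀, κ) ridge on exponential-tailed data
(large Δr₀ with small β imitates an exponential exactly), so among
optima within 0.5 log-likelihood units the most parsimonious (smallest
β) is reported — matching the convention that β = 0 denotes an
exponential tail.  `compare_tail_models` ranks families by AIC and
reports a Vuong-style standard error of the pointwise log-likelihood
difference against the best family.  The default lower cutoff is the
1 km trip filter.

## 4. Simulators

* `simulate_kick_profile` — Poisson up-kick times on [0, t/2], layers
  capped at n = floor((v_max − v₀)/δv), and **mirror reflection** about
  t/2.  The mirror construction realises the stated symmetry of the
  accelerate/decelerate cycle and guarantees arrival at the base speed;
  a free descending Poisson process does not.  An independent-descent
  variant (down-kicks at rate p, floored at the base layer) is available
  behind a flag for sensitivity checks.
* `sample_mean_speed` — the reduced sampler: k ~ Poisson(p′t),
  v̄ = v₀ + kδv′ clipped at v_max.  Exactly the generative story of the
  conditional law on the integer lattice; used for parameter-recovery
  experiments because it carries no triangle-approximation bias.
* `sample_mean_speed_continuous` — inverse-CDF draws from the
  *continuous* conditional law (quantile interpolation across a
  tabulated λ grid).  This is the correct Monte-Carlo counterpart of the
  analytic displacement mixture; the lattice sampler's displacement law
  differs from it visibly at small Δr.
* `simulate_population` — durations drawn as 5 min + Exp(t̄ − 5 min), so
  the filtered-sample mean is exactly t̄; speeds by any of the three
  modes.
* Populations are plain pandas DataFrames with canonical columns
  (vehicle_id, t_start, duration_h, mean_speed_kmh, path_length_km);
  identical seeds give bit-identical tables.

## 5. Trip extraction

Engine-event logs (start/stop events plus position fixes, planar km; log
lat/lon converted on read) are segmented with three rules: an engine-off
gap ≥ 5 min ends a trip; a gap < 30 s merges unconditionally *unless*
the post-gap motion heads back toward the previous segment's origin;
gaps between 30 s and 5 min merge unconditionally.  "Heads back" is
operationalized as: first post-gap displacement within 30° of the
bearing to the previous origin *and* origin distance decreasing over the
first three points — thresholds robust to the 10–30 m position noise of
the data the generator emulates.  Trip duration is wall-clock from first
start to final stop (merged micro-gaps count as driving time, consistent
with travel times that include parking search); path length sums
point-to-point distances; the straight-line displacement is also
emitted.  Total engine-on time is conserved across segmentation and the
merged-gap total is reported per trip.

Signal-loss correction snaps a trip origin farther than 0.1 km
(configurable; well above worst-case stated noise) from the previous
stopping point back onto that stop, using the redundancy between
consecutive events; corrections are counted.  The trip filter keeps
trips strictly longer than 1 km and 5 min.  Free-flow speed per road is
the 85th percentile (linear interpolation between order statistics) of
observed speeds, flagged below 20 samples.  Residence is the area
collecting the most parking time, ties to the earliest-observed area
with a warning.

## 6. Synthetic data

`SyntheticScenario`/`generate_fleet_log` emulate the *structure* of
insurance-style vehicular GPS records so extraction and fitting are
testable with no external data: per-vehicle alternating trips and rests,
kick-model speed profiles embedded on a straight east–west line through
a per-vehicle home, fixes every ≤ 2 km of travel or ≤ 30 s on top-layer
roads, Gaussian position noise (default 0.02 km, the middle of the
10–30 m band), 2-km road segments labelled by layer, 10-km square
municipality tiles, and per-trip micro-stop (20 s) and signal-loss
(0.3–1 km origin displacement) artifacts at configurable rates — every
injection recorded in the ground truth, so artifact handling can be
scored exactly (precision and recall are 1.0 at default thresholds).

Choices the scenario makes, and what they do *not* claim:

* rest times are lognormal (median 45 min away, 4× longer at home)
  conditioned on ≥ 6 min — an unconditioned law would occasionally
  produce rests below the 5-minute stop threshold, merging two
  ground-truth trips and making exact round-trip recovery undefined.
  The law is a plausible-alternation config choice, not a model of rest
  behaviour;
* return trips retrace the outbound route (time-reversed profile), which
  plants residences and keeps vehicles' geometry bounded; outbound
  durations are fresh exponential draws;
* the geometry is a carrier for road ids, positions and area labels —
  not a road network, an origin–destination model, or congestion.

Passing tests on these fleets show the *rules* are implemented correctly
and invert the generator exactly; they do not show robustness to real
GPS pathologies outside the modelled ones (multipath clusters, drift
during long tunnels, clock glitches).

## 7. Problem sizes and tolerances in the tests

Parameter recovery runs at 10⁶ trips (the full experiment takes seconds;
recovery lands within 0.5% for p′, 0.06% for δv′, 0.2% for v₀, against
acceptance bands of 5%/5%/2%).  Monte-Carlo-versus-analytic comparisons
use 10⁵–10⁶ draws and a 3-standard-error criterion per decile.
Goodness-of-fit uses χ² at α = 0.01 on 10⁵ draws.  The null-model
scaling test uses 5 durations × 6–8×10³ trips with 200 Euler steps.
Synthetic-fleet marginal checks use ~10⁴ trips (KS < 0.02).  All
randomness descends from fixed seeds; the suite is deterministic.

## 8. Known limitations

* Constant v₀, p, δv: no congestion/density feedback, no time-of-day or
  regional variation.  The fitting pipeline estimates one parameter set
  per trip table.
* The triangle approximation behind the linear v̄(t) degrades for very
  long trips (p′t ≫ 1 with few layers); the finite-layer saturation of
  v̄(t) is exercised by simulation only, with no closed form provided.
* The continuous conditional law's mean exceeds the linear law by up to
  δv′/2 (Γ-continuation); inference built on the law's shape (the SSE
  fit) is unaffected, but the law should not be used to *define* v̄(t).
* The saddle-point kernel that produces γ = 3/4 is supplied as the
  default effective variance power a = 5/3 via γ = 2/(1+a); the
  machinery accepts any kernel, and the two classical kernels (a = 1, 3)
  are verified against closed forms.
* Tail-family fits assume i.i.d. displacements above the cutoff; no
  per-vehicle dependence correction is attempted.
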