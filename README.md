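# accelwalk

**Randomly accelerated walkers: a mechanistic model of vehicular mobility.**

How far do people drive in a single trip?  Empirical displacement
distributions P(Δr) from GPS and phone data are routinely fitted with
truncated power laws and read as evidence for Lévy-flight mobility.
`accelwalk` implements the opposing, mechanistic account for private-car
travel: a trip is a *randomly accelerated walk* over the hierarchy of
transport layers (urban streets → extra-urban roads → highways), and the
apparent heavy tail of P(Δr) is the short-tailed product of two simple
ingredients — exponentially distributed travel times and speeds that grow
linearly with trip duration.

The model: a trip of duration *t* starts at base speed *v₀* on layer *L₀*
and jumps to the next layer (speed gap *δv*) at Poisson rate *p* during a
symmetric accelerate/decelerate profile.  The mid-trip kick count is
Poisson with mean *pt/2*, giving the linear mean-speed law

&nbsp;&nbsp;&nbsp;&nbsp; v̄(t) = v₀ + p′δv′·t,  with p′ = p/2, δv′ = δv/2,

the conditional speed distribution (Γ-continued Poisson in
k = (v̄−v₀)/δv′, mean λ = p′t, truncated to [v₀, v_max])

&nbsp;&nbsp;&nbsp;&nbsp; P(v̄ | t) ∝ e^(−λ) λ^k / Γ(1+k),

and, mixed over P(t) = (1/t̄)e^(−t/t̄) with the constraint Δr = v̄t, the
displacement distribution

&nbsp;&nbsp;&nbsp;&nbsp; P(Δr) = ∫ P(t) P(v̄ = Δr/t | t) dt/t .

Its large-Δr behaviour is a stretched exponential
P(Δr) ∝ Δr^(−1/2) exp(−C·Δr^(3/4)) — short-tailed, with none of the
superdiffusion a Lévy flight implies, yet easily mistaken for a truncated
power law in a log-log fit.  The package also ships the Brownian-velocity
null model (velocity diffusing with coefficient *D*, so ⟨|v̄|⟩ ∝ t^(1/2)),
which the linear empirical v̄(t) rules out.

Reference parameter values, estimated from a nationwide Italian
private-car GPS data set (~780,000 vehicles): v₀ = 17.9 km/h,
p′ = 1.06 jumps/h, δv′ = 20.9 km/h, v_max = 130 km/h, t̄ = 0.30 h.
Since that data set is proprietary, everything here is exercisable on
synthetic data with known ground truth.

## What's in the box

| module | contents |
|---|---|
| `accelwalk.model_core` | analytic pdfs: conditional speed law, displacement mixture, null-model mixture, stretched tail, saddle-point tail exponents |
| `accelwalk.simulate` | kick-profile, reduced-Poisson and continuous-law trip samplers; Brownian-velocity null trips |
| `accelwalk.fitting` | travel-time MLE, speed-surface binning, base-speed WLS, simultaneous kick fit, tail-family MLE + AIC comparison |
| `accelwalk.model` | `KickModel` / `KickModelResults` — statsmodels-style front end over the pipeline |
| `accelwalk.trip_extraction` | GPS engine-event logs → trips and stops (5-min stop rule, 30-s micro-stop rule, signal-loss correction, 1 km / 5 min filter), 85th-percentile free-flow speeds, residence assignment |
| `accelwalk.synthetic` | ground-truthed synthetic fleet logs and trip tables |
| `accelwalk.cli` | `accelwalk` command: simulate / synth / extract-trips / freeflow / fit-* / predict-pr |

## Worked example

Simulate 200,000 trips at the reference parameters and refit them from
scratch:

```python
import numpy as np
import accelwalk as aw
from accelwalk import KickModel

rng = np.random.default_rng(42)
trips = aw.simulate_population(200_000, aw.REFERENCE_PARAMS, rng)
res = KickModel.from_trips(trips).fit(model_eval="lattice")
print(res.summary())
```

```
Acceleration-kick model of trip speeds
==============================================
trips fitted                    200000
duration bins                       31
kick-fit SSE                1.2679e-04
----------------------------------------------
v0              17.99 km/h      (se 0.0807)
a                21.7 km/h^2    (se 0.219)
p_half          1.054 jumps/h
dv_half         20.89 km/h
t_bar          0.2998 h         (se 0.000484)
----------------------------------------------
derived: p = 2.107 jumps/h, dv = 41.78 km/h, layers = 2
```

Every generating parameter returns: the base speed 17.99 vs 17.9 km/h,
the kick half-rate 1.054 vs 1.06 jumps/h, the half-gap 20.89 vs
20.9 km/h, and the mean travel time 0.2998 vs 0.30 h.  The derived full
gap δv ≈ 42 km/h matches the progression of speed limits (50 → 90 →
130 km/h), and (130 − v₀)/δv ≈ 3 transport layers.  The displacement
prediction then comes with *no* refitting:

```python
curve = res.predict_displacement()      # parameters in, P(dr) out
print(round(curve.integral(), 4))       # 1.0002
res.plot_displacement(sample=trips["path_length_km"])
```

The same workflow from the shell:

```bash
accelwalk simulate --n 200000 --seed 42 --out trips.csv
accelwalk fit-speed --trips trips.csv --out lin.json
accelwalk fit-kicks --trips trips.csv --model-eval lattice --out kicks.json
accelwalk predict-pr --out prediction.csv
```

GPS workflows run on synthetic fleets: `accelwalk synth fleet` writes an
engine-event log (position fixes every ≤2 km or 30 s on highways, 10–30 m
noise, micro-stop and signal-loss artifacts) plus a ground-truth JSON;
`accelwalk extract-trips` segments, corrects and filters it back into trip
tables whose agreement with the ground truth is checked in the test suite.

## Limitations

The model takes v₀, p and δv as constants: no congestion, no time-of-day
or city-to-city variation, and the symmetric-profile (triangle)
approximation degrades for trips longer than ~4 h.  Synthetic fleets use
a deliberately minimal straight-line geometry — a carrier for road labels
and positions, not a road network.  See `docs/methods.md` for the full
statement of assumptions, numerical choices and their rationale.
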