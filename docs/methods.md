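# Methods

## The valuation model

TIMERR treats valuation as reward-rate maximization over a limited window:
a past integration interval `T_ime` (time units, > 0), over which the agent
has earned the experienced reward rate `a_est` (reward units per time unit,
≥ 0), plus the delay `t` to the offer. The subjective value of a reward of
magnitude `r ≥ 0` delayed by `t ≥ 0` is the immediate reward giving the same
total rate over that window,

    SV(r, t) = (r − a_est·t) / (1 + t/T_ime),

and the delay is represented on the compressed subjective-time scale

    ST(t) = t / (1 + t/T_ime),

concave, strictly increasing, bounded by `T_ime`. Substituting one into the
other gives the exact identity `SV = r − D·ST(t)` with discount slope
`D = r/T_ime + a_est`: discounting is linear in subjective time. All units
are user-defined but must be mutually consistent; the theory fixes no
absolute scale. SV is deliberately allowed to go negative (waiting can cost
more than the reward is worth); `r` is restricted to be nonnegative and
`a_est` to be nonnegative, as the model is silent about punishments and
negative experienced rates.

## Error propagation

Perceptual noise is modelled as just-noticeable differences (JNDs):

- subjective time: `δST = k·ST + c`, with dimensionless slope `k ≥ 0`
  (scalar timing) and constant read-out error `c ≥ 0` (subjective-time
  units);
- magnitude: exact Weber's law, `δr = l·r` with Weber fraction `l ≥ 0`.

A magnitude overestimate raises SV while a timing overestimate deepens the
discount, so the aligned worst-case composition adds `δr` and subtracts
`δST`; expanding `SV` at the perturbed arguments and keeping all terms gives

    δSV = δr·(1 − ST/T_ime) + D·δST + δr·δST/T_ime.

The sign (discounting lowers value) is dropped: all returned errors are
magnitudes. The JNDs combine **linearly, not in quadrature** — they are
aligned perceptual error bounds, not independent variances. A
root-sum-square combination would model statistically independent noise
sources; the JND calculus here answers a different question (how large a
coherent misperception is undetectable) and is used throughout.

Key consequences, each exposed as a function and asserted in tests:

- time-only noise (`l = 0`): `δSV = c·D + k·(r − SV)` — for `c = 0` the
  error is exactly proportional to the value change `r − SV` at every
  delay (the value-change Weber fraction *is* `k`);
- immediate reward (`t = 0`): `δSV = r·(l·(1 + c/T_ime) + c/T_ime) + c·a_est`
  — affine in `r`, with a slope (magnitude Weber fraction) that falls with
  `T_ime` and an error that rises with `a_est`: reward history shapes
  magnitude perception;
- at fixed `r` across delays, and at fixed `t` across magnitudes, δSV is
  affine in SV. The decompositions are computed by substituting
  `ST = (r − SV)/D` (fixed `r`) or `r = (SV + a_est·ST)/(1 − ST/T_ime)`
  (fixed `t`) into the combined expression. The printed closed-form
  coefficient groupings are not transcribed from any external source;
  the *reconstruction property* — `slope·SV + intercept` equals the direct
  evaluation for all inputs, to 1e-10 relative — is the normative contract
  and the tested one.

Weber "fraction" is reported against two referents to avoid ambiguity:
`δSV/(r − SV)` (value change, the natural referent for delayed rewards) and
`δSV(r, 0)/r` (magnitude, for immediate rewards). Tables carry both.

## The magnitude-sensing accumulator

Magnitude measurement is integration of a constant sensory input `a > 0`
over a window `t_sensory > 0` (measured magnitude `r = a·t_sensory`),
corrupted by Poisson-like input noise (variance `b²·a`) and balanced
excitatory/inhibitory feedback noise (variance `σ²·r_t`). Additive
combination of the two sources gives the SDE
`dr_t = a·dt + √(σ²·r_t + b²·a)·dW_t`; multiplicative combination gives
`dr_t = a·dt + σ·b·√(a·r_t)·dW_t` (infinitesimal variance `σ²b²·a·r_t`,
the product of the two variance structures). Ito moment equations yield
`⟨r_t⟩ = a·t` in both modes and

    var(r_t) = a·σ²·t²/2 + b²·a·t     (additive)
    var(r_t) = σ²·b²·a²·t²/2          (multiplicative)

hence `CV = √(σ²/(2a) + b²/r)` — approximately constant, deviating upward
at small `r` — versus the exactly constant `CV = σ·b/√2`, independent of
the signal. The test suite re-derives both variances with an independent
symbolic integration of the moment ODEs rather than re-asserting the
closed forms.

### Simulation

Fixed-step Euler-Maruyama, `r ← r + a·Δt + diffusion·√Δt·N(0,1)`, default
`Δt = 0.001` time units and 10,000 trials; no Milstein correction and no
adaptive stepping (first-order weak accuracy is sufficient: at the default
step the discretization bias is far below the Monte-Carlo error, which the
coupled `dt`-halving diagnostic `dt_convergence` verifies on shared
Brownian increments). `t_sensory` need not be a multiple of `Δt`; a final
partial step uses the remainder. Where a trajectory wanders below the
domain of the square-root diffusion (possible in principle for
`r_t < −b²a/σ²`, or `r_t < 0` in multiplicative mode) the radicand is
clamped at zero, the standard treatment of square-root (CIR-type)
diffusions: the diffusion vanishes and the positive drift restores the
state. Reflection at zero was rejected because it alters the moments. The
clamp rate is logged with every run and is 0 at all default operating
points.

Randomness: every run is seeded (`numpy` PCG64); parameter sweeps give each
grid row an independent substream spawned deterministically from the base
seed, keeping rows statistically independent — a deliberate departure from
reusing one seed across conditions, which correlates rows; `shared_seed=True`
restores the shared-stream behavior for common-random-number comparisons.
CV standard errors come from a nonparametric bootstrap (1000 resamples) by
default, or a normal-theory delta method (`se_method="delta"`).

## Model comparison

The contrast with the standard account — Weber magnitude noise, hyperbolic
discounting `SV = r/(1 + k_h·t)`, linear scalar timing `δt = w_t·t` — is a
first-principles Monte-Carlo propagation: percepts are drawn as Gaussian
multiplicative noise with relative sd equal to the Weber fraction,
resampled to stay in the valid domain (truncation rate logged; < 1 % at
the defaults), pushed through the valuation, and the CV of the value change
`r − SV` is reported per delay. Only the qualitative claim is asserted:
TIMERR's profile is flat (equal to `k` in the `c = 0, l = 0` regime, which
the closed form predicts and the MC confirms within 3 standard errors)
while the standard profile's max/min exceeds 1 by far more than sampling
error. No analytic coefficients are claimed for the standard model's error.

## Numerical choices and edge cases

- All algebra is evaluated in double precision; the Eq-route identities
  hold to 1e-12 relative and are asserted on randomized draws.
- Inverting subjective time is ill-conditioned near saturation: the
  relative error of the round trip `inverse(ST(t))` is amplified by the
  condition number `(T_ime + t)/T_ime`, so the 1e-12 round-trip tolerance
  is meaningful only for `t ≲ 10³·T_ime`; the property test scales its
  tolerance with the condition number and the randomized acceptance check
  stays inside the well-conditioned regime.
- Degenerate discounting (`r/T_ime + a_est = 0`) makes the fixed-magnitude
  decomposition undefined (SV does not vary with delay) and raises.
- `dt` must allow at least 10 steps per trajectory; the `dt`-halving
  diagnostic requires `t_sensory` to be an integer multiple of `dt` so the
  coupled-path construction is exact.

## Default operating points

Neither the valuation theory nor its noise model prescribes numerical
parameter values; the defaults used by the experiments and examples are
artifact choices intended to be representative, fixed once:

- environment `T_ime = 10`, `a_est = 0.5`, offer `r = 5` (delays spanning
  0.5–16 time units);
- noise `k = 0.15` (timing slopes of 10–20 % are typical of scalar-timing
  data), `c = 0.1`, `l = 0.05`; the exact-Weber regime (`c = l = 0`) is
  used where the closed form predicts a constant ratio;
- accumulator `a = 2`, `b = 0.5`, `σ = 1` (additive) or `σ = 0.2`
  (multiplicative), `t_sensory = 2`; sweep grids span about a decade per
  parameter (`a ∈ [0.5, 8]`, `b, σ ∈ [0.1, 1]`, `T_ime ∈ [1, 100]`,
  `a_est ∈ [0, 2]`);
- the low-magnitude deviation of the additive CV is probed on a decade of
  expected magnitude `r ∈ [8, 80]` (via the sensory window at fixed
  `a = 2`), chosen so that the `b²/r` term is many standard errors above
  the `σ/√(2a)` asymptote at the small end and within sampling error of it
  at the large end for 10,000 trials;
- Monte-Carlo sizes: 10,000 trials/samples per condition, `Δt = 0.001` —
  large enough that 3·SE bands are a fraction of a percent of the
  quantities compared, small enough that the full acceptance run completes
  in well under a minute.

## What the simulations do and do not show

All inputs here are synthetic by construction — the package implements a
theory, not a data pipeline. The Monte-Carlo machinery emulates the model's
own noise assumptions (Gaussian JND-scaled percept noise, diffusive
accumulation); passing tests therefore establish internal consistency
(simulation agrees with the derived closed forms, the derived forms obey
the claimed Weber properties) and not that real perception obeys this
model. Behavioral Weber fractions, fits of `T_ime`, `a_est`, `k`, `c`, `l`
to data, choice rules built on top of the valuation, and spiking-level
implementations of the accumulator are all out of scope.
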