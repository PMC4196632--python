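"""Contrast TIMERR's flat value-change CV with the standard discounting account.

Standard assumptions — Weber's-law magnitude noise, hyperbolic discounting,
linear scalar timing — do not yield Weber's law in value: the CV of the
value change varies strongly with the delay. TIMERR's linear-in-subjective-
time discounting keeps it flat.
"""

from timerr import (
    StandardModelParams,
    TimeNoiseParams,
    TimerrParams,
    propagate_error_mc,
)

delays = [0.5, 1.0, 2.0, 4.0, 8.0, 16.0]

timerr_prof = propagate_error_mc(
    "timerr", r=5.0, delays=delays, n_samples=10_000, seed=0,
    timerr_params=TimerrParams(T_ime=10.0, a_est=0.5),
    time_noise=TimeNoiseParams(k=0.15, c=0.0, l=0.0),
)
std_prof = propagate_error_mc(
    "standard", r=5.0, delays=delays, n_samples=10_000, seed=1,
    standard_params=StandardModelParams(k_h=0.5, w_t=0.15, l=0.1),
)

print("TIMERR (pure scalar timing, k=0.15): CV of value change per delay")
print(timerr_prof[["delay", "cv", "se_cv", "analytic_cv"]].to_string(index=False))
print("\nhyperbolic + scalar timing (k_h=0.5, w_t=0.15, l=0.1):")
print(std_prof[["delay", "cv", "se_cv"]].to_string(index=False))
print(f"\nTIMERR   CV max/min = {timerr_prof['cv'].max() / timerr_prof['cv'].min():.3f}")
print(f"standard CV max/min = {std_prof['cv'].max() / std_prof['cv'].min():.3f}")
# TIMERR's profile stays at the closed-form constant k across a 32-fold
# range of delays (max/min ~= 1 within sampling error); the standard
# account's profile drops by ~50% — far from Weber's law in value.
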