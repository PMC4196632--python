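"""Propagation of perceptual JNDs into subjective-value error.

Two noise sources feed the error in subjective value:

* the just-noticeable difference (JND) of the subjective representation of
  the delay, taken to be affine in subjective time, ``δST = k·ST + c``
  (``k`` a dimensionless slope — scalar timing — and ``c`` a constant
  read-out error in subjective-time units);
* the JND of the measured reward magnitude, taken to obey exact Weber's law,
  ``δr = l·r`` with Weber fraction ``l``.

Because discounting is linear in subjective time (``SV = r - D·ST`` with
``D = r/T_ime + a_est``), a worst-case-aligned composition of the two JNDs
(magnitude error raises value, timing error deepens the discount) gives

    δSV = δr·(1 - ST/T_ime) + D·δST + δr·δST/T_ime

All returned errors are magnitudes: the sign only records that discounting
lowers value, so it is dropped.  The JNDs combine linearly, *not* in
quadrature — these are aligned worst-case perceptual errors, not independent
variances.

The central results exposed here: the error in the value *change* ``r - SV``
is proportional to that change (Weber's law in value perception), the error
of an immediate reward is proportional to its magnitude, and the combined
error remains affine in SV both across delays at fixed magnitude and across
magnitudes at fixed delay (:func:`weber_decomposition_fixed_r`,
:func:`weber_decomposition_fixed_t`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from timerr.core import (
    ArrayLike,
    RewardOffer,
    TimerrParams,
    discount_slope,
    subjective_time,
    subjective_value,
)

__all__ = [
    "TimeNoiseParams",
    "ValueJND",
    "WeberDecomposition",
    "jnd_subjective_time",
    "sv_error_time_only",
    "sv_error_immediate",
    "sv_error_combined",
    "weber_decomposition_fixed_r",
    "weber_decomposition_fixed_t",
    "weber_fraction_surface",
]


@dataclass(frozen=True)
class TimeNoiseParams:
    """Noise model for perception: affine subjective-time JND plus magnitude Weber fraction.

    ``k``: dimensionless slope of the subjective-time JND (scalar component).
    ``c``: constant read-out error, subjective-time units.
    ``l``: Weber fraction of reward-magnitude measurement (``δr = l·r``).
    """

    k: float
    c: float = 0.0
    l: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k", "c", "l"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative, got {getattr(self, name)}")


@dataclass(frozen=True)
class ValueJND:
    """Magnitude of the subjective-value JND, with its additive breakdown.

    ``components`` holds the magnitude term ``δr·(1 - ST/T_ime)``, the time
    term ``D·δST`` and the cross term ``δr·δST/T_ime``; they sum to
    ``delta_sv``.
    """

    delta_sv: ArrayLike
    components: Mapping[str, ArrayLike] = field(default_factory=dict)

    def __float__(self) -> float:
        return float(self.delta_sv)


@dataclass(frozen=True)
class WeberDecomposition:
    """Affine representation ``δSV = slope·SV + intercept`` along one axis.

    ``slope`` is dimensionless, ``intercept`` in reward units.  A constant
    ratio ``δSV/SV`` (Weber's law proper) corresponds to ``intercept = 0``;
    a nonzero intercept quantifies the departure.
    """

    slope: float
    intercept: float

    def predict(self, sv: ArrayLike) -> ArrayLike:
        return self.slope * np.asarray(sv, dtype=float) + self.intercept

    def weber_fraction_at(self, sv: ArrayLike) -> ArrayLike:
        """Ratio ``δSV / SV`` at a given subjective value (> 0)."""
        sv = np.asarray(sv, dtype=float)
        if np.any(sv <= 0):
            raise ValueError("reference subjective value must be positive")
        out = self.predict(sv) / sv
        return float(out) if np.ndim(out) == 0 else out


def jnd_subjective_time(st: ArrayLike, noise: TimeNoiseParams) -> ArrayLike:
    """Affine JND of subjective time: ``δST = k·st + c``."""
    st = np.asarray(st, dtype=float)
    if np.any(st < 0):
        raise ValueError("subjective time must be nonnegative")
    d = noise.k * st + noise.c
    return float(d) if d.ndim == 0 else d


def _as_scalar_or_array(x: np.ndarray) -> ArrayLike:
    return float(x) if np.ndim(x) == 0 else x


def sv_error_time_only(
    offer: RewardOffer, params: TimerrParams, noise: TimeNoiseParams
) -> ValueJND:
    """Subjective-value error from timing noise alone (magnitude noiseless).

    ``δSV = D·(k·ST + c)`` with ``D = r/T_ime + a_est``; equivalently
    ``c·D + k·(r - SV)`` — the error is affine in the drop of value caused
    by the delay, which is Weber's law for the value change.  The magnitude
    Weber fraction ``noise.l`` is ignored.
    """
    st = subjective_time(offer.t, params)
    d = discount_slope(offer.r, params)
    time_term = np.asarray(d * jnd_subjective_time(st, noise))
    return ValueJND(
        delta_sv=_as_scalar_or_array(time_term),
        components={
            "magnitude": _as_scalar_or_array(np.zeros_like(time_term)),
            "time": _as_scalar_or_array(time_term),
            "cross": _as_scalar_or_array(np.zeros_like(time_term)),
        },
    )


def sv_error_immediate(
    r: ArrayLike,
    params: TimerrParams,
    noise: TimeNoiseParams,
    include_magnitude_noise: bool = False,
) -> ValueJND:
    """Error in the value of an *immediate* reward; affine in ``r``.

    Timing noise only (flag off): ``δSV(r, 0) = c·(r/T_ime + a_est)`` — the
    constant read-out error of the infinitesimal delay already yields
    Weber's law in magnitude.  With magnitude noise included (flag on):
    ``δSV(r, 0) = r·(l·(1 + c/T_ime) + c/T_ime) + c·a_est``.
    """
    if np.any(np.asarray(r) < 0):
        raise ValueError("reward magnitude must be nonnegative")
    if not include_magnitude_noise:
        return sv_error_time_only(RewardOffer(r=r, t=np.zeros_like(np.asarray(r, dtype=float))), params, noise)
    return sv_error_combined(RewardOffer(r=r, t=np.zeros_like(np.asarray(r, dtype=float))), params, noise)


def sv_error_combined(
    offer: RewardOffer, params: TimerrParams, noise: TimeNoiseParams
) -> ValueJND:
    """Combined subjective-value error from magnitude and timing JNDs.

    The aligned (worst-case) composition of ``δr = l·r`` raising value and
    ``δST = k·ST + c`` deepening the discount:

        δSV = δr·(1 - ST/T_ime) + D·δST + δr·δST/T_ime

    Reduces to :func:`sv_error_time_only` at ``l = 0`` and to
    :func:`sv_error_immediate` (flag on) at ``t = 0``.
    """
    r = np.asarray(offer.r, dtype=float)
    st = np.asarray(subjective_time(offer.t, params))
    d = np.asarray(discount_slope(r, params))
    delta_r = noise.l * r
    delta_st = np.asarray(jnd_subjective_time(st, noise))

    mag_term = delta_r * (1.0 - st / params.T_ime)
    time_term = d * delta_st
    cross_term = delta_r * delta_st / params.T_ime
    total = mag_term + time_term + cross_term
    return ValueJND(
        delta_sv=_as_scalar_or_array(total),
        components={
            "magnitude": _as_scalar_or_array(mag_term),
            "time": _as_scalar_or_array(time_term),
            "cross": _as_scalar_or_array(cross_term),
        },
    )


def sv_error_combined_regrouped(
    offer: RewardOffer, params: TimerrParams, noise: TimeNoiseParams
) -> ArrayLike:
    """The combined error regrouped around SV (cross-check route).

        δSV = (l - k)·SV + (l·a_est + l·r·k/T_ime)·ST
              + r·((1 + l)·c/T_ime + k) + c·a_est

    Algebraically identical to :func:`sv_error_combined`; kept as a separate
    route so the identity can be asserted rather than assumed.
    """
    r = np.asarray(offer.r, dtype=float)
    st = np.asarray(subjective_time(offer.t, params))
    sv = np.asarray(subjective_value(offer, params))
    k, c, l = noise.k, noise.c, noise.l
    T, a = params.T_ime, params.a_est
    out = (
        (l - k) * sv
        + (l * a + l * r * k / T) * st
        + r * ((1.0 + l) * c / T + k)
        + c * a
    )
    return _as_scalar_or_array(out)


def weber_decomposition_fixed_r(
    r: float, params: TimerrParams, noise: TimeNoiseParams
) -> WeberDecomposition:
    """Affine-in-SV form of the combined error at fixed magnitude, varying delay.

    Substituting ``ST = (r - SV)/D`` into the regrouped combined error gives
    ``δSV = slope·SV + intercept`` with

        slope     = (l - k) - (l·a_est + l·r·k/T_ime) / D
        intercept = (l·a_est + l·r·k/T_ime)·r/D + r·((1+l)·c/T_ime + k) + c·a_est

    valid for every delay ``t >= 0``.  The affinity in SV is the Weber's-law
    statement for a fixed reward delayed by varying amounts.
    """
    d = discount_slope(r, params)
    if d == 0:
        raise ValueError(
            "degenerate decomposition: r/T_ime + a_est = 0 means no discounting, "
            "so SV does not vary with delay"
        )
    k, c, l = noise.k, noise.c, noise.l
    T, a = params.T_ime, params.a_est
    st_coeff = l * a + l * r * k / T
    slope = (l - k) - st_coeff / d
    intercept = st_coeff * r / d + r * ((1.0 + l) * c / T + k) + c * a
    return WeberDecomposition(slope=slope, intercept=intercept)


def weber_decomposition_fixed_t(
    t: float, params: TimerrParams, noise: TimeNoiseParams
) -> WeberDecomposition:
    """Affine-in-SV form of the combined error at fixed delay, varying magnitude.

    At fixed ``t`` the combined error is affine in ``r``:

        δSV = q·r + a_est·δST,   q = l·(1 - ST/T_ime) + (1 + l)·δST_slope/T_ime ...

    computed here directly from the error expression, then re-expressed in
    SV via ``r = (SV + a_est·ST)/(1 - ST/T_ime)`` (well defined since
    ``ST < T_ime`` for every finite delay).
    """
    if t < 0:
        raise ValueError("delay must be nonnegative")
    st = subjective_time(t, params)
    k, c, l = noise.k, noise.c, noise.l
    T, a = params.T_ime, params.a_est
    delta_st = k * st + c
    # δSV as an affine function of r at fixed ST:
    #   δSV = l·r·(1 - ST/T) + (r/T + a)·δST + l·r·δST/T
    r_coeff = l * (1.0 - st / T) + delta_st / T + l * delta_st / T
    r_const = a * delta_st
    # r = (SV + a·ST)/(1 - ST/T); 1 - ST/T = 1/(1 + t/T) > 0 always.
    shrink = 1.0 - st / T
    slope = r_coeff / shrink
    intercept = r_coeff * a * st / shrink + r_const
    return WeberDecomposition(slope=slope, intercept=intercept)


def weber_fraction_surface(
    r_grid: Iterable[float],
    t_grid: Iterable[float],
    params_grid: Iterable[TimerrParams],
    noise: TimeNoiseParams,
) -> pd.DataFrame:
    """Tabulate Weber fractions over grids of magnitude, delay and environment.

    For each combination the table reports the combined error ``delta_sv``,
    the value-change Weber fraction ``δSV/(r - SV)`` (the referent for
    delayed rewards; NaN where ``r = SV``, i.e. at ``t = 0``) and the
    magnitude Weber fraction ``δSV(r, 0)/r`` (the referent for immediate
    rewards; NaN at ``r = 0``).

    Columns: ``r, t, T_ime, a_est, k, c, l, ST, SV, delta_sv,
    weber_fraction_change, weber_fraction_magnitude``.
    """
    rows = []
    for params, r, t in itertools.product(params_grid, r_grid, t_grid):
        offer = RewardOffer(r=r, t=t)
        st = subjective_time(t, params)
        sv = subjective_value(offer, params)
        dsv = sv_error_combined(offer, params, noise).delta_sv
        change = r - sv
        frac_change = dsv / change if change > 0 else np.nan
        dsv0 = sv_error_immediate(r, params, noise, include_magnitude_noise=True).delta_sv
        frac_mag = dsv0 / r if r > 0 else np.nan
        rows.append(
            {
                "r": r,
                "t": t,
                "T_ime": params.T_ime,
                "a_est": params.a_est,
                "k": noise.k,
                "c": noise.c,
                "l": noise.l,
                "ST": st,
                "SV": sv,
                "delta_sv": dsv,
                "weber_fraction_change": frac_change,
                "weber_fraction_magnitude": frac_mag,
            }
        )
    return pd.DataFrame(rows)
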