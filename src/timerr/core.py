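"""Deterministic TIMERR valuation.

TIMERR values a reward of magnitude ``r`` delayed by ``t`` as the immediate
reward that would produce the same total reward rate over a window made of
the past integration interval ``T_ime`` — the lookback over which the
experienced reward rate ``a_est`` was estimated — plus the delay itself:

.. math::

    SV(r, t) = \\frac{r - a_{est}\\,t}{1 + t/T_{ime}}

The delay is represented internally on a compressed (subjective) time scale

.. math::

    ST(t) = \\frac{t}{1 + t/T_{ime}}

which is concave, strictly increasing, and saturates at ``T_ime``.  On that
scale discounting is exactly linear,

.. math::

    SV = r - (r/T_{ime} + a_{est})\\,ST(t),

an algebraic identity that the error-propagation machinery in
:mod:`timerr.noise` relies on.

All quantities are in user-defined but mutually consistent "model units"
(reward units, time units); the theory fixes no absolute scale.  Subjective
value may legitimately be negative when the opportunity cost ``a_est * t``
exceeds the offered magnitude; no clamping is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TimerrParams",
    "RewardOffer",
    "subjective_time",
    "inverse_subjective_time",
    "subjective_value",
    "subjective_value_linear_form",
    "discount_slope",
]

ArrayLike = float | np.ndarray


@dataclass(frozen=True)
class TimerrParams:
    """Environment/agent state of the TIMERR valuation.

    Parameters
    ----------
    T_ime:
        Past integration interval (time units), strictly positive.  Sets both
        the steepness of discounting and the saturation level of subjective
        time.
    a_est:
        Experienced reward rate over that interval (reward units per time
        unit), nonnegative.
    """

    T_ime: float
    a_est: float = 0.0

    def __post_init__(self) -> None:
        if not np.all(np.asarray(self.T_ime) > 0):
            raise ValueError(f"T_ime must be strictly positive, got {self.T_ime}")
        if not np.all(np.asarray(self.a_est) >= 0):
            raise ValueError(f"a_est must be nonnegative, got {self.a_est}")


@dataclass(frozen=True)
class RewardOffer:
    """A reward of magnitude ``r`` (>= 0) delivered after delay ``t`` (>= 0).

    ``r`` is, strictly, the subjective value of the same reward offered
    immediately: ``r = SV(r, 0)``.  Negative magnitudes (punishments) are
    rejected.
    """

    r: ArrayLike
    t: ArrayLike

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.r) < 0):
            raise ValueError(f"reward magnitude must be nonnegative, got {self.r}")
        if np.any(np.asarray(self.t) < 0):
            raise ValueError(f"delay must be nonnegative, got {self.t}")


def subjective_time(t: ArrayLike, params: TimerrParams) -> ArrayLike:
    """Map an objective delay onto the subjective time scale.

    ``ST(t) = t / (1 + t/T_ime)``: strictly increasing, concave, with
    ``ST(t) <= t`` and ``ST(t) -> T_ime`` as ``t -> inf``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("delay t must be nonnegative")
    st = t / (1.0 + t / params.T_ime)
    return float(st) if st.ndim == 0 else st


def inverse_subjective_time(st: ArrayLike, params: TimerrParams) -> ArrayLike:
    """Objective delay producing subjective time ``st``.

    Inverts ``subjective_time``; defined for ``0 <= st < T_ime`` (the
    subjective scale saturates at ``T_ime``, so larger values correspond to
    no finite delay).
    """
    st = np.asarray(st, dtype=float)
    if np.any(st < 0):
        raise ValueError("subjective time must be nonnegative")
    if np.any(st >= params.T_ime):
        raise ValueError(
            f"subjective time must be < T_ime = {params.T_ime} (the scale saturates there)"
        )
    t = st / (1.0 - st / params.T_ime)
    return float(t) if t.ndim == 0 else t


def subjective_value(offer: RewardOffer, params: TimerrParams) -> ArrayLike:
    """Subjective value of a delayed reward.

    ``SV(r, t) = (r - a_est * t) / (1 + t/T_ime)``.  Equals ``r`` at ``t = 0``
    and may be negative when the forgone reward ``a_est * t`` exceeds ``r``.
    """
    r = np.asarray(offer.r, dtype=float)
    t = np.asarray(offer.t, dtype=float)
    sv = (r - params.a_est * t) / (1.0 + t / params.T_ime)
    return float(sv) if sv.ndim == 0 else sv


def subjective_value_linear_form(
    r: ArrayLike, st: ArrayLike, params: TimerrParams
) -> ArrayLike:
    """Subjective value expressed in the delay's subjective representation.

    ``SV = r - (r/T_ime + a_est) * st`` — discounting is linear in subjective
    time; algebraically identical to :func:`subjective_value` evaluated at
    the delay ``inverse_subjective_time(st)``.
    """
    r = np.asarray(r, dtype=float)
    st = np.asarray(st, dtype=float)
    if np.any(st < 0) or np.any(st >= params.T_ime):
        raise ValueError(f"subjective time must lie in [0, T_ime = {params.T_ime})")
    sv = r - (r / params.T_ime + params.a_est) * st
    return float(sv) if sv.ndim == 0 else sv


def discount_slope(r: ArrayLike, params: TimerrParams) -> ArrayLike:
    """Rate at which value is lost per unit subjective time: ``r/T_ime + a_est``.

    This slope is the pivot of the error-propagation algebra: a JND in
    subjective time costs ``discount_slope * δST`` units of value.
    """
    r = np.asarray(r, dtype=float)
    d = r / params.T_ime + params.a_est
    return float(d) if d.ndim == 0 else d
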