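"""Monte-Carlo contrast: TIMERR vs the standard discounting assumptions.

The standard account of intertemporal valuation combines (1) Weber's-law
noise on the measured reward magnitude, (2) a hyperbolic discounting
function ``SV = r/(1 + k_h·t)``, and (3) a linear subjective representation
of time with scalar (Weber's-law) noise, ``δt = w_t·t``.  Under TIMERR the
propagated error in the value *change* ``r - SV`` is proportional to that
change, so its coefficient of variation is flat across delays.  Under the
standard assumptions the propagated error is far from proportional: the CV
of the value change varies strongly with the delay.

This module makes that contrast computable: :func:`propagate_error_mc`
pushes multiplicative Gaussian percept noise through either valuation and
reports the CV of the value change on a delay grid, together with the TIMERR
closed-form reference from :mod:`timerr.noise`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from timerr.core import (
    RewardOffer,
    TimerrParams,
    discount_slope,
    subjective_time,
    subjective_value,
)
from timerr.noise import TimeNoiseParams, sv_error_combined

__all__ = ["StandardModelParams", "hyperbolic_sv", "propagate_error_mc"]

_MAX_RESAMPLE_ROUNDS = 100


@dataclass(frozen=True)
class StandardModelParams:
    """Hyperbolic discounting with scalar timing and Weber magnitude noise.

    ``k_h``: hyperbolic discount rate (per time unit), > 0.
    ``w_t``: timing Weber fraction (``δt = w_t·t``), >= 0.
    ``l``: magnitude Weber fraction (``δr = l·r``), >= 0.
    """

    k_h: float
    w_t: float = 0.0
    l: float = 0.0

    def __post_init__(self) -> None:
        if self.k_h <= 0:
            raise ValueError(f"k_h must be positive, got {self.k_h}")
        if self.w_t < 0 or self.l < 0:
            raise ValueError("Weber fractions w_t and l must be nonnegative")


def hyperbolic_sv(r: float | np.ndarray, t: float | np.ndarray, params: StandardModelParams):
    """Hyperbolically discounted value ``r / (1 + k_h·t)``."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("delay must be nonnegative")
    sv = np.asarray(r, dtype=float) / (1.0 + params.k_h * t)
    return float(sv) if sv.ndim == 0 else sv


def _truncated_normal_factor(
    rng: np.random.Generator, n: int, rel_sd: float, low: float, high: float = math.inf
) -> tuple[np.ndarray, int]:
    """Draw ``1 + rel_sd·z`` resampled into ``(low, high)``; returns draws and resample count."""
    x = 1.0 + rel_sd * rng.standard_normal(n)
    resampled = 0
    for _ in range(_MAX_RESAMPLE_ROUNDS):
        bad = (x < low) | (x >= high)
        n_bad = int(np.count_nonzero(bad))
        if n_bad == 0:
            break
        resampled += n_bad
        x[bad] = 1.0 + rel_sd * rng.standard_normal(n_bad)
    else:
        raise RuntimeError(
            "percept resampling failed to converge; noise parameters place most "
            "mass outside the valid domain"
        )
    return x, resampled


def propagate_error_mc(
    model: Literal["timerr", "standard"],
    *,
    r: float,
    delays: Iterable[float],
    n_samples: int = 10_000,
    seed: int = 0,
    timerr_params: TimerrParams | None = None,
    time_noise: TimeNoiseParams | None = None,
    standard_params: StandardModelParams | None = None,
) -> pd.DataFrame:
    """CV profile of the value change ``r - SV`` over a delay grid, by Monte Carlo.

    For each delay, percepts are sampled (Gaussian, relative sd = the Weber
    fraction; draws are resampled to stay in the valid domain and the
    truncation rate logged) and the valuation applied:

    * ``model="standard"``: ``r' = r·(1 + l·z₁)``, ``t' = t·(1 + w_t·z₂)``,
      value change ``r' - r'/(1 + k_h·t')``;
    * ``model="timerr"``: ``r' = r·(1 + l·z₁)`` and a perturbed subjective
      time ``ST' = ST + (k·ST + c)·z₂`` (the JND sets the noise scale),
      value change ``(r'/T_ime + a_est)·ST'``.

    Returns one row per delay with columns ``delay, model, mean_change,
    sd_change, cv, se_cv, analytic_cv, truncation_rate``; ``analytic_cv`` is
    the TIMERR closed-form reference ``δSV/(r - SV)`` (NaN for the standard
    model, which has no closed form here).
    """
    delays = [float(t) for t in delays]
    if len(delays) == 0 or any(t <= 0 for t in delays):
        raise ValueError("delays must be a non-empty grid of strictly positive times")
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if model == "timerr":
        if timerr_params is None or time_noise is None:
            raise ValueError("timerr model needs timerr_params and time_noise")
    elif model == "standard":
        if standard_params is None:
            raise ValueError("standard model needs standard_params")
    else:
        raise ValueError(f"unknown model {model!r}")

    children = np.random.SeedSequence(seed).spawn(len(delays))
    rows = []
    for t, child in zip(delays, children):
        rng = np.random.default_rng(child)
        truncated = 0
        if model == "standard":
            p = standard_params
            rf, n_tr = _truncated_normal_factor(rng, n_samples, p.l, 0.0)
            truncated += n_tr
            tf, n_tr = _truncated_normal_factor(rng, n_samples, p.w_t, 0.0)
            truncated += n_tr
            r_p = r * rf
            t_p = t * tf
            change = r_p - hyperbolic_sv(r_p, t_p, p)
            analytic = math.nan
        else:
            tp, nz = timerr_params, time_noise
            st = subjective_time(t, tp)
            rf, n_tr = _truncated_normal_factor(rng, n_samples, nz.l, 0.0)
            truncated += n_tr
            jnd = nz.k * st + nz.c
            if st > 0:
                stf, n_tr = _truncated_normal_factor(
                    rng, n_samples, jnd / st, 0.0, tp.T_ime / st
                )
                st_p = st * stf
                truncated += n_tr
            else:
                st_p = np.zeros(n_samples)
            r_p = r * rf
            change = discount_slope(r_p, tp) * st_p
            offer = RewardOffer(r=r, t=t)
            dsv = sv_error_combined(offer, tp, nz).delta_sv
            drop = r - subjective_value(offer, tp)
            analytic = dsv / drop if drop > 0 else math.nan

        mean = float(np.mean(change))
        sd = float(np.std(change, ddof=1))
        cv = sd / mean if mean > 0 else math.nan
        se_cv = (
            cv * math.sqrt(1.0 / (2.0 * (n_samples - 1)) + cv**2 / n_samples)
            if mean > 0
            else math.nan
        )
        rows.append(
            {
                "delay": t,
                "model": model,
                "mean_change": mean,
                "sd_change": sd,
                "cv": cv,
                "se_cv": se_cv,
                "analytic_cv": analytic,
                "truncation_rate": truncated / (2 * n_samples),
            }
        )
    return pd.DataFrame(rows)
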