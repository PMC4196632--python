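"""Reproducible parameter sweeps ("figure experiments") and their config plumbing.

Each registered experiment regenerates one of the model's headline tables:

``fig3a`` / ``fig3b``
    Magnitude Weber fraction ``δSV(r,0)/r`` as the past integration interval
    (``T_ime``) and the experienced reward rate (``a_est``) vary.  The model
    predicts the fraction falls with ``T_ime`` (better timing, better
    magnitude perception) and rises with ``a_est``; the runner asserts both
    monotonicities.
``fig4`` / ``fig5``
    Accumulator CV sweeps in additive and multiplicative noise mode over
    grids of the input rate ``a``, input noise ``b`` and feedback noise
    ``σ``, with analytic and Monte-Carlo columns; the runner asserts
    row-wise agreement ``|empirical − analytic| ≤ max(3·SE, 5%·analytic)``.
``compare``
    Value-change CV profiles over delay for TIMERR and the standard
    hyperbolic + scalar-timing account.

Grid defaults are artifact choices spanning about a decade per parameter;
the underlying theory prescribes no particular values.  All randomness is
governed by ``SimConfig``; identical configs and seeds reproduce identical
output files byte for byte on a fixed platform.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from timerr.accumulator import AccumulatorParams, SimConfig, cv_sweep
from timerr.compare import StandardModelParams, propagate_error_mc
from timerr.core import TimerrParams
from timerr.noise import TimeNoiseParams, weber_fraction_surface

__all__ = [
    "ExperimentConfig",
    "EXPERIMENTS",
    "run_experiment",
    "run_fig3",
    "run_fig4",
    "run_fig5",
    "run_compare",
]

# Artifact default grids (decade-ish spans); not prescribed by the theory.
DEFAULT_GRIDS: dict[str, list[float]] = {
    "T_ime": list(np.logspace(0, 2, 9)),      # 1 .. 100 time units
    "a_est": list(np.linspace(0.0, 2.0, 9)),  # 0 .. 2 reward units / time
    "a": [0.5, 1.0, 2.0, 4.0, 8.0],
    "b": [0.1, 0.25, 0.5, 1.0],
    "sigma": [0.1, 0.25, 0.5, 1.0],
    "delays": [0.5, 1.0, 2.0, 4.0, 8.0, 16.0],
}

# Reference operating point shared by the figure runners.
DEFAULT_R = 5.0
DEFAULT_TIMERR = TimerrParams(T_ime=10.0, a_est=0.5)
DEFAULT_NOISE = TimeNoiseParams(k=0.15, c=0.1, l=0.05)
DEFAULT_ADDITIVE = AccumulatorParams(a=2.0, b=0.5, sigma=1.0, t_sensory=2.0, mode="additive")
DEFAULT_MULTIPLICATIVE = AccumulatorParams(
    a=2.0, b=0.5, sigma=0.2, t_sensory=2.0, mode="multiplicative"
)
DEFAULT_STANDARD = StandardModelParams(k_h=0.5, w_t=0.15, l=0.1)


@dataclass(frozen=True)
class ExperimentConfig:
    """Which experiment to run, on which grids, with which simulation settings."""

    experiment: str
    grids: dict[str, list[float]] = field(default_factory=dict)
    sim: SimConfig = field(default_factory=SimConfig)
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; "
                f"registered: {sorted(EXPERIMENTS)}"
            )

    def grid(self, name: str) -> list[float]:
        g = self.grids.get(name, DEFAULT_GRIDS[name])
        if len(g) == 0:
            raise ValueError(f"empty grid for {name!r}")
        return [float(x) for x in g]

    def to_dict(self) -> dict:
        return {
            "experiment": self.experiment,
            "grids": {k: [float(x) for x in v] for k, v in self.grids.items()},
            "sim": dataclasses.asdict(self.sim),
            "outdir": self.outdir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(
            experiment=d["experiment"],
            grids={k: list(v) for k, v in d.get("grids", {}).items()},
            sim=SimConfig(**d.get("sim", {})),
            outdir=d.get("outdir"),
        )


def _write_outputs(config: ExperimentConfig, table: pd.DataFrame) -> None:
    if config.outdir is None:
        return
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / f"{config.experiment}.csv", index=False, float_format="%.12g")
    with open(outdir / f"{config.experiment}_config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def _assert_strict(values: np.ndarray, direction: str, what: str) -> None:
    diffs = np.diff(values)
    ok = np.all(diffs < 0) if direction == "decreasing" else np.all(diffs > 0)
    if not ok:
        raise RuntimeError(f"{what} is not strictly {direction}: {values}")


def run_fig3(config: ExperimentConfig) -> pd.DataFrame:
    """Magnitude Weber fraction vs ``T_ime`` (fig3a) or ``a_est`` (fig3b)."""
    panel = config.experiment  # fig3a | fig3b
    if panel == "fig3a":
        params_grid = [
            TimerrParams(T_ime=T, a_est=DEFAULT_TIMERR.a_est) for T in config.grid("T_ime")
        ]
        axis = "T_ime"
        direction = "decreasing"
    else:
        params_grid = [
            TimerrParams(T_ime=DEFAULT_TIMERR.T_ime, a_est=a) for a in config.grid("a_est")
        ]
        axis = "a_est"
        direction = "increasing"
    table = weber_fraction_surface(
        r_grid=[DEFAULT_R], t_grid=[0.0], params_grid=params_grid, noise=DEFAULT_NOISE
    )
    _assert_strict(
        table["weber_fraction_magnitude"].to_numpy(),
        direction,
        f"magnitude Weber fraction vs {axis}",
    )
    _write_outputs(config, table)
    return table


def _run_accumulator_fig(config: ExperimentConfig, base: AccumulatorParams) -> pd.DataFrame:
    pieces = []
    for i, vary in enumerate(("a", "b", "sigma")):
        sub_sim = dataclasses.replace(config.sim, seed=config.sim.seed + i)
        pieces.append(cv_sweep(base, vary, config.grid(vary), sub_sim))
    table = pd.concat(pieces, ignore_index=True)
    bad = (table["empirical_cv"] - table["analytic_cv"]).abs() > np.maximum(
        3.0 * table["se_cv"], 0.05 * table["analytic_cv"]
    )
    if bad.any():
        raise RuntimeError(
            "simulation disagrees with the analytic CV beyond max(3·SE, 5%):\n"
            f"{table[bad]}"
        )
    _write_outputs(config, table)
    return table


def run_fig4(config: ExperimentConfig) -> pd.DataFrame:
    """Additive-mode CV sweeps (approximate Weber's law)."""
    return _run_accumulator_fig(config, DEFAULT_ADDITIVE)


def run_fig5(config: ExperimentConfig) -> pd.DataFrame:
    """Multiplicative-mode CV sweeps (exact Weber's law: analytic CV flat in ``a``)."""
    table = _run_accumulator_fig(config, DEFAULT_MULTIPLICATIVE)
    flat = table.loc[table["param"] == "a", "analytic_cv"].to_numpy()
    if not np.allclose(flat, flat[0], rtol=1e-14):
        raise RuntimeError("multiplicative analytic CV should be independent of a")
    return table


def run_compare(config: ExperimentConfig) -> pd.DataFrame:
    """Value-change CV profiles over delay: TIMERR (flat) vs standard assumptions."""
    delays = config.grid("delays")
    exact_weber_noise = TimeNoiseParams(k=DEFAULT_NOISE.k, c=0.0, l=0.0)
    timerr_profile = propagate_error_mc(
        "timerr",
        r=DEFAULT_R,
        delays=delays,
        n_samples=config.sim.n_trials,
        seed=config.sim.seed,
        timerr_params=DEFAULT_TIMERR,
        time_noise=exact_weber_noise,
    )
    standard_profile = propagate_error_mc(
        "standard",
        r=DEFAULT_R,
        delays=delays,
        n_samples=config.sim.n_trials,
        seed=config.sim.seed + 1,
        standard_params=DEFAULT_STANDARD,
    )
    table = pd.concat([timerr_profile, standard_profile], ignore_index=True)
    _write_outputs(config, table)
    return table


EXPERIMENTS: dict[str, Callable[[ExperimentConfig], pd.DataFrame]] = {
    "fig3a": run_fig3,
    "fig3b": run_fig3,
    "fig4": run_fig4,
    "fig5": run_fig5,
    "compare": run_compare,
}


def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Dispatch a configured experiment to its registered runner."""
    return EXPERIMENTS[config.experiment](config)
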