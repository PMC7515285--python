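"""Reproducible computational experiments over the facilitation model.

Each experiment is a pure function from a configuration (parameter grids,
sample sizes, a seed) to a tidy :class:`pandas.DataFrame`, so every run
is deterministic and every analytic cell can be recomputed independently
from :mod:`synfac.bounds`.  The experiments mirror the standard questions
one asks of the model:

* ``sweep_bounds`` — analytic bound sweeps over parameter grids;
* ``effect_map`` — maps of where facilitation provably increases or
  decreases the (energy-normalized) information rate;
* ``correlated_input_experiment`` — numerical (CTW) classification under
  sinusoidally correlated inhomogeneous-Poisson input;
* ``compare_models`` — CTW rates of the two-state model next to the
  general time-constant model, with the analytic bracket alongside.

Named presets reproduce the canonical figure configurations.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bounds import classify_effect, compute_bounds
from .core import BinaryTrain, InputStats, SynapseParams
from .ctw import CTWConfig, energy_normalized_estimate, mi_rate_estimate
from .simulate import (
    GeneralModelParams,
    RateSignal,
    generate_bernoulli_train,
    generate_inhomogeneous_train,
    simulate_general_release,
    simulate_two_state_release,
)

__all__ = [
    "SweepGrid",
    "sweep_bounds",
    "effect_map",
    "correlated_input_experiment",
    "compare_models",
    "psth",
    "FIGURE_PRESETS",
    "run_preset",
]

logger = logging.getLogger(__name__)

_PARAM_KEYS = ("p1", "q1", "pmax", "qmax", "u", "v", "alpha")
_DEFAULT_GRID = tuple(np.round(np.linspace(0.05, 0.95, 19), 10))


@dataclasses.dataclass(frozen=True)
class SweepGrid:
    """Cartesian parameter grid for analytic sweeps.

    ``axes`` maps parameter names to value lists; the pseudo-axis ``uv``
    ties ``u = v``.  ``fixed`` holds the remaining parameters.  Every grid
    point must define a valid synapse parameterization.
    """

    axes: Mapping[str, Sequence[float]]
    fixed: Mapping[str, float]

    def points(self):
        names = list(self.axes)
        for combo in itertools.product(*(self.axes[n] for n in names)):
            point = dict(self.fixed)
            point.update(zip(names, combo))
            yield point


def _resolve_point(point: dict) -> tuple[SynapseParams, InputStats]:
    point = dict(point)
    if "uv" in point:
        tied = point.pop("uv")
        point["u"] = tied
        point["v"] = tied
    missing = [k for k in _PARAM_KEYS if k not in point]
    if missing:
        raise ValueError(f"grid point {point} missing parameters {missing}")
    try:
        params = SynapseParams(p1=point["p1"], q1=point["q1"], pmax=point["pmax"],
                               qmax=point["qmax"], u=point["u"], v=point["v"])
        stats = InputStats(alpha=point["alpha"])
    except ValueError as err:
        raise ValueError(f"invalid grid point {point}: {err}") from err
    return params, stats


def sweep_bounds(grid: SweepGrid) -> pd.DataFrame:
    """Evaluate the analytic :class:`BoundSet` at every grid point.

    Returns one row per point with the grid coordinates and columns
    ``R1, R2, RLB, RUB, release_prob, R1_E, RLB_E, RUB_E, rate_effect,
    energy_effect``.  Deterministic — no randomness is involved.
    """
    rows = []
    for point in grid.points():
        params, stats = _resolve_point(point)
        bs = compute_bounds(params, stats)
        eff = classify_effect(params, stats)
        row = dict(point)
        row.update(
            R1=bs.r1, R2=bs.r2, RLB=bs.rlb, RUB=bs.rub,
            release_prob=bs.release_prob, R1_E=bs.r1_energy,
            RLB_E=bs.rlb_energy, RUB_E=bs.rub_energy,
            rate_effect=eff.rate_effect.value,
            energy_effect=eff.energy_effect.value,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def effect_map(grid: SweepGrid) -> pd.DataFrame:
    """Classification map (the three-color increases/decreases/undetermined maps).

    Same rows as :func:`sweep_bounds`; provided as its own entry point
    because the maps are usually rendered from the two effect columns
    alone.
    """
    return sweep_bounds(grid)


def _child_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def compare_models(
    p1_values: Sequence[float] = (0.1, 0.5),
    alpha_values: Sequence[float] = (0.1, 0.3, 0.5),
    *,
    q1: float = 0.05,
    pmax: float = 1.0,
    qmax: float = 0.2,
    u: float = 0.5,
    v: float = 0.5,
    tau_L: float = 250.0,
    tau_f: float = 20.0,
    bin_width: float = 1.0,
    n: int = 1_000_000,
    depth: int = 8,
    seed: int = 0,
) -> pd.DataFrame:
    """CTW information rates of the two-state vs the general model.

    For each ``(p1, alpha)`` pair a single input train drives both
    models; the table reports the CTW MI and energy-normalized MI of
    each, the empirical release fractions, and the analytic two-state
    bracket (RLB, RUB and their energy-normalized forms).
    """
    cfg = CTWConfig(depth=depth)
    rows = []
    combos = list(itertools.product(p1_values, alpha_values))
    seeds = _child_seeds(seed, 3 * len(combos))
    for k, (p1, alpha) in enumerate(combos):
        params = SynapseParams(p1=p1, q1=q1, pmax=pmax, qmax=qmax, u=u, v=v)
        gparams = GeneralModelParams(base=params, tau_L_p=tau_L, tau_L_q=tau_L,
                                     tau_f_p=tau_f, tau_f_q=tau_f,
                                     bin_width=bin_width)
        x = generate_bernoulli_train(alpha, n, seed=seeds[3 * k],
                                     bin_width=bin_width)
        y_two = simulate_two_state_release(x, params, seed=seeds[3 * k + 1])
        y_gen = simulate_general_release(x, gparams, seed=seeds[3 * k + 2])
        mi_two = mi_rate_estimate(x, y_two, cfg)
        mi_gen = mi_rate_estimate(x, y_gen, cfg)
        bs = compute_bounds(params, InputStats(alpha))
        rows.append(dict(
            p1=p1, alpha=alpha, n=n,
            mi_two_state=mi_two, mi_general=mi_gen,
            release_two_state=y_two.fraction_ones,
            release_general=y_gen.fraction_ones,
            en_two_state=mi_two / y_two.fraction_ones if y_two.fraction_ones else np.nan,
            en_general=mi_gen / y_gen.fraction_ones if y_gen.fraction_ones else np.nan,
            RLB=bs.rlb, RUB=bs.rub, RLB_E=bs.rlb_energy, RUB_E=bs.rub_energy,
        ))
    return pd.DataFrame(rows)


def psth(signal: RateSignal, n_trials: int, seed: int = 0) -> np.ndarray:
    """Trial-averaged per-bin spike probability (peri-stimulus time histogram)."""
    seeds = _child_seeds(seed, n_trials)
    acc = np.zeros(signal.n_bins)
    for s in seeds:
        acc += generate_inhomogeneous_train(signal, seed=s).symbols
    return acc / n_trials


def correlated_input_experiment(
    amplitudes: Sequence[float] = (0.0, 0.075, 0.15),
    p1_values: Sequence[float] = _DEFAULT_GRID,
    u_values: Sequence[float] = _DEFAULT_GRID,
    *,
    baseline: float = 0.3,
    frequency: float = 1.0,
    q1: float = 0.05,
    v: float = 0.5,
    pmax: float = 1.0,
    qmax: float = 0.2,
    bin_width: float = 1.0,
    n_bins: int = 100_000,
    n_trials: int = 10,
    depth: int = 8,
    seed: int = 0,
) -> pd.DataFrame:
    """Numerical classification of facilitation under correlated input.

    For every stimulus amplitude and every ``(p1, u)`` grid point the same
    inhomogeneous-Poisson input trains (``n_trials`` of them) drive the
    facilitated synapse and its static counterpart (``u = v = 0``); CTW
    estimates of the MI rate and energy-normalized MI rate are compared
    trial-by-trial.  An effect is declared only when the mean paired
    difference exceeds twice its across-trial standard error; otherwise
    the point is *undetermined*.
    """
    cfg = CTWConfig(depth=depth)
    rows = []
    grid = list(itertools.product(amplitudes, p1_values, u_values))
    seeds = _child_seeds(seed, len(grid))
    for point_seed, (amp, p1, u) in zip(seeds, grid):
        fac = SynapseParams(p1=p1, q1=q1, pmax=pmax, qmax=qmax, u=u, v=v)
        static = SynapseParams(p1=p1, q1=q1, pmax=pmax, qmax=qmax, u=0.0, v=0.0)
        signal = RateSignal(baseline=baseline, amplitude=amp,
                            frequency=frequency, bin_width=bin_width,
                            n_bins=n_bins)
        trial_seeds = point_seed.spawn(3 * n_trials)
        mi_diff = np.empty(n_trials)
        en_diff = np.empty(n_trials)
        mi_fac = np.empty(n_trials)
        en_fac = np.empty(n_trials)
        for t in range(n_trials):
            x = generate_inhomogeneous_train(signal, seed=trial_seeds[3 * t])
            y_f = simulate_two_state_release(x, fac, seed=trial_seeds[3 * t + 1])
            y_s = simulate_two_state_release(x, static, seed=trial_seeds[3 * t + 2])
            mi_f = mi_rate_estimate(x, y_f, cfg)
            mi_s = mi_rate_estimate(x, y_s, cfg)
            en_f = mi_f / y_f.fraction_ones
            en_s = mi_s / y_s.fraction_ones
            mi_fac[t] = mi_f
            en_fac[t] = en_f
            mi_diff[t] = mi_f - mi_s
            en_diff[t] = en_f - en_s
        rows.append(dict(
            amplitude=amp, p1=p1, u=u,
            mi_facilitated=mi_fac.mean(),
            en_facilitated=en_fac.mean(),
            mi_diff=mi_diff.mean(), mi_diff_se=_sem(mi_diff),
            en_diff=en_diff.mean(), en_diff_se=_sem(en_diff),
            rate_effect=_mc_effect(mi_diff),
            energy_effect=_mc_effect(en_diff),
        ))
    return pd.DataFrame(rows)


def _sem(x: np.ndarray) -> float:
    if x.size < 2:
        return np.inf
    return float(x.std(ddof=1) / np.sqrt(x.size))


def _mc_effect(diff: np.ndarray) -> str:
    """Monte-Carlo decision rule: mean difference beyond 2 standard errors."""
    margin = 2.0 * _sem(diff)
    m = diff.mean()
    if m > margin:
        return "increases"
    if m < -margin:
        return "decreases"
    return "undetermined"


# ---------------------------------------------------------------------------
# figure presets


def _preset_fig2(**kw):
    grid = SweepGrid(axes={"uv": (0.2, 0.5, 0.8), "alpha": _DEFAULT_GRID},
                     fixed=dict(p1=0.5, q1=0.05, pmax=1.0, qmax=0.2))
    return sweep_bounds(grid)


def _preset_fig3a(**kw):
    grid = SweepGrid(axes={"uv": (0.2, 0.5, 0.8), "alpha": _DEFAULT_GRID},
                     fixed=dict(p1=0.5, q1=0.05, pmax=1.0, qmax=0.2))
    df = sweep_bounds(grid)
    df["RLB_minus_R1"] = df["RLB"] - df["R1"]
    return df


def _preset_fig3b(**kw):
    grid = SweepGrid(axes={"u": _DEFAULT_GRID, "alpha": _DEFAULT_GRID},
                     fixed=dict(p1=0.5, q1=0.05, pmax=1.0, qmax=0.2, v=0.5))
    df = sweep_bounds(grid)
    df["RUB_minus_R1"] = df["RUB"] - df["R1"]
    df["RUB_E_minus_R1_E"] = df["RUB_E"] - df["R1_E"]
    return df


def _preset_fig4(**kw):
    grid = SweepGrid(
        axes={"alpha": (0.2, 0.5, 0.8), "p1": _DEFAULT_GRID, "u": _DEFAULT_GRID},
        fixed=dict(q1=0.05, pmax=1.0, qmax=0.2, v=0.5))
    return effect_map(grid)


def _fig5_map(q1: float) -> pd.DataFrame:
    grid = SweepGrid(
        axes={"alpha": (0.2, 0.5, 0.8), "p1": _DEFAULT_GRID, "u": _DEFAULT_GRID},
        fixed=dict(q1=q1, pmax=1.0, qmax=min(4.0 * q1, 1.0), v=0.5))
    return effect_map(grid)


def _preset_fig5a(**kw):
    return _fig5_map(q1=0.1)


def _preset_fig5b(**kw):
    return _fig5_map(q1=0.01)


def _preset_fig5c(**kw):
    # q1 and v vary; qmax is tied to 4*q1, so build one sub-grid per q1
    frames = []
    for q1 in _DEFAULT_GRID:
        qmax = min(4.0 * q1, 1.0)
        grid = SweepGrid(
            axes={"alpha": (0.2, 0.5, 0.8), "v": _DEFAULT_GRID},
            fixed=dict(p1=0.5, u=0.5, pmax=1.0, q1=q1, qmax=qmax))
        frames.append(effect_map(grid))
    return pd.concat(frames, ignore_index=True)


def _preset_fig6(**kw):
    kw.setdefault("seed", 0)
    return correlated_input_experiment(**kw)


def _preset_fig7(**kw):
    kw.setdefault("alpha_values", tuple(np.round(np.linspace(0.05, 0.95, 10), 10)))
    kw.setdefault("seed", 0)
    return compare_models(**kw)


FIGURE_PRESETS = {
    "fig2": _preset_fig2,
    "fig3a": _preset_fig3a,
    "fig3b": _preset_fig3b,
    "fig4": _preset_fig4,
    "fig5a": _preset_fig5a,
    "fig5b": _preset_fig5b,
    "fig5c": _preset_fig5c,
    "fig6": _preset_fig6,
    "fig7": _preset_fig7,
}


def run_preset(name: str, **overrides) -> pd.DataFrame:
    """Run a named preset experiment; keyword overrides are forwarded.

    Analytic presets (fig2-fig5c) take no overrides; the simulation
    presets (fig6, fig7) accept the corresponding experiment's keyword
    arguments (``n_trials``, ``n``, ``seed``, ...).
    """
    if name not in FIGURE_PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(FIGURE_PRESETS)}")
    logger.info("running preset %s with overrides %s", name, overrides)
    return FIGURE_PRESETS[name](**overrides)
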