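"""Synthetic spike-train generation and release simulation.

Two input generators (homogeneous Bernoulli, and an inhomogeneous
sinusoidal-rate Poisson process on the discrete bin grid) and two release
models:

* the **two-state model**, in which the channel state at bin ``i`` is set
  by the previous input symbol ``X_{i-1}`` alone;
* the **general history-dependent model**, in which the instantaneous
  release probabilities ``p, q`` relax exponentially (time constants
  ``tau_L_*``) toward moving *limit probabilities* ``p_L, q_L`` that jump
  on every spike and decay back to baseline with facilitation decay time
  constants ``tau_f_*``.

Everything lives on a discrete bin grid (default 1 ms, so a per-bin spike
probability alpha equals the rate in kHz); there is no event-driven
continuous-time path.  All randomness flows through
``numpy.random.default_rng(seed)``, so a fixed seed gives bit-identical
trains.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from numba import njit

from .core import BinaryTrain, InputStats, SynapseParams

__all__ = [
    "RateSignal",
    "GeneralModelParams",
    "generate_bernoulli_train",
    "generate_inhomogeneous_train",
    "simulate_two_state_release",
    "simulate_general_release",
]


@dataclasses.dataclass(frozen=True)
class RateSignal:
    """Sinusoidal normalized-rate stimulus for the inhomogeneous input.

    The instantaneous per-bin spike probability is

        alpha(t) = clip(baseline + amplitude * sin(2*pi*frequency*t), 0, 1)

    with ``t = i * bin_width`` (bin_width in ms, frequency in Hz).
    ``amplitude = 0`` recovers the homogeneous Bernoulli input.
    """

    baseline: float
    amplitude: float = 0.0
    frequency: float = 1.0
    bin_width: float = 1.0
    n_bins: int = 100_000

    def __post_init__(self) -> None:
        if self.baseline < 0 or self.amplitude < 0:
            raise ValueError("baseline and amplitude must be non-negative")
        if self.bin_width <= 0 or self.n_bins < 1:
            raise ValueError("bin_width must be > 0 and n_bins >= 1")

    def rates(self) -> np.ndarray:
        """Per-bin probabilities ``alpha(t_i)``, clipped to [0, 1]."""
        t_sec = np.arange(self.n_bins) * (self.bin_width * 1e-3)
        raw = self.baseline + self.amplitude * np.sin(2.0 * np.pi * self.frequency * t_sec)
        return np.clip(raw, 0.0, 1.0)


@dataclasses.dataclass(frozen=True)
class GeneralModelParams:
    """Time-constant parameterization of the general facilitation model.

    ``base`` supplies the baseline/maximum probabilities and facilitation
    coefficients; ``tau_L_p, tau_L_q`` (ms) govern how fast the release
    probabilities relax toward the limit probabilities, and
    ``tau_f_p, tau_f_q`` (ms) how fast the limit probabilities decay back
    to baseline in quiescent intervals.
    """

    base: SynapseParams
    tau_L_p: float = 250.0
    tau_L_q: float = 250.0
    tau_f_p: float = 20.0
    tau_f_q: float = 20.0
    bin_width: float = 1.0

    def __post_init__(self) -> None:
        for name in ("tau_L_p", "tau_L_q", "tau_f_p", "tau_f_q", "bin_width"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_bernoulli_train(alpha: float, n: int, seed=None,
                             bin_width: float | None = None) -> BinaryTrain:
    """i.i.d. Bernoulli(alpha) presynaptic spike train of length ``n``."""
    if n < 1:
        raise ValueError(f"train length must be >= 1, got {n}")
    stats = InputStats(alpha)  # validates alpha
    sym = (_rng(seed).random(n) < stats.alpha).astype(np.uint8)
    return BinaryTrain(symbols=sym, role="input", bin_width=bin_width)


def generate_inhomogeneous_train(signal: RateSignal, seed=None) -> BinaryTrain:
    """Discretized inhomogeneous Poisson spike train with sinusoidal rate.

    Symbol ``i`` is Bernoulli(alpha(t_i)), independent across bins given
    the rate signal.
    """
    rates = signal.rates()
    sym = (_rng(seed).random(signal.n_bins) < rates).astype(np.uint8)
    return BinaryTrain(symbols=sym, role="input", bin_width=signal.bin_width)


def simulate_two_state_release(x: BinaryTrain, params: SynapseParams,
                               seed=None) -> BinaryTrain:
    """Release train of the two-state model driven by spike train ``x``.

    The synapse starts in the baseline state (as if ``X_{-1} = 0``); for
    ``i >= 1`` the state at bin ``i`` is facilitated iff ``X_{i-1} = 1``.
    Release probabilities are ``p1/p2`` when ``X_i = 1`` and ``q1/q2``
    when ``X_i = 0``, per state.
    """
    if x.role != "input":
        raise ValueError(f"expected an input-role train, got role={x.role!r}")
    sym = x.symbols
    facilitated = np.zeros(sym.size, dtype=bool)
    facilitated[1:] = sym[:-1] == 1
    prob = np.where(
        sym == 1,
        np.where(facilitated, params.p2, params.p1),
        np.where(facilitated, params.q2, params.q1),
    )
    y = (_rng(seed).random(sym.size) < prob).astype(np.uint8)
    return BinaryTrain(symbols=y, role="output", bin_width=x.bin_width)


@njit(cache=True)
def _general_release_kernel(x, unif, p1, q1, pmax, qmax, u, v,
                            g_L_p, g_L_q, g_f_p, g_f_q):  # pragma: no cover
    n = x.size
    y = np.empty(n, np.uint8)
    p = p1
    q = q1
    p_lim = p1
    q_lim = q1
    for i in range(n):
        p_lim0 = p_lim
        q_lim0 = q_lim
        if i > 0 and x[i - 1] == 1:
            # spike in the previous bin: limit probabilities jump
            p_lim = p_lim0 + u * (pmax - p_lim0)
            q_lim = q_lim0 + v * (qmax - q_lim0)
        else:
            # quiescent: limit probabilities decay back to baseline
            p_lim = p1 + (p_lim0 - p1) * g_f_p
            q_lim = q1 + (q_lim0 - q1) * g_f_q
        # release probabilities relax toward the start-of-bin limits
        # (simultaneous update: both computed from start-of-bin values)
        p = p_lim0 + (p - p_lim0) * g_L_p
        q = q_lim0 + (q - q_lim0) * g_L_q
        pr = p if x[i] == 1 else q
        y[i] = 1 if unif[i] < pr else 0
    return y


def simulate_general_release(x: BinaryTrain, params: GeneralModelParams,
                             seed=None) -> BinaryTrain:
    """Release train of the general history-dependent facilitation model.

    State variables ``(p, p_L, q, q_L)`` start at the baselines.  Per bin:
    a spike in the previous bin bumps the limit probabilities by
    ``u*(pmax - p_L)`` / ``v*(qmax - q_L)``; otherwise they decay toward
    baseline with per-bin factor ``exp(-bin_width/tau_f)``.  The release
    probabilities relax toward the (start-of-bin) limits with factor
    ``exp(-bin_width/tau_L)``, and the release is drawn with ``p`` on
    spike bins, ``q`` on quiescent bins.  Exact exponential factors make
    the trajectory invariant to splitting a bin in two.
    """
    if x.role != "input":
        raise ValueError(f"expected an input-role train, got role={x.role!r}")
    if x.bin_width is not None and not np.isclose(x.bin_width, params.bin_width):
        raise ValueError(
            f"train bin_width {x.bin_width} != model bin_width {params.bin_width}"
        )
    b = params.base
    dt = params.bin_width
    unif = _rng(seed).random(x.symbols.size)
    y = _general_release_kernel(
        x.symbols, unif, b.p1, b.q1, b.pmax, b.qmax, b.u, b.v,
        np.exp(-dt / params.tau_L_p), np.exp(-dt / params.tau_L_q),
        np.exp(-dt / params.tau_f_p), np.exp(-dt / params.tau_f_q),
    )
    return BinaryTrain(symbols=y, role="output", bin_width=params.bin_width)
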