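"""Parameterization and elementary probability arithmetic of the facilitating synapse.

A chemical synapse is modeled as a binary asymmetric channel: the input
symbol ``X_i`` marks the presence of a presynaptic spike in time bin ``i``
and the output symbol ``Y_i`` marks a vesicle release.  Release can be
spike-evoked (*synchronous*, probability ``p``) or spike-independent
(*asynchronous*, probability ``q``).  Short-term facilitation is captured
by a second channel state: a spike in the previous bin switches the
synapse from its baseline probabilities ``(p1, q1)`` to facilitated ones

    p2 = u * (pmax - p1) + p1,
    q2 = v * (qmax - q1) + q1,

where ``u, v`` are the facilitation coefficients of the two release modes
and ``pmax, qmax`` their ceilings.  The facilitated probabilities are
always derived from ``(p1, pmax, u)`` and ``(q1, qmax, v)``, never stored,
so ``p1 <= p2 <= pmax`` holds by construction.

All information quantities throughout the package are in bits (log base 2).
"""

from __future__ import annotations

import dataclasses
import numbers
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "SynapseParams",
    "InputStats",
    "BinaryTrain",
    "binary_entropy",
    "facilitated_probability",
    "stationary_release_probability",
    "load_parameters",
    "save_train",
    "load_train",
]

_ROLES = ("input", "output")


def binary_entropy(x):
    """Binary entropy ``h(x) = -x log2 x - (1-x) log2 (1-x)`` in bits.

    The convention ``0 * log2(0) = 0`` is enforced by explicit branching,
    so ``binary_entropy(0.0) == binary_entropy(1.0) == 0.0`` exactly.

    Parameters
    ----------
    x : float or array_like
        Probability (or array of probabilities) in ``[0, 1]``.

    Returns
    -------
    float or ndarray
        Entropy in bits, in ``[0, 1]``; a scalar for scalar input.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError(f"binary_entropy argument outside [0, 1]: {x!r}")
    out = np.zeros_like(arr)
    interior = (arr > 0.0) & (arr < 1.0)
    xi = arr[interior]
    out[interior] = -xi * np.log2(xi) - (1.0 - xi) * np.log2(1.0 - xi)
    if np.isscalar(x) or (isinstance(x, np.ndarray) and x.ndim == 0):
        return float(out)
    return out


def facilitated_probability(base: float, max_: float, coeff: float) -> float:
    """Facilitated release probability ``coeff * (max_ - base) + base``.

    Linearly interpolates between the baseline probability and its ceiling;
    the result is guaranteed to lie in ``[base, max_]``.

    Parameters
    ----------
    base : float
        Baseline release probability, ``0 <= base <= max_``.
    max_ : float
        Maximum release probability, ``base <= max_ <= 1``.
    coeff : float
        Facilitation coefficient in ``[0, 1]``.
    """
    if not (0.0 <= base <= max_ <= 1.0):
        raise ValueError(
            f"require 0 <= base <= max <= 1, got base={base}, max={max_}"
        )
    if not (0.0 <= coeff <= 1.0):
        raise ValueError(f"facilitation coefficient outside [0, 1]: {coeff}")
    return coeff * (max_ - base) + base


def _check_prob(name: str, value: float) -> float:
    if not isinstance(value, numbers.Real) or not np.isfinite(value):
        raise ValueError(f"{name} must be a finite real number, got {value!r}")
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value}")
    return float(value)


@dataclasses.dataclass(frozen=True)
class SynapseParams:
    """Release parameters of the two-state facilitating synapse.

    Attributes
    ----------
    p1, q1 : float
        Baseline synchronous / asynchronous release probabilities.
    pmax, qmax : float
        Maximum release probabilities of the two release modes.
    u, v : float
        Facilitation coefficients of synchronous / asynchronous release.
    """

    p1: float
    q1: float
    pmax: float
    qmax: float
    u: float
    v: float

    def __post_init__(self) -> None:
        for name in ("p1", "q1", "pmax", "qmax", "u", "v"):
            object.__setattr__(self, name, _check_prob(name, getattr(self, name)))
        if self.p1 > self.pmax:
            raise ValueError(f"p1={self.p1} exceeds pmax={self.pmax}")
        if self.q1 > self.qmax:
            raise ValueError(f"q1={self.q1} exceeds qmax={self.qmax}")

    @property
    def p2(self) -> float:
        """Synchronous release probability in the facilitated state."""
        return facilitated_probability(self.p1, self.pmax, self.u)

    @property
    def q2(self) -> float:
        """Asynchronous release probability in the facilitated state."""
        return facilitated_probability(self.q1, self.qmax, self.v)


@dataclasses.dataclass(frozen=True)
class InputStats:
    """Statistics of the i.i.d. Bernoulli presynaptic spike process.

    ``alpha`` is the normalized input spike rate: the per-bin probability
    ``P(X_i = 1)`` of a presynaptic spike.  Degenerate values 0 and 1 are
    allowed; every formula in the package is well defined there.
    """

    alpha: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha", _check_prob("alpha", self.alpha))

    @property
    def alpha_bar(self) -> float:
        return 1.0 - self.alpha


@dataclasses.dataclass(eq=False)
class BinaryTrain:
    """A finite 0/1 sequence on a fixed time grid (spikes or releases).

    Attributes
    ----------
    symbols : ndarray of uint8
        The 0/1 symbols.
    role : {"input", "output"}
        Whether the train is a presynaptic spike train or a release train.
    bin_width : float or None
        Bin duration in milliseconds; required only when the train feeds
        the general (time-constant) facilitation model.
    """

    symbols: np.ndarray
    role: str = "input"
    bin_width: float | None = None

    def __post_init__(self) -> None:
        sym = np.asarray(self.symbols)
        if sym.ndim != 1 or sym.size < 1:
            raise ValueError("symbols must be a non-empty 1-D sequence")
        if not np.all((sym == 0) | (sym == 1)):
            raise ValueError("symbols must all be 0 or 1")
        self.symbols = sym.astype(np.uint8)
        if self.role not in _ROLES:
            raise ValueError(f"role must be one of {_ROLES}, got {self.role!r}")
        if self.bin_width is not None and not self.bin_width > 0:
            raise ValueError(f"bin_width must be positive, got {self.bin_width}")

    def __len__(self) -> int:
        return int(self.symbols.size)

    @property
    def fraction_ones(self) -> float:
        """Empirical spike (or release) fraction of the train."""
        return float(self.symbols.mean())


def stationary_release_probability(params: SynapseParams, stats: InputStats) -> float:
    """Stationary per-bin release probability ``P(Y_i = 1)`` of the two-state model.

    With the synapse spending a fraction ``1 - alpha`` of bins in the
    baseline state and ``alpha`` in the facilitated state,

        P(Y=1) = (1-a)*(a*p1 + (1-a)*q1) + a*(a*p2 + (1-a)*q2).

    This is independent of the bin index and serves as the energy proxy
    (releases per bin) for the energy-normalized information rates.
    """
    a = stats.alpha
    ab = stats.alpha_bar
    return ab * (a * params.p1 + ab * params.q1) + a * (a * params.p2 + ab * params.q2)


# ---------------------------------------------------------------------------
# text I/O


def load_parameters(path: str | Path) -> tuple[SynapseParams, InputStats]:
    """Load a parameter point from a YAML config file.

    The file must contain the keys ``p1, q1, pmax, qmax, u, v, alpha``
    (``qmax`` is always explicit — no ``qmax = 4*q1``-style convention is
    assumed).  Extra keys are ignored so the same file can carry, e.g.,
    simulation settings.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ValueError(f"config {path} did not parse to a mapping")
    missing = [k for k in ("p1", "q1", "pmax", "qmax", "u", "v", "alpha") if k not in raw]
    if missing:
        raise ValueError(f"config {path} missing keys: {missing}")
    params = SynapseParams(
        p1=raw["p1"], q1=raw["q1"], pmax=raw["pmax"], qmax=raw["qmax"],
        u=raw["u"], v=raw["v"],
    )
    return params, InputStats(alpha=raw["alpha"])


def save_train(train: BinaryTrain, path: str | Path,
               metadata: Mapping | None = None) -> None:
    """Write a train as one newline-terminated line of space-separated 0/1.

    A sidecar ``<path>.meta.yaml`` records the role, bin width and any
    caller-supplied metadata (generator parameters, seed, ...).
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(" ".join(str(int(s)) for s in train.symbols))
        fh.write("\n")
    meta = {"role": train.role, "bin_width": train.bin_width,
            "length": len(train)}
    if metadata:
        meta.update(dict(metadata))
    with open(str(path) + ".meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def load_train(path: str | Path) -> BinaryTrain:
    """Read a train written by :func:`save_train`.

    Accepts whitespace- or comma-delimited symbols; the sidecar metadata
    file is optional (role defaults to "input" without it).
    """
    text = Path(path).read_text().strip().replace(",", " ")
    symbols = np.array([int(tok) for tok in text.split()], dtype=np.uint8)
    role = "input"
    bin_width = None
    meta_path = Path(str(path) + ".meta.yaml")
    if meta_path.exists():
        meta = yaml.safe_load(meta_path.read_text()) or {}
        role = meta.get("role", role)
        bin_width = meta.get("bin_width", bin_width)
    return BinaryTrain(symbols=symbols, role=role, bin_width=bin_width)
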