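"""Context-tree weighting (CTW) entropy-rate and mutual-information estimation.

CTW is a universal source-coding algorithm: it weights Krichevsky–Trofimov
(KT, add-1/2) estimators over all context trees up to a maximum depth D,
and its normalized codelength converges to the entropy rate of any
stationary ergodic source whose memory is representable at depth <= D.
We use the canonical construction: at every node the KT estimator and the
product of child weights are mixed 1/2 - 1/2, all arithmetic in the log2
domain so nothing underflows.

Mutual information rates for an (input, output) train pair are estimated
as ``H(X) + H(Y) - H(X, Y)``, the joint term running CTW over the
4-symbol alphabet ``2*X_i + Y_i``.  The first D symbols only seed the
context: they are excluded from both the codelength and the normalizing
length, which avoids partial-context boundary bias.  Estimates may come
out slightly negative for finite samples of independent trains and are
reported unclipped.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from numba import njit

from .core import BinaryTrain

__all__ = [
    "CTWConfig",
    "ctw_codelength",
    "entropy_rate_estimate",
    "mi_rate_estimate",
    "energy_normalized_estimate",
]


@dataclasses.dataclass(frozen=True)
class CTWConfig:
    """CTW estimator settings.

    ``depth`` is the maximum context length D (default 8 — generous for
    the two-state model, whose true memory is one step, while still fast;
    raise it when estimating the general model with long time constants).
    ``alphabet_size`` is 2 for single trains and 4 for joint (X, Y)
    sequences.  The per-node estimator is fixed to the KT add-1/2 rule.
    """

    depth: int = 8
    alphabet_size: int = 2

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError(f"depth must be >= 1, got {self.depth}")
        if self.alphabet_size not in (2, 4):
            raise ValueError(f"alphabet_size must be 2 or 4, got {self.alphabet_size}")


@njit(cache=True)
def _ctw_kernel(seq, m, depth):  # pragma: no cover - exercised via wrappers
    """Total CTW codelength in bits of seq[depth:], contexts of length `depth`.

    Tree nodes are materialized lazily; node 0 is the root and the child
    of a node at depth d-1 is indexed by the input symbol d steps back.
    """
    n = seq.size
    n_proc = n - depth
    # capacity: at most min(m**d, n_proc) distinct contexts per depth d
    cap = 1
    level = 1
    for _ in range(depth):
        if level < n_proc:
            level = min(level * m, n_proc)
        cap += level
    children = np.full((cap, m), -1, np.int64)
    counts = np.zeros((cap, m), np.float64)
    log_pe = np.zeros(cap, np.float64)   # log2 KT estimate at node
    log_pw = np.zeros(cap, np.float64)   # log2 weighted probability
    log_cp = np.zeros(cap, np.float64)   # log2 product of child log_pw
    n_nodes = 1
    path = np.empty(depth + 1, np.int64)
    half_m = 0.5 * m
    for t in range(depth, n):
        path[0] = 0
        node = 0
        for d in range(1, depth + 1):
            c = seq[t - d]
            nxt = children[node, c]
            if nxt < 0:
                nxt = n_nodes
                n_nodes += 1
                children[node, c] = nxt
            node = nxt
            path[d] = node
        sym = seq[t]
        child_old = 0.0
        child_new = 0.0
        for d in range(depth, -1, -1):
            node = path[d]
            tot = 0.0
            for j in range(m):
                tot += counts[node, j]
            log_pe[node] += np.log2((counts[node, sym] + 0.5) / (tot + half_m))
            counts[node, sym] += 1.0
            old_lpw = log_pw[node]
            if d == depth:
                new_lpw = log_pe[node]
            else:
                log_cp[node] += child_new - child_old
                a = log_pe[node]
                b = log_cp[node]
                if a < b:
                    a, b = b, a
                new_lpw = a + np.log2(1.0 + 2.0 ** (b - a)) - 1.0
            log_pw[node] = new_lpw
            child_old = old_lpw
            child_new = new_lpw
    return -log_pw[0]


def _as_symbols(seq, m: int) -> np.ndarray:
    sym = seq.symbols if isinstance(seq, BinaryTrain) else np.asarray(seq)
    sym = sym.astype(np.int64)
    if sym.ndim != 1:
        raise ValueError("sequence must be 1-D")
    if sym.size and (sym.min() < 0 or sym.max() >= m):
        raise ValueError(f"symbols outside alphabet range [0, {m})")
    return sym


def ctw_codelength(seq, config: CTWConfig = CTWConfig()) -> float:
    """Weighted-coding codelength in bits of ``seq`` under CTW with KT nodes.

    The first ``config.depth`` symbols only provide context and are not
    charged.  Deterministic: identical input gives bit-identical output.
    """
    sym = _as_symbols(seq, config.alphabet_size)
    if sym.size <= config.depth:
        raise ValueError(
            f"sequence length {sym.size} must exceed depth {config.depth}"
        )
    return float(_ctw_kernel(sym, config.alphabet_size, config.depth))


def entropy_rate_estimate(seq, config: CTWConfig = CTWConfig()) -> float:
    """CTW entropy-rate estimate in bits/symbol: codelength over coded length."""
    sym = _as_symbols(seq, config.alphabet_size)
    if sym.size <= config.depth:
        raise ValueError(
            f"sequence length {sym.size} must exceed depth {config.depth}"
        )
    return float(_ctw_kernel(sym, config.alphabet_size, config.depth)) / (
        sym.size - config.depth
    )


def mi_rate_estimate(x, y, config: CTWConfig = CTWConfig()) -> float:
    """Mutual information rate estimate ``H(X) + H(Y) - H(X,Y)`` in bits/step.

    The joint entropy term runs CTW on the 4-symbol alphabet
    ``2*X_i + Y_i`` at the same depth.  The estimate is reported
    unclipped (it can dip slightly below zero for independent trains).
    """
    xs = _as_symbols(x, 2)
    ys = _as_symbols(y, 2)
    if xs.size != ys.size:
        raise ValueError(f"length mismatch: {xs.size} vs {ys.size}")
    marg = CTWConfig(depth=config.depth, alphabet_size=2)
    hx = entropy_rate_estimate(xs, marg)
    hy = entropy_rate_estimate(ys, marg)
    hxy = entropy_rate_estimate(
        2 * xs + ys, CTWConfig(depth=config.depth, alphabet_size=4)
    )
    return hx + hy - hxy


def energy_normalized_estimate(x, y, config: CTWConfig = CTWConfig()) -> float:
    """MI rate estimate per release: ``mi_rate_estimate / mean(y)`` in bits/release."""
    ys = _as_symbols(y, 2)
    release_fraction = float(ys.mean())
    if release_fraction == 0.0:
        raise ValueError("output train contains no releases; rate per release undefined")
    return mi_rate_estimate(x, y, config) / release_fraction
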