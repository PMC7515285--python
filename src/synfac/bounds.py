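"""Closed-form information rates and bounds for the facilitating synapse.

The mutual information rate of a *static* binary asymmetric channel with
synchronous release probability ``p``, asynchronous release probability
``q`` and normalized input spike rate ``a`` is

    R(p, q, a) = h(a*p + (1-a)*q) - a*h(p) - (1-a)*h(q)          [bits/step]

With facilitation the channel state depends on the previous input symbol,
which makes the exact rate RF the entropy rate of a hidden Markov process
— no closed form is known.  Two closed-form brackets are available:

* lower bound   RLB = (1-a)*R1 + a*R2, the input-weighted average of the
  baseline-state and facilitated-state rates;
* upper bound   RUB = u7 - u6, where u6 is the conditional output entropy
  rate H(Y|X) and u7 is the output entropy conditioned on the previous
  output symbol (the u1..u7 intermediates are defined in
  :func:`upper_bound`).

Energy-normalized rates divide a bits/step rate by the stationary release
probability (releases are the dominant metabolic cost), giving bits per
release.  The classifier compares the facilitated bracket against the
static-synapse rate: when even the lower bound exceeds R1, facilitation
provably increases the rate; when the upper bound falls below R1 it
provably decreases it; in between the bounds cannot discriminate.
"""

from __future__ import annotations

import dataclasses
import enum
import math

from .core import (
    InputStats,
    SynapseParams,
    binary_entropy,
    stationary_release_probability,
)

__all__ = [
    "Effect",
    "EffectClass",
    "BoundSet",
    "single_state_rate",
    "lower_bound",
    "upper_bound",
    "conditional_output_entropy",
    "energy_normalized",
    "compute_bounds",
    "classify_effect",
]


def _clip_rate(value: float) -> float:
    # rates are analytically in [0, 1]; absorb last-bit rounding only
    if -1e-9 < value < 0.0:
        return 0.0
    return value


def single_state_rate(p: float, q: float, alpha: float) -> float:
    """Mutual information rate of the static channel, in bits per step.

    ``R = h(a*p + (1-a)*q) - a*h(p) - (1-a)*h(q)`` with ``a = alpha``.
    Symmetric under ``(p, q) -> (1-p, 1-q)`` and under
    ``(p, q, a) -> (q, p, 1-a)``.
    """
    h = binary_entropy
    a = float(alpha)
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"alpha outside [0, 1]: {alpha}")
    ab = 1.0 - a
    return _clip_rate(h(a * p + ab * q) - a * h(p) - ab * h(q))


def lower_bound(params: SynapseParams, stats: InputStats) -> float:
    """Lower bound ``RLB = (1-a)*R1 + a*R2`` on the facilitated rate.

    The statistical average, over the stationary state occupancy, of the
    rates of the two constituent static channels.
    """
    a = stats.alpha
    r1 = single_state_rate(params.p1, params.q1, a)
    r2 = single_state_rate(params.p2, params.q2, a)
    return _clip_rate((1.0 - a) * r1 + a * r2)


def conditional_output_entropy(params: SynapseParams, stats: InputStats) -> float:
    """Conditional output entropy rate ``H(Y|X)`` of the two-state model, in bits.

    u6 = h(q1)*(1-a)^2 + (h(p1) + h(q2))*a*(1-a) + h(p2)*a^2 :
    each term weights the release-probability entropy of one
    (previous input, current input) combination by its probability.
    This quantity is exact (not a bound) and is used both inside
    :func:`upper_bound` and as an independent cross-check of the
    numerical mutual-information estimator.
    """
    h = binary_entropy
    a = stats.alpha
    ab = stats.alpha_bar
    return (h(params.q1) * ab * ab
            + (h(params.p1) + h(params.q2)) * a * ab
            + h(params.p2) * a * a)


def upper_bound(params: SynapseParams, stats: InputStats) -> float:
    """Upper bound ``RUB = u7 - u6`` on the facilitated rate, in bits/step.

    Intermediates (``a = alpha``, ``ab = 1 - a``)::

        u1 = ab*(a*p1 + ab*q1)          # P(X_{i-1}=0, Y_i=1)
        u2 = ab*q1 + a*q2
        u3 = a*(a*p2 + ab*q2)           # P(X_{i-1}=1, Y_i=1)
        u4 = ab*p1 + a*p2
        u5 = u1 + u3                    # P(Y_i=1), the stationary release prob
        u6 = H(Y|X)                     # conditional_output_entropy
        u7 = u5*h((u1*u2 + u3*u4)/u5) + (1-u5)*h((u1*(1-u2) + u3*(1-u4))/(1-u5))

    Degenerate ``u5`` in {0, 1} makes the corresponding u7 term vanish
    (the 0*log(0) = 0 convention), so boundary inputs ``alpha`` in {0, 1}
    return the exact limits.
    """
    h = binary_entropy
    a = stats.alpha
    ab = stats.alpha_bar
    p1, q1, p2, q2 = params.p1, params.q1, params.p2, params.q2
    u1 = ab * (a * p1 + ab * q1)
    u2 = ab * q1 + a * q2
    u3 = a * (a * p2 + ab * q2)
    u4 = ab * p1 + a * p2
    u5 = u1 + u3
    u6 = conditional_output_entropy(params, stats)
    u7 = 0.0
    if u5 > 0.0:
        arg = (u1 * u2 + u3 * u4) / u5
        u7 += u5 * h(min(max(arg, 0.0), 1.0))
    if u5 < 1.0:
        arg = (u1 * (1.0 - u2) + u3 * (1.0 - u4)) / (1.0 - u5)
        u7 += (1.0 - u5) * h(min(max(arg, 0.0), 1.0))
    return _clip_rate(u7 - u6)


def energy_normalized(rate: float, release_prob: float) -> float:
    """Energy-normalized information rate ``rate / release_prob`` in bits/release."""
    if not 0.0 < release_prob <= 1.0:
        raise ValueError(
            f"energy normalization needs release_prob in (0, 1], got {release_prob}"
        )
    return rate / release_prob


@dataclasses.dataclass(frozen=True)
class BoundSet:
    """All analytic rates and bounds at one parameter point.

    Rates are in bits/step; ``*_energy`` fields in bits/release.
    ``r1_energy`` normalizes the static rate by the *static* release
    probability ``a*p1 + (1-a)*q1``, while ``rlb_energy``/``rub_energy``
    divide the facilitated bounds by the two-state stationary release
    probability.  Energy fields are NaN when the corresponding release
    probability is zero (no releases, no bits per release).
    """

    r1: float
    r2: float
    rlb: float
    rub: float
    release_prob: float
    r1_energy: float
    rlb_energy: float
    rub_energy: float


def compute_bounds(params: SynapseParams, stats: InputStats) -> BoundSet:
    """Evaluate the full :class:`BoundSet` at one parameter point."""
    a = stats.alpha
    ab = stats.alpha_bar
    r1 = single_state_rate(params.p1, params.q1, a)
    r2 = single_state_rate(params.p2, params.q2, a)
    rlb = _clip_rate(ab * r1 + a * r2)
    rub = upper_bound(params, stats)
    pr = stationary_release_probability(params, stats)
    pr1 = a * params.p1 + ab * params.q1
    r1_e = r1 / pr1 if pr1 > 0.0 else math.nan
    rlb_e = rlb / pr if pr > 0.0 else math.nan
    rub_e = rub / pr if pr > 0.0 else math.nan
    return BoundSet(r1=r1, r2=r2, rlb=rlb, rub=rub, release_prob=pr,
                    r1_energy=r1_e, rlb_energy=rlb_e, rub_energy=rub_e)


class Effect(str, enum.Enum):
    """Provable effect of facilitation on an information rate."""

    INCREASES = "increases"
    DECREASES = "decreases"
    UNDETERMINED = "undetermined"


@dataclasses.dataclass(frozen=True)
class EffectClass:
    """Per-parameter-point classification of facilitation's functional role."""

    rate_effect: Effect
    energy_effect: Effect


_TIE_TOL = 1e-12


def _compare(low: float, high: float, reference: float) -> Effect:
    # strict inequalities; ties are undetermined.  Differences within
    # floating-point noise (e.g. the exact collapse at u=v=0) count as ties.
    if low > reference + _TIE_TOL:
        return Effect.INCREASES
    if high < reference - _TIE_TOL:
        return Effect.DECREASES
    return Effect.UNDETERMINED


def classify_effect(params: SynapseParams, stats: InputStats) -> EffectClass:
    """Classify whether facilitation provably raises or lowers the rates.

    rate: *increases* iff RLB > R1, *decreases* iff RUB < R1, otherwise
    *undetermined* (the bracket contains R1, so the bounds cannot say).
    The energy classification is the same comparison on the
    energy-normalized quantities.
    """
    bs = compute_bounds(params, stats)
    rate = _compare(bs.rlb, bs.rub, bs.r1)
    if math.isnan(bs.r1_energy) or math.isnan(bs.rlb_energy):
        energy = Effect.UNDETERMINED
    else:
        energy = _compare(bs.rlb_energy, bs.rub_energy, bs.r1_energy)
    return EffectClass(rate_effect=rate, energy_effect=energy)
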