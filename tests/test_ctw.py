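"""CTW estimator: dual-route reference check, closed-form oracles, MI recovery."""

import math
from collections import defaultdict
from functools import lru_cache

import numpy as np
import pytest

from synfac import (
    CTWConfig,
    InputStats,
    SynapseParams,
    binary_entropy,
    compute_bounds,
    conditional_output_entropy,
    ctw_codelength,
    energy_normalized_estimate,
    entropy_rate_estimate,
    generate_bernoulli_train,
    mi_rate_estimate,
    simulate_two_state_release,
    single_state_rate,
)

LOG2E = 1.0 / math.log(2.0)


def reference_ctw_codelength(seq, m, depth):
    """Independent brute-force CTW codelength (bits) for small sequences.

    Counts are gathered per context (most-recent symbol first, positions
    ``t >= depth`` only); the KT block probability is evaluated in closed
    Gamma-function form (KT is exchangeable, so the sequential product
    depends only on the final counts), and the weighted probability is
    computed by explicit recursion Pw = 1/2*Pe + 1/2*prod(children Pw).
    """
    seq = list(seq)
    counts = defaultdict(lambda: [0] * m)
    for t in range(depth, len(seq)):
        for d in range(depth + 1):
            ctx = tuple(seq[t - 1 - i] for i in range(d))
            counts[ctx][seq[t]] += 1

    def kt_log2(ctx):
        c = counts.get(ctx, [0] * m)
        n = sum(c)
        val = sum(math.lgamma(ci + 0.5) - math.lgamma(0.5) for ci in c)
        val -= math.lgamma(n + 0.5 * m) - math.lgamma(0.5 * m)
        return val * LOG2E

    @lru_cache(maxsize=None)
    def log_pw(ctx):
        lpe = kt_log2(ctx)
        if len(ctx) == depth:
            return lpe
        lchild = sum(log_pw(ctx + (s,)) for s in range(m))
        hi, lo = max(lpe, lchild), min(lpe, lchild)
        return hi + math.log2(1.0 + 2.0 ** (lo - hi)) - 1.0

    return -log_pw(())


class TestAgainstReference:
    @pytest.mark.parametrize("m,depth,n", [(2, 1, 60), (2, 3, 200), (2, 5, 120),
                                           (4, 2, 200), (4, 3, 300)])
    def test_kernel_matches_bruteforce_recursion(self, m, depth, n):
        rng = np.random.default_rng(100 + 10 * m + depth)
        seq = rng.integers(0, m, n)
        got = ctw_codelength(seq, CTWConfig(depth=depth, alphabet_size=m))
        want = reference_ctw_codelength(seq, m, depth)
        assert got == pytest.approx(want, abs=1e-8)

    def test_kernel_matches_reference_on_structured_sequence(self):
        seq = np.tile([0, 0, 1], 100)
        got = ctw_codelength(seq, CTWConfig(depth=4))
        want = reference_ctw_codelength(seq, 2, 4)
        assert got == pytest.approx(want, abs=1e-8)


class TestEntropyRate:
    def test_constant_sequence_codes_almost_freely(self):
        n = 100_000
        rate = entropy_rate_estimate(np.zeros(n, dtype=int), CTWConfig(depth=8))
        assert rate < 0.01

    def test_fair_coin_costs_one_bit(self):
        rng = np.random.default_rng(21)
        seq = rng.integers(0, 2, 100_000)
        rate = entropy_rate_estimate(seq, CTWConfig(depth=8))
        assert rate == pytest.approx(1.0, abs=0.01)

    def test_alternating_sequence_is_predictable(self):
        seq = np.tile([0, 1], 50_000)
        assert entropy_rate_estimate(seq, CTWConfig(depth=1)) < 0.01
        assert entropy_rate_estimate(seq, CTWConfig(depth=8)) < 0.01

    def test_iid_bernoulli_entropy(self):
        rng = np.random.default_rng(22)
        seq = (rng.random(100_000) < 0.3).astype(int)
        rate = entropy_rate_estimate(seq, CTWConfig(depth=8))
        assert rate == pytest.approx(binary_entropy(0.3), abs=0.01)

    def test_markov_chain_entropy_rate(self):
        # first-order chain, P(1|0)=0.1, P(0|1)=0.4; closed-form stationary rate
        a, b, n = 0.1, 0.4, 200_000
        rng = np.random.default_rng(23)
        u = rng.random(n)
        s = np.empty(n, dtype=np.int64)
        s[0] = 0
        for i in range(1, n):
            s[i] = (u[i] < a) if s[i - 1] == 0 else (u[i] >= b)
        pi1 = a / (a + b)
        true_rate = (1 - pi1) * binary_entropy(a) + pi1 * binary_entropy(b)
        est = entropy_rate_estimate(s, CTWConfig(depth=8))
        assert est == pytest.approx(true_rate, abs=0.01)

    def test_depth_robustness_for_short_memory_source(self, fig2_params):
        # two-state output has one-step memory; D=8 and D=16 must agree
        x = generate_bernoulli_train(0.3, 100_000, seed=24)
        y = simulate_two_state_release(x, fig2_params, seed=25)
        e8 = entropy_rate_estimate(y, CTWConfig(depth=8))
        e16 = entropy_rate_estimate(y, CTWConfig(depth=16))
        assert abs(e8 - e16) < 0.005

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            ctw_codelength(np.array([0, 1, 0]), CTWConfig(depth=8))

    def test_determinism_bit_exact(self):
        rng = np.random.default_rng(26)
        seq = rng.integers(0, 2, 50_000)
        assert ctw_codelength(seq) == ctw_codelength(seq.copy())


class TestMutualInformation:
    def test_self_information_is_input_entropy(self):
        x = generate_bernoulli_train(0.3, 100_000, seed=27)
        mi = mi_rate_estimate(x, x)
        assert mi == pytest.approx(binary_entropy(0.3), abs=0.02)

    def test_independent_trains_carry_no_information(self):
        x = generate_bernoulli_train(0.3, 100_000, seed=28)
        y = generate_bernoulli_train(0.4, 100_000, seed=29)
        assert abs(mi_rate_estimate(x, y)) < 0.01

    def test_memoryless_channel_recovers_closed_form(self):
        n = 300_000
        params = SynapseParams(0.5, 0.05, 1.0, 0.2, 0.0, 0.0)
        x = generate_bernoulli_train(0.3, n, seed=30)
        y = simulate_two_state_release(x, params, seed=31)
        assert mi_rate_estimate(x, y) == pytest.approx(
            single_state_rate(0.5, 0.05, 0.3), abs=0.01
        )

    def test_length_mismatch_rejected(self):
        x = generate_bernoulli_train(0.3, 1000, seed=0)
        y = generate_bernoulli_train(0.3, 999, seed=1)
        with pytest.raises(ValueError, match="mismatch"):
            mi_rate_estimate(x, y)

    def test_estimate_lies_within_analytic_bracket(self, fig2_params, fig2_stats):
        n, eps = 100_000, 0.03
        x = generate_bernoulli_train(fig2_stats.alpha, n, seed=32)
        y = simulate_two_state_release(x, fig2_params, seed=33)
        mi = mi_rate_estimate(x, y)
        bs = compute_bounds(fig2_params, fig2_stats)
        assert bs.rlb - eps <= mi <= bs.rub + eps

    def test_conditional_entropy_cross_check(self, fig2_params, fig2_stats):
        # H(Y) - MI isolates H(Y|X), which is exactly computable (u6)
        n = 1_000_000
        x = generate_bernoulli_train(fig2_stats.alpha, n, seed=34)
        y = simulate_two_state_release(x, fig2_params, seed=35)
        hy = entropy_rate_estimate(y)
        mi = mi_rate_estimate(x, y)
        u6 = conditional_output_entropy(fig2_params, fig2_stats)
        assert hy - mi == pytest.approx(u6, abs=0.01)


class TestEnergyNormalizedEstimate:
    def test_self_information_per_release(self):
        x = generate_bernoulli_train(0.3, 100_000, seed=36)
        est = energy_normalized_estimate(x, x)
        assert est == pytest.approx(binary_entropy(0.3) / 0.3, rel=0.05)

    def test_memoryless_channel_matches_analytic_ratio(self, fig2_stats):
        n = 300_000
        params = SynapseParams(0.5, 0.05, 1.0, 0.2, 0.0, 0.0)
        x = generate_bernoulli_train(0.3, n, seed=37)
        y = simulate_two_state_release(x, params, seed=38)
        bs = compute_bounds(params, fig2_stats)
        assert energy_normalized_estimate(x, y) == pytest.approx(
            bs.r1_energy, rel=0.10
        )

    def test_facilitated_estimate_within_energy_bracket(self, fig2_params, fig2_stats):
        n, eps = 1_000_000, 0.02
        x = generate_bernoulli_train(fig2_stats.alpha, n, seed=39)
        y = simulate_two_state_release(x, fig2_params, seed=40)
        est = energy_normalized_estimate(x, y)
        bs = compute_bounds(fig2_params, fig2_stats)
        assert bs.rlb_energy - eps <= est <= bs.rub_energy + eps

    def test_silent_output_rejected(self):
        x = generate_bernoulli_train(0.3, 1000, seed=41)
        y = np.zeros(1000, dtype=np.uint8)
        with pytest.raises(ValueError, match="release"):
            energy_normalized_estimate(x, y)
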