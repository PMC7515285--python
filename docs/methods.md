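# Methods

## Channel model

Time is discretized into bins (default 1 ms, so a per-bin spike
probability `α` equals the input rate in kHz).  The presynaptic spike
train `X` is i.i.d. Bernoulli(`α`); temporal input correlations are
introduced only through the inhomogeneous generator below.  The release
train `Y` is produced by a binary asymmetric channel whose state at bin
`i` is set by `X_{i−1}`: baseline probabilities `(p1, q1)` without a
preceding spike, facilitated probabilities `(p2, q2)` after one, with
`p2 = u(pmax−p1)+p1` and `q2 = v(qmax−q1)+q1`.  `p2, q2` are always
derived, never stored, so `p1 ≤ p2 ≤ pmax` and `q1 ≤ q2 ≤ qmax` hold by
construction.  The simulation starts in the baseline state (as if
`X_{−1} = 0`); this affects a single symbol and no stationary quantity.

All information quantities are in bits (log base 2); `0·log 0 = 0` is
enforced by explicit branching, not floating-point accident.  Degenerate
inputs `α ∈ {0, 1}` are allowed everywhere and evaluate to the exact
limits.

## Analytic rates and bounds

The static-channel rate `R(p,q,α) = h(αp+ᾱq) − αh(p) − ᾱh(q)` gives the
per-state rates `R1, R2`.  The facilitated rate is bracketed by
`R_LB = ᾱR1 + αR2` and `R_UB = u7 − u6` with

    u1 = ᾱ(αp1+ᾱq1)   u2 = ᾱq1+αq2   u3 = α(αp2+ᾱq2)   u4 = ᾱp1+αp2
    u5 = u1+u3        u6 = h(q1)ᾱ² + (h(p1)+h(q2))αᾱ + h(p2)α²
    u7 = u5·h((u1u2+u3u4)/u5) + ū5·h((u1ū2+u3ū4)/ū5)

The grouping of `u6` makes it the conditional output entropy rate
`H(Y|X)` and of `u7` the previous-output-conditioned output entropy; this
is the only grouping under which `R_UB` collapses to `R1` when `u=v=0`, a
property the test suite verifies numerically to 1e−12 alongside the
bracket `0 ≤ R_LB ≤ R_UB ≤ 1` on random parameter points.  `u5` equals
the stationary release probability, which is computed independently and
cross-checked.  Degenerate `u5 ∈ {0,1}` terms vanish by the `0·log 0`
convention rather than raising.

Energy-normalized rates divide by the release probability: the static
rate by `αp1 + ᾱq1`, the facilitated bounds by the two-state stationary
release probability.  A zero release probability makes bits-per-release
undefined: the standalone quotient raises, and the bound-set fields are
NaN (mapped to *undetermined* by the classifier).

The effect classifier uses strict inequalities (`R_LB > R1` → increases,
`R_UB < R1` → decreases, otherwise undetermined).  Differences within
1e−12 count as ties: at `u=v=0` the collapse is exact analytically but
one ulp apart in floating point, and the bounds genuinely cannot
discriminate there.

## Simulators

* **Bernoulli input**: `n` i.i.d. draws; all randomness flows through
  `numpy.random.default_rng(seed)`, so a fixed seed gives bit-identical
  trains across runs and platforms.  Experiment-level seeds are fanned
  out with `numpy.random.SeedSequence.spawn`, keeping whole experiment
  tables byte-reproducible.
* **Inhomogeneous input**: per-bin Bernoulli with
  `α(t) = clip(baseline + amplitude·sin(2πft), 0, 1)` — a discretized
  inhomogeneous Poisson process.  The default stimulus (baseline 0.3,
  amplitudes 0/0.075/0.15, 1 Hz) is the canonical correlated-input
  condition.
* **Two-state release**: vectorized; the per-bin release probability is a
  pure function of `(X_{i−1}, X_i)`.
* **General release**: four state variables.  Limit probabilities
  `p_L, q_L` jump by `u(pmax−p_L)`, `v(qmax−q_L)` when the previous bin
  spiked and otherwise decay toward baseline with time constants
  `τ_f` (default 20 ms); the instantaneous probabilities `p, q` relax
  toward the limits with time constants `τ_L` (default 250 ms).
  Exponential steps use the exact per-bin factor `exp(−Δt/τ)`, so the
  trajectory is invariant to splitting a bin.  The relaxation of `p`
  targets the start-of-bin `p_L` and the decay of `p_L` uses start-of-bin
  values too (a simultaneous update): the coupling order within a bin is
  not dictated by the model, and the simultaneous form is symmetric and
  robust to bin size.  Order per bin: facilitation jump (from the
  previous bin's spike) → decay/relaxation → release draw, mirroring how
  `X_{i−1}` selects the state that governs `Y_i` in the two-state model.

### Two-state vs general model: a known regime restriction

The two-state model is the `τ → 0` caricature of the general model: it
keeps facilitation for exactly one bin.  The models can only agree when
facilitation decays within an inter-spike interval.  On a 1 ms grid with
`τ_f = 20` ms, normalized rates `α ≥ 0.1` mean inter-spike intervals of
2–10 ms, so the limit probabilities accumulate far beyond the
single-spike level `p2` (e.g. stationary mean `p_L ≈ 0.87` at `p1 = 0.5`,
`α = 0.3`, `u = 0.5`), and the slow `τ_L = 250` ms relaxation smooths `p`
into a nearly constant elevated value.  The general model then behaves
like a quasi-static channel with elevated probabilities and transmits
substantially more information than the two-state model — `compare_models`
measures relative differences from ~25% up to ~3× at the default
time constants.  The dedicated comparison test asserts a 10% agreement
tolerance in this regime and therefore fails; it is kept as an honest
record of where the approximation breaks rather than weakened.  Agreement
to within the tolerance requires facilitation that decays within a bin
(`τ_f` ≲ bin width and fast `p`-tracking), i.e. genuinely rapid decay.

## CTW estimation

Canonical context-tree weighting: every node of the (lazily materialized)
suffix tree up to depth `D` holds a Krichevsky–Trofimov add-½ estimator;
internal nodes mix the node estimate and the product of child weights
½–½.  All arithmetic is in the log2 domain, so nothing underflows, and
the per-symbol update touches only the `D+1` nodes on the current context
path (a numba kernel; ~1 s per 10⁶ symbols at `D = 8`).  The first `D`
symbols seed the context and are excluded from both the codelength and
the normalizing length, avoiding partial-context boundary bias.

Mutual information is estimated as `Ĥ(X) + Ĥ(Y) − Ĥ(X,Y)`, the joint
term running over the 4-symbol alphabet `2X_i + Y_i` at the same depth.
A conditional-CTW decomposition `Ĥ(Y) − Ĥ(Y|X)` would need
side-information trees; the joint-alphabet form is a single well-defined
estimator, and the exactly computable `u6 = H(Y|X)` provides the
cross-check (`Ĥ(Y) − MI ≈ u6` within 0.01 at n = 10⁶ in the tests).
Estimates are reported unclipped — slightly negative values for
independent finite samples are informative, and clipping would bias the
estimator-within-bounds checks.  Default depth `D = 8`: the two-state
memory is one step, so this is generous, while the general model's long
time constants motivate the config-exposed larger depths.  The test
suite validates the kernel bit-for-bit against an independent brute-force
recursion (block-KT in Gamma-function form) on small sequences, and
against closed-form entropy rates (constant, i.i.d., first-order Markov)
at large `n`.

## Experiments and their default conditions

Experiments are pure functions (config, seed) → tidy DataFrame; every
analytic cell is recomputable from the bounds module alone.  Default
grids put `α, u, p1` on 19-point uniform grids over [0.05, 0.95];
figure presets carry the canonical fixed parameters (`p1=0.5, q1=0.05,
pmax=1, qmax=0.2` unless a preset varies them; `qmax = 4·q1` in the
asynchronous-release presets, capped at 1 where `q1 > 0.25`; `qmax` is
always explicit in configs, never inferred).  The correlated-input
experiment classifies a grid point only when the mean paired
(facilitated − static) difference across trials exceeds twice its
standard error; the paired design (the same input trains drive both
synapses) cancels most sampling noise.  Its defaults (10 trials of 10⁵
bins) keep a full 19×19×3 map affordable; the PSTH convention of 1000
trials applies to rate reconstruction, not to the MI maps.  The
acceptance script uses 10⁶-bin trains for single-point estimates and
5·10⁵ for the six-point model comparison — sizes at which CTW bias and
variance are each well below the 0.01-bit scale of interest.

## What the synthetic data does and does not show

The generators emulate stationary Bernoulli/inhomogeneous-Poisson spike
trains and single-vesicle stochastic release.  They do not emulate
vesicle-pool depletion (short-term depression), multi-vesicle release,
refractoriness or non-Poisson spike statistics, calcium dynamics, or
postsynaptic decoding.  Passing tests therefore validate the
information-theoretic machinery under the model's assumptions, not the
biological completeness of the model.

## Known limitations

* The exact facilitated rate `R_F` is never computed — only bracketed and
  estimated; the bracket width grows with the facilitation asymmetry.
* The CTW estimator is consistent for stationary ergodic sources with
  memory ≤ `D`; under 1 Hz sinusoidal input the source is cyclostationary
  on a timescale (1000 bins) far beyond any practical depth, so those MI
  estimates are best read as comparative (facilitated vs static on the
  same trains), which is how the classification uses them.
* The general model's agreement with the two-state model is restricted to
  the rapid-decay regime discussed above.
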