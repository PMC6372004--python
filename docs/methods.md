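# Methods

## Model

All afferent activity is homogeneous Poisson at rate `f` per afferent.  A
frozen-noise pattern is one realization over `N` afferents and duration
`L`; a presentation session replays it at regular onsets with independent
per-spike uniform jitter on `[-T, T]`, and fills the time between
presentations with fresh Poisson background.  During a presentation window
the replayed pattern *replaces* background activity (the pattern is itself
a realization of the same process, so the in-window statistics are
unchanged); jittered spikes that land slightly outside their window are
kept.  Uniform rather than normal jitter is a modeling choice that keeps
the smeared input current piecewise linear and hence exactly integrable.

The detector is a LIF with instantaneous (Dirac) synapses: a presynaptic
spike through weight `w` deflects the potential by exactly `w`, so
potentials are counted in unit-EPSP units, and a threshold `θ` reads as
"number of synchronous maximal-weight spikes".  There is no refractory
period; after a threshold crossing the potential resets to 0 (the resting
potential; the reset value is a convention we fix and document).

## Closed-form SNR

With Strategy #n (connect to all afferents with ≥ n spikes in a window
`Δt`), the selected count and in-window rate are Poisson tails:
`M = N·P(X≥n)`, `r = Nf·P(X≥n−1)`, `X ~ Poisson(fΔt)`.  Shot-noise
filtering gives the noise potential mean `τfM` and variance `τfM/2`; the
Gaussian reading of the SNR needs `τfM ≫ 1`, and the code warns below 10.

Jitter smears the rectangular in-window rate into a trapezoid with rise
and fall `min(Δt, 2T)`, plateau `|Δt − 2T|`, height `min(1, Δt/2T)` in
reduced units, and area `Δt` always (jitter moves spikes, it does not
create or destroy them).  The reduced membrane equation `τ dv/dt = −v + i`
with piecewise-linear `i = at + b` integrates exactly as

    v(t) = a(t − τ) + b + (v0 − b + aτ)·e^(−t/τ).

We derived this solution directly from the differential equation rather
than transcribing it, because the printed form of the reference solution
garbles the roles of slope and intercept typographically; the derived form
reproduces the published intermediate values (`v1`, `v2`, peak location
and height) exactly, which is what the oracle tests check.

The peak lies on the trapezoid's falling edge (before the crossing the
drive exceeds `v`, after it `v` decays), giving `t_max = τ·log(1 + 2T(h −
v2)/τ)` and `v_max = h − t_max/2T`.  Numerically we compute the log
argument in the cancellation-free form `1 + (1 − e^(−t1/τ))·e^(−t2/τ)`
(algebraically identical to the textbook expression, stable when `τ`
dwarfs the trapezoid), and handle `T = 0` by the explicit limit branch
`v_max = 1 − e^(−Δt/τ)` rather than by epsilon perturbation.  Poisson
pmf/tails come from scipy.stats, which is overflow-safe to large `n`.

## Optimization

`optimize_snr` maximizes the SNR over `(log τ, log Δt)` per strategy with
SLSQP under the inequality `τfM ≥ 10`, from an 8×8 log-spaced multistart
grid (the surface is smooth but can be multimodal across decades), keeping
the best feasible local optimum; ties across strategies break toward
smaller `n`.  Search bounds are 0.1 ms to 10 s on both variables; hitting
the `Δt` cap raises a warning (the theory assumes `L` large enough that
`Δt` is unconstrained).  The constraint binds at small `f·T` (the
optimizer then inflates `τ` to keep enough synaptic traffic), reported via
`constraint_active`.  Plane sweeps reuse the same machinery per grid point
and flag per-point failures instead of aborting.

## Simulation

Clock-based forward Euler with a 0.1-ms bin (validated as ≤ τ/10):
`V[k+1] = V[k](1 − Δ/τ) + Σ w_i` over the bin's spikes; threshold test
after integration; crossing recorded at the bin end.  Threshold-free
traces use the same recursion evaluated by a linear filter.  SNR
measurement takes per-presentation peaks over `[onset − T, onset + L + T]`
(jitter can push the peak outside the nominal window) and noise statistics
from bins farther than `5τ` after any window (the decay transient would
otherwise contaminate `σ_noise`).  The theory-validation experiment runs
20 patterns × 200 presentations per (strategy, jitter) point at desk
scale (100 × 1000 at full scale), simulating only the selected afferents —
the rest carry zero weight and cannot move the potential.  The membrane
time constant for this experiment defaults to 18 ms and is a configuration
knob; theory and simulation always use the same value, and the tested
property (agreement within ensemble spread) holds for whichever is set.

## Plasticity

Learning is additive all-to-all LTP with a homeostatic LTD stand-in: each
synapse keeps a presynaptic trace (decay `τ_pre` = 20 ms, increment
`δA_pre` = 0.01 per spike); at each postsynaptic spike every weight
receives its trace plus `w_out < 0` and is clipped to `[0, 1]`.  Traces
decay by exact exponentials of bin-aligned intervals (closed form, no
Euler error in the learning rule); within a bin the order is: integrate
inputs → threshold test → apply LTP + `w_out` with traces updated through
the current bin → clip → reset.  Initial weights are uniform at
`w0 = θ / (τfN − √(2τfN))`, placing the mean noise potential two standard
deviations above threshold so the naive neuron fires (~20 Hz at the
reference point) and learning can bootstrap.  A neuron silent for the
first 50 presentations is reported dead rather than simulated to the end.

Two structural facts shape the learned state.  First, the LTP/LTD balance
point: an afferent whose pattern spike precedes the postsynaptic spike by
`δ* = τ_pre·ln(δA_pre/|w_out|)` (21 ms at mode 1) gains exactly nothing
per presentation, so afferents near that distance drift only diffusively —
a residue of 0.5–5% of weights never binarizes in finite time.
Convergence is therefore defined as ≥ 95% of weights within 0.05 of
{0, 1}.  Second, the learned window length is the smaller of that balance
length and the threshold-crossing latency, and it sits within a few
percent of the margin boundary of the optimality criterion, which is why
the optimal fraction `p` is an intrinsically sharp statistic.

Optimality classification: after the convergence gate, weights partition
at 0.5 into reinforced/depressed; the run is optimal when some window of
the pattern, scanned exhaustively at 0.1-ms resolution, has duration
within 10% of the optimal `Δt` and a ≥1-spike afferent set matching the
reinforced set up to a symmetric difference of 5% of its size.  The
mismatch tolerance exists because exact set equality is unattainable in
principle: a single balance-point straggler interleaved at the window edge
would otherwise veto every window at `N = 10⁴`.  On exactly-binarized
constructed fixtures the tolerant criterion and exact set equality agree.

The "doubled learning rate" variant scales the whole update — `δA_pre` to
0.02 *and* `w_out` to −7×10⁻³ — preserving the LTP/LTD balance length
while doubling convergence speed; scaling only the LTP increment would
instead lengthen the learned window by ~70% and slow the depression of
background synapses, changing the detector rather than the speed.

## Problem sizes and sampling

Desk-scale presets: theory validation 20 patterns × 200 presentations;
mode analysis 25 replicates per operating point in the test suite and
40 (28 for the 800-ms variant) in the acceptance script; the plane sweep
3×3 log-spaced points (7×7 at full scale).  Learned-fraction estimates at
these counts carry binomial standard errors of 6–10 percentage points,
and the in-suite checks use the exact binomial 95% acceptance region
around the full-scale reference fractions.

## Known limitations

Single detector only — no population readout, lateral inhibition, delay
lines, or downstream full-pattern assembly; no spike-timing-dependent LTD
(the homeostatic term replaces it); homogeneous Poisson background only,
uniform jitter only, no refractoriness; the Gaussian noise approximation
(and the SNR as a false-alarm proxy) degrades when `τfM` is small, where
the potential distribution skews positive.  The synthetic generator does
not emulate rate nonstationarity, correlations between afferents, or
biological weight-dependence of plasticity, so passing tests certify the
model's internal consistency, not fidelity to any particular circuit.
The learned-window equilibrium is sensitive at the percent level to
integration conventions (reset value, intra-bin ordering, trace
quantization); these are fixed and documented above, and the mode
fractions are reproducible given them, but small implementation-level
differences can shift the fractions by tens of percentage points because
the equilibrium window length sits at the optimality margin.
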