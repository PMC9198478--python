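# Methods

## Model

The neuron is a single-compartment leaky integrator,

    tau dv/dt = -(v - v_E) + R I_s(t),
    I_s(t)    = sum_i g_i(t) (E_s - v(t)),

with one membrane voltage shared by all synapses (the model deliberately
has no dendritic subunits, no dendritic spikes and no voltage-gated
conductances; synapses are excitatory only, E_s well above threshold).
Input sources are pooled into conductance groups.  Group kinetics come in
two flavours:

- **saturating** (`set_to_max`): an afferent spike sets g_i to its
  ceiling `drive_scale * g_max`; g_i decays exponentially with tau_s and
  can never exceed the ceiling.  This models the finite conductance
  available per unit of membrane surface when co-located synapses
  interact: stimulating a saturated patch harder recruits nothing more;
  only stimulating a *different* patch does.
- **additive unbounded** (`additive_unbounded`): each spike adds
  `drive_scale * g_max`.  A single such group pooling all sources is the
  classical LIF, whose total drive depends only on the number of input
  spikes — the linearity that confines it to linearly separable
  computations.

A somatic spike is recorded whenever the end-of-step voltage reaches
threshold; the voltage resets to `v_reset` while conductances persist
(the standard integrate-and-fire convention; nothing about the synapse
knows the soma fired).

### Parameters

| parameter | default | unit | meaning |
|-----------|---------|------|---------|
| tau       | 20      | ms   | membrane time constant |
| v_E (v_rest) | -65  | mV   | resting / reset potential |
| R         | 20      | MOhm | input resistance |
| E_s       | 0       | mV   | synaptic reversal potential |
| tau_s     | 1       | ms   | synaptic decay time constant |
| g_max     | 100     | pS   | per-group conductance ceiling / per-spike increment |
| drive_scale | 1 (calibrated: 100) | — | uniform multiplier on all ceilings |
| dt        | 0.1     | ms   | integration step (guard: dt ≤ tau_s/5) |

With these magnitudes R·g_max = 2×10⁻³ (dimensionless), so a single
1 ms conductance volley deflects the membrane by only a few microvolts —
five hundred times less than the 3 mV gap between rest and the nominal
-62 mV threshold.  The absolute scale of the drive is therefore treated
as a free parameter (the qualitative result is scale-invariant because
saturation pins the scattered:clustered conductance ratio at exactly
2:1), and the protocol calibrates it; all conductance-arithmetic results
(100 pS vs 200 pS) are reported at `drive_scale = 1`.

## Numerical integration

Between events each group conductance decays exactly
(`g ← g·exp(-dt/tau_s)`); arrivals are binned to the step containing
them and applied at the bin start, simultaneous arrivals in ascending
source order (observable only for unbounded groups, where order cannot
matter; fixed for reproducibility).

The membrane update is exponential Euler: with the conductances frozen
over a step the ODE is affine with fixed point
`v* = (v_E + R·g·E_s)/(1 + R·g)` and effective time constant
`tau/(1 + R·g)`, and the update is its exact solution.  The frozen value
used for each group is its *exact within-step average*
`g·(tau_s/dt)·(1 - exp(-dt/tau_s))` rather than the value at either end
of the step: the synaptic time constant (1 ms) is only 10× the default
step, and end-point freezing leaves a first-order bias of tens of
microvolts at calibrated drive, comparable to the decision margins the
protocol relies on.  With the averaged coefficient the dt = 0.1 ms and
dt = 0.001 ms trajectories agree to ~0.02 µV in peak voltage at
calibrated drive (sub-nanovolt at unit drive).  The public `step_voltage`
primitive keeps the plain frozen-g contract; the averaging is a
`run_simulation` composition choice.

Trace conventions: voltage sample k is the state at the end of step k;
conductance sample k is the value just after the step's arrivals (the
within-step maximum), so an isolated volley registers its full 100/200 pS
peak in the stored trace.

## Separability certification

`is_linearly_separable` decides whether weights w and threshold Theta
exist with f(X) = 1 iff w·X ≥ Theta on every specified row.

- **LP method**: feasibility of `{w·X ≥ Theta (1-rows), w·X ≤ Theta - 1
  (0-rows)}` via `scipy.optimize.linprog` (HiGHS).  The unit margin
  closes the open strict inequality without loss of generality — the
  constraint system is scale-invariant, so any strict separator rescales
  into the margin.  Returned witnesses are replayed through the exact
  definition on every row before being reported.
- **Exhaustive method** (n ≤ 4): brute force over integer
  w ∈ {-8..8}ⁿ; a threshold exists iff the smallest 1-row dot product
  exceeds the largest 0-row dot product, and that smallest dot product is
  itself an integer witness threshold.  Generous bounds for n ≤ 4
  threshold functions; used as the independent oracle, never the
  default.  The two methods agree on all 16 full 2-input and all 256
  full 3-input functions (14 and 104 separable, the classical threshold-
  function counts).

`check_pairing_contradiction` searches for the proof-by-contradiction
structure directly: two 0-rows with disjoint active inputs and two
1-rows with disjoint active inputs covering the same input multiset.
Summing the 0-row constraints bounds the summed weights by 2·Theta;
summing the 1-row constraints forces them above it.  The certificate is
sufficient (never necessary) for inseparability.  Rows with no active
inputs are excluded — the device is defined over tuples of active
inputs, so XOR (whose 0-rows are 00 and 11) is handled by the generic
checkers instead.

`make_cfbp(m)` generalises the four-input table to 2m inputs: clusters
A = {1..m}, B = {m+1..2m}; 0-rows are the two cluster indicators; 1-rows
are S1 = {1..⌈m/2⌉} ∪ {m+1..m+⌊m/2⌋} and its complement in A∪B.  This
reduces to the canonical table at m = 2 and preserves the pairing
structure (the 0-row union and 1-row union are both A∪B) for every m,
so the whole family is certified inseparable.

## Stimulation protocol and calibration

Each table row is one independent episode (state reset between episodes;
order-invariant).  Active inputs are driven either with one simultaneous
spike at t0 = 10 ms (**spike mode**, deterministic) or with independent
homogeneous Poisson trains at 50 Hz for the 500 ms episode (**rate
mode**, seeded).  The episode's Boolean output is 1 iff the soma fires
at least once — the "does the neuron activate" reading of the truth
table; a firing-rate criterion would be a straightforward variant but is
not the default.

**Calibration** runs the episodes with spiking disabled and measures
each episode's peak depolarisation.  If the largest 0-class peak is
below the smallest 1-class peak, the threshold is placed at their
midpoint; the drive scale is multiplied by 10 (from the spec's own
value) until that midpoint is at least 0.5 mV above rest, so the
decision is not made at numerical-noise level.  The default SIF
calibrates at drive ×100, threshold ≈ -64.17 mV, margin ≈ 0.27 mV.  If
the classes produce no gap the result is *not calibratable* — a
scientific verdict, not an error: this is precisely what happens to the
LIF, whose four episode traces are bit-identical in spike mode.  In rate
mode each episode's peak is averaged over 5 fixed-seed draws before the
midpoint is taken.

**Verdicts** (`implements_table`): spike mode is deterministic and uses
one run.  Rate mode repeats the whole protocol over 20 independent seeds
and requires every repetition to match every row — a deliberately
conservative unanimity criterion, because the claim being tested is
categorical — and reports the fraction of matching repetitions either
way.

## What the generators emulate, and what they do not

Spike-mode episodes emulate a single coincident presynaptic volley; they
are the cleanest reading of the truth table and carry the package's
categorical results.  Rate-mode episodes emulate sustained asynchronous
presynaptic activity with *independent* streams.  That independence has a
consequence worth stating plainly: a scattered episode only recruits its
200 pS advantage during cross-group coincidences within ~tau_s, which at
50 Hz × 500 ms occur ~0.6–1.3 times per episode and are sometimes absent,
while a clustered episode's temporal summation fluctuates from seed to
seed.  The two classes' peak-response distributions therefore overlap at
every drive scale, and the unanimous 20-seed rate-mode verdict for the
feature-binding table is negative under these input statistics even
though the mean responses order correctly.  Correlated input streams
(which real presynaptic populations often provide, and on which the
rate-based contrast in fact depends) would make the rate verdict
categorical as well; they are outside the current generator.  Passing
tests therefore establish the spike-mode claim categorically and the
rate-mode claim only ordinally (scattered > clustered on average).

Real granule cells additionally have conductance noise, inhibition,
synaptic depression and non-stationary input rates, none of which are
modelled; absolute firing rates produced by this model are not
predictions.

## Design choices where the design was open

- Saturation semantics: set-to-max.  Additive-then-clip is
  indistinguishable whenever one increment reaches the bound, so the
  simpler rule is canonical.
- LIF jump semantics: additive and unbounded at 100 pS/spike, making
  total drive a function of spike count alone — exactly the linearity
  the null model is meant to embody.  Whether the LIF pools one or two
  unbounded conductances is immaterial (identical traces for these
  protocols); the pooled form is used.
- Both saturating groups share identical kinetics and reversal
  potentials; the groups are treated symmetrically throughout.
- Episode length 500 ms, episode independence, t0 = 10 ms: unconstrained
  by the biology; chosen long relative to tau and fixed.
- Degenerate inputs: tables with a single output class are trivially
  separable (certifiers) and not calibratable (protocol); empty patterns
  yield silent episodes and output 0.

## Problem sizes

Default test and acceptance runs use 500 ms episodes at dt = 0.1 ms
(5 000 steps), 1 000-episode randomized saturation sweeps, exhaustive
enumeration up to n = 3 (256 functions × two certification methods), and
dense-reference integrations at dt = 0.001 ms over 50 ms fixtures.
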