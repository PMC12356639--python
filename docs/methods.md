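# Methods

## The model

`spwnet` simulates a local CA3 network of four populations of adaptive
exponential integrate-and-fire (AdEx) neurons: athorny pyramids (A, 2700),
thorny pyramids (T, 5300), PV+ basket cells (B, 150) and a putative
anti-sharp-wave interneuron class (C, 100), modelled on CCK+ basket cells.
Each neuron follows

    C dV/dt = -g_L (V - E_L) + g_L Δ_T exp((V - V_T)/Δ_T) - u + I_ext + I_syn
    τ_u du/dt = -u + a (V - E_L)

with a spike emitted when V reaches the numeric cutoff V_stop, after which
V is clamped at V_reset for a refractory time (3 ms) and u jumps by b.
Athorny cells are reset *above* threshold (V_reset = -42 mV > V_T = -48 mV),
which is how AdEx produces the burst firing seen in that cell type.
Synapses are conductance-based with single-exponential decay (glutamatergic
τ_d = 2 ms, E_rev = 0 mV; GABAergic τ_d = 4 ms, E_rev = -70 mV), a 1 ms
latency, and the physically standard driving force I_syn = Σ g (E_rev - V).
Connectivity is quenched Bernoulli per ordered pair, without autapses;
reciprocal directions are sampled independently.

Between the pyramidal populations the connection probabilities are the
experimentally measured ones (A→A 15%, T→A 11%, T→T 8%, A→T 4%, in
pre→post reading); all pathways involving interneurons use a common 20%.
Background currents hold each population slightly above its non-transient
rheobase (+10%; +40% for C, which must keep the rest of the network
inhibited between events). Mutual inhibition between B and C creates
bistability between a C-dominated quiescent state and a B-dominated
sharp-wave state; pyramidal spike-frequency adaptation terminates each
sharp wave and finite-size spiking fluctuations trigger the next one.

Two optional variants exist, both off by default: short-term depression of
E→E synapses (per-presynaptic-spike decrement η_dep with exponential
recovery τ_dep; since the efficacy of every synapse of one presynaptic
neuron follows the identical trajectory it is stored per neuron and
updated in closed form at spike times, which is exact), and quenched
heterogeneity (E→E weights and latencies with relative SD 1/4, excitatory
E_L with SD |E_L|/20 and g_L with relative SD 1/4; the conductance SD is
read as g_L/4 because a conductance SD in mV units is dimensionally
impossible).

## Numerics

Forward Euler at dt = 0.05 ms (numba-compiled; conductance increments are
event-based, so only the membrane/adaptation equations and exponential
conductance decays are integrated continuously). The exponential argument
is capped at +16 and skipped below -14, where the term is < 1e-4 pA.
V_stop defaults to V_T + 10 Δ_T = V_T + 25 mV; population statistics were
checked to be insensitive to V_stop within ±10 mV of that choice and to
halving/doubling of dt. Initial conditions: V ~ Uniform(E_L, V_T) per
neuron, u = 0, conductances 0; a 500 ms warmup is discarded. Synaptic
latency is rounded to integer steps. Heterogeneous latencies use a
per-edge delay ring; homogeneous runs use a single-slot spike queue.

A single global seed is expanded into named per-stage streams (network
construction, simulation, screen generation), so toggling one stage never
perturbs another's randomness.

## Event analysis

The LFP proxy is the mean over pyramidal neurons of the instantaneous
basket-cell synaptic current g_B (V - E_rev_B), in pA per neuron — the
perisomatic inhibitory current thought to dominate the stratum-pyramidale
field potential. It is sampled at 1 ms, low-pass filtered at 5 Hz
(2nd-order Butterworth, applied forward-backward for zero phase), and
local maxima more than 50 pA above the baseline L_0 (the median of the
filtered trace, robust while events occupy < 50% of the recording) are
sharp waves. Onset/offset are the nearest crossings of the half-height
level L_0 + (L_p - L_0)/2; detection is therefore invariant to constant
offsets. Population-rate peaks (1 ms bins, Gaussian smoothing σ = 5 ms,
which preserves the spike count) are located inside each event window; if
a population shows two peaks more than 50 ms apart both are recorded and
the first is used for the delay = first-T-peak minus first-A-peak. A
population must reach 2 spikes/s (configurable) for an event to enter the
delay statistics. Non-event rates are computed outside the union of
[onset, offset] windows.

The half-height duration is measured on the 5 Hz-filtered trace, which is
wider than the underlying rate transient; this is inherent to the
definition, not a parameter.

## Connectivity sweeps

Varying a connection probability changes event sizes, so at every grid
point a common weight factor is recalibrated until the mean event LFP peak
matches a reference (the default network's own mean peak) within ±10 pA.
Modes: `ee` scales all four E→E blocks, `eb` scales A→B and T→B. The
root-finder is a bracketed geometric bisection on the factor (≤12
iterations, 30 s simulation per iteration by default; shorter in the test
suite), relying on the empirically monotone growth of event size with
synaptic strength; a factor producing no events counts as below target.
Per-point statistics extend the simulated time until a minimum event count
is reached or a cap (default 120 s) is hit.

## Reproduced operating point, and what is not reproduced

With the published parameter tables exactly as printed, this
implementation produces the qualitative regime the model was built to
demonstrate: bistable alternation between a quiescent C-dominated state
and sharp-wave events in which basket cells reach 50–70 spikes/s, C cells
fall silent, pyramidal rates peak at tens of spikes/s, the athorny peak
precedes the thorny peak, pyramidal adaptation surges toward the event
end, and the delay grows dramatically (to > 100 ms, with double athorny
peaks) when the A→T connectivity is removed and shrinks when A→A is
reduced or A→T increased. At the p(A→T) = 0 corner the outcome depends on
event size: with weaker events the thorny population activates late
(delays ≈ 130 ms), while after full recalibration to the default event
size the thorny population can be suppressed entirely (< 1 spike/s) —
the winner-take-all corner that the validity threshold masks, by design,
in sweep outputs.

The *quantitative* operating point differs from the published one: events
occur at ≈ 0.03–0.07/s (published ≈ 1/s), quiescent pyramidal rates are
≈ 0.02–0.2 spikes/s (published 0.4), the mean delay at default parameters
is ≈ 45 ms (published 29 ms) and the filtered half-height duration
≈ 120 ms (published ≈ 80 ms). Extensive verification (an independent
second engine, dt and V_stop sensitivity checks, closed-form rheobase and
f-I oracles, mean-field balance estimates) indicates the implementation is
faithful to the printed equations and tables; the discrepancy traces to
the extreme sensitivity of the fluctuation-driven escape rate out of the
quiescent state. Adding as little as +5 to +10 pA (2–3%) to the pyramidal
background currents moves the incidence from 0.07 to 0.6–1.0 events/s —
and at the incidence-matching point the delay becomes ≈ 27 ms — i.e. the
operating point is set more finely than the 2–3 significant figures of
the printed parameter values resolve. The defaults here remain the printed
values; no compensating adjustment is applied. Conclusions that rest on
relative comparisons (delay trends across connectivity, event anatomy)
are robust; absolute incidence-class statistics should be read with the
above in mind.

## Synthetic paired-recording screens

The generator emulates the multi-patch protocol: groups of up to eight
simultaneously patched cells (66:34 thorny:athorny), each stimulated with
four APs at 20 Hz while the others are recorded; 40 sweeps per ordered
pair at 20 kHz. Connections are Bernoulli with the measured type-pair
probabilities; connected pairs draw a log-normal amplitude (medians
1.08/0.88/0.57/0.66 mV, dispersion σ = 0.4), Gaussian latency
(1.5 ± 0.3 ms, truncated at 0.3 ms), a per-AP release probability (0.8)
and a multiplicative per-pulse depression factor (imposed EPSP4/EPSP1 =
factor³). EPSPs are difference-of-exponentials kernels (rise 2 ms, decay
20 ms, unit peak — typical somatic EPSP values, config-exposed) on
Ornstein-Uhlenbeck membrane noise (SD 0.2 mV, τ 2 ms). A small fraction
of cells (5%) and sweeps (3%, never the first sweep of a pair, which
anchors the drift reference) deliberately violates the QC thresholds.

What the generator does not emulate: correlated noise across cells,
electrode drift dynamics, polysynaptic contamination, IQR-matched
amplitude distributions, or voltage-dependent driving-force changes.
Passing recovery tests therefore demonstrates the pipeline's correctness
on data with known ground truth, not its robustness to every artefact of
real recordings.

Analysis conventions (objective surrogates for decisions made visually at
the rig): a connection requires the averaged post-AP1 peak (mean over
±0.25 ms around the maximum, which suppresses max-picking bias) to exceed
3× the averaged-trace baseline SD and a 0.15 mV floor; single-sweep
successes for failure rates use a 1 ms boxcar-smoothed peak against 2× the
raw single-sweep baseline SD (failure rates are overestimated for
amplitudes near the noise floor — a limitation shared with any
threshold-based single-sweep classification); latency is the 20%-of-peak
rise time of the averaged first EPSP relative to the AP peak (for the
default kernel this sits 0.35 ms after the kernel onset); short-term
plasticity uses the deconvolution d(t) = τ dV/dt + V with τ = 55 ms,
low-pass filtered at 300 Hz, peaks referenced to a 2 ms pre-AP local
baseline and normalized to pulse 1. Because failures dilute the averaged
trace, the generator's ground-truth tables carry both the drawn unitary
amplitude and the release-probability-scaled expected average amplitude;
recovery is assessed against the latter.

Group comparisons follow the standard nonparametric path: Shapiro-Wilk
normality gate, Mann-Whitney-U for two groups or Kruskal-Wallis for more,
with a hand-implemented Dunn's post hoc (rank-based z with tie
correction, Bonferroni-adjusted) when the omnibus test is significant at
α = 0.05; its type-I error is calibrated at 5% in the test suite.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run desk-scale versions of the
full experiments: default-network statistics from ~100–300 s of network
time over 3+ seeds (8250 neurons, ~6.3 million synapses), sweep trends
from 3-point grids with 15–30 s calibration/statistics blocks, and screen
recovery from 72-cell screens (504 tested pairs). These sizes were chosen
so each check resolves the effect it asserts; all are configurable
upward.

## Known limitations

- The quantitative incidence mismatch discussed above.
- Euler integration makes spike times accurate to dt; latency quantization
  adds up to half a step of jitter.
- The LFP proxy ignores every synaptic pathway except B→pyramidal, by
  construction.
- `compare_groups` reports the Shapiro-Wilk gate but always proceeds
  nonparametrically; a parametric branch is intentionally absent.
- Ripple-band (~200 Hz) structure is outside the model's scope: it
  produces sharp waves, not ripples.
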