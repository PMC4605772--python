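# Methods

## The model circuit

`klinfo` simulates the putative minimal circuit for salt klinotaxis in
*C. elegans*: the ASE chemosensory pair, modelled as idealized ON and OFF
cells, feeding two layers of interneurons (AIYL/R, AIZL/R) and four SMB neck
motor neurons (SMBDL/DR/VL/VR) that drive the neck-angle velocity. The
sensory stage applies a windowed derivative to the recent concentration
history: the mean of the newest `N` samples minus the mean of the preceding
`M` samples. The ON cell outputs that derivative when positive, the OFF cell
its negation when non-positive; exactly one of the two is active at any
instant. Interneurons and motor neurons are passive isopotential nodes with
a shared membrane time constant `tau`; chemical synapses are logistic
functions `sigma(V_pre + theta_pre)` of the presynaptic potential, gap
junctions are non-rectifying conductances `g (V_other - V_self)` with
`g > 0`, and the SMB cells carry self-connections standing in for the
voltage dependence of inward currents. The motor layer additionally receives
a sinusoidal pattern-generator drive of period `T = 4.2 s`: ventral cells
receive `+w_PG sin(2 pi t / T)`, dorsal cells the antiphase signal (all
phase conventions elsewhere in the package refer to the ventral drive). The
neck-angle velocity is `phi = w_NMJ ((sigma_SMBDL + sigma_SMBDR) -
(sigma_SMBVL + sigma_SMBVR))`, and the body is a point moving at a constant
`v = 0.022 cm/s` whose heading integrates `phi`.

Integration is explicit Euler with `dt = 0.01 s` (`T/420`), the conventional
choice for this family of network models; `dt` is exposed everywhere, and a
test verifies first-order convergence under refinement. The windowed sensory
sums are maintained incrementally (O(1) per step); the residual float drift
is below 1e-12 in concentration units, orders of magnitude under both the
stimulus scale and one histogram bin, and a test pins that bound. Before any
stimulus, state is all-zero potentials with the concentration history
pre-filled with the baseline value, so the sensory derivative starts at
exactly zero; assays then let the circuit settle onto its unstimulated
attractor (default six locomotion cycles) before stimulation.

Parameter choices that the source material leaves open:

* `N` and `M` are evolvable integers in [1, 105] steps. The upper bound lets
  the combined window `N + M` span up to half a locomotion cycle (2.1 s at
  `dt = 0.01 s`), matching the observation that sensory information persists
  for about half a cycle in competent circuits.
* Left/right cell equations mirror each other with the L/R indices swapped;
  only dorsal/ventral parameters are tied (when the symmetry flag is set),
  leaving the left/right parameters free to differ.
* The baseline concentration is arbitrary (the sensory stage is
  translation-invariant, asserted by a test); it defaults to 1.0.

## Environments and behavior

The behavioral environment is a planar radial gradient, conical by default
(concentration decreasing linearly with distance from the peak at
0.45 concentration/cm, floored at zero) with a Gaussian alternative. The
slope is chosen so that the perceived rate of concentration change —
bounded by `v * slope` — spans roughly ±0.01 per second, the same range the
open-loop stimulus ensembles use. The chemotaxis index scores a run as
`1 - mean(distance to peak) / initial distance`, clipped to [0, 1]; it is
the fitness of the evolutionary search. The empirical distribution of
perceived concentration changes pools per-step `dc/dt` over repeated runs
from random start poses (default 500 s per run).

## Evolutionary search

Unknown parameters are evolved with a real-valued genetic algorithm:
genotypes in [-1, 1] map linearly to the documented ranges (sensor weights
±500 — the sensory signal is of order 0.01, so effective drive needs gains
of order 100; other weights and biases ±15; gap conductances (0.01, 2.5];
`w_PG` ±10; `w_NMJ` ±3; `tau` in [0.1, 2] s). Dorsal/ventral symmetry is
enforced in the encoding. Selection is tournament (size 3) with elitism 2,
uniform crossover (rate 0.5) and Gaussian mutation (scale 0.15 in genotype
units). Fitness is the chemotaxis index averaged over three deterministic
start poses 2 cm from the peak, headed tangentially, over 400 s runs.
Circuits above a chemotaxis index of 0.75 across independent seeded runs
(one best circuit per run) form the ensemble. With the default settings
roughly three quarters of runs succeed.

The packaged fixtures are one frozen ensemble produced this way (the
manifest records each circuit's seed and fitness). The `"best"` fixture is
the canonical high-performer used in examples and lesion tests: the
highest-fitness circuit whose information architecture matches the modal
pattern of the ensemble (dominant-AIY asymmetry, gap-junction-mediated AIZ
symmetry). Tests that depend on a specific circuit load fixtures rather
than re-evolving.

## Open-loop assays

The information analysis isolates the circuit from the environment. The
concentration step assay delivers a trial-specific jump `dc` at a fixed
pattern-generator phase (default phase 0; a phase sweep exposes the onset
phase) and records two locomotion cycles. The information clamp assay ramps
concentration at a trial-specific constant rate `cdot`; because the sensory
derivative then settles to the constant `cdot * dt * (N + M) / 2`, the
chemosensors hold a constant output and all remaining time dependence
downstream comes from the oscillatory drive. The sensory settling window
(`N + M` steps) plus two locomotion cycles are excluded before the one-cycle
recording. Stimulus ensembles default to 2200 presentations drawn uniformly
from ±0.01 (steps: concentration units; clamps: concentration per second),
with a 220-trial fast mode used by the test suite; an empirical mode
resamples stimuli from the closed-loop perceived-change distribution.
Recorded variables are the two chemosensor potentials, the eight synaptic
outputs, and the neck-angle velocity.

## Information measures

Distributions are induced by the stimulus ensemble: at each recorded time
the joint distribution of (stimulus, response) over trials is estimated
with average shifted histograms — 50 bins per dimension (both stimulus and
response) and 12 shifts per dimension, averaging all shift combinations.
The averaging is computed in closed form: on the fine grid of
`bins * shifts` cells per dimension the shift-average reduces to linear
(cloud-in-cell) weights on two adjacent coarse bins per dimension, which is
exactly the mean of all shifted histograms (a test checks this against the
brute-force average). Binning ranges are the sampled stimulus range and
each variable's observed min/max; a constant response collapses to a single
slot. Joint (multi-variable) responses reduce per-dimension bins to keep
the total cell count near 50^2 (e.g. 7 per dimension for the SMB
quadruple), a sample-size sanity measure at 2200 trials.

All measures use base-2 logarithms with the `0 log 0 = 0` convention and
are reported both in bits and normalized by the stimulus entropy `H(S)`
(computed from the same estimator's stimulus marginal), so 0 means the
stimulus is indistinguishable and 1 uniquely determined. Mutual information
is the standard double sum; specific information for a stimulus value `s`
is the expected reduction in surprise about `s` given the response (its
stimulus-weighted average recovers the mutual information exactly, a
property test); transfer entropy from `Y` to `X` at time `t` is the
conditional mutual information `I(X_t; Y_{t-1} | X_{t-1})` — lag-1 source,
order-1 conditioning, the appropriate convention for a deterministic system
— estimated with the same per-dimension binning on the triple.

Estimator bias worth knowing about: smoothing across shifted grids leaks
probability mass between adjacent cells, so even a perfect noiseless
readout of the stimulus estimates normalized MI around 0.8 rather than 1.0
at the default 50 bins / 12 shifts. The bias is shared across variables, so
normalized profiles remain comparable (orderings, extrema locations and
layer-preservation ratios are unaffected; a robustness test checks
invariance of these features from 20 to 200 bins). Exact normalization
extremes (1 for an invertible readout, 0 for a constant one) hold
analytically and are verified on analytic joints. Negative estimates cannot
occur for MI or TE (plug-in estimates of nonnegative quantities on exact
distributions); specific information can be legitimately negative and is
clipped only in report summaries, never in tests.

## Derived summaries

The information architecture assembles, per node, the time-averaged
normalized MI and the positive/negative split of time-averaged specific
information (mass on stimulus slots above vs below zero, clipped at zero,
normalized to sum to 1), and per anatomical edge the time-averaged transfer
entropy. Sensor and interneuron quantities use the step assay; SMB and neck
quantities the clamp assay. The symmetry index of a cell pair is the ratio
of the smaller to the larger time-averaged MI (1 = symmetric, 0 = one cell
silent; defined as 1 when both vanish). Gating curves report per-SMB-cell
MI versus stimulus-onset phase at a fixed 50 ms delay and delay-averaged
over a cycle. Timing metrics read onset/offset times off threshold
crossings of normalized MI (threshold 0.05, configurable; the joint ASE
pair stands for the sensors, the neck-angle velocity for the output).
Ensemble reports align cells before averaging: the AIY cell with more
cumulative information is ranked first, the AIZ cells align to the side of
the dominant AIY, and SMB pairs rank by cumulative information.

Two conventions worth making explicit. First, the fixed 50 ms gating delay
mirrors the classical presentation, but in our evolved circuits the motor
response often has not exceeded one output bin that soon after a step
(membrane time constants run 0.1-0.4 s), so phase dependence is judged on
the cycle-averaged gating curves, which integrate the whole response; the
dorsal/ventral half-cycle shift is exact by construction under the
symmetry constraint and is asserted at float precision. Second, gating is
typically one-sided: the SMB pair downstream of the informative AIZ side
shows deep phase modulation while the opposite pair stays flat, so
ensemble-level gating assertions use the most-modulated cell.

## Scale of the shipped analyses

The study conditions (2200 trials, 50 bins, 12 shifts) are the package
defaults. The test suite and examples run reduced problem sizes chosen to
keep full runs inexpensive while leaving every qualitative conclusion
unchanged: 220 trials, 8-phase sweeps, and ensembles of 10-20 circuits
evolved at population 40 for 40-60 generations. The ensemble-level
assertions are majority-vote over evolved circuits, mirroring how the
architecture features are ensemble-typical rather than universal.

## Known limitations

* The body is a point; no agar mechanics, body undulation, pirouettes or
  klinokinesis. Closed-loop information analysis (where action shapes the
  stimulus distribution) is out of scope.
* The estimator is a plug-in estimator for noiseless, unlimited-data
  simulation; it has no bias correction for noisy experimental recordings.
* Synergy/redundancy decompositions across multiple variables are not
  implemented.
* The evolved ensemble stands in for the original study's (whose parameters
  are not published); exact reproduction of that ensemble's values is not
  attempted, and all ensemble-level statements are qualitative.
* Our genetic search frequently converges on fully one-sided circuits that
  route stimulus information down a single left/right channel through both
  interneuron layers; the gap-junction-rebalanced AIZ layer is a
  substantial minority motif here rather than the majority one. The
  chemical-route dominance into AIY, SMB gating with antiphase
  dorsal/ventral structure, and the neck-information dip are
  near-universal; the AIY-asymmetric/AIZ-symmetric ordering holds only for
  the canonical subset (the `"best"` fixture among them). How common that
  motif is depends on evolutionary conditions we could only choose, not
  copy.
* In the evolved worms the perceived concentration-change distribution
  concentrates near the extremes (wide heading swings), with a clear bias
  toward increases; a near-zero mode would require smaller head-sweep
  amplitudes than our circuits adopt.
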