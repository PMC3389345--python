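# Methods

## The granule-cell model

The simulator is a single-compartment conductance-based model in the
patch-clamp unit system (mV, pA, nS, pF, ms):

    C dV/dt = I_inj + ξ(t)
              − g_L (V − E_L)
              − g_rect a∞(V) (V − E_K)
              − g_Na m³h (V − E_Na)
              − g_K n⁴ (V − E_K)

* **Passive leak** `g_L`, `E_L` sets the resting potential and the
  hyperpolarized-limb input resistance (R = 1/g_L when all other
  conductances are zero, so the model reduces exactly to an RC cell).
* **Outwardly rectifying leak** (TASK-like): instantaneous Boltzmann
  activation a∞(V) = 1/(1 + exp(−(V − V½)/k)), reversing at E_K. It
  opposes depolarization near threshold and is the main determinant of
  the rheobase; reducing it raises the depolarized-range specific
  resistance, the mechanism behind the trisomic-like parameter set.
* **Spike conductances**: classic Hodgkin–Huxley m³h sodium and n⁴
  delayed-rectifier rate functions, each with a voltage shift along the
  V axis and a dimensionless speed multiplier. The sodium shift is
  −5 mV (activation positioned so the regenerative knee sits near
  −60 mV, giving rheobase densities of ~4–5 pA/pF from a −80 mV rest);
  the potassium shift is +20 mV (a high-threshold, Kv3-like rectifier
  that stays out of the subthreshold range, clips the overshoot little,
  and still repolarizes fast — granule-cell APs fall almost as fast as
  they rise). Speed multipliers (1.9 for Na, 3.6 for K relative to the
  classic 6.3 °C squid rates) set the ~700 µs half-width.
* **Noise** ξ(t): white Gaussian current noise, one independent sample
  per integration step (default SD 1 pA).

Default wild-type parameters (C = 3 pF, g_L = 0.9 nS, E_L = −79.8 mV,
g_rect = 2.5 nS with V½ = −52 mV, k = 6 mV, g_Na = 160 nS, E_Na = +65 mV,
g_K = 150 nS, E_K = −90 mV) were chosen against phenomenological anchors:
resting potential ≈ −80 mV (junction-corrected), input resistance
~1.1 GΩ at rest rising toward threshold, rheobase ≈ 14 pA (~4.7 pA/pF),
AP overshoot ≈ +20 mV, AHP ≈ −80 mV (amplitude ≈ 100 mV), half-width
≈ 710 µs, maximal rate of fall ≈ 0.75× the maximal rate of rise, tonic
firing up to >90 APs per 500 ms step, and first-AP latency longest at
rheobase and shortening with current.

**Integration.** Fixed-step exponential Euler at 16 µs, matching the
62.5 kHz acquisition rate so recorded samples coincide with integration
steps; gates use the closed-form update x ← x∞ + (x − x∞)·exp(−Δt/τₓ)
with rates frozen at the step's starting voltage. The initial state is
the algebraic resting fixed point (found by bracketed root-solving of
the steady-state current balance), and the 100 ms pre-step baseline
relaxes any residual. A 10× finer step changes AP counts only through
the phase of the last spike relative to the step offset on the fastest
sweeps (validated in the test suite). Non-finite voltages abort with a
diagnostic rather than propagating.

**Junction potential.** The simulator integrates the true membrane
potential; stored sweeps add the liquid junction potential (8.8 mV) to
emulate the amplifier read-out. All analysis outputs subtract it again
(`corrected = recorded − jp`), so the analysis-time correction round-trips
the model's actual voltages.

**Populations.** Each cell draws parameters from a generator named by
(population seed, cell index), so populations are order-independent and
individually reproducible. Capacitance is log-normal with CV 0.25
(matching the interquartile spread reported for real GCs); maximal
conductances scale with the drawn relative area (capacitance / mean
capacitance) times a residual log-normal density factor with CV 0.1 —
channel numbers track membrane area, and what varies between cells
beyond size is channel *density*. The leak reversal magnitude carries a
CV of 0.02, producing the ~2 mV between-cell spread of resting
potentials seen in recordings. Kinetics are shared within a population.

**The trisomic-like ("TS") parameter set** scales the wild-type set by:
capacitance ×1.25, rectifying leak ×0.7, g_Na ×1.45, g_K ×1.18, Na and K
rate speeds ×1.1, and shifts the Na rate functions by +1.8 mV. The
reasoning: the capacitance scaling alone reproduces the larger cells;
the rectifier reduction raises the specific resistance approaching
threshold and lowers the rheobase density; conductance scalings *above*
the capacitance scaling raise channel density, and together with the
kinetic speed-up make the APs larger, faster-rising/falling and
narrower; and the small depolarizing Na shift cancels the
threshold-lowering effect of the extra sodium, keeping the measured
voltage threshold (and the resting potential) at wild-type values — the
defining "changed excitability without changed threshold" pattern. A
naive uniform conductance scaling below the capacitance scaling fails
this pattern (it *lowers* channel density, widening the APs). One known
residual: the TS-like AHP ends up 1–2 mV deeper than wild type, where
real trisomic GCs show no AHP change; within this model family the
deeper trough is inseparable from the larger, faster spike.

**What the generator does not emulate**: electrode/bridge-balance
artifacts, series-resistance errors in current clamp, temperature
effects, sag/rebound currents, synaptic (including tonic GABA-A)
conductances, multi-compartment effects, slow adaptation beyond the
HH gates, and recording drift. Passing tests therefore show that the
*analysis* recovers what this model family generates under realistic
sampling and noise — not that the model captures every feature of real
granule-cell data. In particular, amplitude accommodation during long
trains is milder here than in real GCs.

## Analysis conventions

* Baseline window: final 50% of the pre-step epoch (minimum 5 ms);
  steady-state window: final 20% of the step. Both configurable.
* Capacitance fit: single exponential from 2 samples after onset to 90%
  of the step, on the −10 pA sweep with fallback to −8 pA; τ outside
  (0.1, 100) ms is flagged. R = ΔV/I from the fitted asymptote,
  C = τ/R.
* Transient capacitance: C = Q/(ΔV − I_ss·R_s), with Q the integrated
  current above steady state; dividing by the series-corrected step
  (the voltage the membrane capacitor actually reaches) removes most of
  the finite-membrane-resistance bias of the naive Q/ΔV estimator.
* V–I curves use only AP-free sweeps; curves with fewer than 4 points
  are excluded from sigmoid fitting. Boltzmann fits initialize from the
  data extremes and the mid-range crossing, retry from 3 jittered
  starts on non-convergence, and fall back to a straight line (constant
  dV/dI) when the fitted |s| exceeds 10× the current range. R(V) is
  evaluated only inside the fitted current range.
* Grid averaging interpolates each cell linearly onto integer multiples
  of the spacing (0.5 pA/pF default, 0.1 optional) restricted to the
  cell's observed range; grid points with fewer than 3 contributing
  cells are dropped in pipeline output (SEM is 0 where one cell
  contributes, for the single-cell case).
* AP detection: local maxima above −20 mV separated by ≥1 ms inside the
  step window. Phase-plane threshold: the first sample of the final
  rise where centred-difference dV/dt reaches 10 mV/ms and stays above
  it up to the point of maximal rise; events never reaching the
  criterion are rejected as spurious. AHP: minimum within 10 ms of the
  peak, bounded by the next AP's threshold. Half-width: time between
  the two crossings of (overshoot + AHP)/2, sub-sample by linear
  interpolation. Amplitude ≡ overshoot − AHP (the same definition feeds
  the half-amplitude level and the accommodation profiles, for internal
  consistency).
* Rheobase-AP pooling: the first three APs from the rheobase sweep,
  topped up from the next sweeps in ascending order when fewer than
  three fired; each feature is averaged over the pooled APs. The
  2× rheobase sweep is the protocol step nearest twice the rheobase,
  ties toward the larger step.
* Firing frequency = AP count / step duration (mean instantaneous
  frequency is reported alongside as an alternative).
* Statistics: Shapiro–Wilk gate at α = 0.05 per group; Student's t uses
  pooled variance; Mann–Whitney is exact (no ties, n₁·n₂ ≤ 400) or the
  tie-corrected normal approximation; quartiles use linear
  interpolation between order statistics. The mixed ANOVA keeps grid
  levels covered by ≥70% of cells and drops cells missing any kept
  level (complete-case); no sphericity correction and no
  multiple-testing correction are applied; significance is read at
  p < 0.05. An all-equal sample is treated as maximally non-normal by
  the gate; two all-equal groups are rejected as degenerate.

## Problem sizes and determinism

The default study is 20 + 20 cells × 26 sweeps × 700 ms at 62.5 kHz;
one full simulate–extract–compare run takes ~40 s on one CPU (the
integrator is a compiled numba kernel batched over all traces). The
test suite uses shortened protocols for unit tests and runs the full
directional-recovery experiment at n = 20/20 over ten master seeds. All
randomness flows from explicit seeds: population seeds derive from the
master seed, per-cell generators from (population seed, cell index), so
every report is byte-reproducible given (config, seed).

## Known limitations

* The model's voltage threshold (~−55 mV junction-corrected) sits a few
  mV below the ~−48 mV reported for real mature GCs; pushing it higher
  in this two-spike-conductance model costs the long near-rheobase
  latencies and the rising R(V) profile, which were prioritized.
* Between-cell scatter of AP features is somewhat larger than in real
  data because rheobase quantization (the 2 pA protocol grid) interacts
  with threshold accommodation across the pooled APs.
* The fall-versus-rise regression slope across cells is inside (−1, 0)
  as in real GCs but smaller in magnitude; the across-cell covariance
  of rise and fall rates depends on population structure that is only
  coarsely modelled.
* The exact Mann–Whitney switches to the normal approximation in the
  presence of any tie, slightly conservative for small samples with few
  ties.
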