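# gcephys

Intrinsic-excitability analysis of cerebellar granule neurons from
current-clamp step protocols, with a conductance-based granule-cell
simulator for generating synthetic recordings.

Cerebellar granule cells (GCs) are tiny (input capacitance of a few pF),
electrically compact neurons whose firing is shaped by a voltage-dependent
input resistance: subthreshold depolarization recruits a regenerative
sodium component that steepens the voltage–current relation as the cell
approaches threshold. Studies of GC excitability — for example comparisons
between wild-type and trisomic (Down-syndrome-model, "TS") mice — rest on
a standard analysis chain applied to families of constant-current steps
(−10 pA ascending in +2 pA increments, sampled at 62.5 kHz):

* **Passive properties** — resting potential from pre-step baselines
  (corrected for a liquid junction potential, 8.8 mV by default); input
  capacitance *C*ᵢₙ measured two ways, from the time constant of a single
  exponential fitted to the deflection under a −10 pA (or −8 pA) step
  (τ = RC, C = τ/R) and from the charge of the voltage-clamp capacitive
  transient under a 5 mV jump (C = Q/ΔV).
* **Voltage-dependent input resistance** — per-cell subthreshold V–I
  relations (currents normalized by *C*ᵢₙ to current density, pA/pF),
  fitted with a Boltzmann sigmoid
  V(I) = A₁ + (A₂ − A₁)/(1 + exp(−(I − I₀)/s));
  the input resistance R(V) = dV/dI is its analytic first derivative.
  Per-cell curves are averaged across cells on an equally spaced
  current-density grid (0.5 or 0.1 pA/pF).
* **AP waveform metrology** — phase-plane analysis (dV/dt against V) of
  the first three APs at or just above rheobase: voltage threshold
  (dV/dt criterion, 10 mV/ms), maximal rates of rise and fall, overshoot,
  afterhyperpolarization (AHP), amplitude (overshoot − AHP) and width at
  half amplitude with sub-sample interpolation.
* **Firing metrics** — rheobase (and rheobase density), latency to the
  first AP at rheobase and at twice rheobase (the chronaxie), f–I curves
  (AP count / step duration against current density above rheobase), and
  accommodation profiles (AP amplitudes relative to the first AP,
  instantaneous frequencies) for sweeps evoking ≥ 4, 22 and 46 APs.
* **Statistics** — per-feature two-group comparisons gated by the
  Shapiro–Wilk normality test (Student's t with pooled variance and
  mean ± SEM summaries when both groups pass; Mann–Whitney U — exact
  enumeration when n₁·n₂ ≤ 400 and no ties — with median (Q1, Q3)
  summaries otherwise), and a two-way mixed repeated-measures ANOVA over
  the V–I curves (genotype × current level, cells as subjects, genotype
  tested against subjects-within-groups, df = (1, n₁+n₂−2)).

Because raw recordings of this kind are rarely deposited, the package
includes a single-compartment Hodgkin–Huxley-type GC model (passive leak,
outwardly rectifying potassium-like leak with Boltzmann activation, m³h
sodium and n⁴ potassium spike conductances, exponential-Euler integration
at 16 µs) with seeded log-normal population variability, and a default
trisomic-like parameter set that reproduces the qualitative effect
pattern reported for Ts65Dn GCs: larger cells, higher specific resistance
near threshold, lower rheobase density, larger/faster/narrower APs,
unchanged resting potential and voltage threshold.

## Worked example

Simulate 20 wild-type-like and 20 TS-like cells, extract all features and
compare the genotypes:

```bash
gcephys run --seed 7 --out demo
# 16 features compared, 12 significant at p < 0.05; report under demo/report
```

The report (`demo/report/report.json`) contains one record per feature;
the key rows of this run:

```
resting_mv           student_t     WT: -80.3 ± 0.326 mV       TS: -79.8 ± 0.39 mV        p=0.359
cin_exp_pf           student_t     WT: 2.79 ± 0.181 pF        TS: 3.45 ± 0.187 pF        p=0.015 *
rheobase_pa_per_pf   student_t     WT: 4.83 ± 0.177 pA/pF     TS: 3.21 ± 0.138 pA/pF     p=0.000 *
vthresh_mv           student_t     WT: -54.6 ± 0.175 mV       TS: -55.1 ± 0.227 mV       p=0.111
amplitude_mv         mann_whitney  WT: 95.1 (92.1, 98.6) mV   TS: 112 (107, 114) mV      p=0.000 *
half_width_us        mann_whitney  WT: 710 (700, 736) us      TS: 602 (592, 620) us      p=0.000 *
```

Reading this: the TS-like population has a ~25% larger input capacitance,
fires at a ~1.6 pA/pF lower rheobase density and produces larger, ~15%
narrower action potentials, while the resting potential and the voltage
threshold do not differ — the canonical excitability phenotype. The same
run writes per-cell features (`features/features.tsv`), gridded V–I and
R(V) curves, f–I curves, accommodation profiles and threshold-aligned
average-AP traces (`curves/`), and the raw sweep files themselves
(`cells/*.cellset.tsv`, a greppable tab-delimited text format).

The stages also run separately on existing files:

```bash
gcephys simulate --seed 7 --n 20 --out demo
gcephys extract  --in demo --dvdt-criterion 10 --grid-spacing 0.5
gcephys compare  --in demo
```

All settings (model parameters, protocol timing, analysis windows,
statistics) live in a flat `key = value` config file passed with
`--config`; see `gcephys.config` for the schema.

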