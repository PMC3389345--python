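"""Synthetic current-clamp recordings from the granule-cell model.

This module generates the data the analysis pipeline consumes: analytic
passive RC responses, conductance-based simulated cells, seeded
two-genotype populations, and voltage-clamp capacitive transients.

The simulated membrane potential is the *true* potential of the model
cell; stored sweeps emulate the amplifier read-out, which overestimates
the membrane potential by the liquid junction potential.  The
analysis-time correction (subtracting ``junction_potential``) therefore
recovers the model's actual voltages.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from . import _kernel
from ._kernel import N_PARAMS
from .params import (
    CellRecording,
    CurrentTransient,
    GCModelParams,
    PopulationSpec,
    StepProtocol,
    SweepRecord,
)

__all__ = [
    "passive_rc_response",
    "simulate_cell",
    "sample_population",
    "simulate_cap_transient",
    "resting_state",
    "steady_state_voltage",
]


class SimulationDivergence(RuntimeError):
    """Raised when the integrated membrane potential goes non-finite."""


def _params_row(p: GCModelParams) -> np.ndarray:
    row = np.empty(N_PARAMS)
    row[_kernel.P_CAP] = p.capacitance
    row[_kernel.P_GL] = p.leak_conductance
    row[_kernel.P_EL] = p.leak_reversal
    row[_kernel.P_GRECT] = p.rect_conductance
    row[_kernel.P_RHALF] = p.rect_half
    row[_kernel.P_RSLOPE] = p.rect_slope
    row[_kernel.P_GNA] = p.na_conductance
    row[_kernel.P_ENA] = p.na_reversal
    row[_kernel.P_NASHIFT] = p.na_shift
    row[_kernel.P_NASCALE] = p.na_rate_scale
    row[_kernel.P_GK] = p.k_conductance
    row[_kernel.P_EK] = p.k_reversal
    row[_kernel.P_KSHIFT] = p.k_shift
    row[_kernel.P_KSCALE] = p.k_rate_scale
    return row


def _gate_inf(v: float, shift: float, rates) -> float:
    a, b = rates(v - shift)
    return a / (a + b)


def steady_state_current(params: GCModelParams, v: float, i_inj: float = 0.0) -> float:
    """Net membrane current (pA, outward positive) at voltage ``v`` with
    all gates at their steady state; zero at a stable fixed point."""
    p = params
    m = _gate_inf(v, p.na_shift, _kernel._m_rates)
    h = _gate_inf(v, p.na_shift, _kernel._h_rates)
    n = _gate_inf(v, p.k_shift, _kernel._n_rates)
    a = 1.0 / (1.0 + np.exp(-(v - p.rect_half) / p.rect_slope))
    ionic = (
        p.leak_conductance * (v - p.leak_reversal)
        + p.rect_conductance * a * (v - p.k_reversal)
        + p.na_conductance * m**3 * h * (v - p.na_reversal)
        + p.k_conductance * n**4 * (v - p.k_reversal)
    )
    return ionic - i_inj


def steady_state_voltage(
    params: GCModelParams, i_inj: float = 0.0, bracket: tuple[float, float] = (-150.0, -20.0)
) -> float:
    """Most hyperpolarized root of the current-balance equation.

    Solved by bisection on a fine voltage scan followed by Brent's
    method, independent of the time-stepping integrator.
    """
    vs = np.linspace(bracket[0], bracket[1], 2601)
    f = np.array([steady_state_current(params, v, i_inj) for v in vs])
    sign_change = np.nonzero(np.diff(np.sign(f)) != 0)[0]
    if sign_change.size == 0:
        raise ValueError("no subthreshold fixed point in bracket")
    lo, hi = vs[sign_change[0]], vs[sign_change[0] + 1]
    return brentq(lambda v: steady_state_current(params, v, i_inj), lo, hi)


def resting_state(params: GCModelParams) -> float:
    """Resting potential of the model (mV, true membrane potential)."""
    return steady_state_voltage(params, 0.0)


def passive_rc_response(
    R: float,
    C: float,
    I: float,
    protocol: StepProtocol,
    v_rest: float = -80.0,
) -> SweepRecord:
    """Analytic voltage response of an RC cell to one current step.

    Parameters
    ----------
    R : GOhm
    C : pF
    I : pA
    v_rest : mV
        Baseline potential (as recorded).

    The on-response is ``v_rest + I*R*(1 - exp(-t/RC))`` and the
    relaxation after step offset is the mirrored exponential, both exact
    to machine precision at the sample times.
    """
    if R <= 0 or C <= 0:
        raise ValueError("R and C must be > 0")
    tau = R * C  # ms
    dt = protocol.sample_dt
    n = protocol.n_samples
    on, off = protocol.onset_index, protocol.offset_index
    t = np.arange(n) * dt
    v = np.full(n, float(v_rest))
    during = (t > t[on]) & (t <= t[off])
    v[during] = v_rest + I * R * (1.0 - np.exp(-(t[during] - t[on]) / tau))
    v_off = v_rest + I * R * (1.0 - np.exp(-(t[off] - t[on]) / tau))
    after = t > t[off]
    v[after] = v_rest + (v_off - v_rest) * np.exp(-(t[after] - t[off]) / tau)
    return SweepRecord(
        time_step=dt / 1000.0,
        voltage=v,
        command_current=float(I),
        step_onset_index=on,
        step_offset_index=off,
    )


def _simulate_traces(
    params_rows: np.ndarray,
    currents: np.ndarray,
    protocol: StepProtocol,
    noise_sd: np.ndarray,
    rng_list: list[np.random.Generator | None],
    dt: float,
) -> np.ndarray:
    """Integrate a batch of traces; returns (n_traces, n_samples) recorded
    true membrane potential."""
    sample_dt = protocol.sample_dt
    record_every = int(round(sample_dt / dt))
    if not np.isclose(record_every * dt, sample_dt, rtol=1e-9):
        raise ValueError("integration_dt must divide the sampling interval")
    n_steps = (protocol.n_samples - 1) * record_every
    onset_step = protocol.onset_index * record_every
    offset_step = protocol.offset_index * record_every

    n_traces = params_rows.shape[0]
    out = np.empty((n_traces, protocol.n_samples))
    v0 = np.empty(n_traces)
    for i in range(n_traces):
        p_row = params_rows[i]
        # settle from the algebraic fixed point; baseline then relaxes any residual
        v0[i] = _v0_cache_lookup(p_row)

    if np.any(noise_sd > 0):
        noise = np.empty((n_traces, n_steps))
        for i in range(n_traces):
            if noise_sd[i] > 0:
                noise[i] = rng_list[i].normal(0.0, noise_sd[i], n_steps)
            else:
                noise[i] = 0.0
    else:
        noise = np.empty((n_traces, 0))

    bad = _kernel.integrate_batch(
        params_rows,
        np.asarray(currents, dtype=float),
        noise,
        v0,
        dt,
        n_steps,
        onset_step,
        offset_step,
        record_every,
        out,
    )
    if bad >= 0:
        raise SimulationDivergence(
            f"membrane potential diverged (non-finite) in trace {bad}; "
            "reduce integration_dt or check parameters"
        )
    return out


_V0_CACHE: dict[bytes, float] = {}


def _v0_cache_lookup(p_row: np.ndarray) -> float:
    key = p_row.tobytes()
    if key not in _V0_CACHE:
        if len(_V0_CACHE) > 4096:
            _V0_CACHE.clear()
        p = GCModelParams(
            capacitance=p_row[_kernel.P_CAP],
            leak_conductance=p_row[_kernel.P_GL],
            leak_reversal=p_row[_kernel.P_EL],
            rect_conductance=p_row[_kernel.P_GRECT],
            rect_half=p_row[_kernel.P_RHALF],
            rect_slope=p_row[_kernel.P_RSLOPE],
            na_conductance=p_row[_kernel.P_GNA],
            na_reversal=p_row[_kernel.P_ENA],
            na_shift=p_row[_kernel.P_NASHIFT],
            na_rate_scale=p_row[_kernel.P_NASCALE],
            k_conductance=p_row[_kernel.P_GK],
            k_reversal=p_row[_kernel.P_EK],
            k_shift=p_row[_kernel.P_KSHIFT],
            k_rate_scale=p_row[_kernel.P_KSCALE],
        )
        _V0_CACHE[key] = steady_state_voltage(p, 0.0)
    return _V0_CACHE[key]


def simulate_cell(
    params: GCModelParams,
    protocol: StepProtocol,
    seed: int,
    cell_id: str = "cell_000",
    genotype: str = "WT",
    junction_potential: float = 8.8,
) -> CellRecording:
    """Simulate one cell's full sweep family.

    One sweep per protocol amplitude; deterministic given ``seed``.
    Stored voltages are the recorded (junction-uncorrected) potentials,
    i.e. true membrane potential + ``junction_potential``.
    """
    rng = np.random.default_rng(seed)
    n_sweeps = len(protocol.step_amplitudes)
    rows = np.tile(_params_row(params), (n_sweeps, 1))
    noise_sd = np.full(n_sweeps, params.noise_sd)
    rngs: list[np.random.Generator | None] = [
        np.random.default_rng(rng.integers(0, 2**31 - 1)) for _ in range(n_sweeps)
    ]
    v = _simulate_traces(
        rows,
        np.array(protocol.step_amplitudes),
        protocol,
        noise_sd,
        rngs,
        params.integration_dt,
    )
    sweeps = [
        SweepRecord(
            time_step=protocol.sample_dt / 1000.0,
            voltage=v[i] + junction_potential,
            command_current=protocol.step_amplitudes[i],
            step_onset_index=protocol.onset_index,
            step_offset_index=protocol.offset_index,
        )
        for i in range(n_sweeps)
    ]
    return CellRecording(
        cell_id=cell_id,
        genotype=genotype,
        sweeps=sweeps,
        sampling_rate=protocol.sampling_rate,
        junction_potential=junction_potential,
    )


_CONDUCTANCE_FIELDS = ("leak_conductance", "rect_conductance", "na_conductance", "k_conductance")


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean log-normal multiplier with the given CV."""
    sigma = np.sqrt(np.log(1.0 + cv**2))
    return float(rng.lognormal(-0.5 * sigma**2, sigma))


def draw_cell_params(spec: PopulationSpec, index: int) -> GCModelParams:
    """Per-cell parameters for cell ``index``.

    Fields are drawn log-normally around the means with the spec's CVs
    from a generator named by (seed, index).  With ``area_coupled`` the
    maximal conductances additionally scale with the cell's drawn
    relative area (capacitance / mean capacitance), their own CVs acting
    as residual channel-density variability.
    """
    rng = np.random.default_rng([spec.seed, index])
    overrides = {}
    area = 1.0
    for name in sorted(spec.between_cell_cv):
        cv = spec.between_cell_cv[name]
        mean = getattr(spec.mean_params, name)
        if mean == 0:
            continue
        factor = _lognormal_factor(rng, cv) if cv > 0 else 1.0
        if name == "capacitance":
            area = factor
        if spec.area_coupled and name in _CONDUCTANCE_FIELDS:
            continue  # applied after the area factor is known
        if cv > 0:
            overrides[name] = float(mean * factor)
    if spec.area_coupled:
        for name in _CONDUCTANCE_FIELDS:
            if name not in spec.between_cell_cv:
                continue
            cv = spec.between_cell_cv[name]
            mean = getattr(spec.mean_params, name)
            if mean == 0:
                continue
            resid = _lognormal_factor(rng, cv) if cv > 0 else 1.0
            overrides[name] = float(mean * area * resid)
    return spec.mean_params.with_(**overrides)


def sample_population(
    spec: PopulationSpec,
    protocol: StepProtocol | None = None,
    junction_potential: float = 8.8,
) -> list[CellRecording]:
    """Simulate ``spec.n_cells`` cells with independent per-cell parameters.

    Reproducible: each cell has its own generator derived from
    (seed, cell index), so the population does not depend on simulation
    order.  All cells of the population are integrated in one batched
    kernel call.
    """
    protocol = protocol or StepProtocol()
    n_sweeps = len(protocol.step_amplitudes)
    all_rows = []
    all_currents = []
    noise_sd = []
    rngs: list[np.random.Generator | None] = []
    cell_params = []
    for c in range(spec.n_cells):
        p = draw_cell_params(spec, c)
        cell_params.append(p)
        row = _params_row(p)
        sweep_rng = np.random.default_rng([spec.seed, c, 1])
        for j, amp in enumerate(protocol.step_amplitudes):
            all_rows.append(row)
            all_currents.append(amp)
            noise_sd.append(p.noise_sd)
            rngs.append(np.random.default_rng(sweep_rng.integers(0, 2**31 - 1)))
    dt = spec.mean_params.integration_dt
    v = _simulate_traces(
        np.array(all_rows), np.array(all_currents), protocol, np.array(noise_sd), rngs, dt
    )
    cells = []
    for c in range(spec.n_cells):
        sweeps = [
            SweepRecord(
                time_step=protocol.sample_dt / 1000.0,
                voltage=v[c * n_sweeps + j] + junction_potential,
                command_current=protocol.step_amplitudes[j],
                step_onset_index=protocol.onset_index,
                step_offset_index=protocol.offset_index,
            )
            for j in range(n_sweeps)
        ]
        cells.append(
            CellRecording(
                cell_id=f"{spec.genotype_label}_{c:03d}",
                genotype=spec.genotype_label,
                sweeps=sweeps,
                sampling_rate=protocol.sampling_rate,
                junction_potential=junction_potential,
            )
        )
    return cells


def simulate_cap_transient(
    params: GCModelParams,
    voltage_step: float = 5.0,
    series_resistance: float = 10.0,
    duration: float = 3.0,
    time_step: float = 5e-7,
) -> CurrentTransient:
    """Capacitive current transient under a voltage-clamp step.

    Models the passive pipette-cell circuit: series resistance Rs (MOhm)
    in series with the membrane RC (R_m = 1/leak_conductance, C).  For a
    command step dV the clamp current is the closed-form double term

        I(t) = I_ss + (I_peak - I_ss) exp(-t/tau)

    with ``I_peak = dV/Rs``, ``I_ss = dV/(Rs + R_m)`` and
    ``tau = Rs R_m C / (Rs + R_m)``.  A zero step yields the degenerate
    all-zero trace.

    ``duration`` in ms, ``time_step`` in s.
    """
    if series_resistance <= 0:
        raise ValueError("series_resistance must be > 0")
    rs = series_resistance  # MOhm
    c = params.capacitance  # pF
    t = np.arange(0.0, duration * 1e-3, time_step)  # s
    if voltage_step == 0.0:
        return CurrentTransient(time_step, np.zeros_like(t), 0.0, rs)
    if params.leak_conductance > 0:
        rm = 1000.0 / params.leak_conductance  # MOhm
        i_ss = 1000.0 * voltage_step / (rs + rm)  # pA (mV/MOhm = nA)
        tau = rs * rm * c / (rs + rm) * 1e-6  # s  (MOhm * pF = us)
    else:
        i_ss = 0.0
        tau = rs * c * 1e-6
    i_peak = 1000.0 * voltage_step / rs
    current = i_ss + (i_peak - i_ss) * np.exp(-t / tau)
    return CurrentTransient(time_step, current, voltage_step, rs)
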