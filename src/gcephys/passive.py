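"""Passive membrane properties and voltage-dependent input resistance.

The analysis chain is: resting potential from pre-step baselines; input
capacitance from (a) the time constant of a single exponential fitted to
the voltage deflection under a small negative current step and (b) the
charge of the voltage-clamp capacitive transient; subthreshold
steady-state V-I relations per cell (optionally normalized to current
density, pA/pF); Boltzmann sigmoid fits of V(I); the input resistance as
the analytic first derivative dV/dI of the fit; and across-cell averages
of density-normalized curves on a shared equally spaced grid.

All returned voltages are corrected for the liquid junction potential
(``corrected = recorded - junction_potential``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .params import CellRecording, CurrentTransient
from .spikes import SpikeConfig, detect_aps

__all__ = [
    "PassiveConfig",
    "PassiveSummary",
    "VICurve",
    "SigmoidFit",
    "GriddedCurve",
    "resting_potential",
    "fit_cin_exponential",
    "cin_from_transient",
    "steady_state_vi",
    "fit_sigmoid_vi",
    "rin_curve",
    "grid_average",
]


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class PassiveConfig:
    """Windows and tolerances for the passive analysis.

    baseline_fraction — final fraction of the pre-step epoch used as
    baseline; steady_state_fraction — final fraction of the step used
    for steady-state voltages; fit_start_samples / fit_end_fraction —
    exponential-fit window relative to the step onset; min_baseline_ms —
    minimum usable baseline window; tau_bounds_ms — plausibility range
    for the fitted membrane time constant.
    """

    baseline_fraction: float = 0.5
    steady_state_fraction: float = 0.2
    fit_start_samples: int = 2
    fit_end_fraction: float = 0.9
    min_baseline_ms: float = 5.0
    tau_bounds_ms: tuple[float, float] = (0.1, 100.0)
    cin_probe_currents: tuple[float, ...] = (-10.0, -8.0)


@dataclass
class PassiveSummary:
    resting_potential: float  # mV, junction-corrected
    cin_exp_fit: float | None = None  # pF
    cin_transient: float | None = None  # pF
    tau_m: float | None = None  # ms
    r_step: float | None = None  # GOhm
    flags: list[str] = field(default_factory=list)


@dataclass
class VICurve:
    """Subthreshold steady-state voltage-current relation of one cell."""

    currents: np.ndarray  # pA or pA/pF
    voltages: np.ndarray  # mV, junction-corrected
    density: bool  # True when currents are pA/pF
    cell_id: str = ""
    usable_for_fit: bool = True

    def __post_init__(self):
        self.currents = np.asarray(self.currents, dtype=float)
        self.voltages = np.asarray(self.voltages, dtype=float)
        if np.any(np.diff(self.currents) <= 0):
            raise ValueError("currents must be strictly increasing")


@dataclass
class SigmoidFit:
    """Boltzmann fit V(I) = A1 + (A2 - A1) / (1 + exp(-(I - I0)/s)).

    A1 is the hyperpolarized asymptote, A2 the depolarized one; I0 the
    midpoint and s the slope factor in the units of the fitted currents.
    ``linear_fallback`` marks near-linear data, for which the derivative
    is treated as the constant line slope.
    """

    a1: float
    a2: float
    i0: float
    s: float
    residual_sd: float
    current_range: tuple[float, float]
    density: bool
    linear_fallback: bool = False
    slope: float | None = None  # mV per unit current, fallback only
    intercept: float | None = None

    def predict(self, i: np.ndarray) -> np.ndarray:
        i = np.asarray(i, dtype=float)
        if self.linear_fallback:
            return self.intercept + self.slope * i
        return _boltzmann(i, self.a1, self.a2, self.i0, self.s)

    def derivative(self, i: np.ndarray) -> np.ndarray:
        """Analytic dV/dI along the fitted range."""
        i = np.asarray(i, dtype=float)
        if self.linear_fallback:
            return np.full_like(i, self.slope)
        e = np.exp(-(i - self.i0) / self.s)
        return (self.a2 - self.a1) * e / (self.s * (1.0 + e) ** 2)


@dataclass
class GriddedCurve:
    grid: np.ndarray  # pA/pF
    mean_voltage: np.ndarray  # mV
    sem_voltage: np.ndarray  # mV
    n_per_point: np.ndarray  # contributing cells


def _baseline_window(rec: CellRecording, cfg: PassiveConfig) -> tuple[int, int]:
    on = rec.sweeps[0].step_onset_index
    start = int(round(on * (1.0 - cfg.baseline_fraction)))
    dt = rec.sweeps[0].time_step * 1000.0
    if (on - start) * dt < cfg.min_baseline_ms:
        raise ValueError(
            f"baseline window {(on - start) * dt:.2f} ms shorter than "
            f"minimum {cfg.min_baseline_ms} ms"
        )
    return start, on


def resting_potential(rec: CellRecording, cfg: PassiveConfig = PassiveConfig()) -> float:
    """Junction-corrected mean of the pre-step baselines of all sweeps."""
    start, on = _baseline_window(rec, cfg)
    vals = [s.voltage[start:on].mean() for s in rec.sweeps]
    return float(np.mean(vals)) - rec.junction_potential


def _exp_rise(t, v0, dv, tau):
    # clipped exponent keeps the optimizer out of overflow territory
    return v0 + dv * (1.0 - np.exp(np.clip(-t / tau, -700.0, 50.0)))


def fit_cin_exponential(
    rec: CellRecording,
    cfg: PassiveConfig = PassiveConfig(),
    spike_cfg: SpikeConfig = SpikeConfig(),
) -> PassiveSummary:
    """Input capacitance from the membrane time constant.

    A single exponential is fitted to the voltage deflection of the
    -10 pA sweep (fallback -8 pA); R = dV_ss / I and C = tau / R.
    """
    sweep = None
    for probe in cfg.cin_probe_currents:
        for s in rec.sweeps:
            if np.isclose(s.command_current, probe) and not detect_aps(s, spike_cfg):
                sweep = s
                break
        if sweep is not None:
            break
    if sweep is None:
        raise ValueError(
            f"cell {rec.cell_id}: no AP-free sweep at {cfg.cin_probe_currents} pA"
        )
    dt = sweep.time_step * 1000.0
    on, off = sweep.step_onset_index, sweep.step_offset_index
    i0 = on + cfg.fit_start_samples
    i1 = on + int(round(cfg.fit_end_fraction * (off - on)))
    t = (np.arange(i0, i1) - on) * dt
    v = sweep.voltage[i0:i1]

    v_base = sweep.voltage[: on ].mean() if on else v[0]
    dv_guess = v[-1] - v_base
    tau_guess = max(dt, 0.1 * t[-1])
    try:
        popt, _ = curve_fit(
            _exp_rise, t, v, p0=(v_base, dv_guess, tau_guess), maxfev=10000
        )
    except RuntimeError as err:
        raise FitError(f"exponential fit failed: {err}") from err
    v0, dv, tau = popt
    tau = float(abs(tau))
    r = float(dv / sweep.command_current)  # GOhm (mV / pA)
    cin = tau / r
    summary = PassiveSummary(
        resting_potential=resting_potential(rec, cfg),
        cin_exp_fit=float(cin),
        tau_m=tau,
        r_step=r,
    )
    lo, hi = cfg.tau_bounds_ms
    if not (lo < tau < hi):
        summary.flags.append(f"tau {tau:.3g} ms outside ({lo}, {hi})")
    return summary


def cin_from_transient(tr: CurrentTransient) -> float:
    """Capacitance from the charge of a voltage-clamp transient.

    C = (integral of the current above its steady state) / dV_m, where
    dV_m is the command step minus the steady-state drop across the
    series resistance (the voltage the membrane capacitor actually
    charges to).  The steady state is the mean of the final 10% of the
    trace.
    """
    if tr.voltage_step == 0:
        raise ValueError("degenerate transient: zero voltage step")
    i = tr.current
    n_tail = max(1, i.size // 10)
    i_ss = i[-n_tail:].mean()
    dt_ms = tr.time_step * 1000.0
    q = np.trapezoid(i - i_ss, dx=dt_ms)  # pA*ms = fC
    dv_m = tr.voltage_step - i_ss * tr.series_resistance * 1e-3  # pA*MOhm = uV
    return float(q / dv_m)  # fC / mV = pF


def steady_state_vi(
    rec: CellRecording,
    cin: float | None = None,
    cfg: PassiveConfig = PassiveConfig(),
    spike_cfg: SpikeConfig = SpikeConfig(),
) -> VICurve:
    """Steady-state V-I relation over the AP-free sweeps.

    The steady-state voltage is the junction-corrected mean over the
    final ``steady_state_fraction`` of the step.  With ``cin`` the
    currents are expressed as density (pA/pF).  Curves with fewer than
    4 points are flagged unusable for sigmoid fitting.
    """
    currents, voltages = [], []
    for s in rec.sweeps:
        if detect_aps(s, spike_cfg):
            continue
        on, off = s.step_onset_index, s.step_offset_index
        w0 = off - int(round(cfg.steady_state_fraction * (off - on)))
        voltages.append(s.voltage[w0:off].mean() - rec.junction_potential)
        currents.append(s.command_current / cin if cin else s.command_current)
    curve = VICurve(
        currents=np.array(currents),
        voltages=np.array(voltages),
        density=cin is not None,
        cell_id=rec.cell_id,
        usable_for_fit=len(currents) >= 4,
    )
    if not curve.usable_for_fit:
        warnings.warn(f"cell {rec.cell_id}: only {len(currents)} subthreshold points")
    return curve


def _boltzmann(i, a1, a2, i0, s):
    return a1 + (a2 - a1) / (1.0 + np.exp(-(i - i0) / s))


def fit_sigmoid_vi(curve: VICurve, rng: np.random.Generator | None = None) -> SigmoidFit:
    """Least-squares Boltzmann fit of a V-I curve.

    Initialization from the data extremes and the mid-range crossing;
    non-convergence retried from 3 jittered starts.  Data whose fitted
    slope factor exceeds 10x the current range are flagged as linear and
    handled by a straight-line fallback.
    """
    if not curve.usable_for_fit or curve.currents.size < 4:
        raise ValueError("curve unusable for fitting (fewer than 4 points)")
    i, v = curve.currents, curve.voltages
    i_range = float(i.max() - i.min())
    a1_0, a2_0 = float(v.min()), float(v.max())
    mid = 0.5 * (a1_0 + a2_0)
    i0_0 = float(np.interp(mid, v, i))
    s_0 = i_range / 4.0
    rng = rng or np.random.default_rng(0)

    def _linear() -> SigmoidFit:
        slope, intercept = np.polyfit(i, v, 1)
        resid = v - (intercept + slope * i)
        return SigmoidFit(
            a1=a1_0, a2=a2_0, i0=i0_0, s=np.inf,
            residual_sd=float(np.std(resid, ddof=1)),
            current_range=(float(i.min()), float(i.max())),
            density=curve.density,
            linear_fallback=True, slope=float(slope), intercept=float(intercept),
        )

    p0 = (a1_0, a2_0, i0_0, s_0)
    for attempt in range(4):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(_boltzmann, i, v, p0=p0, maxfev=20000)
        except RuntimeError:
            jitter = rng.normal(1.0, 0.2, 4)
            p0 = (a1_0 * jitter[0], a2_0 * jitter[1], i0_0 + i_range * (jitter[2] - 1), s_0 * jitter[3])
            continue
        a1, a2, i0, s = popt
        if abs(s) > 10.0 * i_range:
            return _linear()
        resid = v - _boltzmann(i, *popt)
        return SigmoidFit(
            a1=float(a1), a2=float(a2), i0=float(i0), s=float(s),
            residual_sd=float(np.std(resid, ddof=1)),
            current_range=(float(i.min()), float(i.max())),
            density=curve.density,
        )
    return _linear()


def rin_curve(fit: SigmoidFit, n_points: int = 101) -> tuple[np.ndarray, np.ndarray]:
    """Input resistance against membrane potential from a sigmoid fit.

    Returns (fitted membrane potential mV, dV/dI) evaluated on an even
    current grid across the fitted range only.  dV/dI is in GOhm for
    raw-current fits (mV/pA) and in capacitance-specific units
    (GOhm * pF) for density fits (mV per pA/pF).  Extrapolation beyond
    the fitted range is refused by construction.
    """
    i = np.linspace(fit.current_range[0], fit.current_range[1], n_points)
    return fit.predict(i), fit.derivative(i)


def grid_average(
    curves: list[VICurve],
    spacing: float = 0.5,
    min_n: int = 1,
) -> GriddedCurve:
    """Across-cell average of density V-I curves on a shared grid.

    Each cell is linearly interpolated onto integer multiples of
    ``spacing`` restricted to the cell's own observed current range;
    grid points with fewer than ``min_n`` contributing cells are
    dropped.  SEM is 0 where a single cell contributes.
    """
    if not curves:
        raise ValueError("no curves")
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    if not all(c.density for c in curves) and any(c.density for c in curves):
        raise ValueError("curves mix density and raw-current units")
    lo = min(c.currents.min() for c in curves)
    hi = max(c.currents.max() for c in curves)
    k0, k1 = int(np.ceil(lo / spacing - 1e-9)), int(np.floor(hi / spacing + 1e-9))
    grid = np.arange(k0, k1 + 1) * spacing
    vals = np.full((len(curves), grid.size), np.nan)
    for j, c in enumerate(curves):
        inside = (grid >= c.currents.min() - 1e-12) & (grid <= c.currents.max() + 1e-12)
        vals[j, inside] = np.interp(grid[inside], c.currents, c.voltages)
    n = np.sum(~np.isnan(vals), axis=0)
    keep = n >= max(1, min_n)
    if not np.any(keep):
        raise ValueError("no grid point reaches min_n cells (empty range intersection)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(vals[:, keep], axis=0)
        sd = np.nanstd(vals[:, keep], axis=0, ddof=1)
    nk = n[keep]
    sem = np.where(nk > 1, sd / np.sqrt(nk), 0.0)
    return GriddedCurve(
        grid=grid[keep], mean_voltage=mean, sem_voltage=np.nan_to_num(sem), n_per_point=nk
    )
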