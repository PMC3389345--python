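"""Domain types for granule-cell recordings and the conductance-based model.

Units follow the patch-clamp convention used throughout the package:
voltage in mV, current in pA, conductance in nS, capacitance in pF,
time in ms (sampling rates in Hz).  With these units the membrane
equation ``C dV/dt = I - sum(g_x * (V - E_x))`` is dimensionally
consistent without conversion factors (nS * mV = pA, pA / pF = mV/ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "GCModelParams",
    "StepProtocol",
    "SweepRecord",
    "CellRecording",
    "PopulationSpec",
    "CurrentTransient",
    "wt_params",
    "ts_params",
    "default_protocol",
]


@dataclass(frozen=True)
class GCModelParams:
    """Parameters of the single-compartment granule-cell model.

    The model carries a passive leak, an outwardly rectifying
    potassium-like leak with instantaneous Boltzmann activation
    (TASK-type), and Hodgkin-Huxley m3h sodium / n4 potassium spike
    conductances whose rate functions can be shifted along the voltage
    axis and scaled in speed.

    Parameters
    ----------
    capacitance
        Whole-cell input capacitance, pF.
    leak_conductance
        Voltage-independent leak, nS.  With all other conductances zero
        the model reduces exactly to an RC cell with R = 1/leak_conductance.
    leak_reversal
        Leak reversal potential, mV; the main determinant of the resting
        potential.
    rect_conductance
        Maximal conductance of the outwardly rectifying leak, nS.
    rect_half, rect_slope
        Boltzmann half-activation voltage (mV) and slope factor (mV) of
        the rectifier; activation = 1 / (1 + exp(-(V - half)/slope)).
    na_conductance, na_reversal
        Maximal transient sodium conductance (nS) and reversal (mV).
    na_shift, na_rate_scale
        Voltage shift (mV) applied to the sodium rate functions and a
        dimensionless multiplier on their speed.
    k_conductance, k_reversal
        Maximal delayed-rectifier potassium conductance (nS) and
        reversal (mV); the rectifier leak also reverses at k_reversal.
    k_shift, k_rate_scale
        Voltage shift and speed multiplier for the potassium gate.
    noise_sd
        SD of white Gaussian current noise added at each integration
        step, pA.
    integration_dt
        Fixed integration step, ms.
    """

    capacitance: float = 3.0
    leak_conductance: float = 0.9
    leak_reversal: float = -79.8
    rect_conductance: float = 2.5
    rect_half: float = -52.0
    rect_slope: float = 6.0
    na_conductance: float = 160.0
    na_reversal: float = 65.0
    na_shift: float = -5.0
    na_rate_scale: float = 1.9
    k_conductance: float = 150.0
    k_reversal: float = -90.0
    k_shift: float = 20.0
    k_rate_scale: float = 3.6
    noise_sd: float = 1.0
    integration_dt: float = 0.016

    def __post_init__(self) -> None:
        if not self.capacitance > 0:
            raise ValueError(f"capacitance must be > 0, got {self.capacitance}")
        for name in ("leak_conductance", "rect_conductance", "na_conductance", "k_conductance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not (self.na_reversal > 0 > self.k_reversal):
            raise ValueError("require na_reversal > 0 > k_reversal")
        if not self.integration_dt > 0:
            raise ValueError("integration_dt must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def with_(self, **kwargs) -> "GCModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    @property
    def membrane_resistance(self) -> float:
        """Passive membrane resistance 1/leak_conductance, GOhm."""
        return 1.0 / self.leak_conductance


def wt_params() -> GCModelParams:
    """Default wild-type-like parameter set."""
    return GCModelParams()


def ts_params() -> GCModelParams:
    """Default trisomic-like ("TS") parameter set.

    Relative to wild type: 25% higher capacitance, 30% less rectifying
    leak, 45% more sodium and 18% more potassium conductance, 10% faster
    sodium and potassium kinetics, and a 1.8 mV depolarizing shift of
    the sodium rate functions.  The conductance scalings exceed the
    capacitance scaling so specific channel density rises; together with
    the kinetic speed-up this gives a larger cell with a higher specific
    resistance near threshold, a lower rheobase density and larger,
    faster, narrower action potentials, while the sodium shift
    compensates the threshold-lowering effect of the extra sodium so the
    resting potential and voltage threshold stay at wild-type values.
    """
    wt = wt_params()
    return wt.with_(
        capacitance=wt.capacitance * 1.25,
        rect_conductance=wt.rect_conductance * 0.7,
        na_conductance=wt.na_conductance * 1.45,
        k_conductance=wt.k_conductance * 1.18,
        na_rate_scale=wt.na_rate_scale * 1.1,
        k_rate_scale=wt.k_rate_scale * 1.1,
        na_shift=wt.na_shift + 1.8,
    )


def _default_amplitudes() -> tuple[float, ...]:
    return tuple(float(a) for a in range(-10, 42, 2))


@dataclass(frozen=True)
class StepProtocol:
    """A family of constant-current steps.

    Defaults follow the standard granule-cell protocol: steps from
    -10 pA ascending in +2 pA increments (here up to +40 pA), acquired
    at 62.5 kHz.
    """

    baseline_duration: float = 100.0
    step_duration: float = 500.0
    post_duration: float = 100.0
    step_amplitudes: tuple[float, ...] = field(default_factory=_default_amplitudes)
    sampling_rate: float = 62500.0

    def __post_init__(self) -> None:
        amps = tuple(float(a) for a in self.step_amplitudes)
        object.__setattr__(self, "step_amplitudes", amps)
        if len(amps) == 0:
            raise ValueError("need at least one step amplitude")
        if any(b <= a for a, b in zip(amps, amps[1:])):
            raise ValueError("step amplitudes must be strictly increasing")
        for name in ("baseline_duration", "step_duration", "post_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")

    @property
    def total_duration(self) -> float:
        """Sweep length, ms."""
        return self.baseline_duration + self.step_duration + self.post_duration

    @property
    def sample_dt(self) -> float:
        """Sampling interval, ms."""
        return 1000.0 / self.sampling_rate

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration / self.sample_dt))

    @property
    def onset_index(self) -> int:
        return int(round(self.baseline_duration / self.sample_dt))

    @property
    def offset_index(self) -> int:
        return int(round((self.baseline_duration + self.step_duration) / self.sample_dt))


@dataclass(eq=False)
class SweepRecord:
    """One voltage sweep under a single constant current step.

    ``voltage`` holds the potentials as recorded (i.e. not corrected for
    the liquid junction potential); times are implicit via ``time_step``
    (seconds per sample).
    """

    time_step: float
    voltage: np.ndarray
    command_current: float
    step_onset_index: int
    step_offset_index: int

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, dtype=float)
        if not (0 <= self.step_onset_index < self.step_offset_index < self.voltage.size):
            raise ValueError("require 0 <= onset < offset < sweep length")
        if not np.all(np.isfinite(self.voltage)):
            raise ValueError("sweep contains non-finite samples")

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.voltage.size) * self.time_step

    @property
    def sampling_rate(self) -> float:
        return 1.0 / self.time_step


@dataclass
class CellRecording:
    """A cell's ordered sweep family plus metadata.

    Sweeps are ordered by strictly increasing command current and share
    the sampling rate and step timing.  ``junction_potential`` (mV) is
    the calculated liquid junction potential; recorded voltages
    overestimate the true membrane potential by this amount, so the
    analysis-time correction is ``corrected = recorded - junction_potential``.
    """

    cell_id: str
    genotype: str
    sweeps: list[SweepRecord]
    sampling_rate: float
    junction_potential: float = 8.8

    def __post_init__(self) -> None:
        if not self.sweeps:
            raise ValueError("a recording needs at least one sweep")
        currents = [s.command_current for s in self.sweeps]
        if any(b <= a for a, b in zip(currents, currents[1:])):
            raise ValueError("sweep currents must be strictly increasing")
        ref = self.sweeps[0]
        for s in self.sweeps:
            if not np.isclose(s.time_step, ref.time_step, rtol=1e-9):
                raise ValueError("sweeps disagree on sampling rate")
            if (s.step_onset_index, s.step_offset_index) != (
                ref.step_onset_index,
                ref.step_offset_index,
            ):
                raise ValueError("sweeps disagree on step timing")

    @property
    def currents(self) -> np.ndarray:
        return np.array([s.command_current for s in self.sweeps])

    @property
    def step_duration(self) -> float:
        """Step length in ms."""
        s = self.sweeps[0]
        return (s.step_offset_index - s.step_onset_index) * s.time_step * 1000.0

    def sweep_at(self, current: float) -> SweepRecord:
        """Return the sweep whose command current equals ``current``."""
        for s in self.sweeps:
            if np.isclose(s.command_current, current):
                return s
        raise KeyError(f"no sweep at {current} pA")


@dataclass(frozen=True)
class PopulationSpec:
    """Specification of a simulated population of cells.

    Per-cell parameters are drawn log-normally around ``mean_params``
    with the per-field coefficients of variation in ``between_cell_cv``
    (field name -> CV).  By default only capacitance and the maximal
    conductances vary between cells; kinetics are shared.

    With ``area_coupled`` (default) the maximal conductances co-vary
    with the drawn capacitance — channel number scales with membrane
    area — and their CV entries are the *residual* cell-to-cell CV of
    channel density on top of that scaling.  Without it every field is
    drawn independently with its stated marginal CV.
    """

    mean_params: GCModelParams
    n_cells: int
    genotype_label: str
    seed: int
    between_cell_cv: dict = field(
        default_factory=lambda: {
            "capacitance": 0.25,
            "leak_conductance": 0.1,
            "rect_conductance": 0.1,
            "na_conductance": 0.1,
            "k_conductance": 0.1,
            # small CV on the leak reversal magnitude gives the ~2 mV
            # cell-to-cell spread of resting potentials seen in recordings
            "leak_reversal": 0.02,
        }
    )
    area_coupled: bool = True

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for k, v in self.between_cell_cv.items():
            if v < 0:
                raise ValueError(f"CV for {k} must be >= 0")
            if not hasattr(self.mean_params, k):
                raise ValueError(f"unknown parameter field {k!r}")


@dataclass
class CurrentTransient:
    """A voltage-clamp capacitive transient under a small voltage jump."""

    time_step: float  # s
    current: np.ndarray  # pA
    voltage_step: float  # mV
    series_resistance: float  # MOhm

    def __post_init__(self) -> None:
        self.current = np.asarray(self.current, dtype=float)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.current.size) * self.time_step


def default_protocol() -> StepProtocol:
    return StepProtocol()
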