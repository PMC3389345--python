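"""Shared fixtures: analytic RC recordings and simulated cells.

Expensive simulations are session-scoped; most unit tests use a
shortened protocol so the whole suite stays fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from gcephys import StepProtocol, passive_rc_response, simulate_cell, wt_params, ts_params
from gcephys.params import CellRecording, SweepRecord


@pytest.fixture(scope="session")
def protocol() -> StepProtocol:
    return StepProtocol()


@pytest.fixture(scope="session")
def short_protocol() -> StepProtocol:
    return StepProtocol(
        baseline_duration=50.0,
        step_duration=300.0,
        post_duration=50.0,
        step_amplitudes=tuple(float(a) for a in range(-10, 42, 2)),
    )


def make_rc_recording(
    R: float = 1.0,
    C: float = 3.0,
    protocol: StepProtocol | None = None,
    v_rest: float = -71.2,
    jp: float = 8.8,
    cell_id: str = "rc",
) -> CellRecording:
    protocol = protocol or StepProtocol()
    sweeps = [
        passive_rc_response(R, C, I, protocol, v_rest=v_rest)
        for I in protocol.step_amplitudes
    ]
    return CellRecording(cell_id, "WT", sweeps, protocol.sampling_rate, junction_potential=jp)


@pytest.fixture(scope="session")
def rc_recording() -> CellRecording:
    # recorded rest -71.2 mV -> junction-corrected -80 mV
    return make_rc_recording()


@pytest.fixture(scope="session")
def wt_cell(short_protocol) -> CellRecording:
    """One noiseless wild-type-like cell on the shortened protocol."""
    return simulate_cell(
        wt_params().with_(noise_sd=0.0), short_protocol, seed=11, cell_id="wt_fix"
    )


@pytest.fixture(scope="session")
def wt_cell_noisy(short_protocol) -> CellRecording:
    return simulate_cell(wt_params(), short_protocol, seed=12, cell_id="wt_noisy")


def make_sweep(voltage: np.ndarray, dt_ms: float = 0.016, on: int | None = None,
               off: int | None = None, current: float = 10.0) -> SweepRecord:
    """Wrap a raw voltage array into a sweep (default: step spans all but
    the first/last 5% of samples)."""
    n = len(voltage)
    if on is None:
        on = n // 20
    if off is None:
        off = n - n // 20
    return SweepRecord(
        time_step=dt_ms / 1000.0,
        voltage=np.asarray(voltage, dtype=float),
        command_current=current,
        step_onset_index=on,
        step_offset_index=off,
    )


def triangular_spike(
    base: float = -70.0,
    peak: float = 10.0,
    rise_ms: float = 0.3,
    fall_ms: float = 0.6,
    dt_ms: float = 0.016,
    pad_ms: float = 5.0,
    ahp: float | None = None,
) -> np.ndarray:
    """Piecewise-linear AP: flat baseline, linear rise, linear fall to
    ``ahp`` (default: back to base), flat tail."""
    ahp = base if ahp is None else ahp
    n_pad = int(round(pad_ms / dt_ms))
    n_rise = int(round(rise_ms / dt_ms))
    n_fall = int(round(fall_ms / dt_ms))
    return np.concatenate(
        [
            np.full(n_pad, base),
            np.linspace(base, peak, n_rise, endpoint=False),
            np.linspace(peak, ahp, n_fall + 1),
            np.full(n_pad, ahp),
        ]
    )
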