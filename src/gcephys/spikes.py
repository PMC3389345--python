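"""Action-potential detection and waveform metrology.

Conventions follow standard current-clamp practice for granule cells:

* APs are detected as local maxima above a floor voltage inside the
  current-step window, separated by a refractory distance.
* The voltage threshold and the maximal rates of rise and fall are taken
  from the phase-plane trajectory (dV/dt against V, with dV/dt from
  centred differences): the threshold is the voltage at which dV/dt
  first reaches the criterion (default 10 mV/ms) on the final
  suprathreshold rise to the peak.
* AP amplitude is measured between the overshoot (peak) and the
  afterhyperpolarization (the minimum after the peak), and the
  half-width is the width at the voltage level halfway between the two,
  with sub-sample resolution by linear interpolation.

All functions operate on voltages as stored in the sweep; outputs that
are voltages live on the same scale as the input (the caller applies any
junction-potential correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import linregress

from .params import CellRecording, SweepRecord

__all__ = [
    "SpikeConfig",
    "APEvent",
    "detect_aps",
    "phase_plane_features",
    "ap_waveform_features",
    "extract_events",
    "rheobase",
    "rheobase_ap_summary",
    "latency_metrics",
    "fi_curve",
    "accommodation_profiles",
    "average_ap",
    "fall_vs_rise_regression",
]


class NoRheobaseError(ValueError):
    """No sweep in the recording fires an action potential."""


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class SpikeConfig:
    """Detection and measurement settings.

    peak_floor : mV — minimum peak height for a local maximum to count
        as an AP.
    refractory : ms — minimum separation between detected peaks.
    dvdt_criterion : mV/ms — phase-plane threshold criterion.
    ahp_window : ms — AHP search window after the peak (bounded by the
        next AP's threshold when that comes first).
    pre_peak_window : ms — how far before the peak the threshold search
        may extend; also the minimum pre-peak context required.
    """

    peak_floor: float = -20.0
    refractory: float = 1.0
    dvdt_criterion: float = 10.0
    ahp_window: float = 10.0
    pre_peak_window: float = 2.0


@dataclass
class APEvent:
    """One action potential's measurements (indices into the sweep)."""

    peak_index: int
    peak_voltage: float
    threshold_index: int | None = None
    threshold_voltage: float | None = None
    ahp_index: int | None = None
    ahp_voltage: float | None = None
    max_rise: float | None = None
    max_fall: float | None = None
    half_width: float | None = None  # microseconds

    @property
    def amplitude(self) -> float | None:
        """Overshoot-to-AHP amplitude, mV."""
        if self.ahp_voltage is None:
            return None
        return self.peak_voltage - self.ahp_voltage


def _dt_ms(sweep: SweepRecord) -> float:
    return sweep.time_step * 1000.0


def dvdt_trace(sweep: SweepRecord) -> np.ndarray:
    """dV/dt in mV/ms from centred differences (one-sided at the ends)."""
    return np.gradient(sweep.voltage, _dt_ms(sweep))


def detect_aps(sweep: SweepRecord, cfg: SpikeConfig = SpikeConfig()) -> list[APEvent]:
    """Detect AP peaks inside the step window.

    Local maxima above ``cfg.peak_floor`` separated by at least
    ``cfg.refractory``; an empty list is a valid result.
    """
    dt = _dt_ms(sweep)
    on, off = sweep.step_onset_index, sweep.step_offset_index
    seg = sweep.voltage[on:off]
    distance = max(1, int(round(cfg.refractory / dt)))
    peaks, _ = find_peaks(seg, height=cfg.peak_floor, distance=distance)
    return [APEvent(peak_index=int(on + p), peak_voltage=float(seg[p])) for p in peaks]


def phase_plane_features(
    sweep: SweepRecord,
    event: APEvent,
    cfg: SpikeConfig = SpikeConfig(),
    search_start: int | None = None,
) -> APEvent | None:
    """Fill in threshold from the phase-plane criterion.

    The threshold sample is the first sample of the final rise on which
    dV/dt reaches ``cfg.dvdt_criterion`` and stays above it up to the
    point of maximal rise.  Returns None (event rejected as spurious)
    when the criterion is never met before the peak.
    """
    dt = _dt_ms(sweep)
    v = sweep.voltage
    dvdt = dvdt_trace(sweep)
    pre = int(round(cfg.pre_peak_window / dt))
    if event.peak_index < pre:
        return None
    lo = event.peak_index - pre
    if search_start is not None:
        lo = max(lo, search_start)
    if lo >= event.peak_index:
        return None
    imax = lo + int(np.argmax(dvdt[lo : event.peak_index + 1]))
    if dvdt[imax] < cfg.dvdt_criterion:
        return None
    k = imax
    while k > lo and dvdt[k - 1] >= cfg.dvdt_criterion:
        k -= 1
    event.threshold_index = int(k)
    event.threshold_voltage = float(v[k])
    return event


def ap_waveform_features(
    sweep: SweepRecord,
    event: APEvent,
    cfg: SpikeConfig = SpikeConfig(),
    next_threshold_index: int | None = None,
) -> APEvent:
    """Complete the event with AHP, rates, amplitude and half-width.

    The AHP is the minimum between the peak and the earlier of the next
    AP's threshold and ``cfg.ahp_window`` after the peak.  Max rise/fall
    are the dV/dt extrema between threshold and AHP.  A truncated AP at
    the sweep end keeps its features missing.
    """
    if event.threshold_index is None:
        raise ValueError("threshold must be computed first (phase_plane_features)")
    dt = _dt_ms(sweep)
    v = sweep.voltage
    n = v.size
    end = event.peak_index + int(round(cfg.ahp_window / dt))
    if next_threshold_index is not None:
        end = min(end, next_threshold_index)
    if event.peak_index + max(2, int(round(0.05 / dt))) >= n:
        return event  # truncated: nothing after the peak to measure
    truncated = end > n - 1 and next_threshold_index is None
    end = min(end, n - 1)
    if truncated:
        warnings.warn("AHP window truncated at sweep end; features left missing")
        return event

    seg = v[event.peak_index : end + 1]
    ahp_rel = int(np.argmin(seg))
    event.ahp_index = int(event.peak_index + ahp_rel)
    event.ahp_voltage = float(seg[ahp_rel])

    dvdt = dvdt_trace(sweep)
    event.max_rise = float(np.max(dvdt[event.threshold_index : event.peak_index + 1]))
    event.max_fall = float(np.min(dvdt[event.peak_index : event.ahp_index + 1]))

    level = 0.5 * (event.peak_voltage + event.ahp_voltage)
    t_rise = _crossing_time(v, event.threshold_index, event.peak_index, level, dt, rising=True)
    t_fall = _crossing_time(v, event.peak_index, event.ahp_index, level, dt, rising=False)
    if t_rise is not None and t_fall is not None:
        event.half_width = (t_fall - t_rise) * 1000.0  # ms -> us
    return event


def _crossing_time(
    v: np.ndarray, i0: int, i1: int, level: float, dt: float, rising: bool
) -> float | None:
    """Sub-sample time (ms) of the level crossing nearest the peak."""
    seg = v[i0 : i1 + 1]
    if rising:
        below = np.nonzero(seg < level)[0]
        if below.size == 0 or below[-1] + 1 >= seg.size:
            return None
        j = below[-1]  # last sample below the level before the peak
        frac = (level - seg[j]) / (seg[j + 1] - seg[j])
    else:
        above = np.nonzero(seg >= level)[0]
        if above.size == 0:
            return None
        j = above[0]
        while j + 1 < seg.size and seg[j + 1] >= level:
            j += 1
        if j + 1 >= seg.size:
            return None
        frac = (seg[j] - level) / (seg[j] - seg[j + 1])
    return (i0 + j + frac) * dt


_EVENT_CACHE: "weakref.WeakKeyDictionary[SweepRecord, dict]" = None  # type: ignore[assignment]


def extract_events(sweep: SweepRecord, cfg: SpikeConfig = SpikeConfig()) -> list[APEvent]:
    """Detect and fully measure all APs of a sweep.

    Spurious peaks (phase-plane criterion never met) are dropped.  The
    AHP of each AP is bounded by the next AP's threshold.  Results are
    memoized per (sweep, config) since several per-cell measurements
    revisit the same sweeps.
    """
    global _EVENT_CACHE
    if _EVENT_CACHE is None:
        import weakref

        _EVENT_CACHE = weakref.WeakKeyDictionary()
    per_sweep = _EVENT_CACHE.setdefault(sweep, {})
    if cfg in per_sweep:
        return per_sweep[cfg]
    events = _extract_events_uncached(sweep, cfg)
    per_sweep[cfg] = events
    return events


def _extract_events_uncached(sweep: SweepRecord, cfg: SpikeConfig) -> list[APEvent]:
    events = detect_aps(sweep, cfg)
    kept: list[APEvent] = []
    prev_peak = None
    for ev in events:
        ev = phase_plane_features(sweep, ev, cfg, search_start=prev_peak)
        if ev is not None:
            kept.append(ev)
            prev_peak = ev.peak_index
    for i, ev in enumerate(kept):
        nxt = kept[i + 1].threshold_index if i + 1 < len(kept) else None
        ap_waveform_features(sweep, ev, cfg, next_threshold_index=nxt)
    return kept


def rheobase(
    rec: CellRecording,
    cin: float | None = None,
    cfg: SpikeConfig = SpikeConfig(),
) -> tuple[float, float | None]:
    """Smallest injected current whose sweep contains >= 1 AP.

    Returns (current pA, current density pA/pF or None without ``cin``).
    Raises NoRheobaseError when no sweep fires.
    """
    for sweep in rec.sweeps:
        if len(extract_events(sweep, cfg)) >= 1:
            dens = sweep.command_current / cin if cin else None
            return float(sweep.command_current), dens
    raise NoRheobaseError(f"cell {rec.cell_id}: no sweep fires")


def events_by_sweep(
    rec: CellRecording, cfg: SpikeConfig = SpikeConfig()
) -> list[tuple[SweepRecord, list[APEvent]]]:
    return [(s, extract_events(s, cfg)) for s in rec.sweeps]


def rheobase_ap_summary(
    rec: CellRecording,
    cfg: SpikeConfig = SpikeConfig(),
    n_aps: int = 3,
) -> dict:
    """Mean waveform features of the first APs at or just above rheobase.

    APs are pooled from the rheobase sweep first; if fewer than
    ``n_aps`` are available, the earliest APs of the next sweeps (in
    ascending current order) are added until ``n_aps`` are pooled.  Each
    feature is averaged over the pooled APs that carry it.
    """
    pooled: list[tuple[SweepRecord, APEvent]] = []
    pooling_order: list[float] = []
    started = False
    for sweep, events in events_by_sweep(rec, cfg):
        if not events:
            continue
        started = True
        for ev in events:
            if len(pooled) < n_aps:
                pooled.append((sweep, ev))
                pooling_order.append(sweep.command_current)
        if len(pooled) >= n_aps:
            break
    if not started or not pooled:
        raise NoRheobaseError(f"cell {rec.cell_id}: no usable APs")

    def _mean(attr):
        vals = [getattr(ev, attr) for _, ev in pooled]
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)) if vals else None

    return {
        "threshold_voltage": _mean("threshold_voltage"),
        "overshoot": _mean("peak_voltage"),
        "ahp": _mean("ahp_voltage"),
        "amplitude": _mean("amplitude"),
        "half_width": _mean("half_width"),
        "max_rise": _mean("max_rise"),
        "max_fall": _mean("max_fall"),
        "n_aps": len(pooled),
        "pooling_order": pooling_order,
        "events": pooled,
    }


def latency_metrics(
    rec: CellRecording, cfg: SpikeConfig = SpikeConfig()
) -> tuple[float, float | None]:
    """Latency (ms) from step onset to the first AP threshold crossing,
    at rheobase and at the protocol step nearest 2x rheobase (ties
    toward the larger step).  The second value is None when the nearest
    2x sweep does not fire."""
    per_sweep = events_by_sweep(rec, cfg)
    rheo_sweep = None
    for sweep, events in per_sweep:
        if events:
            rheo_sweep, rheo_events = sweep, events
            break
    if rheo_sweep is None:
        raise NoRheobaseError(f"cell {rec.cell_id}: no sweep fires")
    dt = _dt_ms(rheo_sweep)

    def _latency(sweep, events):
        ev = events[0]
        idx = ev.threshold_index if ev.threshold_index is not None else ev.peak_index
        return (idx - sweep.step_onset_index) * dt

    lat_rheo = _latency(rheo_sweep, rheo_events)

    target = 2.0 * rheo_sweep.command_current
    amps = np.array([s.command_current for s in rec.sweeps])
    dist = np.abs(amps - target)
    # ties toward the larger amplitude
    best = np.nonzero(dist == dist.min())[0][-1]
    sweep2, events2 = per_sweep[best]
    lat_2x = _latency(sweep2, events2) if events2 else None
    return lat_rheo, lat_2x


def fi_curve(
    rec: CellRecording,
    cin: float,
    cfg: SpikeConfig = SpikeConfig(),
) -> list[dict]:
    """Firing frequency against current density above rheobase.

    One record per suprathreshold sweep: frequency = AP count / step
    duration; the abscissa is the sweep's current density minus the
    rheobase density.  Mean instantaneous frequency (mean 1/ISI) is
    reported alongside.
    """
    rheo_pa, rheo_dens = rheobase(rec, cin, cfg)
    out = []
    for sweep, events in events_by_sweep(rec, cfg):
        if sweep.command_current < rheo_pa or not events:
            continue
        dur_s = (sweep.step_offset_index - sweep.step_onset_index) * sweep.time_step
        peaks_ms = np.array([ev.peak_index for ev in events]) * _dt_ms(sweep)
        isis = np.diff(peaks_ms)
        out.append(
            {
                "current_density_above_rheobase": sweep.command_current / cin - rheo_dens,
                "frequency": len(events) / dur_s,
                "mean_instantaneous_frequency": float(np.mean(1000.0 / isis))
                if isis.size
                else None,
                "n_aps": len(events),
            }
        )
    return out


def accommodation_profiles(
    rec: CellRecording,
    count_thresholds: tuple[int, ...] = (4, 22, 46),
    cfg: SpikeConfig = SpikeConfig(),
) -> dict[int, dict]:
    """Amplitude-accommodation and instantaneous-frequency profiles.

    For each count threshold, the lowest-current sweep with at least
    that many APs is selected; the profile holds the AP amplitudes as a
    fraction of the first AP's and the instantaneous frequencies 1/ISI.
    Thresholds with no qualifying sweep are absent from the result.
    """
    per_sweep = events_by_sweep(rec, cfg)
    out: dict[int, dict] = {}
    for thr in count_thresholds:
        for sweep, events in per_sweep:
            if len(events) >= thr:
                amps = np.array(
                    [ev.amplitude if ev.amplitude is not None else np.nan for ev in events]
                )
                peaks_ms = np.array([ev.peak_index for ev in events]) * _dt_ms(sweep)
                out[thr] = {
                    "current_pa": sweep.command_current,
                    "relative_amplitudes": amps / amps[0],
                    "instantaneous_frequencies": 1000.0 / np.diff(peaks_ms),
                }
                break
    return out


def average_ap(
    cells: list[CellRecording],
    cfg: SpikeConfig = SpikeConfig(),
    window: float = 4.0,
    pre_window: float = 1.0,
    n_aps: int = 3,
) -> dict:
    """Across-cell average AP aligned on threshold.

    For each cell the (up to) ``n_aps`` rheobase APs are averaged over
    [-pre_window, +window] ms around their threshold sample; the
    across-cell mean and SEM are computed pointwise.  Voltages are
    junction-corrected.  Cells whose windows run past the sweep edges
    contribute a truncated window and set the ``truncated`` flag.
    """
    if not cells:
        raise InsufficientDataError("no cells")
    dt = _dt_ms(cells[0].sweeps[0])
    n_pre = int(round(pre_window / dt))
    n_post = int(round(window / dt))
    t = (np.arange(-n_pre, n_post + 1)) * dt
    cell_means = []
    truncated = False
    for rec in cells:
        try:
            summ = rheobase_ap_summary(rec, cfg, n_aps=n_aps)
        except NoRheobaseError:
            continue
        wins = []
        for sweep, ev in summ["events"]:
            if ev.threshold_index is None:
                continue
            lo = ev.threshold_index - n_pre
            hi = ev.threshold_index + n_post + 1
            if lo < 0 or hi > sweep.voltage.size:
                truncated = True
                continue
            wins.append(sweep.voltage[lo:hi] - rec.junction_potential)
        if wins:
            cell_means.append(np.mean(wins, axis=0))
    if not cell_means:
        raise InsufficientDataError("no usable APs in any cell")
    arr = np.array(cell_means)
    mean = arr.mean(axis=0)
    sem = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0]) if arr.shape[0] > 1 else np.zeros_like(mean)
    return {"time_ms": t, "mean": mean, "sem": sem, "n_cells": arr.shape[0], "truncated": truncated}


def fall_vs_rise_regression(rows) -> dict[str, dict]:
    """Per-genotype OLS of max rate of fall on max rate of rise.

    ``rows``: iterable of mappings with keys ``genotype``, ``max_rise``,
    ``max_fall``.  Raises InsufficientDataError for a genotype with
    fewer than 2 points.
    """
    groups: dict[str, list[tuple[float, float]]] = {}
    for r in rows:
        if r.get("max_rise") is None or r.get("max_fall") is None:
            continue
        groups.setdefault(r["genotype"], []).append((r["max_rise"], r["max_fall"]))
    out = {}
    for g, pts in groups.items():
        if len(pts) < 2:
            raise InsufficientDataError(f"genotype {g}: need >= 2 cells for regression")
        x, y = np.array(pts).T
        res = linregress(x, y)
        out[g] = {
            "slope": float(res.slope),
            "intercept": float(res.intercept),
            "r_value": float(res.rvalue),
            "n": len(pts),
        }
    return out
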