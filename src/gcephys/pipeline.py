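"""End-to-end pipeline: simulate -> extract -> compare.

Stages are file-based and pure functions of their inputs plus the
configuration, so re-running a stage on unchanged inputs reproduces its
outputs exactly.  Layout under the output directory:

.. code-block:: text

    out/
      cells/      <cell_id>.cellset.tsv, <cell_id>.transient.tsv
      features/   features.tsv
      curves/     vi_grid_<genotype>.tsv, rin_<genotype>.tsv,
                  fi_<genotype>.tsv, avg_ap_<genotype>.tsv,
                  accommodation_<genotype>_min<N>.tsv
      report/     report.json, report.tsv
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import trace_io
from .params import CellRecording, GCModelParams, PopulationSpec, StepProtocol, ts_params, wt_params
from .passive import (
    PassiveConfig,
    FitError,
    cin_from_transient,
    fit_cin_exponential,
    fit_sigmoid_vi,
    grid_average,
    resting_potential,
    rin_curve,
    steady_state_vi,
)
from .simulate import sample_population, simulate_cap_transient, draw_cell_params
from .spikes import (
    NoRheobaseError,
    SpikeConfig,
    accommodation_profiles,
    average_ap,
    fall_vs_rise_regression,
    fi_curve,
    latency_metrics,
    rheobase,
    rheobase_ap_summary,
)
from .stats import mixed_anova_vi, two_group_compare

log = logging.getLogger("gcephys")

__all__ = ["PipelineConfig", "run_pipeline", "extract_cell", "simulate_stage", "extract_stage", "compare_stage"]

# feature column -> (unit, lower-is-missing marker) used in reports
FEATURE_UNITS = {
    "resting_mv": "mV",
    "cin_exp_pf": "pF",
    "cin_transient_pf": "pF",
    "tau_ms": "ms",
    "r_step_gohm": "GOhm",
    "rheobase_pa": "pA",
    "rheobase_pa_per_pf": "pA/pF",
    "vthresh_mv": "mV",
    "overshoot_mv": "mV",
    "ahp_mv": "mV",
    "amplitude_mv": "mV",
    "half_width_us": "us",
    "max_rise_mv_per_ms": "mV/ms",
    "max_fall_mv_per_ms": "mV/ms",
    "latency_rheobase_ms": "ms",
    "latency_2x_ms": "ms",
}


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full run needs; deterministic given the seed."""

    wt_params: GCModelParams = field(default_factory=wt_params)
    ts_params: GCModelParams = field(default_factory=ts_params)
    n_wt: int = 20
    n_ts: int = 20
    genotype_labels: tuple[str, str] = ("WT", "TS")
    protocol: StepProtocol = field(default_factory=StepProtocol)
    junction_potential: float = 8.8
    passive: PassiveConfig = field(default_factory=PassiveConfig)
    spikes: SpikeConfig = field(default_factory=SpikeConfig)
    grid_spacing: float = 0.5  # pA/pF
    min_n_grid: int = 3
    anova_coverage: float = 0.7  # fraction of cells a level must reach
    alpha: float = 0.05
    gate_alpha: float = 0.05
    seed: int = 0
    transient_step_mv: float = 5.0
    transient_series_mohm: float = 10.0

    def __post_init__(self):
        if self.n_wt < 1 or self.n_ts < 1:
            raise ValueError("population sizes must be >= 1 (zero cells configured)")


def population_specs(cfg: PipelineConfig) -> tuple[PopulationSpec, PopulationSpec]:
    wt = PopulationSpec(
        mean_params=cfg.wt_params,
        n_cells=cfg.n_wt,
        genotype_label=cfg.genotype_labels[0],
        seed=cfg.seed * 2 + 1,
    )
    ts = PopulationSpec(
        mean_params=cfg.ts_params,
        n_cells=cfg.n_ts,
        genotype_label=cfg.genotype_labels[1],
        seed=cfg.seed * 2 + 2,
    )
    return wt, ts


def simulate_stage(cfg: PipelineConfig, out_dir: Path) -> list[CellRecording]:
    """Simulate both populations and write cell sets plus voltage-clamp
    capacitive transients."""
    cells_dir = Path(out_dir) / "cells"
    cells_dir.mkdir(parents=True, exist_ok=True)
    recordings: list[CellRecording] = []
    for spec in population_specs(cfg):
        recs = sample_population(spec, cfg.protocol, cfg.junction_potential)
        for idx, rec in enumerate(recs):
            trace_io.write_cellset(rec, cells_dir / f"{rec.cell_id}.cellset.tsv")
            p = draw_cell_params(spec, idx)
            tr = simulate_cap_transient(
                p, cfg.transient_step_mv, cfg.transient_series_mohm
            )
            trace_io.write_series(
                {"time_s": tr.times, "current_pa": tr.current},
                cells_dir / f"{rec.cell_id}.transient.tsv",
            )
        recordings.extend(recs)
    log.info("simulated %d cells", len(recordings))
    return recordings


def extract_cell(
    rec: CellRecording,
    cfg: PipelineConfig,
    transient=None,
) -> dict:
    """One cell's complete feature row (voltages junction-corrected)."""
    row: dict = {"cell_id": rec.cell_id, "genotype": rec.genotype}
    jp = rec.junction_potential
    row["resting_mv"] = resting_potential(rec, cfg.passive)
    try:
        ps = fit_cin_exponential(rec, cfg.passive, cfg.spikes)
        row["cin_exp_pf"] = ps.cin_exp_fit
        row["tau_ms"] = ps.tau_m
        row["r_step_gohm"] = ps.r_step
    except (ValueError, FitError) as err:
        log.warning("cell %s: capacitance fit failed (%s)", rec.cell_id, err)
        ps = None
    if transient is not None:
        row["cin_transient_pf"] = cin_from_transient(transient)
    cin = row.get("cin_exp_pf")
    try:
        rheo_pa, rheo_dens = rheobase(rec, cin, cfg.spikes)
        row["rheobase_pa"] = rheo_pa
        row["rheobase_pa_per_pf"] = rheo_dens
        summ = rheobase_ap_summary(rec, cfg.spikes)
        row["vthresh_mv"] = _corr(summ["threshold_voltage"], jp)
        row["overshoot_mv"] = _corr(summ["overshoot"], jp)
        row["ahp_mv"] = _corr(summ["ahp"], jp)
        row["amplitude_mv"] = summ["amplitude"]
        row["half_width_us"] = summ["half_width"]
        row["max_rise_mv_per_ms"] = summ["max_rise"]
        row["max_fall_mv_per_ms"] = summ["max_fall"]
        row["n_aps_pooled"] = summ["n_aps"]
        lat, lat2 = latency_metrics(rec, cfg.spikes)
        row["latency_rheobase_ms"] = lat
        row["latency_2x_ms"] = lat2
    except NoRheobaseError:
        log.warning("cell %s: no rheobase (no sweep fires)", rec.cell_id)
    return row


def _corr(v: float | None, jp: float) -> float | None:
    return None if v is None else v - jp


def load_cells(cells_dir: Path) -> list[CellRecording]:
    files = sorted(Path(cells_dir).glob("*.cellset.tsv"))
    if not files:
        raise FileNotFoundError(f"no cell-set files in {cells_dir}")
    return [trace_io.read_cellset(f) for f in files]


def extract_stage(
    cfg: PipelineConfig, out_dir: Path, recordings: list[CellRecording] | None = None
) -> pd.DataFrame:
    """Per-cell feature extraction plus per-genotype curve files."""
    out_dir = Path(out_dir)
    cells_dir = out_dir / "cells"
    feat_dir = out_dir / "features"
    curves_dir = out_dir / "curves"
    feat_dir.mkdir(parents=True, exist_ok=True)
    curves_dir.mkdir(parents=True, exist_ok=True)
    if recordings is None:
        recordings = load_cells(cells_dir)
    # canonical order = file order, so in-memory and re-loaded runs agree
    recordings = sorted(recordings, key=lambda r: r.cell_id)

    rows = []
    density_curves: dict[str, list] = {}
    fi_rows: dict[str, list] = {}
    for rec in recordings:
        tr_path = cells_dir / f"{rec.cell_id}.transient.tsv"
        transient = None
        if tr_path.exists():
            t = pd.read_csv(tr_path, sep="\t")
            from .params import CurrentTransient

            transient = CurrentTransient(
                time_step=float(t.time_s.iloc[1] - t.time_s.iloc[0]),
                current=t.current_pa.to_numpy(),
                voltage_step=cfg.transient_step_mv,
                series_resistance=cfg.transient_series_mohm,
            )
        row = extract_cell(rec, cfg, transient)
        rows.append(row)
        cin = row.get("cin_exp_pf")
        if cin:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                curve = steady_state_vi(rec, cin, cfg.passive, cfg.spikes)
            if curve.usable_for_fit:
                density_curves.setdefault(rec.genotype, []).append(curve)
            if row.get("rheobase_pa") is not None:
                fi_rows.setdefault(rec.genotype, []).extend(
                    dict(pt, cell_id=rec.cell_id) for pt in fi_curve(rec, cin, cfg.spikes)
                )

    table = pd.DataFrame(rows)
    trace_io.write_feature_table(table, feat_dir / "features.tsv")

    by_geno: dict[str, list[CellRecording]] = {}
    for rec in recordings:
        by_geno.setdefault(rec.genotype, []).append(rec)

    for geno, curves in density_curves.items():
        grid = grid_average(curves, cfg.grid_spacing, cfg.min_n_grid)
        trace_io.write_series(
            {
                "current_density_pa_per_pf": grid.grid,
                "mean_voltage_mv": grid.mean_voltage,
                "sem_voltage_mv": grid.sem_voltage,
                "n_cells": grid.n_per_point,
            },
            curves_dir / f"vi_grid_{geno}.tsv",
        )
        # input resistance from the sigmoid fit of the group-mean curve
        from .passive import VICurve

        mean_curve = VICurve(grid.grid, grid.mean_voltage, density=True, cell_id=f"mean_{geno}")
        try:
            fit = fit_sigmoid_vi(mean_curve)
            v_fit, r_fit = rin_curve(fit)
            trace_io.write_series(
                {"membrane_potential_mv": v_fit, "specific_resistance_gohm_pf": r_fit},
                curves_dir / f"rin_{geno}.tsv",
            )
        except (ValueError, RuntimeError) as err:
            log.warning("%s: sigmoid fit of mean V-I failed (%s)", geno, err)

    for geno, pts in fi_rows.items():
        df = pd.DataFrame(pts)
        trace_io.write_series(
            {c: df[c].to_numpy() for c in df.columns if c != "cell_id"},
            curves_dir / f"fi_{geno}.tsv",
        )

    for geno, recs in by_geno.items():
        try:
            avg = average_ap(recs, cfg.spikes)
            trace_io.write_series(
                {
                    "time_ms": avg["time_ms"],
                    "mean_mv": avg["mean"],
                    "sem_mv": avg["sem"],
                },
                curves_dir / f"avg_ap_{geno}.tsv",
            )
        except ValueError as err:
            log.warning("%s: average AP unavailable (%s)", geno, err)
        for thr_count, prof in _pooled_accommodation(recs, cfg).items():
            trace_io.write_series(prof, curves_dir / f"accommodation_{geno}_min{thr_count}.tsv")
    return table


def _pooled_accommodation(recs: list[CellRecording], cfg: PipelineConfig) -> dict[int, dict]:
    """Across cells: mean relative amplitude and instantaneous frequency
    per AP number, for each count threshold."""
    out: dict[int, dict] = {}
    for thr in (4, 22, 46):
        rel_amp: list[np.ndarray] = []
        inst_f: list[np.ndarray] = []
        for rec in recs:
            prof = accommodation_profiles(rec, (thr,), cfg.spikes).get(thr)
            if prof is None:
                continue
            rel_amp.append(prof["relative_amplitudes"][:thr])
            inst_f.append(prof["instantaneous_frequencies"][: thr - 1])
        if not rel_amp:
            continue
        n = min(len(a) for a in rel_amp)
        ra = np.vstack([a[:n] for a in rel_amp])
        fi = np.vstack([f[: n - 1] for f in inst_f])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[thr] = {
                "ap_number": np.arange(1, n + 1),
                "mean_relative_amplitude": np.nanmean(ra, axis=0),
                "sem_relative_amplitude": np.nanstd(ra, axis=0, ddof=1) / np.sqrt(ra.shape[0]),
                "mean_instantaneous_frequency_hz": np.concatenate(
                    [[np.nan], np.nanmean(fi, axis=0)]
                ),
                "n_cells": np.full(n, ra.shape[0]),
            }
    return out


def compare_stage(cfg: PipelineConfig, out_dir: Path, table: pd.DataFrame | None = None) -> dict:
    """Two-genotype statistics over the feature table and V-I curves."""
    out_dir = Path(out_dir)
    report_dir = out_dir / "report"
    report_dir.mkdir(parents=True, exist_ok=True)
    if table is None:
        table = trace_io.read_feature_table(out_dir / "features" / "features.tsv")
    g_a, g_b = cfg.genotype_labels
    a_rows = table[table.genotype == g_a]
    b_rows = table[table.genotype == g_b]

    features_report = []
    for col, unit in FEATURE_UNITS.items():
        if col not in table.columns:
            continue
        a = a_rows[col].dropna().to_numpy(dtype=float)
        b = b_rows[col].dropna().to_numpy(dtype=float)
        if a.size < 3 or b.size < 3:
            continue
        res = two_group_compare(a, b, cfg.gate_alpha, feature=col, unit=unit)
        features_report.append(res.as_dict())

    # mixed ANOVA over per-cell density V-I curves on the shared grid
    anova_dict = None
    try:
        curves = {g_a: [], g_b: []}
        recordings = load_cells(out_dir / "cells")
        cin_by_cell = table.set_index("cell_id")["cin_exp_pf"].to_dict()
        for rec in recordings:
            cin = cin_by_cell.get(rec.cell_id)
            if not cin or not np.isfinite(cin):
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                c = steady_state_vi(rec, cin, cfg.passive, cfg.spikes)
            k0 = int(np.ceil(c.currents.min() / cfg.grid_spacing - 1e-9))
            k1 = int(np.floor(c.currents.max() / cfg.grid_spacing + 1e-9))
            lv = np.arange(k0, k1 + 1) * cfg.grid_spacing
            if lv.size and rec.genotype in curves:
                curves[rec.genotype].append((lv, np.interp(lv, c.currents, c.voltages)))
        levels = _covered_levels(curves[g_a] + curves[g_b], cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            anova = mixed_anova_vi(
                curves[g_a], curves[g_b], levels=levels, group_labels=(g_a, g_b)
            )
        anova_dict = anova.as_dict()
    except (ValueError, FileNotFoundError) as err:
        log.warning("V-I mixed ANOVA unavailable: %s", err)

    regression = None
    try:
        regression = fall_vs_rise_regression(
            table.rename(
                columns={"max_rise_mv_per_ms": "max_rise", "max_fall_mv_per_ms": "max_fall"}
            )
            .replace({np.nan: None})
            .to_dict("records")
        )
    except ValueError as err:
        log.warning("fall-vs-rise regression unavailable: %s", err)

    report = {
        "genotypes": [g_a, g_b],
        "n_cells": [int(len(a_rows)), int(len(b_rows))],
        "alpha": cfg.alpha,
        "gate_alpha": cfg.gate_alpha,
        "dvdt_criterion_mv_per_ms": cfg.spikes.dvdt_criterion,
        "features": features_report,
        "vi_mixed_anova": anova_dict,
        "fall_vs_rise_regression": regression,
    }
    trace_io.write_json_report(report, report_dir / "report.json")
    flat = pd.DataFrame(features_report)
    if not flat.empty:
        flat["n_a"] = [n[0] for n in flat.pop("n")]
        flat.to_csv(report_dir / "report.tsv", sep="\t", index=False, na_rep="NA")
    return report


def _covered_levels(curves, cfg: PipelineConfig) -> np.ndarray:
    """Grid levels covered by at least ``anova_coverage`` of the cells."""
    if not curves:
        raise ValueError("no usable V-I curves")
    counts: dict[float, int] = {}
    for lv, _ in curves:
        for l in np.round(lv, 9):
            counts[l] = counts.get(l, 0) + 1
    need = int(np.ceil(cfg.anova_coverage * len(curves)))
    levels = sorted(l for l, c in counts.items() if c >= need)
    if not levels:
        raise ValueError("no level reaches the coverage fraction")
    return np.array(levels)


def run_pipeline(cfg: PipelineConfig, out_dir) -> dict:
    """simulate -> extract -> compare, with stage timings logged."""
    out_dir = Path(out_dir)
    t0 = time.time()
    simulate_stage(cfg, out_dir)
    t1 = time.time()
    log.info("simulate stage: %.1f s", t1 - t0)
    # extraction reads the written files so every stage is a pure
    # function of its input files plus the config
    table = extract_stage(cfg, out_dir)
    t2 = time.time()
    log.info("extract stage: %.1f s", t2 - t1)
    report = compare_stage(cfg, out_dir, table)
    log.info("compare stage: %.1f s", time.time() - t2)
    return report
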