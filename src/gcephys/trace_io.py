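"""Plain-text file formats for sweep sets, feature tables and reports.

A *cell-set* file carries one cell's complete sweep family:

.. code-block:: text

    # cell_id=WT_000
    # genotype=WT
    # sampling_rate_hz=62500
    # step_onset_s=0.1
    # step_duration_s=0.5
    # junction_potential_mv=8.8
    # step_amplitudes_pa=-10,-8,-6
    0	-71.2	-71.2	-71.2
    1.6e-05	-71.21	-71.2	-71.19
    ...

Header lines are ``# key=value``; the body is tab-delimited with time
(seconds) in the first column and one voltage column (mV, as recorded,
junction-uncorrected) per sweep.  Values are written with 9 significant
digits, so a write -> read -> write cycle is byte-identical.

Feature tables and curve files are tab-delimited text with a header row;
missing values use the ``NA`` token.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .params import CellRecording, SweepRecord

__all__ = [
    "write_cellset",
    "read_cellset",
    "write_feature_table",
    "read_feature_table",
    "write_series",
    "MissingMetadataError",
    "InconsistentSweepCountError",
    "NonUniformTimeError",
]

NA = "NA"
_FLOAT_FMT = "%.9g"

_MANDATORY_KEYS = (
    "cell_id",
    "genotype",
    "sampling_rate_hz",
    "step_onset_s",
    "step_duration_s",
    "junction_potential_mv",
    "step_amplitudes_pa",
)


class CellSetFormatError(ValueError):
    """Base class for malformed cell-set files."""


class MissingMetadataError(CellSetFormatError):
    pass


class InconsistentSweepCountError(CellSetFormatError):
    pass


class NonUniformTimeError(CellSetFormatError):
    pass


def write_cellset(rec: CellRecording, path) -> None:
    """Serialize a recording; lossless at 9 significant digits."""
    path = Path(path)
    first = rec.sweeps[0]
    onset_s = first.step_onset_index * first.time_step
    duration_s = (first.step_offset_index - first.step_onset_index) * first.time_step
    amps = ",".join(_FLOAT_FMT % s.command_current for s in rec.sweeps)
    header = [
        f"# cell_id={rec.cell_id}",
        f"# genotype={rec.genotype}",
        f"# sampling_rate_hz={_FLOAT_FMT % rec.sampling_rate}",
        f"# step_onset_s={_FLOAT_FMT % onset_s}",
        f"# step_duration_s={_FLOAT_FMT % duration_s}",
        f"# junction_potential_mv={_FLOAT_FMT % rec.junction_potential}",
        f"# step_amplitudes_pa={amps}",
    ]
    t = first.times
    body = np.column_stack([t] + [s.voltage for s in rec.sweeps])
    with path.open("w") as fh:
        fh.write("\n".join(header) + "\n")
        np.savetxt(fh, body, fmt=_FLOAT_FMT, delimiter="\t")


def read_cellset(path) -> CellRecording:
    """Parse a cell-set file back into a CellRecording.

    Raises MissingMetadataError, InconsistentSweepCountError or
    NonUniformTimeError for the corresponding defects.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    n_header = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            key, _, value = line.rstrip("\n").lstrip("# ").partition("=")
            meta[key.strip()] = value.strip()
    missing = [k for k in _MANDATORY_KEYS if k not in meta]
    if missing:
        raise MissingMetadataError(f"{path}: missing metadata {missing}")

    amps = [float(a) for a in meta["step_amplitudes_pa"].split(",")]
    try:
        data = pd.read_csv(
            path, sep="\t", skiprows=n_header, header=None, dtype=float
        ).to_numpy()
    except (ValueError, pd.errors.ParserError) as err:
        raise CellSetFormatError(f"{path}: malformed body ({err})") from err
    if data.ndim != 2 or data.shape[1] != 1 + len(amps):
        raise InconsistentSweepCountError(
            f"{path}: {data.shape[1] - 1} sweep columns but "
            f"{len(amps)} step amplitudes declared"
        )
    t = data[:, 0]
    dt = np.diff(t)
    dt0 = dt[0]
    if dt0 <= 0 or np.any(np.abs(dt - dt0) > 1e-6 * dt0):
        raise NonUniformTimeError(f"{path}: time base not uniform within 1 ppm")

    fs = float(meta["sampling_rate_hz"])
    time_step = 1.0 / fs
    onset = int(round(float(meta["step_onset_s"]) * fs))
    offset = onset + int(round(float(meta["step_duration_s"]) * fs))
    sweeps = [
        SweepRecord(
            time_step=time_step,
            voltage=data[:, 1 + j],
            command_current=amps[j],
            step_onset_index=onset,
            step_offset_index=offset,
        )
        for j in range(len(amps))
    ]
    return CellRecording(
        cell_id=meta["cell_id"],
        genotype=meta["genotype"],
        sweeps=sweeps,
        sampling_rate=fs,
        junction_potential=float(meta["junction_potential_mv"]),
    )


def write_feature_table(rows, path) -> None:
    """Write per-cell feature rows as tab-delimited text.

    ``rows`` is a list of mappings (or a DataFrame) with one row per
    cell; duplicate cell ids are rejected; missing features become NA.
    """
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no rows to write")
    if "cell_id" in df.columns and df["cell_id"].duplicated().any():
        dups = df.loc[df["cell_id"].duplicated(), "cell_id"].tolist()
        raise ValueError(f"duplicate cell_id values: {dups}")
    df.to_csv(path, sep="\t", index=False, na_rep=NA, float_format=_FLOAT_FMT)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)


def write_series(columns: dict[str, np.ndarray], path) -> None:
    """Write aligned named series (grids, means, SEMs...) as TSV."""
    pd.DataFrame(columns).to_csv(path, sep="\t", index=False, na_rep=NA, float_format=_FLOAT_FMT)


def write_json_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
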