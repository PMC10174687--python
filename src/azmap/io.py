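"""Readers and writers for event tables and trace stores.

Event tables are delimited text (CSV or TSV, auto-detected by extension)
with a header row.  Traces are stored either as a wide CSV
(``event_id, detection_index, baseline_frames, v0, v1, ...``) or as an HDF5
file with one dataset per event id and a ``frame_ms`` attribute.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .config import AcquisitionConfig
from .errors import (
    EmptyInputError,
    FormatError,
    OrphanTraceError,
    RowParseError,
    SchemaError,
)
from .model import MANDATORY_COLUMNS, Dataset, FluorescenceTrace, event_time_ms


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def load_events(path: str | Path, config: AcquisitionConfig) -> Dataset:
    """Read an event table and return a validated :class:`Dataset`.

    The table must name at least ``bouton_id, x_nm, y_nm, stim_index,
    frame_offset``; unknown columns are preserved.  ``time_ms`` is derived
    from the stimulus index and frame offset under the frame-start
    convention.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"bouton_id": str})
    if len(df) == 0:
        raise EmptyInputError(f"{path} contains no events")
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path} missing mandatory column(s): {missing}")
    for col in ("x_nm", "y_nm"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is row 1
            raise RowParseError(f"{path}: non-numeric {col} at file row {row}")
        df[col] = coerced
    for col in ("stim_index", "frame_offset"):
        try:
            df[col] = df[col].astype(int)
        except (TypeError, ValueError) as exc:
            raise RowParseError(f"{path}: non-integer {col}: {exc}") from None
    if "event_id" in df.columns:
        df["event_id"] = df["event_id"].astype(str)
    df["time_ms"] = event_time_ms(df["stim_index"], df["frame_offset"], config)
    return Dataset(config=config, events=df)


def write_events(dataset: Dataset, path: str | Path) -> None:
    """Write the event table as delimited text (separator by extension)."""
    path = Path(path)
    dataset.events.to_csv(path, sep=_sep_for(path), index=False)


def load_traces(path: str | Path, dataset: Dataset) -> Dataset:
    """Attach traces from a wide CSV or an HDF5 store to *dataset*.

    Events without traces remain usable for purely spatial operations.
    A trace whose event id is absent from the event table is an error.
    """
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        traces = _read_traces_h5(path, dataset.config)
    else:
        traces = _read_traces_csv(path, dataset.config)
    known = set(dataset.events["event_id"])
    orphans = [eid for eid in traces if eid not in known]
    if orphans:
        raise OrphanTraceError(f"traces without matching events: {orphans[:5]}")
    dataset.traces.update(traces)
    return dataset


def _read_traces_csv(path: Path, config: AcquisitionConfig) -> dict[str, FluorescenceTrace]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
        if header[:3] != ["event_id", "detection_index", "baseline_frames"]:
            raise FormatError(
                f"{path}: expected header event_id,detection_index,baseline_frames,v0,..."
            )
        width = len(header)
        traces: dict[str, FluorescenceTrace] = {}
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(",")
            # trailing empty cells pad shorter traces in a wide CSV
            vals = [p for p in parts[3:] if p != ""]
            if len(parts) != width:
                raise FormatError(f"{path}: ragged row at line {lineno}")
            traces[parts[0]] = FluorescenceTrace(
                event_id=parts[0],
                frame_ms=config.frame_ms,
                values=np.array([float(v) for v in vals]),
                detection_index=int(parts[1]),
                baseline_frames=int(parts[2]),
            )
    if not traces:
        raise EmptyInputError(f"{path} contains no traces")
    return traces


def write_traces_csv(traces: dict[str, FluorescenceTrace], path: str | Path) -> None:
    """Write traces as a wide CSV, padding short rows with empty cells."""
    path = Path(path)
    if not traces:
        raise EmptyInputError("no traces to write")
    n_max = max(len(t.values) for t in traces.values())
    with open(path, "w") as fh:
        cols = ",".join(f"v{i}" for i in range(n_max))
        fh.write(f"event_id,detection_index,baseline_frames,{cols}\n")
        for eid in sorted(traces):
            t = traces[eid]
            vals = [repr(float(v)) for v in t.values] + [""] * (n_max - len(t.values))
            fh.write(f"{eid},{t.detection_index},{t.baseline_frames},{','.join(vals)}\n")


def _read_traces_h5(path: Path, config: AcquisitionConfig) -> dict[str, FluorescenceTrace]:
    traces: dict[str, FluorescenceTrace] = {}
    with h5py.File(path, "r") as fh:
        for eid in fh:
            ds = fh[eid]
            traces[str(eid)] = FluorescenceTrace(
                event_id=str(eid),
                frame_ms=float(ds.attrs.get("frame_ms", config.frame_ms)),
                values=np.asarray(ds[()], dtype=float),
                detection_index=int(ds.attrs["detection_index"]),
                baseline_frames=int(ds.attrs["baseline_frames"]),
            )
    if not traces:
        raise EmptyInputError(f"{path} contains no traces")
    return traces


def write_traces_h5(traces: dict[str, FluorescenceTrace], path: str | Path) -> None:
    """Write traces to HDF5, one dataset per event id."""
    if not traces:
        raise EmptyInputError("no traces to write")
    with h5py.File(path, "w") as fh:
        for eid, t in traces.items():
            ds = fh.create_dataset(eid, data=t.values)
            ds.attrs["frame_ms"] = t.frame_ms
            ds.attrs["detection_index"] = t.detection_index
            ds.attrs["baseline_frames"] = t.baseline_frames
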