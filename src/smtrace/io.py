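"""Table and image-stack readers/writers with strict schema validation.

Traces travel as delimiter-separated tables (UTF-8, header row mandatory):
``trace_id, frame, time_s, intensity`` for single-channel traces and
``trace_id, frame, time_s, donor, acceptor`` for FRET pairs.  Ground truth
is a sidecar event table plus a ``key=value`` parameter manifest embedding
the seed.  Movies are multi-frame 16-bit grayscale TIFF stacks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import tifffile

from smtrace.errors import SchemaError
from smtrace.imaging import MovieStack, ROI
from smtrace.traces import FluorescenceTrace, FretTrace

TRACE_COLUMNS = ("trace_id", "frame", "time_s", "intensity")
FRET_COLUMNS = ("trace_id", "frame", "time_s", "donor", "acceptor")
ROI_COLUMNS = ("trace_id", "row", "col")
EVENT_COLUMNS = ("trace_id", "event_time_s", "event_kind", "site_index")


def _read_table(path, columns, delimiter="\t"):
    try:
        frame = pd.read_csv(path, sep=delimiter)
    except Exception as exc:
        raise SchemaError(f"cannot parse table: {exc}", path=path) from exc
    for col in columns:
        if col not in frame.columns:
            raise SchemaError("missing required column", path=path, column=col)
    numeric = [c for c in columns if c != "trace_id" and c != "event_kind"]
    for col in numeric:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # 1-based, plus header row
            raise SchemaError("non-numeric value", path=path, line=line,
                              column=col)
        frame[col] = coerced
    return frame


def write_trace_table(traces, path, delimiter="\t"):
    rows = []
    for t in traces:
        rows.append(pd.DataFrame({
            "trace_id": t.trace_id,
            "frame": np.arange(t.n_frames),
            "time_s": t.time,
            "intensity": t.intensity,
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, sep=delimiter, index=False)


def read_trace_table(path, delimiter="\t"):
    frame = _read_table(path, TRACE_COLUMNS, delimiter)
    traces = []
    for trace_id, group in frame.groupby("trace_id", sort=False):
        group = group.sort_values("frame")
        time = group["time_s"].to_numpy(dtype=float)
        dt = float(np.median(np.diff(time))) if time.size > 1 else 0.1
        traces.append(FluorescenceTrace(
            trace_id=str(trace_id), time=time,
            intensity=group["intensity"].to_numpy(dtype=float),
            frame_interval=dt,
        ))
    return traces


def write_fret_table(traces, path, delimiter="\t"):
    rows = []
    for t in traces:
        rows.append(pd.DataFrame({
            "trace_id": t.trace_id,
            "frame": np.arange(t.n_frames),
            "time_s": t.time,
            "donor": t.donor,
            "acceptor": t.acceptor,
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, sep=delimiter, index=False)


def read_fret_table(path, delimiter="\t", check_frames=15):
    frame = _read_table(path, FRET_COLUMNS, delimiter)
    traces = []
    for trace_id, group in frame.groupby("trace_id", sort=False):
        group = group.sort_values("frame")
        time = group["time_s"].to_numpy(dtype=float)
        dt = float(np.median(np.diff(time))) if time.size > 1 else 0.1
        traces.append(FretTrace(
            trace_id=str(trace_id), time=time,
            donor=group["donor"].to_numpy(dtype=float),
            acceptor=group["acceptor"].to_numpy(dtype=float),
            check_frames=check_frames, frame_interval=dt,
        ))
    return traces


def write_roi_table(rois, path, delimiter="\t"):
    pd.DataFrame({
        "trace_id": [r.trace_id for r in rois],
        "row": [r.row for r in rois],
        "col": [r.col for r in rois],
    }).to_csv(path, sep=delimiter, index=False)


def read_roi_table(path, delimiter="\t"):
    frame = _read_table(path, ROI_COLUMNS, delimiter)
    return [ROI(row=int(r.row), col=int(r.col), trace_id=str(r.trace_id))
            for r in frame.itertuples()]


def write_ground_truth(truths, path, manifest_path=None, delimiter="\t"):
    """Event sidecar table plus an optional key=value parameter manifest."""
    rows = []
    for trace_id, truth in truths.items():
        for time, kind, site in truth.events:
            rows.append((trace_id, time, kind, site))
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(
        path, sep=delimiter, index=False
    )
    if manifest_path is not None:
        params = {}
        for trace_id, truth in truths.items():
            for key, value in truth.params.items():
                params.setdefault(key, value)
        write_results(params, manifest_path)


def write_results(mapping, path):
    """Flat key=value result/manifest file."""
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in mapping.items():
            fh.write(f"{key}={value}\n")


def read_results(path):
    out = {}
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise SchemaError("expected key=value", path=path, line=i)
            key, value = line.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def write_stack(stack: MovieStack, path):
    """Write a movie as a multi-frame 16-bit grayscale TIFF."""
    data = np.clip(np.rint(stack.data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")


def read_stack(path, pixel_size=0.1, frame_interval=0.1, channel="eGFP"):
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return MovieStack(data=data, pixel_size=pixel_size,
                      frame_interval=frame_interval, channel=channel)
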