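"""Text I/O for traces and event logs.

Trace files are tab-delimited UTF-8 with "." decimals and a "#"-prefixed
header block carrying the metadata as ``# key: <json>`` lines, followed by a
column-name line and the five sample columns (time_s, extension_nm,
force_pN, torque_pNnm, device_turns).  Event logs are structured text, one
typed record per line; the ground-truth fork trajectory is stored as 1 Hz
checkpoints (events are lossless, the trajectory is decimated).
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np

from .simulate import EventLog, TraceRecord

__all__ = ["TraceParseError", "write_trace", "read_trace", "write_event_log", "read_event_log"]

_COLUMNS = ("time_s", "extension_nm", "force_pN", "torque_pNnm", "device_turns")


class TraceParseError(ValueError):
    """Malformed trace or event-log file."""


def write_trace(trace: TraceRecord, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for key in sorted(trace.metadata):
            fh.write(f"# {key}: {json.dumps(trace.metadata[key])}\n")
        fh.write("\t".join(_COLUMNS) + "\n")
        cols = (trace.time, trace.extension, trace.force, trace.torque, trace.device_turns)
        for row in zip(*cols):
            fh.write("\t".join(f"{v:.9g}" for v in row) + "\n")


def read_trace(path) -> TraceRecord:
    path = Path(path)
    metadata: dict = {}
    data_rows: list = []
    header_seen = False
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" not in body:
                    raise TraceParseError(f"{path}:{lineno}: malformed metadata line")
                key, _, value = body.partition(":")
                try:
                    metadata[key.strip()] = json.loads(value.strip())
                except json.JSONDecodeError:
                    metadata[key.strip()] = value.strip()
                continue
            if not header_seen:
                if tuple(line.split("\t")) != _COLUMNS:
                    raise TraceParseError(
                        f"{path}:{lineno}: expected column header {_COLUMNS}, got {line!r}"
                    )
                header_seen = True
                continue
            parts = line.split("\t")
            if len(parts) != len(_COLUMNS):
                raise TraceParseError(f"{path}:{lineno}: expected {len(_COLUMNS)} columns")
            try:
                data_rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise TraceParseError(f"{path}:{lineno}: non-numeric value ({exc})") from None
    if not header_seen or not data_rows:
        raise TraceParseError(f"{path}: no sample data found")
    arr = np.asarray(data_rows)
    try:
        return TraceRecord(
            metadata=metadata,
            time=arr[:, 0],
            extension=arr[:, 1],
            force=arr[:, 2],
            torque=arr[:, 3],
            device_turns=arr[:, 4],
        )
    except ValueError as exc:
        raise TraceParseError(f"{path}: invalid trace data: {exc}") from None


def _fmt(value) -> str:
    if value is None:
        return "none"
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float) and math.isinf(value):
        return "inf"
    return json.dumps(value)


def _parse(token: str):
    if token == "none":
        return None
    if token == "true":
        return True
    if token == "false":
        return False
    if token == "inf":
        return math.inf
    return json.loads(token)


def write_event_log(log: EventLog, path, checkpoint_interval: float = 1.0) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"loading_time\t{_fmt(log.loading_time)}\n")
        fh.write(f"drawn_stall_torque\t{_fmt(log.drawn_stall_torque)}\n")
        fh.write(f"stall_entry_time\t{_fmt(log.stall_entry_time)}\n")
        fh.write(f"inactivation_time\t{_fmt(log.inactivation_time)}\n")
        fh.write(f"restarted\t{_fmt(log.restarted)}\n")
        fh.write(f"second_stall_entry_time\t{_fmt(log.second_stall_entry_time)}\n")
        fh.write(f"unwind_start\t{_fmt(log.unwind_start)}\n")
        fh.write(f"unwind_end\t{_fmt(log.unwind_end)}\n")
        fh.write(f"stall_wait_actual\t{_fmt(log.stall_wait_actual)}\n")
        for start, end in log.pause_intervals:
            fh.write(f"pause\t{start:.6g}\t{end:.6g}\n")
        t, fork = log.checkpoints(checkpoint_interval, log._fs)
        for ti, fi in zip(t, fork):
            fh.write(f"checkpoint\t{ti:.6g}\t{fi:.6g}\n")


def read_event_log(path) -> EventLog:
    """Read an event log; the fork trajectory comes back at checkpoint
    resolution (events are lossless)."""
    path = Path(path)
    fields: dict = {}
    pauses: list = []
    cp_t: list = []
    cp_f: list = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            try:
                if parts[0] == "pause":
                    pauses.append((float(parts[1]), float(parts[2])))
                elif parts[0] == "checkpoint":
                    cp_t.append(float(parts[1]))
                    cp_f.append(float(parts[2]))
                else:
                    fields[parts[0]] = _parse(parts[1])
            except (IndexError, ValueError, json.JSONDecodeError) as exc:
                raise TraceParseError(f"{path}:{lineno}: malformed record ({exc})") from None
    dt = cp_t[1] - cp_t[0] if len(cp_t) > 1 else 1.0
    return EventLog(
        loading_time=fields.get("loading_time", 0.0),
        pause_intervals=pauses,
        stall_entry_time=fields.get("stall_entry_time"),
        drawn_stall_torque=fields.get("drawn_stall_torque", math.nan),
        inactivation_time=fields.get("inactivation_time"),
        restarted=fields.get("restarted"),
        second_stall_entry_time=fields.get("second_stall_entry_time"),
        unwind_start=fields.get("unwind_start"),
        unwind_end=fields.get("unwind_end"),
        stall_wait_actual=fields.get("stall_wait_actual"),
        fork_truth=np.asarray(cp_f),
        net_turns_truth=np.asarray([]),
        mode_codes=np.asarray([], dtype=np.int8),
        _fs=1.0 / dt if dt > 0 else 1.0,
    )
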