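"""Plain-text file formats for sequences, recordings and analysis tables.

All files are delimited text with ``#``-prefixed metadata header lines
(``# key = value``); times are serialized in seconds with 6 decimal places
(1 µs, comfortably finer than the 1 ms valve resolution).  The recording
reader tolerates the two layouts a spike-time deposit may use: a spike-only
column (requiring a paired stimulus-sequence file) or a two-column
time/event layout carrying valve open/close events alongside spikes.
"""

from __future__ import annotations

import os
from typing import Optional

import numpy as np
import pandas as pd

from .orn import SpikeTrainRecording
from .plume import BLANK, WHIFF, PlumeParams, StimulusSequence

__all__ = [
    "write_sequence",
    "read_sequence",
    "write_recording",
    "read_recording",
    "write_table",
    "read_table",
]

_TIME_FMT = "%.6f"


def _format_meta(metadata: dict) -> list[str]:
    return [f"# {k} = {v}" for k, v in metadata.items()]


def _parse_meta_value(text: str):
    text = text.strip()
    if text == "None":
        return None
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    return text


def _read_lines(path):
    meta: dict = {}
    rows: list[tuple[int, str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = _parse_meta_value(value)
                continue
            rows.append((lineno, line))
    return meta, rows


def write_sequence(sequence: StimulusSequence, path) -> None:
    """Write a stimulus sequence: metadata, header, one event per row."""
    meta = {
        "format": "ornplume-sequence",
        "total_duration_s": _TIME_FMT % sequence.total_duration,
        "seed": sequence.seed,
        "whiff_cap_s": sequence.whiff_cap,
        "final_truncated": sequence.final_truncated,
    }
    if sequence.params is not None:
        p = sequence.params
        meta.update(
            {"d_m": p.d, "U_mps": p.U, "dU_mps": p.dU, "a_m": p.a, "chi": p.chi,
             "tau_override_s": p.tau_override}
        )
    lines = _format_meta(meta)
    lines.append("onset_s\tduration_s\tkind")
    for onset, dur, kind in sequence.events:
        lines.append(f"{_TIME_FMT % onset}\t{_TIME_FMT % dur}\t{kind}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_sequence(path) -> StimulusSequence:
    """Read a stimulus sequence written by :func:`write_sequence`."""
    meta, rows = _read_lines(path)
    onsets, durations, kinds = [], [], []
    for lineno, line in rows:
        fields = line.split("\t")
        if fields[0] == "onset_s":  # header
            continue
        if len(fields) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 fields, got {len(fields)}")
        try:
            onsets.append(float(fields[0]))
            durations.append(float(fields[1]))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed number: {exc}") from None
        if fields[2] not in (WHIFF, BLANK):
            raise ValueError(f"{path}:{lineno}: unknown event kind {fields[2]!r}")
        kinds.append(fields[2])
    params = None
    if "d_m" in meta:
        params = PlumeParams(
            d=float(meta["d_m"]),
            U=float(meta.get("U_mps", 1.0)),
            dU=float(meta.get("dU_mps", 0.1)),
            a=float(meta.get("a_m", 0.1)),
            chi=float(meta.get("chi", 0.4)),
            tau_override=(
                float(meta["tau_override_s"])
                if meta.get("tau_override_s") is not None
                else None
            ),
        )
    return StimulusSequence(
        onsets=np.array(onsets),
        durations=np.array(durations),
        kinds=np.array(kinds),
        total_duration=float(meta.get("total_duration_s", onsets[-1] + durations[-1])),
        params=params,
        seed=meta.get("seed"),
        whiff_cap=meta.get("whiff_cap_s"),
        final_truncated=bool(meta.get("final_truncated", False)),
    )


def write_recording(
    recording: SpikeTrainRecording,
    path,
    sequence_path: Optional[str] = None,
) -> None:
    """Write a recording: one spike time per row, metadata in '#' lines.

    When ``sequence_path`` is given, the paired stimulus sequence is written
    there and referenced in the recording's metadata (spike-only layout,
    mirroring one deposited per-neuron file: one sensillum per insect).
    """
    meta = {
        "format": "ornplume-recording",
        "neuron_id": recording.neuron_id,
        "distance_m": recording.distance_label,
        "dose_ng": recording.dose_label,
    }
    if sequence_path is not None:
        write_sequence(recording.sequence, sequence_path)
        meta["sequence_file"] = os.path.basename(str(sequence_path))
    lines = _format_meta(meta)
    lines.append("spike_time_s")
    lines.extend(_TIME_FMT % t for t in recording.spikes)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_recording(path, sequence: Optional[StimulusSequence] = None) -> SpikeTrainRecording:
    """Read a recording; tolerates spike-only and spike+valve layouts.

    Spike-only files need a stimulus pairing: either an explicit
    ``sequence`` argument or a ``sequence_file`` metadata reference
    (resolved relative to the recording).  Two-column files may interleave
    ``valve_open``/``valve_close`` events with spikes; the stimulus sequence
    is then reconstructed from the valve events.
    """
    meta, rows = _read_lines(path)
    spikes: list[float] = []
    valve_events: list[tuple[float, str]] = []
    for lineno, line in rows:
        fields = line.split("\t")
        if fields[0] in ("spike_time_s", "time_s"):  # header
            continue
        try:
            t = float(fields[0])
        except ValueError:
            raise ValueError(f"{path}:{lineno}: malformed time {fields[0]!r}") from None
        if t < 0:
            raise ValueError(f"{path}:{lineno}: negative time {t!r}")
        if len(fields) == 1 or fields[1] == "spike":
            spikes.append(t)
        elif fields[1] in ("valve_open", "valve_close"):
            valve_events.append((t, fields[1]))
        else:
            raise ValueError(f"{path}:{lineno}: unknown event label {fields[1]!r}")

    if sequence is None:
        if valve_events:
            sequence = _sequence_from_valves(valve_events, spikes)
        elif meta.get("sequence_file"):
            seq_path = os.path.join(os.path.dirname(os.path.abspath(str(path))),
                                    str(meta["sequence_file"]))
            sequence = read_sequence(seq_path)
        else:
            raise ValueError(
                f"{path}: spike-only recording without a paired stimulus file; "
                "pass sequence= or add a 'sequence_file' metadata line"
            )
    return SpikeTrainRecording(
        spikes=np.array(sorted(spikes)),
        sequence=sequence,
        distance_label=meta.get("distance_m"),
        dose_label=meta.get("dose_ng"),
        neuron_id=str(meta["neuron_id"]) if meta.get("neuron_id") is not None else None,
    )


def _sequence_from_valves(valve_events, spikes) -> StimulusSequence:
    """Reconstruct a whiff/blank sequence from valve open/close event times."""
    valve_events = sorted(valve_events)
    onsets, durations, kinds = [], [], []
    t = 0.0
    open_t = None
    for when, label in valve_events:
        if label == "valve_open":
            if open_t is not None:
                raise ValueError("valve_open while the valve is already open")
            if when > t:
                onsets.append(t)
                durations.append(when - t)
                kinds.append(BLANK)
            open_t = when
        else:
            if open_t is None:
                raise ValueError("valve_close without a preceding valve_open")
            onsets.append(open_t)
            durations.append(when - open_t)
            kinds.append(WHIFF)
            t = when
            open_t = None
    end = max([t] + [s for s in spikes] + [w for w, _ in valve_events])
    if end > t:
        onsets.append(t)
        durations.append(end - t)
        kinds.append(BLANK)
    return StimulusSequence(
        onsets=np.array(onsets),
        durations=np.array(durations),
        kinds=np.array(kinds),
        total_duration=float(end),
        final_truncated=True,
    )


def write_table(df: pd.DataFrame, path, metadata: Optional[dict] = None) -> None:
    """Write a DataFrame as tab-delimited text with '#' metadata lines."""
    with open(path, "w", encoding="utf-8") as fh:
        if metadata:
            fh.write("\n".join(_format_meta(metadata)) + "\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_table(path) -> tuple[pd.DataFrame, dict]:
    """Read a tab-delimited table and its '#' metadata."""
    meta, _ = _read_lines(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    return df, meta
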