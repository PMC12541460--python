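"""Readers and writers for trace tables, ground-truth sidecars, and results.

The trace table is one row per spot per frame cycle with columns
``spot_id, cycle_index, time_s, I_DexDem, I_DexAem, I_AexAem``, written as
tab-delimited text (``.tsv``) or a columnar binary (``.parquet``).  Metadata
(key: value) travels in ``#``-prefixed header lines of the text formats.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .preprocess import EventRecord
from .scheme import StatePath
from .state_calling import StateCall
from .trace import SpotTrace

__all__ = [
    "write_traces",
    "read_traces",
    "write_truth",
    "read_truth",
    "write_events",
    "write_calls",
    "write_table",
    "read_table",
]

TRACE_COLUMNS = ["spot_id", "cycle_index", "time_s", "I_DexDem", "I_DexAem", "I_AexAem"]


def write_table(df: pd.DataFrame, path, header: dict | None = None) -> None:
    """Write a DataFrame as TSV (or parquet by suffix) with a comment header."""
    path = Path(path)
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
        return
    buf = _io.StringIO()
    for key, val in (header or {}).items():
        buf.write(f"# {key}: {val}\n")
    df.to_csv(buf, sep="\t", index=False, float_format="%.6f")
    path.write_text(buf.getvalue())


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".parquet":
        return pd.read_parquet(path)
    return pd.read_csv(path, sep="\t", comment="#")


def write_traces(traces: list[SpotTrace], path, header: dict | None = None) -> None:
    df = pd.concat([t.to_frame() for t in traces], ignore_index=True)
    write_table(df, path, header)


def read_traces(path) -> list[SpotTrace]:
    """Load a trace table back into per-spot traces (sorted by spot id)."""
    df = read_table(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"trace table {path} is missing column(s): {', '.join(missing)}"
        )
    return [
        SpotTrace.from_frame(g, spot_id=str(sid))
        for sid, g in df.groupby("spot_id", sort=True)
    ]


def write_truth(traces: list[SpotTrace], states_path, bleach_path=None) -> None:
    """Write the ground-truth sidecar: state segments and per-dye bleach times."""
    srows, brows = [], []
    for t in traces:
        if t.truth is not None:
            for label, start, end in t.truth.segments:
                srows.append((t.spot_id, label, start, end))
        for dye, tb in (t.bleach_times or {}).items():
            brows.append((t.spot_id, dye, tb if np.isfinite(tb) else np.inf))
    write_table(
        pd.DataFrame(srows, columns=["spot_id", "state_label", "start_s", "end_s"]),
        states_path,
    )
    if bleach_path is not None:
        write_table(
            pd.DataFrame(brows, columns=["spot_id", "dye", "bleach_time_s"]),
            bleach_path,
        )


def read_truth(states_path) -> dict[str, StatePath]:
    """Load the state sidecar as per-spot StatePaths (no scheme attached)."""
    df = read_table(states_path)
    out = {}
    for sid, g in df.groupby("spot_id", sort=True):
        g = g.sort_values("start_s")
        segments = [
            (str(r.state_label), float(r.start_s), float(r.end_s))
            for r in g.itertuples()
        ]
        out[str(sid)] = StatePath(
            segments=segments, total_duration=segments[-1][2] if segments else 0.0
        )
    return out


def events_frame(events: list[EventRecord]) -> pd.DataFrame:
    cols = [
        "spot_id",
        "orc_arrival_s",
        "orc_departure_s",
        "mcm_arrival_s",
        "mcm_departure_s",
        "cdt1_release_s",
        "second_mcm_arrival_s",
        "censored_end",
        "orc_censored",
        "mcm_censored",
        "bleach_suspected",
    ]
    return pd.DataFrame([{c: getattr(e, c) for c in cols} for e in events])


def write_events(events: list[EventRecord], path, header: dict | None = None) -> None:
    write_table(events_frame(events), path, header)


def calls_frame(calls: list[StateCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        if c.high_intervals:
            for (a, b, cen), (a_s, b_s, _) in zip(c.high_intervals, c.high_intervals_s):
                rows.append(
                    dict(
                        spot_id=c.spot_id,
                        threshold=c.threshold,
                        start_s=a_s,
                        end_s=b_s,
                        start_cycle=a,
                        end_cycle=b,
                        censored=cen,
                        stable_recruitment=c.stable_recruitment,
                    )
                )
        else:
            rows.append(
                dict(
                    spot_id=c.spot_id,
                    threshold=c.threshold,
                    start_s=np.nan,
                    end_s=np.nan,
                    start_cycle=np.nan,
                    end_cycle=np.nan,
                    censored=False,
                    stable_recruitment=c.stable_recruitment,
                )
            )
    return pd.DataFrame(rows)


def write_calls(calls: list[StateCall], path, header: dict | None = None) -> None:
    write_table(calls_frame(calls), path, header)
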