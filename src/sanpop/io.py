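"""Plain-text I/O for traces, fiducials, episodes and population tables.

All formats are small CSV files so that runs remain auditable with ordinary
spreadsheet or command-line tools.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .rhythm import EpisodeCall, FiducialSeries

_FIDUCIAL_TYPES = ("P", "QRSon", "R", "QRSoff", "Tend")


def write_trace(path, time_s: np.ndarray, em_mv: np.ndarray) -> None:
    """Two-column membrane-potential / ECG trace CSV (time_s, em_mV)."""
    pd.DataFrame({"time_s": time_s, "em_mV": em_mv}).to_csv(path, index=False)


def read_trace(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df["time_s"].to_numpy(), df["em_mV"].to_numpy()


def write_beats(path, beat_times: np.ndarray) -> None:
    """One-column beat-time CSV."""
    pd.DataFrame({"beat_time_s": np.asarray(beat_times)}).to_csv(path, index=False)


def read_beats(path) -> np.ndarray:
    return pd.read_csv(path)["beat_time_s"].to_numpy()


def write_fiducials(path, f: FiducialSeries) -> None:
    """Long-format fiducial CSV: columns (type, time_s).

    ``type`` is one of P, QRSon, R, QRSoff, Tend. The recording duration and
    species tag travel as '# key=value' header comments.
    """
    rows = []
    series = {
        "P": f.p_times,
        "R": f.r_times,
        "QRSon": f.qrs_onsets,
        "QRSoff": f.qrs_offsets,
        "Tend": f.t_ends,
    }
    for kind, times in series.items():
        if times is None:
            continue
        rows.extend({"type": kind, "time_s": t} for t in np.asarray(times))
    df = pd.DataFrame(rows, columns=["type", "time_s"]).sort_values("time_s")
    with open(path, "w") as fh:
        fh.write(f"# duration={f.duration}\n# species={f.species}\n")
        df.to_csv(fh, index=False)


def read_fiducials(path) -> FiducialSeries:
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
            body_start = i + 1
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])))
    unknown = set(df["type"]) - set(_FIDUCIAL_TYPES)
    if unknown:
        raise ValueError(f"unknown fiducial types in {path}: {sorted(unknown)}")

    def series(kind: str):
        t = np.sort(df.loc[df["type"] == kind, "time_s"].to_numpy())
        return t if t.size else None

    p = series("P")
    r = series("R")
    all_times = df["time_s"].to_numpy()
    duration = float(meta.get("duration", all_times.max() if all_times.size else 0.0))
    return FiducialSeries(
        p_times=p if p is not None else np.empty(0),
        r_times=r if r is not None else np.empty(0),
        duration=duration,
        species=meta.get("species", "zebrafish"),
        qrs_onsets=series("QRSon"),
        qrs_offsets=series("QRSoff"),
        t_ends=series("Tend"),
    )


def write_episodes(path, calls: Sequence[EpisodeCall]) -> None:
    """Episode CSV: (kind, onset_s, offset_s, evidence)."""
    pd.DataFrame(
        [
            dict(kind=c.kind, onset_s=c.onset, offset_s=c.offset, evidence=c.evidence)
            for c in calls
        ],
        columns=["kind", "onset_s", "offset_s", "evidence"],
    ).to_csv(path, index=False)


def read_episodes(path) -> list[EpisodeCall]:
    df = pd.read_csv(path)
    return [
        EpisodeCall(row.kind, row.onset_s, row.offset_s, row.evidence)
        for row in df.itertuples()
    ]
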