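"""CSV readers and writers for the canonical telemetry layouts.

Two plain-text dialects are supported:

* beats CSV — ``time_s,rr_ms,sbp_mmHg,dbp_mmHg`` with ``#``-prefixed header
  lines carrying the absolute anchor datetime and subject id.  One row per
  beat; the RR cell of the first beat is empty (an RR interval needs two
  beats).  Pressure columns are optional.
* channels CSV — ``timestamp_iso8601,subject_id,channel,value`` long layout,
  one value per subject per channel per time bin (the layout of the
  deposited 2 h-bin dataset).

Floats are written with ``repr`` so that a write/read round trip is
bit-exact.
"""

from __future__ import annotations

import math
from datetime import datetime

import numpy as np
import pandas as pd

from .design import ExperimentDesign
from .series import CHANNELS, BeatSeries, ChannelSeries, PressureBeatSeries, ValidationError

BEAT_COLUMNS = ("time_s", "rr_ms", "sbp_mmHg", "dbp_mmHg")
CHANNEL_COLUMNS = ("timestamp_iso8601", "subject_id", "channel", "value")


def _fmt(x) -> str:
    if x is None:
        return ""
    x = float(x)
    return "" if math.isnan(x) else repr(x)


# -- beats ------------------------------------------------------------------

def write_beats(pbs: PressureBeatSeries | BeatSeries, path) -> None:
    """Write a (pressure) beat series to the canonical beats CSV."""
    if isinstance(pbs, BeatSeries):
        pbs = PressureBeatSeries(beats=pbs)
    b = pbs.beats
    lines = []
    if b.anchor is not None:
        lines.append(f"# anchor={b.anchor.isoformat()}")
    if b.subject_id is not None:
        lines.append(f"# subject={b.subject_id}")
    if not b.valid.all():
        lines.append("# invalid=" + ",".join(str(i) for i in np.where(~b.valid)[0]))
    has_bp = pbs.sbp is not None
    header = "time_s,rr_ms" + (",sbp_mmHg,dbp_mmHg" if has_bp else "")
    lines.append(header)
    rr = [""] + [_fmt(x) for x in b.rr]
    for i in range(b.n_beats):
        row = f"{_fmt(b.t[i])},{rr[i]}"
        if has_bp:
            row += f",{_fmt(pbs.sbp[i])},{_fmt(pbs.dbp[i])}"
        lines.append(row)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_beats(path, design: ExperimentDesign | None = None) -> PressureBeatSeries:
    """Read a beats CSV, validate invariants and attach schedule labels.

    Raises :class:`ValidationError` naming the offending line for
    non-increasing beat times or non-positive RR values.
    """
    anchor: datetime | None = None
    subject: str | None = None
    invalid_idx: list[int] = []
    n_head = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_head += 1
            key, _, val = line[1:].strip().partition("=")
            if key == "anchor":
                anchor = datetime.fromisoformat(val)
            elif key == "subject":
                subject = val
            elif key == "invalid" and val:
                invalid_idx = [int(s) for s in val.split(",")]
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValidationError(f"malformed beats CSV {path}: {exc}") from exc
    if "time_s" not in df.columns:
        raise ValidationError(f"{path}: missing required column time_s")

    def _line(i: int) -> int:  # 1-based physical line of data row i
        return n_head + 2 + i

    t = df["time_s"].to_numpy(dtype=float)
    if np.any(~np.isfinite(t)):
        raise ValidationError(f"{path}: non-numeric time_s at line {_line(int(np.argmax(~np.isfinite(t))))}")
    dt = np.diff(t)
    if np.any(dt <= 0):
        i = int(np.argmax(dt <= 0)) + 1
        raise ValidationError(f"{path}: beat times not increasing at line {_line(i)}")
    if "rr_ms" in df.columns and df["rr_ms"].notna().any():
        rr = df["rr_ms"].to_numpy(dtype=float)[1:]
        bad = ~(rr > 0)
        if np.any(bad):
            i = int(np.argmax(bad)) + 1
            raise ValidationError(f"{path}: non-positive RR at line {_line(i)}")
    else:
        rr = np.diff(t) * 1000.0
    valid = np.ones(len(rr), dtype=bool)
    for i in invalid_idx:
        valid[i] = False
    beats = BeatSeries(t=t, rr=rr, valid=valid, subject_id=subject, anchor=anchor)
    sbp = df["sbp_mmHg"].to_numpy(dtype=float) if "sbp_mmHg" in df.columns else None
    dbp = df["dbp_mmHg"].to_numpy(dtype=float) if "dbp_mmHg" in df.columns else None
    pbs = PressureBeatSeries(beats=beats, sbp=sbp, dbp=dbp)
    if design is not None and anchor is not None:
        beats.meta["phase_labels"] = beats.phase_labels(design)
        beats.meta["light_labels"] = beats.light_labels(design)
    return pbs


# -- channels ---------------------------------------------------------------

def write_channels(series, path) -> None:
    """Write one or more :class:`ChannelSeries` to the long channels CSV."""
    if isinstance(series, ChannelSeries):
        series = [series]
    lines = [",".join(CHANNEL_COLUMNS)]
    for s in series:
        stamps = np.datetime_as_string(s.t, unit="s")
        for ts, v in zip(stamps, s.value):
            lines.append(f"{ts},{s.subject_id},{s.channel},{_fmt(v)}")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_channels(path, design: ExperimentDesign) -> list[ChannelSeries]:
    """Read a channels CSV into labelled series, one per subject x channel.

    Unknown channel names are rejected with the list of accepted names.
    An empty file yields an empty list.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        return []
    except pd.errors.ParserError as exc:
        raise ValidationError(f"malformed channels CSV {path}: {exc}") from exc
    if len(df) == 0:
        return []
    missing = set(CHANNEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    unknown = sorted(set(df["channel"].astype(str)) - set(CHANNELS))
    if unknown:
        raise ValidationError(
            f"unknown channel(s) {unknown}; accepted: {', '.join(CHANNELS)}"
        )
    out: list[ChannelSeries] = []
    df["timestamp_iso8601"] = pd.to_datetime(df["timestamp_iso8601"])
    for (subj, chan), grp in df.groupby(["subject_id", "channel"], sort=True):
        grp = grp.sort_values("timestamp_iso8601", kind="stable")
        out.append(
            ChannelSeries.build(
                t=grp["timestamp_iso8601"].to_numpy(),
                value=grp["value"].to_numpy(dtype=float),
                channel=str(chan),
                subject_id=str(subj),
                design=design,
            )
        )
    return out
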