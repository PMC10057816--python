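"""Experiment design: light/dark schedule, phase calendar and clock arithmetic.

The housing schedule is clock based: a 12 h light cycle (LC, lights on at
07:00) and a 12 h dark cycle (DC, lights off at 19:00).  The experiment
calendar is an ordered list of day labels (3 control days ``C-3..C-1``, 5
hindlimb-unloading days ``HU1..HU5``, 2 recovery days ``R+1``/``R+2``), one
per calendar day starting at ``start_date``.  A daily handling window
(10:00-11:00, when the experimenter enters the room) is excluded from all
aggregate statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time

import numpy as np
import yaml

CONTROL = "Control"
UNLOADING = "Unloading"
RECOVERY = "Recovery"

DEFAULT_PHASES: tuple[str, ...] = (
    "C-3", "C-2", "C-1", "HU1", "HU2", "HU3", "HU4", "HU5", "R+1", "R+2",
)

_SECONDS_PER_DAY = 86400.0


def _time_to_seconds(t: time) -> float:
    return t.hour * 3600.0 + t.minute * 60.0 + t.second + t.microsecond * 1e-6


def clock_seconds(timestamps) -> np.ndarray:
    """Seconds past local midnight for an array of timestamps."""
    ts = np.asarray(timestamps, dtype="datetime64[ns]")
    return (ts - ts.astype("datetime64[D]")) / np.timedelta64(1, "s")


@dataclass(frozen=True)
class ExperimentDesign:
    """Calendar and schedule bookkeeping for one telemetry experiment.

    Parameters
    ----------
    phase_labels : ordered day labels, one per calendar day.
    lights_on, lights_off : clock times delimiting the light cycle;
        LC holds for ``lights_on <= clock < lights_off``.
    excluded_window : daily clock interval dropped from aggregation
        (animal-handling hour).
    day_boundary : clock time at which the day label rolls over
        (midnight: days run midnight-to-midnight).
    start_date : calendar date of the first phase label.
    """

    phase_labels: tuple[str, ...] = DEFAULT_PHASES
    lights_on: time = time(7, 0)
    lights_off: time = time(19, 0)
    excluded_window: tuple[time, time] = (time(10, 0), time(11, 0))
    day_boundary: time = time(0, 0)
    start_date: date = date(2022, 2, 7)

    def __post_init__(self) -> None:
        object.__setattr__(self, "phase_labels", tuple(self.phase_labels))
        if self.lights_on == self.lights_off:
            raise ValueError("lights_on and lights_off must differ")
        lo, hi = self.excluded_window
        length = (_time_to_seconds(hi) - _time_to_seconds(lo)) % _SECONDS_PER_DAY
        if length >= 12 * 3600:
            raise ValueError("excluded_window must be shorter than 12 h")
        if len(set(self.phase_labels)) != len(self.phase_labels):
            raise ValueError("phase labels must be unique")

    # -- condition grouping -------------------------------------------------
    def condition_of(self, label: str) -> str:
        """Map a day label to its experimental condition."""
        if label.startswith("C"):
            return CONTROL
        if label.startswith("HU"):
            return UNLOADING
        if label.startswith("R"):
            return RECOVERY
        raise ValueError(f"unrecognised phase label {label!r}")

    @property
    def start_datetime(self) -> datetime:
        return datetime.combine(self.start_date, self.day_boundary)

    def phase_date(self, label: str) -> date:
        """Calendar date on which a given phase label runs."""
        idx = self.phase_labels.index(label)
        return (np.datetime64(self.start_date) + np.timedelta64(idx, "D")).astype(date)


def label_light_phase(t, design: ExperimentDesign) -> str:
    """Light-phase label for a single clock time or timestamp.

    LC iff ``lights_on <= t < lights_off`` (boundary inclusive at lights-on).
    """
    if isinstance(t, time):
        clk = _time_to_seconds(t)
    elif isinstance(t, datetime):
        clk = _time_to_seconds(t.time())
    else:
        clk = float(clock_seconds([t])[0])
    return light_labels(np.array([clk]), design, _clock=True)[0]


def light_labels(timestamps, design: ExperimentDesign, _clock: bool = False) -> np.ndarray:
    """Vectorised LC/DC labels for an array of timestamps."""
    clk = np.asarray(timestamps, dtype=float) if _clock else clock_seconds(timestamps)
    on = _time_to_seconds(design.lights_on)
    off = _time_to_seconds(design.lights_off)
    if on < off:
        lc = (clk >= on) & (clk < off)
    else:  # schedule wrapping midnight
        lc = (clk >= on) | (clk < off)
    return np.where(lc, "LC", "DC")


def phase_labels_for(timestamps, design: ExperimentDesign) -> np.ndarray:
    """Day label for each timestamp; '' for samples outside the calendar."""
    ts = np.asarray(timestamps, dtype="datetime64[ns]")
    start = np.datetime64(design.start_datetime)
    idx = np.floor((ts - start) / np.timedelta64(1, "D")).astype(int)
    labels = np.array(design.phase_labels + ("",))
    idx = np.where((idx >= 0) & (idx < len(design.phase_labels)), idx, -1)
    return labels[idx]


def in_excluded_window(timestamps, design: ExperimentDesign) -> np.ndarray:
    """Boolean mask of samples falling inside the daily excluded window."""
    clk = clock_seconds(timestamps)
    lo = _time_to_seconds(design.excluded_window[0])
    hi = _time_to_seconds(design.excluded_window[1])
    if lo < hi:
        return (clk >= lo) & (clk < hi)
    return (clk >= lo) | (clk < hi)


# -- structured config ------------------------------------------------------

def design_to_yaml(design: ExperimentDesign, path) -> None:
    doc = {
        "phase_labels": list(design.phase_labels),
        "lights_on": design.lights_on.strftime("%H:%M"),
        "lights_off": design.lights_off.strftime("%H:%M"),
        "excluded_window": [t.strftime("%H:%M") for t in design.excluded_window],
        "day_boundary": design.day_boundary.strftime("%H:%M"),
        "start_date": design.start_date.isoformat(),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def design_from_yaml(path) -> ExperimentDesign:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)

    def _t(s: str) -> time:
        h, m = s.split(":")
        return time(int(h), int(m))

    return ExperimentDesign(
        phase_labels=tuple(doc["phase_labels"]),
        lights_on=_t(doc["lights_on"]),
        lights_off=_t(doc["lights_off"]),
        excluded_window=tuple(_t(s) for s in doc["excluded_window"]),
        day_boundary=_t(doc["day_boundary"]),
        start_date=date.fromisoformat(doc["start_date"]),
    )
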