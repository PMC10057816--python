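"""In-memory containers for beat-level and channel-level telemetry.

``BeatSeries`` holds R-peak times (seconds from recording start) and the
derived RR intervals in milliseconds; ``PressureBeatSeries`` pairs it with
beat-aligned systolic/diastolic pressures; ``ChannelSeries`` is a timestamped
scalar channel (activity counts, temperature, pressure, heart rate) carrying
its light-phase and experiment-phase labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
import pandas as pd

from .design import ExperimentDesign, light_labels, phase_labels_for

CHANNELS: tuple[str, ...] = (
    "activity",
    "temperature_subcutaneous",
    "temperature_core",
    "sbp",
    "dbp",
    "mbp",
    "hr",
)


class ValidationError(ValueError):
    """Raised when telemetry data violate a container invariant."""


@dataclass
class BeatSeries:
    """R-peak times and RR intervals.

    ``t`` are beat times in seconds from recording start (strictly
    increasing, ``n`` beats); ``rr`` are the ``n-1`` inter-beat intervals in
    ms.  ``valid[i]`` flags interval ``i`` (equivalently the beat
    terminating it): False marks an ectopic/artifact interval.  ``anchor``
    is the absolute wall-clock datetime of ``t == 0`` and links the series
    to the light/dark schedule.
    """

    t: np.ndarray
    rr: np.ndarray
    valid: np.ndarray | None = None
    subject_id: str | None = None
    anchor: datetime | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)
        if self.valid is None:
            self.valid = np.ones(len(self.rr), dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if len(self.rr) != len(self.t) - 1:
            raise ValidationError(
                f"rr has {len(self.rr)} entries; expected {len(self.t) - 1}"
            )
        if len(self.valid) != len(self.rr):
            raise ValidationError("valid mask length must match rr")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            i = int(np.argmax(dt <= 0))
            raise ValidationError(f"beat times not strictly increasing at beat {i + 1}")
        bad = self.valid & ~(self.rr > 0)
        if np.any(bad):
            i = int(np.argmax(bad))
            raise ValidationError(f"non-positive RR at interval {i}")

    @classmethod
    def from_times(cls, t, **kwargs) -> "BeatSeries":
        t = np.asarray(t, dtype=float)
        return cls(t=t, rr=np.diff(t) * 1000.0, **kwargs)

    @property
    def n_beats(self) -> int:
        return len(self.t)

    def clock_seconds(self) -> np.ndarray:
        """Seconds past local midnight for every beat (requires anchor)."""
        if self.anchor is None:
            raise ValueError("BeatSeries has no anchor datetime")
        base = (
            self.anchor.hour * 3600
            + self.anchor.minute * 60
            + self.anchor.second
            + self.anchor.microsecond * 1e-6
        )
        return (base + self.t) % 86400.0

    def light_labels(self, design: ExperimentDesign) -> np.ndarray:
        from .design import light_labels as _ll

        return _ll(self.clock_seconds(), design, _clock=True)

    def phase_labels(self, design: ExperimentDesign) -> np.ndarray:
        if self.anchor is None:
            raise ValueError("BeatSeries has no anchor datetime")
        ts = np.datetime64(self.anchor) + (self.t * 1e9).astype("timedelta64[ns]")
        return phase_labels_for(ts, design)


@dataclass
class PressureBeatSeries:
    """Beat-aligned arterial pressures on top of a :class:`BeatSeries`.

    ``sbp``/``dbp`` carry one value per beat (mmHg).  They may be None when
    the upstream file holds only the beat annotations.
    """

    beats: BeatSeries
    sbp: np.ndarray | None = None
    dbp: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("sbp", "dbp"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                setattr(self, name, v)
                if len(v) != self.beats.n_beats:
                    raise ValidationError(f"{name} length must equal number of beats")
        if self.sbp is not None and self.dbp is not None:
            bad = ~(self.sbp > self.dbp)
            if np.any(bad):
                i = int(np.argmax(bad))
                raise ValidationError(f"sbp <= dbp at beat {i}")

    @property
    def aligned_sbp(self) -> np.ndarray:
        """SBP at interval-terminating beats, index-aligned with ``beats.rr``."""
        if self.sbp is None:
            raise ValueError("series carries no pressure channel")
        return self.sbp[1:]


@dataclass
class ChannelSeries:
    """A timestamped scalar telemetry channel with schedule labels."""

    t: np.ndarray
    value: np.ndarray
    channel: str
    subject_id: str = ""
    light_phase: np.ndarray | None = None
    phase: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValidationError(
                f"unknown channel {self.channel!r}; accepted: {', '.join(CHANNELS)}"
            )
        self.t = np.asarray(self.t, dtype="datetime64[ns]")
        self.value = np.asarray(self.value, dtype=float)
        if len(self.t) != len(self.value):
            raise ValidationError("timestamps and values must have equal length")
        if len(self.t) > 1 and np.any(np.diff(self.t) < np.timedelta64(0, "ns")):
            raise ValidationError("timestamps must be non-decreasing")

    @classmethod
    def build(
        cls, t, value, channel: str, subject_id: str, design: ExperimentDesign
    ) -> "ChannelSeries":
        """Construct and label from the experiment design."""
        obj = cls(t=t, value=value, channel=channel, subject_id=subject_id)
        obj.light_phase = light_labels(obj.t, design)
        obj.phase = phase_labels_for(obj.t, design)
        return obj

    def __len__(self) -> int:
        return len(self.t)

    def subset(self, mask) -> "ChannelSeries":
        out = ChannelSeries(
            t=self.t[mask],
            value=self.value[mask],
            channel=self.channel,
            subject_id=self.subject_id,
        )
        if self.light_phase is not None:
            out.light_phase = np.asarray(self.light_phase)[mask]
        if self.phase is not None:
            out.phase = np.asarray(self.phase)[mask]
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "timestamp": self.t,
                "subject_id": self.subject_id,
                "channel": self.channel,
                "value": self.value,
            }
        )
        if self.light_phase is not None:
            df["light_phase"] = self.light_phase
        if self.phase is not None:
            df["phase"] = self.phase
        return df
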