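"""Spontaneous baroreflex sensitivity by the sequence technique.

A baroreflex sequence is a ramp of at least three beats with strictly
monotone systolic pressure, mirrored by a strictly monotone same-direction
change in the RR intervals (optionally lagged by a fixed number of beats).
The per-sequence slope of RR on SBP (ordinary least squares, ms/mmHg)
estimates the reflex gain; the BRS estimate is the unweighted mean slope
over all up and down sequences pooled.  No SBP, RR or correlation
thresholds are applied; any nonzero change counts and exact ties break a
run.

Detection operates on interval-aligned arrays: SBP at the beat terminating
each RR interval, index-aligned with ``BeatSeries.rr``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from datetime import time

import numpy as np

from .design import ExperimentDesign
from .series import PressureBeatSeries

log = logging.getLogger(__name__)


@dataclass
class Ramp:
    direction: str  # "up" | "down"
    start: int  # first aligned (interval) index
    stop: int  # last aligned index, inclusive

    @property
    def length(self) -> int:
        return self.stop - self.start + 1


@dataclass
class BaroSequence:
    direction: str
    beat_indices: list[int]  # indices into the beat-time array
    sbp_values: np.ndarray  # mmHg
    rr_values: np.ndarray  # ms
    slope: float  # ms/mmHg
    r: float  # correlation coefficient (recorded, never thresholded)

    @property
    def length(self) -> int:
        return len(self.beat_indices)


@dataclass
class BRSResult:
    brs: float  # ms/mmHg, mean slope; NaN when no sequences
    n_up: int
    n_down: int
    n_sequences: int
    sequences: list[BaroSequence]
    lag: int
    n_skipped: int = 0  # ramps lost to lag pushing past the series end


def find_ramps(pbs: PressureBeatSeries, min_len: int = 3) -> list[Ramp]:
    """Maximal strictly monotone SBP runs of at least ``min_len`` beats.

    Maximal runs are not split into sub-ramps; a beat may terminate one
    ramp and start the next (a local extremum belongs to both).
    """
    sbp = pbs.aligned_sbp
    n = len(sbp)
    ramps: list[Ramp] = []
    if n < min_len:
        return ramps
    sign = np.sign(np.diff(sbp))
    i = 0
    while i < n - 1:
        s = sign[i]
        if s == 0:
            i += 1
            continue
        j = i
        while j < n - 1 and sign[j] == s:
            j += 1
        if j - i + 1 >= min_len:
            ramps.append(Ramp("up" if s > 0 else "down", i, j))
        i = j
    return ramps


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(np.dot(xc, xc))
    slope = float(np.dot(xc, yc)) / sxx
    denom = np.sqrt(sxx * float(np.dot(yc, yc)))
    r = float(np.dot(xc, yc) / denom) if denom > 0 else float("nan")
    return slope, r


def match_sequences(
    ramps: list[Ramp], pbs: PressureBeatSeries, lag: int = 0
) -> list[BaroSequence]:
    """Keep ramps whose lagged RR response is strictly monotone in the same
    direction, and fit the per-sequence regression slope."""
    sbp = pbs.aligned_sbp
    rr = pbs.beats.rr
    out: list[BaroSequence] = []
    skipped = 0
    for ramp in ramps:
        idx = np.arange(ramp.start, ramp.stop + 1)
        ridx = idx + lag
        if ridx[-1] >= len(rr):
            skipped += 1
            continue
        dr = np.diff(rr[ridx])
        mono_up = np.all(dr > 0)
        mono_down = np.all(dr < 0)
        if (ramp.direction == "up" and not mono_up) or (
            ramp.direction == "down" and not mono_down
        ):
            continue
        slope, r = _ols_slope(sbp[idx], rr[ridx])
        out.append(
            BaroSequence(
                direction=ramp.direction,
                beat_indices=list(idx + 1),  # interval i ends at beat i+1
                sbp_values=sbp[idx].copy(),
                rr_values=rr[ridx].copy(),
                slope=slope,
                r=r,
            )
        )
    if skipped:
        log.info("%d ramps skipped: lag pushes indices past the series end", skipped)
        match_sequences.last_skipped = skipped  # diagnostics hook
    else:
        match_sequences.last_skipped = 0
    return out


def brs(sequences: list[BaroSequence], lag: int = 0) -> BRSResult:
    """Pool up and down sequences into one mean-slope BRS estimate."""
    n_up = sum(1 for s in sequences if s.direction == "up")
    n_down = len(sequences) - n_up
    if not sequences:
        warnings.warn("no baroreflex sequences detected; BRS undefined",
                      RuntimeWarning, stacklevel=2)
        estimate = float("nan")
    else:
        estimate = float(np.mean([s.slope for s in sequences]))
    return BRSResult(
        brs=estimate, n_up=n_up, n_down=n_down, n_sequences=len(sequences),
        sequences=list(sequences), lag=lag,
        n_skipped=getattr(match_sequences, "last_skipped", 0),
    )


def analyze(pbs: PressureBeatSeries, min_len: int = 3, lag: int = 0) -> BRSResult:
    """find_ramps + match_sequences + brs on one beat-aligned recording."""
    seqs = match_sequences(find_ramps(pbs, min_len=min_len), pbs, lag=lag)
    return brs(seqs, lag=lag)


def brs_protocol(
    recording: PressureBeatSeries,
    design: ExperimentDesign | None = None,
    window_s: float = 180.0,
    n_windows: int = 3,
    search_interval: tuple[time, time] = (time(8, 0), time(10, 0)),
    min_len: int = 3,
    lag: int = 0,
) -> BRSResult:
    """Stable-window BRS: the same window selection as the triplicate HRV
    protocol, sequences pooled across windows before averaging."""
    from .hrv import _slice_beats, _stable_windows, clean_rr

    cleaned = clean_rr(recording.beats)
    windows = _stable_windows(cleaned, design, window_s, n_windows, search_interval)
    pooled: list[BaroSequence] = []
    for start, _ in windows:
        keep = (recording.beats.t >= start) & (recording.beats.t <= start + window_s)
        idx = np.where(keep)[0]
        if len(idx) < min_len + 1:
            log.info("window at %.0f s empty or too short; skipped", start)
            continue
        piece = PressureBeatSeries(
            beats=_slice_beats(recording.beats, start, window_s),
            sbp=recording.sbp[idx],
            dbp=None if recording.dbp is None else recording.dbp[idx],
        )
        pooled.extend(match_sequences(find_ramps(piece, min_len=min_len), piece, lag=lag))
    return brs(pooled, lag=lag)
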