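"""Heart-rate-variability analysis of cleaned RR series.

Time domain: mean RR, SDNN (sample SD of normal RR) and RMSSD (root mean
square of successive differences).  Frequency domain: the RR tachogram is
linearly interpolated onto a uniform 50 Hz grid and fed to a Welch
periodogram (1024-point Hanning segments, 50% overlap); band powers are
integrated over the murine VLF (0.01-0.10 Hz), LF (0.10-1.00 Hz) and HF
(1.00-5.00 Hz) bands.  VLF is computed but flagged as excluded from
downstream interpretation.

Because telemetry in awake mice is non-stationary, the protocol-level entry
point ``triplicate_hrv`` analyses three independent stable 3-min windows
between 08:00 and 10:00 and averages the metrics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from datetime import time

import numpy as np
import pandas as pd
from scipy import signal

from .design import ExperimentDesign
from .series import BeatSeries, PressureBeatSeries

log = logging.getLogger(__name__)

#: Spectral bands in Hz, half-open [low, high); a boundary frequency belongs
#: to the upper band.
BANDS: dict[str, tuple[float, float]] = {
    "vlf": (0.01, 0.10),
    "lf": (0.10, 1.00),
    "hf": (1.00, 5.00),
}


@dataclass(frozen=True)
class CleaningParams:
    """Ectopic/artifact flagging rule: deviation from a running median."""

    tolerance_ms: float = 20.0
    window_beats: int = 11

    def __post_init__(self) -> None:
        if self.tolerance_ms <= 0:
            raise ValueError("tolerance_ms must be positive")


@dataclass
class HRVTimeDomain:
    mean_rr: float  # ms
    sdnn: float  # ms
    rmssd: float  # ms
    n_beats: int  # valid RR intervals used
    n_excluded: int


@dataclass
class SpectralResult:
    freqs: np.ndarray
    psd: np.ndarray  # one-sided, ms^2/Hz
    vlf: float  # ms^2 (excluded from interpretation downstream)
    lf: float
    hf: float
    lf_hf: float
    fs: float
    segment_len: int
    overlap_frac: float


def clean_rr(beats: BeatSeries, params: CleaningParams | None = None) -> BeatSeries:
    """Flag ectopic/artifact RR intervals and interpolate over them.

    An interval deviating from the 11-beat running median by more than the
    tolerance (20 ms default) is flagged invalid and its value replaced by
    linear interpolation between neighbouring valid intervals.  The input
    series is left untouched.  If more than 20% of intervals end up flagged
    a warning is logged and ``meta['quality_flag']`` is set.
    """
    params = params or CleaningParams()
    if len(beats.rr) < 10:
        raise ValueError("cleaning requires at least 10 beats")
    rr = beats.rr.copy()
    med = (
        pd.Series(rr)
        .rolling(params.window_beats, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    flagged = np.abs(rr - med) > params.tolerance_ms
    valid = beats.valid & ~flagged
    if not valid.any():
        raise ValueError("no valid RR intervals remain after cleaning")
    idx = np.arange(len(rr))
    rr[~valid] = np.interp(idx[~valid], idx[valid], rr[valid])
    out = BeatSeries(
        t=beats.t.copy(), rr=rr, valid=valid, subject_id=beats.subject_id,
        anchor=beats.anchor, meta=dict(beats.meta),
    )
    frac = float((~valid).mean())
    out.meta["flagged_frac"] = frac
    if frac > 0.20:
        log.warning("%.0f%% of RR intervals flagged; series quality is suspect", 100 * frac)
        out.meta["quality_flag"] = "high_artifact_fraction"
    return out


def time_domain(beats: BeatSeries) -> HRVTimeDomain:
    """Mean RR, SDNN and RMSSD over valid intervals.

    SDNN uses the n-1 denominator.  RMSSD uses successive differences of
    adjacent valid intervals only; pairs spanning an invalid interval are
    excluded.
    """
    rr = beats.rr
    valid = beats.valid
    good = rr[valid]
    if len(good) < 2:
        raise ValueError("time-domain HRV requires at least 2 valid RR intervals")
    pair = valid[:-1] & valid[1:]
    diffs = np.diff(rr)[pair]
    rmssd = float(np.sqrt(np.mean(diffs**2))) if len(diffs) else float("nan")
    return HRVTimeDomain(
        mean_rr=float(np.mean(good)),
        sdnn=float(np.std(good, ddof=1)),
        rmssd=rmssd,
        n_beats=int(valid.sum()),
        n_excluded=int((~valid).sum()),
    )


def resample_tachogram(beats: BeatSeries, fs: float = 50.0) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate the RR tachogram onto a uniform grid.

    The RR series is treated as a function located at the interval-ending
    beat times and interpolated onto a grid spanning the recording at
    ``fs`` Hz.  Returns (time grid s, RR values ms).
    """
    if len(beats.rr) < 2:
        raise ValueError("resampling requires at least 2 RR intervals")
    pos = beats.t[1:]
    grid = np.arange(pos[0], pos[-1], 1.0 / fs)
    return grid, np.interp(grid, pos, beats.rr)


def band_powers(
    freqs: np.ndarray, psd: np.ndarray, bands: dict[str, tuple[float, float]] = BANDS
) -> dict[str, float]:
    """Trapezoidal band powers over half-open [low, high) frequency bands."""
    out = {}
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    for name, (lo, hi) in bands.items():
        m = (freqs >= lo) & (freqs < hi)
        out[name] = float(np.trapezoid(psd[m], freqs[m])) if m.sum() >= 2 else 0.0
    return out


def welch_psd(
    values: np.ndarray,
    fs: float = 50.0,
    segment_len: int = 1024,
    overlap: float = 0.5,
    bands: dict[str, tuple[float, float]] = BANDS,
) -> SpectralResult:
    """Welch periodogram of the resampled tachogram plus band powers.

    Hanning-windowed ``segment_len``-point segments with the given overlap;
    per-segment mean removal; one-sided density normalisation in ms^2/Hz so
    the integral over (0, fs/2] matches the series variance up to windowing
    loss.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < segment_len:
        raise ValueError(
            f"series of {len(x)} samples is shorter than one {segment_len}-point "
            f"segment; need at least {segment_len / fs:.2f} s at {fs:g} Hz"
        )
    freqs, psd = signal.welch(
        x, fs=fs, window="hann", nperseg=segment_len,
        noverlap=int(round(overlap * segment_len)), detrend="constant",
        scaling="density", return_onesided=True,
    )
    if np.ptp(x) == 0:  # constant input: suppress float residue of detrending
        psd = np.zeros_like(psd)
    pw = band_powers(freqs, psd, bands)
    hf = pw.get("hf", 0.0)
    lf = pw.get("lf", 0.0)
    if hf > 0:
        lf_hf = lf / hf
    else:
        warnings.warn("HF power is zero; LF/HF undefined", RuntimeWarning, stacklevel=2)
        lf_hf = float("nan")
    return SpectralResult(
        freqs=freqs, psd=psd, vlf=pw.get("vlf", 0.0), lf=lf, hf=hf, lf_hf=lf_hf,
        fs=fs, segment_len=segment_len, overlap_frac=overlap,
    )


@dataclass
class TriplicateHRV:
    """Averaged triplicate-protocol result with selection audit trail."""

    time_domain: HRVTimeDomain
    spectral: SpectralResult
    window_starts: list[float]  # seconds from recording start
    per_window_time: list[HRVTimeDomain]
    per_window_spectral: list[SpectralResult]


def _stable_windows(
    beats: BeatSeries,
    design: ExperimentDesign | None,
    window_s: float,
    n_windows: int,
    search_interval: tuple[time, time],
    stride_s: float | None = None,
) -> list[tuple[float, float]]:
    """Select the n most stable non-overlapping windows.

    Candidate windows tile the search interval (stride = window length by
    default, so candidates are disjoint and greedy selection is optimal
    within them).  Ranking: lowest artifact fraction, then lowest RR
    variance, then earliest start — an explicit stand-in for by-eye
    selection of stable intervals.
    """
    if stride_s is None:
        stride_s = window_s
    t0, t1 = beats.t[0], beats.t[-1]
    if beats.anchor is not None and search_interval is not None:
        base = (
            beats.anchor.hour * 3600 + beats.anchor.minute * 60 + beats.anchor.second
        )
        lo = (search_interval[0].hour * 3600 + search_interval[0].minute * 60) - base
        hi = (search_interval[1].hour * 3600 + search_interval[1].minute * 60) - base
        t0, t1 = max(t0, lo), min(t1, hi)
    candidates = []
    start = t0
    while start + window_s <= t1 + 1e-9:
        sel = (beats.t[1:] > start) & (beats.t[1:] <= start + window_s)
        if sel.sum() >= 10:
            artifact = float((~beats.valid[sel]).mean())
            var = float(np.var(beats.rr[sel]))
            candidates.append((artifact, var, start))
        start += stride_s
    candidates.sort()
    chosen: list[tuple[float, float]] = []
    for artifact, var, start in candidates:
        if all(start + window_s <= s or start >= s + window_s for s, _ in chosen):
            chosen.append((start, artifact))
        if len(chosen) == n_windows:
            break
    if len(chosen) < n_windows:
        # quality-first packing can strand feasible space; fall back to the
        # best windows on the non-overlapping grid partition
        grid = [c for c in candidates if abs((c[2] - t0) % window_s) < 1e-6]
        if len(grid) >= n_windows:
            chosen = [(start, artifact) for artifact, _, start in grid[:n_windows]]
    if len(chosen) < n_windows:
        raise ValueError(
            f"only {len(chosen)} qualifying {window_s:.0f}-s windows found; "
            f"{n_windows} required"
        )
    return sorted(chosen)


def _slice_beats(beats: BeatSeries, start: float, window_s: float) -> BeatSeries:
    keep = (beats.t >= start) & (beats.t <= start + window_s)
    idx = np.where(keep)[0]
    t = beats.t[idx]
    # interval i ends at beat i+1, so the kept intervals are idx[1:] - 1
    return BeatSeries(
        t=t, rr=beats.rr[idx[1:] - 1], valid=beats.valid[idx[1:] - 1],
        subject_id=beats.subject_id, anchor=beats.anchor,
    )


def triplicate_hrv(
    recording: PressureBeatSeries | BeatSeries,
    design: ExperimentDesign | None = None,
    window_s: float = 180.0,
    n_windows: int = 3,
    search_interval: tuple[time, time] = (time(8, 0), time(10, 0)),
    cleaning: CleaningParams | None = None,
    fs: float = 50.0,
    segment_len: int = 1024,
) -> TriplicateHRV:
    """Triplicate stable-window HRV: clean, select, analyse, average.

    Selects ``n_windows`` non-overlapping windows of ``window_s`` seconds
    with the lowest artifact fraction (ties: lowest RR variance, then
    earliest), computes time- and frequency-domain metrics per window and
    returns their arithmetic means together with the window start times.
    """
    beats = recording.beats if isinstance(recording, PressureBeatSeries) else recording
    cleaned = clean_rr(beats, cleaning)
    windows = _stable_windows(cleaned, design, window_s, n_windows, search_interval)
    tds, sps, starts = [], [], []
    for start, _ in windows:
        piece = _slice_beats(cleaned, start, window_s)
        tds.append(time_domain(piece))
        _, vals = resample_tachogram(piece, fs=fs)
        sps.append(welch_psd(vals, fs=fs, segment_len=segment_len))
        starts.append(float(start))
    mean_td = HRVTimeDomain(
        mean_rr=float(np.mean([d.mean_rr for d in tds])),
        sdnn=float(np.mean([d.sdnn for d in tds])),
        rmssd=float(np.mean([d.rmssd for d in tds])),
        n_beats=int(np.sum([d.n_beats for d in tds])),
        n_excluded=int(np.sum([d.n_excluded for d in tds])),
    )
    mean_sp = SpectralResult(
        freqs=sps[0].freqs,
        psd=np.mean([s.psd for s in sps], axis=0),
        vlf=float(np.mean([s.vlf for s in sps])),
        lf=float(np.mean([s.lf for s in sps])),
        hf=float(np.mean([s.hf for s in sps])),
        lf_hf=float(np.mean([s.lf_hf for s in sps])),
        fs=fs, segment_len=segment_len, overlap_frac=sps[0].overlap_frac,
    )
    return TriplicateHRV(
        time_domain=mean_td, spectral=mean_sp, window_starts=starts,
        per_window_time=tds, per_window_spectral=sps,
    )
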