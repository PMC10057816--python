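"""Seeded synthetic telemetry with known ground truth.

Every generator is a pure function of its spec (including the seed), so any
downstream estimate — spectral band power, baroreflex gain, cosinor
parameters, phase effects — can be compared against the construction truth
without re-reading configuration.

Beat series come from an integral pulse frequency modulation (IPFM) model:
an instantaneous RR signal (mean plus LF/HF sinusoids) defines a continuous
beat rate whose integral emits a beat at every unit crossing.  Defining the
oscillations in continuous time, rather than adding sinusoids to discrete RR
values, means the resampling + Welch chain is exercised on exactly the kind
of signal it assumes.

Ectopic beats are injected with the standard morphology: the affected beat
fires early (0.6 of its RR interval) and the next interval absorbs the
compensatory pause, leaving total time unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, time, timedelta

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.signal import lfilter

from .design import CONTROL, RECOVERY, UNLOADING, ExperimentDesign, light_labels
from .series import BeatSeries, ChannelSeries, PressureBeatSeries

# -- specs ------------------------------------------------------------------


@dataclass(frozen=True)
class RRGenSpec:
    """IPFM beat-series spec: mean RR, LF/HF sinusoids, noise, ectopics.

    Components are (frequency Hz, amplitude ms) pairs constrained to the
    murine LF (0.10-1.00 Hz) and HF (1.00-5.00 Hz) bands.
    """

    mean_rr: float = 100.0  # ms
    lf_component: tuple[float, float] | None = (0.4, 3.0)
    hf_component: tuple[float, float] | None = (2.5, 3.0)
    noise_sd: float = 0.0  # ms, white per-beat
    ectopic_rate: float = 0.0  # probability per beat
    duration: float = 180.0  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_rr <= 0:
            raise ValueError("mean_rr must be positive")
        if self.lf_component is not None:
            f = self.lf_component[0]
            if not (0.10 <= f < 1.00):
                raise ValueError("LF component frequency must lie in [0.10, 1.00) Hz")
        if self.hf_component is not None:
            f = self.hf_component[0]
            if not (1.00 <= f < 5.00):
                raise ValueError("HF component frequency must lie in [1.00, 5.00) Hz")
        if not (0 <= self.ectopic_rate < 1):
            raise ValueError("ectopic_rate must lie in [0, 1)")


@dataclass(frozen=True)
class BaroGenSpec:
    """Baroreflex coupling spec: true gain, SBP ramp process, RR noise."""

    gain: float = 1.5  # ms/mmHg, the true BRS
    sbp_base: float = 120.0  # mmHg
    ramp_rate: float = 7.0  # injected ramps per minute
    ramp_len: int = 4  # beats per ramp
    ramp_step: float = 2.5  # mmHg per beat within a ramp
    rr_noise_sd: float = 0.0  # ms
    lag: int = 0  # beats between SBP and RR response
    walk_sd: float = 0.1  # mmHg, mean-reverting between-ramp walk
    quantum: float = 0.5  # mmHg, pressure digitisation step (0 disables)
    pulse_pressure: float = 30.0  # mmHg, SBP - DBP
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.gain):
            raise ValueError("gain must be finite")
        if self.ramp_len < 3:
            raise ValueError("ramp_len must be >= 3 beats")
        if self.ramp_step <= 0:
            raise ValueError("ramp_step must be positive")
        if self.lag < 0:
            raise ValueError("lag must be non-negative")


@dataclass(frozen=True)
class CircadianGenSpec:
    """Circadian channel spec: cosine + LC/DC square wave + noise.

    The noiseless signal is
    ``M + A * [(1 - w) * cos(2*pi*t/tau + phi) + w * step(t)]`` with
    ``w = square_wave_frac`` and ``step`` equal to -1 during the light cycle
    and +1 during the dark cycle (rodents are nocturnally active).  The
    square-wave term models the step-like component of rodent behaviour that
    a pure cosine cannot capture.
    """

    mesor: float = 33.8
    amplitude: float = 0.8
    acrophase: float = -0.7  # radians, reference = local midnight
    period_h: float = 24.0
    square_wave_frac: float = 0.0
    noise_sd: float = 0.0
    sampling_interval_min: float = 5.0
    days: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.period_h <= 0:
            raise ValueError("period must be positive")
        if not (0 <= self.square_wave_frac <= 1):
            raise ValueError("square_wave_frac must lie in [0, 1]")


@dataclass(frozen=True)
class HUEffectSpec:
    """Per-phase effects of hindlimb unloading on each channel.

    Defaults reproduce the headline phase effects: 85% drop in locomotor
    activity throughout HU, 11% HR drop at the HU1 nadir (half persisting at
    HU2), recovery tachycardia, ~1.1 degC temperature drop, ~6 mmHg SBP rise
    and a 70% attenuation of every channel's circadian amplitude during HU.
    """

    activity_drop_frac: float = 0.85
    hr_drop_frac: float = 0.11
    hr_rise_frac: float = 0.044
    temp_drop: float = 1.1  # degC
    sbp_rise: float = 6.0  # mmHg
    amplitude_atten_frac: float = 0.7

    def __post_init__(self) -> None:
        for name in ("activity_drop_frac", "hr_drop_frac", "hr_rise_frac", "amplitude_atten_frac"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")


# -- beat-level generators --------------------------------------------------


def gen_rr(spec: RRGenSpec) -> tuple[BeatSeries, np.ndarray]:
    """Generate an IPFM beat series; returns (series, ectopic truth mask).

    The truth mask flags RR intervals perturbed by ectopic injection (the
    early interval and its compensatory pause).  With zero amplitudes and
    zero noise all RR equal ``mean_rr`` exactly.
    """
    rng = np.random.default_rng(spec.seed)
    comps = [c for c in (spec.lf_component, spec.hf_component) if c is not None and c[1] > 0]
    if not comps and spec.noise_sd == 0:
        n = int(round(spec.duration * 1000.0 / spec.mean_rr))
        rr = np.full(n, float(spec.mean_rr))
    else:
        dt = 1e-3
        pad = 2.0 * spec.mean_rr / 1000.0
        tg = np.arange(0.0, spec.duration + pad, dt)
        rr_inst = np.full_like(tg, spec.mean_rr)
        for f, amp in comps:
            ph = rng.uniform(0, 2 * np.pi)
            rr_inst += amp * np.cos(2 * np.pi * f * tg + ph)
        if np.any(rr_inst <= 0):
            raise ValueError("component amplitudes exceed mean RR; rate undefined")
        rate = 1000.0 / rr_inst  # beats per second
        integral = cumulative_trapezoid(rate, dx=dt, initial=0.0)
        n = int(integral[-1])
        tb = np.interp(np.arange(1, n + 1, dtype=float), integral, tg)
        rr = np.diff(np.concatenate(([0.0], tb))) * 1000.0
        if spec.noise_sd > 0:
            rr = rr + rng.normal(0.0, spec.noise_sd, len(rr))
    ectopic = np.zeros(len(rr), dtype=bool)
    if spec.ectopic_rate > 0:
        hits = np.where(rng.random(len(rr)) < spec.ectopic_rate)[0]
        for i in hits:
            if i < 1 or i >= len(rr) - 1 or ectopic[i - 1 : i + 2].any():
                continue
            early = 0.4 * rr[i]
            rr[i] -= early
            rr[i + 1] += early
            ectopic[i] = ectopic[i + 1] = True
    t = np.concatenate(([0.0], np.cumsum(rr) / 1000.0))
    return BeatSeries(t=t, rr=rr), ectopic


def gen_coupled_bp(beats: BeatSeries, spec: BaroGenSpec) -> tuple[PressureBeatSeries, dict]:
    """Couple beat-aligned SBP to the RR series with a known baroreflex gain.

    SBP follows a mean-reverting random walk with inserted monotone ramps;
    the RR response is ``rr[i + lag] += gain * (sbp[i] - sbp_base) + noise``
    on the interval-aligned arrays.  With ``rr_noise_sd = 0`` and a matching
    analyzer lag the sequence method recovers ``gain`` exactly.
    """
    rng = np.random.default_rng(spec.seed)
    rr = beats.rr.copy()
    n = len(rr)
    # AR(1) walk around sbp_base: s[i] = base + 0.9*(s[i-1]-base) + e[i],
    # digitised to the telemetry pressure resolution.  Quantisation makes
    # small between-ramp fluctuations tie out, as in recorded pressures, so
    # that detected sequences are dominated by genuine ramps.
    innov = rng.normal(0.0, spec.walk_sd, n)
    sbp_a = spec.sbp_base + lfilter([1.0], [1.0, -0.9], innov)
    if spec.quantum > 0:
        sbp_a = np.round(sbp_a / spec.quantum) * spec.quantum
    duration_min = (beats.t[-1] - beats.t[0]) / 60.0
    n_ramps = int(round(spec.ramp_rate * duration_min))
    starts: list[int] = []
    directions: list[int] = []
    if n_ramps > 0 and n > spec.ramp_len:
        candidates = rng.permutation(n - spec.ramp_len)
        occupied = np.zeros(n, dtype=bool)
        for c in candidates:
            if len(starts) >= n_ramps:
                break
            lo, hi = max(0, c - 1), min(n, c + spec.ramp_len + 1)
            if occupied[lo:hi].any():
                continue
            occupied[lo:hi] = True
            starts.append(int(c))
            directions.append(int(rng.choice((-1, 1))))
        order = np.argsort(starts)
        starts = [starts[i] for i in order]
        directions = [directions[i] for i in order]
        for c, d in zip(starts, directions):
            base = sbp_a[c]
            sbp_a[c : c + spec.ramp_len] = base + d * spec.ramp_step * np.arange(spec.ramp_len)
    delta = spec.gain * (sbp_a - spec.sbp_base)
    m = n - spec.lag
    rr[spec.lag :] += delta[:m]
    if spec.rr_noise_sd > 0:
        rr[spec.lag :] += rng.normal(0.0, spec.rr_noise_sd, m)
    t = beats.t[0] + np.concatenate(([0.0], np.cumsum(rr) / 1000.0))
    out_beats = BeatSeries(
        t=t, rr=rr, valid=beats.valid.copy(), subject_id=beats.subject_id,
        anchor=beats.anchor, meta=dict(beats.meta),
    )
    sbp_full = np.concatenate(([spec.sbp_base], sbp_a))
    dbp_full = sbp_full - spec.pulse_pressure
    truth = {
        "gain": spec.gain,
        "n_ramps": len(starts),
        "ramp_starts": np.asarray(starts, dtype=int),  # aligned (interval) indices
        "directions": np.asarray(directions, dtype=int),
    }
    return PressureBeatSeries(beats=out_beats, sbp=sbp_full, dbp=dbp_full), truth


# -- channel-level generators -----------------------------------------------


def circadian_signal(hours: np.ndarray, lc_mask: np.ndarray, spec: CircadianGenSpec) -> np.ndarray:
    """Noiseless circadian waveform at the given hours-since-midnight grid."""
    w = spec.square_wave_frac
    cosine = np.cos(2 * np.pi * hours / spec.period_h + spec.acrophase)
    step = np.where(lc_mask, -1.0, 1.0)
    return spec.mesor + spec.amplitude * ((1 - w) * cosine + w * step)


def gen_circadian(
    spec: CircadianGenSpec,
    design: ExperimentDesign | None = None,
    channel: str = "temperature_subcutaneous",
    subject_id: str = "sim",
) -> ChannelSeries:
    """Generate a circadian channel sampled from local midnight of day 1."""
    if design is None:
        design = ExperimentDesign()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.days * 24 * 60 / spec.sampling_interval_min))
    hours = np.arange(n) * spec.sampling_interval_min / 60.0
    t0 = np.datetime64(datetime.combine(design.start_date, time(0)))
    ts = t0 + (hours * 3600e9).astype("timedelta64[ns]")
    lc = light_labels(ts, design) == "LC"
    y = circadian_signal(hours, lc, spec)
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, n)
    return ChannelSeries.build(t=ts, value=y, channel=channel, subject_id=subject_id, design=design)


DEFAULT_CIRCADIAN: dict[str, CircadianGenSpec] = {
    # Control-period parameters per channel (mesor, amplitude, acrophase rad).
    "activity": CircadianGenSpec(mesor=0.26, amplitude=0.18, acrophase=-1.10,
                                 square_wave_frac=0.5, noise_sd=0.05),
    "temperature_subcutaneous": CircadianGenSpec(mesor=33.81, amplitude=0.78, acrophase=-0.69,
                                                 square_wave_frac=0.3, noise_sd=0.3),
    "sbp": CircadianGenSpec(mesor=128.3, amplitude=6.32, acrophase=-0.76,
                            square_wave_frac=0.2, noise_sd=5.0),
    "dbp": CircadianGenSpec(mesor=102.3, amplitude=5.37, acrophase=-1.18,
                            square_wave_frac=0.2, noise_sd=5.0),
    "hr": CircadianGenSpec(mesor=590.6, amplitude=18.2, acrophase=0.30,
                           square_wave_frac=0.2, noise_sd=25.0),
}

# Spontaneous BRS gain multipliers by phase: vagal rise early in HU, decline
# late in HU and at reloading.
BRS_PHASE_FACTOR = {
    "HU1": 1.35, "HU2": 1.35, "HU4": 0.75, "HU5": 0.75, "R+1": 0.70, "R+2": 0.85,
}


def _phase_params(channel: str, phase: str, cond: str, hu: HUEffectSpec,
                  mesor: float, amplitude: float) -> tuple[float, float]:
    """Effective (mesor, amplitude) for one channel on one experiment day."""
    m, a = mesor, amplitude
    if cond == UNLOADING:
        a *= 1 - hu.amplitude_atten_frac
        if channel == "activity":
            m *= 1 - hu.activity_drop_frac
            a *= 1 - hu.activity_drop_frac
        elif channel.startswith("temperature"):
            m -= hu.temp_drop
        elif channel == "sbp":
            m += hu.sbp_rise
        elif channel == "dbp":
            m += 0.7 * hu.sbp_rise
        elif channel == "hr":
            if phase == "HU1":
                m *= 1 - hu.hr_drop_frac
                a *= 1 - hu.hr_drop_frac
            elif phase == "HU2":
                m *= 1 - hu.hr_drop_frac / 2
                a *= 1 - hu.hr_drop_frac / 2
    elif cond == RECOVERY and channel == "hr":
        m *= 1 + hu.hr_rise_frac
        a *= 1 + hu.hr_rise_frac
    return m, a


@dataclass
class ExperimentData:
    """A complete synthetic multi-subject experiment plus its ground truth."""

    design: ExperimentDesign
    channels: list[ChannelSeries]
    beats: dict[tuple[str, str], PressureBeatSeries]  # (subject, phase) -> series
    truth_channels: pd.DataFrame
    truth_beats: pd.DataFrame

    def write(self, out_dir) -> None:
        """Emit the canonical CSV layouts plus the truth table."""
        import os

        from .io import write_beats, write_channels

        os.makedirs(out_dir, exist_ok=True)
        write_channels(self.channels, os.path.join(out_dir, "channels.csv"))
        beat_dir = os.path.join(out_dir, "beats")
        os.makedirs(beat_dir, exist_ok=True)
        for (subj, phase), pbs in self.beats.items():
            safe = phase.replace("+", "p").replace("-", "m")
            write_beats(pbs, os.path.join(beat_dir, f"{subj}_{safe}.csv"))
        self.truth_channels.to_csv(os.path.join(out_dir, "truth_channels.csv"), index=False)
        self.truth_beats.to_csv(os.path.join(out_dir, "truth_beats.csv"), index=False)


def gen_experiment(
    design: ExperimentDesign | None = None,
    circ: dict[str, CircadianGenSpec] | None = None,
    hu: HUEffectSpec | None = None,
    n_subjects: int = 8,
    seed: int = 0,
    include_beats: bool = False,
    beat_duration_s: float = 1200.0,
    brs_base_gain: float = 1.5,
    subject_cv: tuple[float, float, float] = (0.02, 0.15, 0.25),
) -> ExperimentData:
    """Generate complete per-subject datasets for the 10-day protocol.

    Channel values follow the per-channel circadian specs with per-day
    mesor/amplitude effects from ``hu`` and mild between-subject variation
    (``subject_cv``: fractional SD of mesor, fractional SD of amplitude, SD
    of acrophase in radians).  When ``include_beats`` is set, each subject
    additionally gets one beat-level pressure recording per day anchored at
    08:00 (the morning analysis window) with a phase-dependent true BRS
    gain.
    """
    design = design or ExperimentDesign()
    circ = circ or DEFAULT_CIRCADIAN
    hu = hu or HUEffectSpec()
    root = np.random.default_rng(seed)
    channels: list[ChannelSeries] = []
    beats: dict[tuple[str, str], PressureBeatSeries] = {}
    truth_c: list[dict] = []
    truth_b: list[dict] = []
    n_days = len(design.phase_labels)
    for s in range(n_subjects):
        subject = f"m{s + 1:02d}"
        srng = np.random.default_rng(root.integers(0, 2**31 - 1))
        for channel, base in circ.items():
            mesor_s = base.mesor * (1 + srng.normal(0, subject_cv[0]))
            amp_s = max(base.amplitude * (1 + srng.normal(0, subject_cv[1])), 0.0)
            phi_s = base.acrophase + srng.normal(0, subject_cv[2])
            n_per_day = int(round(24 * 60 / base.sampling_interval_min))
            hours = np.arange(n_days * n_per_day) * base.sampling_interval_min / 60.0
            t0 = np.datetime64(datetime.combine(design.start_date, time(0)))
            ts = t0 + (hours * 3600e9).astype("timedelta64[ns]")
            lc = light_labels(ts, design) == "LC"
            day_idx = (hours // 24).astype(int)
            m_arr = np.empty_like(hours)
            a_arr = np.empty_like(hours)
            for d, phase in enumerate(design.phase_labels):
                cond = design.condition_of(phase)
                m_d, a_d = _phase_params(channel, phase, cond, hu, mesor_s, amp_s)
                sel = day_idx == d
                m_arr[sel] = m_d
                a_arr[sel] = a_d
                truth_c.append({
                    "subject_id": subject, "channel": channel, "phase": phase,
                    "mesor": m_d, "amplitude": a_d, "acrophase": phi_s,
                    "square_wave_frac": base.square_wave_frac, "noise_sd": base.noise_sd,
                })
            w = base.square_wave_frac
            cosine = np.cos(2 * np.pi * hours / base.period_h + phi_s)
            step = np.where(lc, -1.0, 1.0)
            y = m_arr + a_arr * ((1 - w) * cosine + w * step)
            if base.noise_sd > 0:
                y = y + srng.normal(0.0, base.noise_sd, len(y))
            channels.append(ChannelSeries.build(
                t=ts, value=y, channel=channel, subject_id=subject, design=design))
        if include_beats:
            hr_spec = circ.get("hr", DEFAULT_CIRCADIAN["hr"])
            for phase in design.phase_labels:
                cond = design.condition_of(phase)
                hr_eff, _ = _phase_params("hr", phase, cond, hu, hr_spec.mesor, hr_spec.amplitude)
                gain = brs_base_gain * BRS_PHASE_FACTOR.get(phase, 1.0)
                # reflex-independent RR modulation competes with the SBP-RR
                # coupling in sequence detection; amplitudes are kept modest
                # so detected counts land near the ~20-per-analysis regime
                rr_spec = RRGenSpec(
                    mean_rr=60000.0 / hr_eff, lf_component=(0.4, 1.0),
                    hf_component=(2.5, 1.0), noise_sd=0.8, ectopic_rate=0.003,
                    duration=beat_duration_s, seed=int(srng.integers(0, 2**31 - 1)),
                )
                base_beats, ect = gen_rr(rr_spec)
                bp_spec = BaroGenSpec(gain=gain, rr_noise_sd=0.8,
                                      seed=int(srng.integers(0, 2**31 - 1)))
                pbs, bp_truth = gen_coupled_bp(base_beats, bp_spec)
                pbs.beats.subject_id = subject
                pbs.beats.anchor = datetime.combine(design.phase_date(phase), time(8, 0))
                pbs.beats.meta["ectopic_truth"] = ect
                beats[(subject, phase)] = pbs
                truth_b.append({
                    "subject_id": subject, "phase": phase, "brs_gain": gain,
                    "mean_rr_ms": rr_spec.mean_rr, "n_ramps": bp_truth["n_ramps"],
                    "n_ectopic": int(ect.sum()),
                })
    return ExperimentData(
        design=design,
        channels=channels,
        beats=beats,
        truth_channels=pd.DataFrame(truth_c),
        truth_beats=pd.DataFrame(truth_b),
    )
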