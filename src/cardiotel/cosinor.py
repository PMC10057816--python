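"""Single-component fixed-period cosinor rhythmometry.

Model: ``Y(t) = M + A*cos(2*pi*t/tau + phi) + e`` with the period tau fixed
(24 h by default).  The fit is linearised as
``Y = M + beta*cos(omega t) + gamma*sin(omega t)`` and solved by least
squares; then ``A = sqrt(beta^2 + gamma^2)`` and
``phi = atan2(-gamma, beta)`` in (-pi, pi].  The time origin for the
acrophase is local midnight of the first day of the series, so ``-phi *
tau / (2*pi)`` is the clock hour of the fitted peak.

Rhythm detection is the zero-amplitude F test:
``F = (model SS / 2) / (RSS / (n - 3))`` on (2, n-3) degrees of freedom.
Group-level summaries average per-subject fits (mean +/- SD; acrophase via
circular statistics) and test the group rhythm with the population-mean
cosinor test (Hotelling T^2 on the per-subject (beta, gamma) pairs).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import CONTROL, RECOVERY, UNLOADING, ExperimentDesign
from .series import ChannelSeries

log = logging.getLogger(__name__)

_TWO_PI = 2 * np.pi


def wrap_angle(phi) -> np.ndarray | float:
    """Wrap angles to (-pi, pi]."""
    out = -(np.mod(-np.asarray(phi, dtype=float) + np.pi, _TWO_PI) - np.pi)
    return float(out) if np.isscalar(phi) or np.ndim(phi) == 0 else out


def acrophase_to_hours(phi: float, period_h: float = 24.0) -> float:
    """Clock hour (after the reference midnight) of the fitted peak."""
    return float((-phi % _TWO_PI) / _TWO_PI * period_h)


@dataclass
class CosinorFit:
    mesor: float
    amplitude: float
    acrophase: float  # radians in (-pi, pi], reference local midnight
    period_h: float
    beta: float  # cosine coefficient
    gamma: float  # sine coefficient
    rss: float
    mss: float  # model sum of squares attributable to (beta, gamma)
    n: int
    p_rhythm: float
    channel: str = ""
    subject_id: str = ""
    condition: str = ""

    @property
    def acrophase_hours(self) -> float:
        return acrophase_to_hours(self.acrophase, self.period_h)


def fit_cosinor(series: ChannelSeries, period_h: float = 24.0,
                condition: str = "") -> CosinorFit:
    """Least-squares cosinor fit of one subject's channel series.

    Requires at least 4 finite samples spanning a full period and a
    full-rank design (samples not all at one clock time).
    """
    t = np.asarray(series.t, dtype="datetime64[ns]")
    y = np.asarray(series.value, dtype=float)
    ok = np.isfinite(y)
    t, y = t[ok], y[ok]
    n = len(y)
    if n < 4:
        raise ValueError(f"cosinor fit requires >= 4 samples; got {n}")
    day0 = t.min().astype("datetime64[D]")
    hours = (t - day0) / np.timedelta64(1, "h")
    span = float(hours.max() - hours.min())
    if span < period_h:
        raise ValueError(
            f"series spans {span:.1f} h; at least one full period "
            f"({period_h:g} h) is required"
        )
    omega = _TWO_PI / period_h
    X = np.column_stack([np.ones(n), np.cos(omega * hours), np.sin(omega * hours)])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 3:
        raise ValueError("rank-deficient cosinor design (samples at a single clock time?)")
    mesor, beta, gamma = (float(c) for c in coef)
    resid = y - X @ coef
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    mss = max(tss - rss, 0.0)
    fit = CosinorFit(
        mesor=mesor,
        amplitude=float(np.hypot(beta, gamma)),
        acrophase=wrap_angle(np.arctan2(-gamma, beta)),
        period_h=period_h, beta=beta, gamma=gamma, rss=rss, mss=mss, n=n,
        p_rhythm=float("nan"), channel=series.channel,
        subject_id=series.subject_id, condition=condition,
    )
    fit.p_rhythm = rhythm_test(fit)
    return fit


def rhythm_test(fit: CosinorFit) -> float:
    """Zero-amplitude F test p-value for one fit.

    ``F = (MSS/2) / (RSS/(n-3))`` against F(2, n-3).  A perfect (noiseless)
    fit underflows to p = 0.
    """
    if fit.n <= 3:
        warnings.warn("rhythm test needs n > 3; returning NaN", RuntimeWarning, stacklevel=2)
        return float("nan")
    if fit.rss <= 0:
        return 0.0
    F = (fit.mss / 2.0) / (fit.rss / (fit.n - 3))
    return float(stats.f.sf(F, 2, fit.n - 3))


@dataclass
class GroupCosinor:
    channel: str
    condition: str
    n: int
    mesor_mean: float
    mesor_sd: float
    amplitude_mean: float
    amplitude_sd: float
    acrophase_mean: float  # circular mean, radians
    acrophase_sd: float  # arithmetic SD after unwrapping to the mean's branch
    p_rhythm_group: float  # population-mean cosinor zero-amplitude test
    fits: list[CosinorFit] = field(default_factory=list)


def _population_mean_test(betas: np.ndarray, gammas: np.ndarray) -> float:
    """Population-mean cosinor zero-amplitude test (Hotelling T^2).

    Tests whether the population mean (beta, gamma) vector is zero across
    subjects; F = k(k-2)/(2(k-1)) * m' S^-1 m on (2, k-2) df.
    """
    k = len(betas)
    if k < 3:
        warnings.warn("population-mean rhythm test needs >= 3 subjects",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    m = np.array([betas.mean(), gammas.mean()])
    S = np.cov(np.vstack([betas, gammas]), ddof=1)
    det = np.linalg.det(S)
    if not np.isfinite(det) or det <= 0:
        # degenerate dispersion (e.g. identical fits): rhythm is either
        # exactly absent or exactly shared
        return 1.0 if np.allclose(m, 0) else 0.0
    t2 = k * float(m @ np.linalg.solve(S, m))
    F = (k - 2) / (2.0 * (k - 1)) * t2
    return float(stats.f.sf(F, 2, k - 2))


def group_cosinor(fits: list[CosinorFit]) -> GroupCosinor:
    """Aggregate per-subject fits: mean +/- SD, circular acrophase stats and
    the population-mean rhythm test."""
    if len(fits) < 2:
        raise ValueError("group summary requires at least 2 subject fits")
    channels = {f.channel for f in fits}
    if len(channels) > 1:
        raise ValueError(f"mixed channels in group: {sorted(channels)}")
    conditions = {f.condition for f in fits}
    mes = np.array([f.mesor for f in fits])
    amp = np.array([f.amplitude for f in fits])
    phi = np.array([f.acrophase for f in fits])
    z = np.exp(1j * phi).mean()
    circ_mean = float(np.angle(z)) if np.abs(z) > 0 else float("nan")
    unwrapped = circ_mean + wrap_angle(phi - circ_mean)
    betas = np.array([f.beta for f in fits])
    gammas = np.array([f.gamma for f in fits])
    return GroupCosinor(
        channel=channels.pop(),
        condition=conditions.pop() if len(conditions) == 1 else "mixed",
        n=len(fits),
        mesor_mean=float(mes.mean()), mesor_sd=float(mes.std(ddof=1)),
        amplitude_mean=float(amp.mean()), amplitude_sd=float(amp.std(ddof=1)),
        acrophase_mean=wrap_angle(circ_mean),
        acrophase_sd=float(np.std(unwrapped, ddof=1)),
        p_rhythm_group=_population_mean_test(betas, gammas),
        fits=list(fits),
    )


def cosinor_by_condition(
    series_list: list[ChannelSeries],
    design: ExperimentDesign,
    period_h: float = 24.0,
) -> tuple[pd.DataFrame, dict[str, GroupCosinor]]:
    """Per-condition group cosinor table for one channel across subjects.

    Each subject's series is split into Control / Unloading / Recovery by
    its phase labels, fitted per condition, and aggregated.  Cells whose
    data cannot support a fit (e.g. less than one full period) are left
    missing with the reason logged.  Returns the summary table (layout:
    parameter rows x condition columns) and the per-condition group
    results.
    """
    conditions = (CONTROL, UNLOADING, RECOVERY)
    per_cond: dict[str, list[CosinorFit]] = {c: [] for c in conditions}
    for s in series_list:
        if s.phase is None:
            raise ValueError("series must carry phase labels (use ChannelSeries.build)")
        conds = np.array([design.condition_of(p) if p else "" for p in s.phase])
        for cond in conditions:
            sub = s.subset(conds == cond)
            if len(sub) == 0:
                continue
            try:
                per_cond[cond].append(fit_cosinor(sub, period_h=period_h, condition=cond))
            except ValueError as exc:
                log.info("cosinor fit skipped (%s, %s, %s): %s",
                         s.subject_id, s.channel, cond, exc)
    groups: dict[str, GroupCosinor] = {}
    rows = ["MESOR", "MESOR_sd", "Acrophase", "Acrophase_sd",
            "Amplitude", "Amplitude_sd", "Rhythm_p", "n"]
    table = pd.DataFrame(index=rows, columns=list(conditions), dtype=float)
    for cond in conditions:
        fits = per_cond[cond]
        if len(fits) < 2:
            log.info("condition %s has %d fit(s); group cell left missing", cond, len(fits))
            continue
        g = group_cosinor(fits)
        groups[cond] = g
        table.loc[:, cond] = [
            g.mesor_mean, g.mesor_sd, g.acrophase_mean, g.acrophase_sd,
            g.amplitude_mean, g.amplitude_sd, g.p_rhythm_group, g.n,
        ]
    return table, groups
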