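"""Day-level and light/dark summarisation, percent change and report assembly.

Daily summaries give, per subject and experiment day, the 24 h mean and the
12 h light-cycle (LC) / dark-cycle (DC) means, always excluding the daily
handling window (10:00-11:00 by default) — so the "24 h mean" is computed
over the 23 retained hours.  Percent changes are referenced to the last
control day (C-1), computed per subject and then averaged, with the pooled
order emitted alongside as a robustness column.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import ExperimentDesign, in_excluded_window, light_labels, phase_labels_for
from .series import ChannelSeries

log = logging.getLogger(__name__)

SUMMARY_COLUMNS = [
    "subject_id", "phase", "channel", "mean_24h", "lc_mean", "dc_mean",
    "n_samples", "n_excluded",
]

REPORT_SCHEMA: dict[str, list[str]] = {
    "daily_summaries": SUMMARY_COLUMNS,
    "percent_change": ["channel", "phase", "reference", "pct_change",
                       "pct_change_pooled", "absolute_change"],
    "hrv": ["subject_id", "phase", "mean_rr", "sdnn", "rmssd", "lf", "hf", "lf_hf"],
    "brs": ["subject_id", "phase", "brs", "n_up", "n_down", "n_sequences"],
    "cosinor": ["channel", "condition", "parameter", "value"],
}


def daily_summaries(
    series: ChannelSeries | list[ChannelSeries], design: ExperimentDesign
) -> pd.DataFrame:
    """Per subject x day: 24 h, LC and DC means with handling-hour exclusion.

    Days with zero retained samples are omitted (logged with the reason).
    """
    if isinstance(series, ChannelSeries):
        series = [series]
    rows = []
    for s in series:
        lp = s.light_phase if s.light_phase is not None else light_labels(s.t, design)
        ph = s.phase if s.phase is not None else phase_labels_for(s.t, design)
        excluded = in_excluded_window(s.t, design)
        df = pd.DataFrame({
            "value": s.value, "light": np.asarray(lp), "phase": np.asarray(ph),
            "excluded": excluded,
        })
        df = df[df["phase"] != ""]
        for phase, grp in df.groupby("phase", sort=False):
            keep = grp[~grp["excluded"]]
            n_excl = int(grp["excluded"].sum())
            if len(keep) == 0:
                log.info("subject %s day %s: zero retained samples; row omitted",
                         s.subject_id, phase)
                continue
            lc = keep.loc[keep["light"] == "LC", "value"]
            dc = keep.loc[keep["light"] == "DC", "value"]
            rows.append({
                "subject_id": s.subject_id, "phase": phase, "channel": s.channel,
                "mean_24h": float(keep["value"].mean()),
                "lc_mean": float(lc.mean()) if len(lc) else float("nan"),
                "dc_mean": float(dc.mean()) if len(dc) else float("nan"),
                "n_samples": int(len(keep)), "n_excluded": n_excl,
            })
    out = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    order = {p: i for i, p in enumerate(design.phase_labels)}
    return out.sort_values(
        ["channel", "subject_id", "phase"],
        key=lambda c: c.map(order) if c.name == "phase" else c,
        kind="stable",
    ).reset_index(drop=True)


def percent_change(summaries: pd.DataFrame, reference: str = "C-1") -> pd.DataFrame:
    """Per channel x day change of the 24 h mean vs the reference day.

    ``pct_change`` is computed per subject then averaged across subjects;
    ``pct_change_pooled`` averages subjects first (robustness column).  A
    zero reference leaves the percent column missing but keeps the absolute
    change.
    """
    rows = []
    for channel, grp in summaries.groupby("channel", sort=True):
        wide = grp.pivot_table(index="subject_id", columns="phase",
                               values="mean_24h", aggfunc="mean")
        if reference not in wide.columns:
            raise ValueError(f"reference day {reference!r} absent for channel {channel}")
        ref = wide[reference]
        for phase in wide.columns:
            tgt = wide[phase]
            with np.errstate(divide="ignore", invalid="ignore"):
                per_subj = 100.0 * (tgt - ref) / ref.where(ref != 0)
            pooled_ref = ref.mean()
            pooled = (
                100.0 * (tgt.mean() - pooled_ref) / pooled_ref
                if pooled_ref != 0 else float("nan")
            )
            rows.append({
                "channel": channel, "phase": phase, "reference": reference,
                "pct_change": float(per_subj.mean()) if per_subj.notna().any() else float("nan"),
                "pct_change_pooled": pooled,
                "absolute_change": float((tgt - ref).mean()),
            })
    return pd.DataFrame(rows, columns=REPORT_SCHEMA["percent_change"])


def bin_series(
    series: ChannelSeries,
    design: ExperimentDesign,
    width_h: float = 2.0,
    label: str = "mid",
) -> ChannelSeries:
    """Average a channel into fixed-width bins anchored at local midnight.

    ``label`` places the output timestamps at the bin midpoint (``"mid"``,
    the convention used for cosinor fitting) or the bin start (``"start"``,
    the deposited-layout convention).  Light/dark labels are always
    assigned by bin start time, since the 2 h grid aligns with the 07:00
    lights-on boundary.  Empty bins are simply missing from the output.
    """
    if label not in ("mid", "start"):
        raise ValueError("label must be 'mid' or 'start'")
    t = np.asarray(series.t, dtype="datetime64[ns]")
    day0 = t.min().astype("datetime64[D]").astype("datetime64[ns]")
    width = np.timedelta64(int(width_h * 3600e9), "ns")
    idx = ((t - day0) / width).astype(int)
    df = pd.DataFrame({"bin": idx, "value": series.value})
    agg = df.groupby("bin", sort=True)["value"].mean()
    starts = day0 + agg.index.to_numpy() * width
    stamps = starts + (width // 2 if label == "mid" else np.timedelta64(0, "ns"))
    out = ChannelSeries(
        t=stamps, value=agg.to_numpy(), channel=series.channel,
        subject_id=series.subject_id,
    )
    out.light_phase = light_labels(starts, design)
    out.phase = phase_labels_for(starts, design)
    return out


@dataclass
class ReportBundle:
    """Machine-readable result bundle: tables + config echo + seed registry."""

    tables: dict[str, pd.DataFrame]
    config: dict
    seed: int | None = None

    def validate(self, strict: bool = False) -> list[str]:
        """Check tables against the published schema; returns problem notes."""
        notes = []
        for name, cols in REPORT_SCHEMA.items():
            if name not in self.tables:
                notes.append(f"table {name!r} absent")
                continue
            missing = [c for c in cols if c not in self.tables[name].columns]
            if missing:
                notes.append(f"table {name!r} missing columns {missing}")
        if notes and strict:
            raise ValueError("report bundle incomplete: " + "; ".join(notes))
        for n in notes:
            log.warning("report: %s", n)
        return notes

    def write(self, out_dir, strict: bool = False) -> list[str]:
        notes = self.validate(strict=strict)
        os.makedirs(out_dir, exist_ok=True)
        for name, df in sorted(self.tables.items()):
            df.to_csv(os.path.join(out_dir, f"{name}.csv"), index=False)
        manifest = {
            "tables": {name: int(len(df)) for name, df in sorted(self.tables.items())},
            "config": self.config,
            "seed": self.seed,
            "notes": notes,
        }
        with open(os.path.join(out_dir, "manifest.json"), "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        return notes


def assemble_report(
    tables: dict[str, pd.DataFrame],
    config: dict | None = None,
    seed: int | None = None,
) -> ReportBundle:
    """Bundle analysis tables with the run configuration and seed."""
    return ReportBundle(tables=dict(tables), config=dict(config or {}), seed=seed)
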