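"""Cycle-wise PLR amplitude: ROI extrema after light re-onset.

The statistic: for each dark -> bright transition, the amplitude is the
maximum pupil diameter in the 0-100 ms window after re-onset minus the
minimum diameter in the 100-200 ms window.  Both windows are half-open
relative to the re-onset time, ``[0, 100)`` and ``[100, 200)`` ms, so the
0-200 ms span is partitioned without double counting.  Plotted against the
preceding dark duration across the 50 ramp cycles, these amplitudes form the
dark-adaptation recovery curve.

Amplitude tables are plain pandas DataFrames with columns::

    subject_id, eye, group, age_years, phase, cycle_id, dark_ms,
    d_max_mm, d_min_mm, amplitude, missing_reason

``missing_reason`` is the empty string for usable rows; negative amplitudes
on noisy traces are retained (clipping would bias group means).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .protocol import ReonsetEvent, StimulusProtocol, reonset_times
from .synth import PupilRecording, SubjectRecord

__all__ = [
    "RoiConfig",
    "AmplitudeRow",
    "extract_cycle",
    "build_table",
    "average_eyes",
    "recovery_curve",
    "read_amplitude_table",
]


def read_amplitude_table(path) -> pd.DataFrame:
    """Read an amplitude CSV; an empty missing_reason means 'not missing'."""
    df = pd.read_csv(path)
    if "missing_reason" in df.columns:
        df["missing_reason"] = df["missing_reason"].fillna("").astype(str)
    return df

TABLE_COLUMNS = [
    "subject_id",
    "eye",
    "group",
    "age_years",
    "phase",
    "cycle_id",
    "dark_ms",
    "d_max_mm",
    "d_min_mm",
    "amplitude",
    "missing_reason",
]


@dataclass(frozen=True)
class RoiConfig:
    """Measurement windows relative to re-onset, half-open, in ms."""

    max_window_ms: tuple[float, float] = (0.0, 100.0)
    min_window_ms: tuple[float, float] = (100.0, 200.0)
    min_valid_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not (self.max_window_ms[0] < self.max_window_ms[1]):
            raise ValueError("max_window_ms must be a non-empty interval")
        if not (self.min_window_ms[0] < self.min_window_ms[1]):
            raise ValueError("min_window_ms must be a non-empty interval")
        if self.max_window_ms[1] > self.min_window_ms[0]:
            raise ValueError("max window must precede min window")
        if not 0 < self.min_valid_fraction <= 1:
            raise ValueError("min_valid_fraction must be in (0, 1]")


@dataclass(frozen=True)
class AmplitudeRow:
    subject_id: str
    eye: str
    cycle_id: str
    phase: str
    dark_ms: float
    d_max_mm: float
    d_min_mm: float
    amplitude: float
    missing_reason: str = ""

    @property
    def missing(self) -> bool:
        return self.missing_reason != ""


def _roi_stat(
    rec: PupilRecording,
    t0_ms: float,
    window: tuple[float, float],
    min_valid_fraction: float,
):
    """(stat_ok, n_valid, n_total, values) for one half-open ROI window."""
    t = rec.t_ms.astype(float)
    lo, hi = t0_ms + window[0], t0_ms + window[1]
    in_roi = (t >= lo) & (t < hi)
    n_total = int(in_roi.sum())
    sel = in_roi & rec.valid
    n_valid = int(sel.sum())
    ok = n_total > 0 and n_valid >= min_valid_fraction * n_total
    return ok, n_valid, n_total, rec.diameter_mm[sel]


def extract_cycle(
    rec: PupilRecording,
    reonset: ReonsetEvent,
    roi: RoiConfig | None = None,
    subject_id: str | None = None,
) -> AmplitudeRow:
    """Amplitude of one cycle: ROI max (pre-constriction) minus ROI min.

    Returns a row flagged missing with reason ``out_of_span`` when the ROIs
    fall outside the recording, or ``roi_invalid`` when either window has
    fewer than ``min_valid_fraction`` valid samples.
    """
    if roi is None:
        roi = RoiConfig()
    sid = subject_id or rec.subject_id
    t_end = float(rec.t_ms[-1]) if rec.n_samples else -1.0
    common = dict(
        subject_id=sid,
        eye=rec.eye,
        cycle_id=reonset.cycle_id,
        phase=reonset.phase,
        dark_ms=float(reonset.preceding_dark_ms),
    )
    dt_ms = 1000.0 / rec.sample_rate_hz
    if (
        rec.n_samples == 0
        or reonset.time_ms + roi.min_window_ms[1] - dt_ms > t_end
        or reonset.time_ms < rec.t_ms[0]
    ):
        return AmplitudeRow(
            d_max_mm=np.nan, d_min_mm=np.nan, amplitude=np.nan,
            missing_reason="out_of_span", **common,
        )
    ok_max, *_, vals_max = _roi_stat(
        rec, reonset.time_ms, roi.max_window_ms, roi.min_valid_fraction
    )
    ok_min, *_, vals_min = _roi_stat(
        rec, reonset.time_ms, roi.min_window_ms, roi.min_valid_fraction
    )
    if not (ok_max and ok_min):
        return AmplitudeRow(
            d_max_mm=np.nan, d_min_mm=np.nan, amplitude=np.nan,
            missing_reason="roi_invalid", **common,
        )
    d_max = float(np.max(vals_max))
    d_min = float(np.min(vals_min))
    return AmplitudeRow(
        d_max_mm=d_max, d_min_mm=d_min, amplitude=d_max - d_min, **common
    )


def build_table(
    recordings: list[PupilRecording],
    protocol: StimulusProtocol,
    subjects: list[SubjectRecord] | pd.DataFrame,
    roi: RoiConfig | None = None,
) -> pd.DataFrame:
    """One amplitude row per (recording, re-onset event), joined with the
    subject table (group, age)."""
    if isinstance(subjects, pd.DataFrame):
        subj_df = subjects
    else:
        subj_df = pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in subjects],
                "group": [s.group for s in subjects],
                "age_years": [s.age_years for s in subjects],
            }
        )
    meta = subj_df.set_index("subject_id")[["group", "age_years"]]
    events = reonset_times(protocol)
    rows = []
    for rec in recordings:
        if rec.subject_id not in meta.index:
            raise KeyError(
                f"subject {rec.subject_id!r} present in recordings but not in the subject table"
            )
        group = meta.loc[rec.subject_id, "group"]
        age = meta.loc[rec.subject_id, "age_years"]
        for ev in events:
            row = extract_cycle(rec, ev, roi)
            rows.append(
                {
                    "subject_id": row.subject_id,
                    "eye": row.eye,
                    "group": group,
                    "age_years": age,
                    "phase": row.phase,
                    "cycle_id": row.cycle_id,
                    "dark_ms": row.dark_ms,
                    "d_max_mm": row.d_max_mm,
                    "d_min_mm": row.d_min_mm,
                    "amplitude": row.amplitude,
                    "missing_reason": row.missing_reason,
                }
            )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def average_eyes(table: pd.DataFrame) -> pd.DataFrame:
    """Average non-missing amplitudes across eyes per (subject, cycle).

    Single-eye rows pass through; if every eye is missing the averaged row is
    missing with the first eye's reason.  The ``eye`` column becomes ``both``
    wherever more than one eye contributed.
    """
    if table.empty:
        return table.copy()
    rows = []
    for _, sub in table.groupby(["subject_id", "cycle_id"], sort=False):
        ok = sub[sub["missing_reason"] == ""]
        out = sub.iloc[0].copy()
        if len(sub) > 1:
            out["eye"] = "both"
        if len(ok):
            out["d_max_mm"] = ok["d_max_mm"].mean()
            out["d_min_mm"] = ok["d_min_mm"].mean()
            out["amplitude"] = ok["amplitude"].mean()
            out["missing_reason"] = ""
        rows.append(out[TABLE_COLUMNS])
    return pd.DataFrame(rows).reset_index(drop=True)[TABLE_COLUMNS]


def recovery_curve(table: pd.DataFrame, group: str) -> pd.DataFrame:
    """Cross-subject mean and SD of ramp amplitude per dark duration.

    Missing rows are excluded; a dark duration with no usable rows is omitted.
    """
    if group not in set(table["group"].unique()):
        raise ValueError(f"unknown group {group!r}")
    sub = table[
        (table["group"] == group)
        & (table["phase"] == "ramp")
        & (table["missing_reason"] == "")
    ]
    if sub.empty:
        return pd.DataFrame(columns=["dark_ms", "mean_amplitude", "sd"])
    out = (
        sub.groupby("dark_ms")["amplitude"]
        .agg(mean_amplitude="mean", sd=lambda x: x.std(ddof=0) if len(x) > 1 else 0.0)
        .reset_index()
        .sort_values("dark_ms", ignore_index=True)
    )
    return out
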