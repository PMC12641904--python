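"""Synthetic cohorts and 200 Hz pupil recordings under the stimulation protocol.

The forward model stands in for raw study data, which is not publicly
deposited.  Its core is a dark-adaptation recovery law for the constriction
amplitude: after ``d`` ms of darkness the pupillary light reflex amplitude is

    A(d) = A_inf(age, group) * (1 - exp(-d / tau_group)),

a saturating exponential, the simplest kinetics consistent with first-order
photopigment regeneration.  Slower recovery in the AMD group is realised as a
larger time constant ``tau``; the age-related amplitude decline (attenuated in
AMD) acts linearly on the asymptote ``A_inf``.

A recording is built epoch-by-epoch: in darkness the pupil dilates toward
``baseline + dark_gain`` with time constant ``tau_dilation``; at each light
re-onset the diameter follows a unimodal constriction transient
``A(d) * g(t)`` with ``g(t) = (t/t_peak) * exp(1 - t/t_peak)`` (peak 1 at
``t_peak``), superposed on the exponential relaxation back to baseline.
Hippus (slow sinusoidal pupil unrest), white measurement noise and Poisson
blink gaps are added on top.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .protocol import StimulusProtocol, reonset_times

__all__ = [
    "GroupParams",
    "CohortConfig",
    "SubjectRecord",
    "PupilRecording",
    "constriction_kernel",
    "amplitude_law",
    "simulate_recording",
    "simulate_cohort",
    "simulate_amplitude_table",
    "simulate_model_form_table",
    "write_recording",
    "read_recording",
    "subjects_to_frame",
]

#: diameter value stored at invalid (blink) samples
SENTINEL = np.nan


@dataclass(frozen=True)
class GroupParams:
    """Generative parameters of one study group (all sizes in mm / ms)."""

    tau_recovery_ms: float
    amp_max_mm: float
    age_slope_mm_per_year: float
    baseline_mm: float = 5.0
    dark_gain_mm: float = 1.0
    tau_dilation_ms: float = 1500.0
    kernel_peak_ms: float = 150.0
    noise_sd_mm: float = 0.05
    hippus_amp_mm: float = 0.10
    hippus_freq_hz: float = 0.2
    blink_rate_hz: float = 0.1
    blink_dur_ms_range: tuple[float, float] = (100.0, 300.0)

    def __post_init__(self) -> None:
        if self.tau_recovery_ms <= 0 or self.tau_dilation_ms <= 0:
            raise ValueError("time constants must be positive")
        if self.amp_max_mm <= 0 or self.baseline_mm <= 0:
            raise ValueError("amp_max_mm and baseline_mm must be positive")
        if self.kernel_peak_ms <= 0:
            raise ValueError("kernel_peak_ms must be positive")
        for name in ("noise_sd_mm", "hippus_amp_mm", "blink_rate_hz"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def default_group_params() -> dict[str, GroupParams]:
    """Default generative conditions for the two groups.

    AMD recovers with twice the control time constant (slower dark
    adaptation) and shows a weaker age-related amplitude decline, so the
    Age x Group interaction is positive with Control as reference.
    """
    return {
        "Control": GroupParams(
            tau_recovery_ms=1800.0, amp_max_mm=1.2, age_slope_mm_per_year=0.010
        ),
        "AMD": GroupParams(
            tau_recovery_ms=3600.0, amp_max_mm=1.2, age_slope_mm_per_year=0.004
        ),
    }


#: multiplicative lognormal between-subject jitter (sigma of log) per field
DEFAULT_JITTER_SIGMA: dict[str, float] = {
    "tau_recovery_ms": 0.15,
    "amp_max_mm": 0.12,
    "baseline_mm": 0.05,
    "dark_gain_mm": 0.10,
    "tau_dilation_ms": 0.10,
}


@dataclass(frozen=True)
class CohortConfig:
    """Study-cohort generating conditions: 14 AMD + 14 age-matched controls."""

    n_amd: int = 14
    n_control: int = 14
    age_mean_years: float = 75.0
    age_sd_years: float = 7.0
    age_reference_years: float = 75.0
    seed: int = 0
    group_params: dict[str, GroupParams] = field(default_factory=default_group_params)
    jitter_sigma: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_JITTER_SIGMA)
    )

    def __post_init__(self) -> None:
        if self.n_amd < 0 or self.n_control < 0:
            raise ValueError("group sizes must be non-negative")
        if self.n_amd + self.n_control < 1:
            raise ValueError("cohort must contain at least one subject")
        if self.age_sd_years < 0:
            raise ValueError("age_sd_years must be non-negative")


@dataclass(frozen=True)
class SubjectRecord:
    """One simulated participant with realised (jittered) parameters."""

    subject_id: str
    group: Literal["AMD", "Control"]
    age_years: float
    params: GroupParams
    age_reference_years: float
    seed: int

    def __post_init__(self) -> None:
        if self.group not in ("AMD", "Control"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.age_years <= 0:
            raise ValueError("age_years must be positive")


@dataclass
class PupilRecording:
    """Uniformly sampled pupil-diameter trace with per-sample validity."""

    subject_id: str
    eye: Literal["left", "right"]
    sample_rate_hz: float
    t_ms: np.ndarray
    diameter_mm: np.ndarray
    valid: np.ndarray
    protocol_ref: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.t_ms) == len(self.diameter_mm) == len(self.valid)):
            raise ValueError("t_ms, diameter_mm and valid must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.t_ms)

    def copy(self) -> "PupilRecording":
        return PupilRecording(
            subject_id=self.subject_id,
            eye=self.eye,
            sample_rate_hz=self.sample_rate_hz,
            t_ms=self.t_ms.copy(),
            diameter_mm=self.diameter_mm.copy(),
            valid=self.valid.copy(),
            protocol_ref=self.protocol_ref,
            meta=dict(self.meta),
        )

    def equals(self, other: "PupilRecording") -> bool:
        return (
            self.subject_id == other.subject_id
            and self.eye == other.eye
            and self.sample_rate_hz == other.sample_rate_hz
            and np.array_equal(self.t_ms, other.t_ms)
            and np.array_equal(self.diameter_mm, other.diameter_mm, equal_nan=True)
            and np.array_equal(self.valid, other.valid)
        )


def constriction_kernel(t_ms: np.ndarray | float, peak_ms: float) -> np.ndarray:
    """Unimodal constriction transient g(t) = (t/p) * exp(1 - t/p).

    g(0) = 0, g(peak_ms) = 1, g -> 0 as t -> inf.
    """
    t = np.asarray(t_ms, dtype=float)
    out = np.where(t >= 0, (t / peak_ms) * np.exp(1.0 - t / peak_ms), 0.0)
    return out


def asymptotic_amplitude(subject: SubjectRecord) -> float:
    """A_inf: asymptotic amplitude after infinite dark, age-adjusted, floor 0."""
    p = subject.params
    a = p.amp_max_mm - p.age_slope_mm_per_year * (
        subject.age_years - subject.age_reference_years
    )
    return max(a, 0.0)


def amplitude_law(dark_ms: float | np.ndarray, subject: SubjectRecord) -> np.ndarray:
    """Recovery law A(d) = A_inf * (1 - exp(-d / tau)); monotone, A(0) = 0."""
    d = np.asarray(dark_ms, dtype=float)
    if np.any(d < 0):
        raise ValueError("dark_ms must be non-negative")
    a_inf = asymptotic_amplitude(subject)
    return a_inf * (1.0 - np.exp(-d / subject.params.tau_recovery_ms))


def simulate_recording(
    subject: SubjectRecord,
    protocol: StimulusProtocol,
    rng: np.random.Generator | None = None,
    eye: str = "left",
) -> PupilRecording:
    """Simulate one 200 Hz pupil trace for ``subject`` under ``protocol``.

    Reproducible: when ``rng`` is omitted it is seeded from ``subject.seed``,
    so the same subject always yields the same recording.
    """
    if len(protocol.epochs) < 2:
        raise ValueError("protocol must contain at least one bright/dark cycle")
    if rng is None:
        rng = np.random.default_rng(subject.seed)
    p = subject.params
    dt_ms = 1000.0 / protocol.sample_rate_hz
    n = int(protocol.total_duration_ms / dt_ms)
    t = np.arange(n) * dt_ms

    diameter = np.empty(n)
    state = p.baseline_mm  # diameter at the running epoch boundary
    prev_dark_ms = None
    for ep in protocol.epochs:
        lo = int(np.ceil(ep.onset_ms / dt_ms))
        hi = int(np.ceil(ep.end_ms / dt_ms))
        hi = min(hi, n)
        t_rel = t[lo:hi] - ep.onset_ms
        if ep.level == "dark":
            target = p.baseline_mm + p.dark_gain_mm
            diameter[lo:hi] = target + (state - target) * np.exp(
                -t_rel / p.tau_dilation_ms
            )
            state = target + (state - target) * np.exp(
                -ep.duration_ms / p.tau_dilation_ms
            )
            prev_dark_ms = ep.duration_ms
        else:
            relax = p.baseline_mm + (state - p.baseline_mm) * np.exp(
                -t_rel / p.tau_dilation_ms
            )
            if prev_dark_ms is not None:
                amp = float(amplitude_law(prev_dark_ms, subject))
                relax = relax - amp * constriction_kernel(t_rel, p.kernel_peak_ms)
            diameter[lo:hi] = relax
            state = p.baseline_mm + (state - p.baseline_mm) * np.exp(
                -ep.duration_ms / p.tau_dilation_ms
            )
            prev_dark_ms = None

    if p.hippus_amp_mm > 0:
        phase = rng.uniform(0, 2 * np.pi)
        diameter += p.hippus_amp_mm * np.sin(
            2 * np.pi * p.hippus_freq_hz * t / 1000.0 + phase
        )
    else:
        rng.uniform(0, 2 * np.pi)  # keep the stream position stable
    if p.noise_sd_mm > 0:
        diameter += rng.normal(0.0, p.noise_sd_mm, size=n)
    else:
        rng.normal(0.0, 1.0, size=n)

    valid = np.ones(n, dtype=bool)
    if p.blink_rate_hz > 0:
        total_s = protocol.total_duration_ms / 1000.0
        n_blinks = rng.poisson(p.blink_rate_hz * total_s)
        starts = np.sort(rng.uniform(0, protocol.total_duration_ms, size=n_blinks))
        durs = rng.uniform(*p.blink_dur_ms_range, size=n_blinks)
        for s, d in zip(starts, durs):
            lo = int(np.ceil(s / dt_ms))
            hi = int(np.ceil((s + d) / dt_ms))
            valid[lo : min(hi, n)] = False
    diameter[~valid] = SENTINEL

    return PupilRecording(
        subject_id=subject.subject_id,
        eye=eye,  # type: ignore[arg-type]
        sample_rate_hz=protocol.sample_rate_hz,
        t_ms=np.round(t).astype(np.int64) if dt_ms.is_integer() else t,
        diameter_mm=diameter,
        valid=valid,
        protocol_ref="default",
    )


def _realize_subject(
    subject_id: str,
    group: str,
    age: float,
    base: GroupParams,
    jitter_sigma: dict[str, float],
    age_reference: float,
    rng: np.random.Generator,
    seed: int,
) -> SubjectRecord:
    updates = {}
    for name, sigma in jitter_sigma.items():
        if sigma > 0:
            updates[name] = getattr(base, name) * rng.lognormal(0.0, sigma)
    params = replace(base, **updates) if updates else base
    return SubjectRecord(
        subject_id=subject_id,
        group=group,  # type: ignore[arg-type]
        age_years=age,
        params=params,
        age_reference_years=age_reference,
        seed=seed,
    )


def simulate_cohort(
    config: CohortConfig,
    protocol: StimulusProtocol,
    simulate_traces: bool = True,
) -> tuple[list[SubjectRecord], list[PupilRecording]]:
    """Draw the cohort and (optionally) simulate one recording per subject.

    Ages are drawn from the shared distribution for both groups (age-matched
    by construction).  One eye per subject, matching the study design.
    Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    subjects: list[SubjectRecord] = []
    plan = [("AMD", i) for i in range(config.n_amd)] + [
        ("Control", i) for i in range(config.n_control)
    ]
    for group, i in plan:
        age = float(rng.normal(config.age_mean_years, config.age_sd_years))
        age = max(age, 40.0)  # clip to a plausible study-population floor
        sid = f"{group.lower()}_{i + 1:02d}"
        seed = int(rng.integers(0, 2**31 - 1))
        subjects.append(
            _realize_subject(
                sid,
                group,
                age,
                config.group_params[group],
                config.jitter_sigma,
                config.age_reference_years,
                rng,
                seed,
            )
        )
    recordings: list[PupilRecording] = []
    if simulate_traces:
        for s in subjects:
            recordings.append(simulate_recording(s, protocol))
    return subjects, recordings


def simulate_amplitude_table(
    config: CohortConfig,
    protocol: StimulusProtocol,
    rng: np.random.Generator | None = None,
    amplitude_noise_sd: float = 0.05,
) -> pd.DataFrame:
    """Cycle-wise amplitude table drawn directly from the recovery law.

    Bypasses trace synthesis and ROI extraction: each ramp re-onset yields
    ``A(d) + e`` with iid Gaussian ``e``.  Used for simulation studies of the
    downstream statistics where the trace machinery is not under test.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    subjects, _ = simulate_cohort(config, protocol, simulate_traces=False)
    events = [ev for ev in reonset_times(protocol) if ev.phase == "ramp"]
    rows = []
    for s in subjects:
        darks = np.array([ev.preceding_dark_ms for ev in events], dtype=float)
        amps = amplitude_law(darks, s) + rng.normal(0, amplitude_noise_sd, len(darks))
        for ev, a in zip(events, amps):
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "eye": "left",
                    "group": s.group,
                    "age_years": s.age_years,
                    "phase": ev.phase,
                    "cycle_id": ev.cycle_id,
                    "dark_ms": ev.preceding_dark_ms,
                    "d_max_mm": np.nan,
                    "d_min_mm": np.nan,
                    "amplitude": a,
                    "missing_reason": "",
                }
            )
    return pd.DataFrame(rows)


def simulate_model_form_table(
    n_amd: int = 14,
    n_control: int = 14,
    beta_intercept: float = 0.4,
    beta_time: float = 1e-4,
    beta_group: float = 0.0,
    beta_age: float = 0.0,
    beta_age_group: float = 0.0,
    group_intercept_sd: float = 0.0,
    noise_sd: float = 0.05,
    age_mean: float = 75.0,
    age_sd: float = 7.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Amplitude table generated from the mixed model's own linear form.

    ``amplitude = b0 + b_t*Time + b_g*AMD + b_a*Age_c + b_ag*Age_c*AMD
    + u_group + e`` with iid Gaussian errors and (optionally) a group-level
    intercept.  This is the generator that matches the fitted model's
    assumptions exactly; it calibrates type-I error and parameter recovery of
    the fitter without confounding from between-subject heterogeneity.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    darks = 100.0 * np.arange(1, 51)
    rows = []
    u = {g: rng.normal(0, group_intercept_sd) if group_intercept_sd > 0 else 0.0
         for g in ("AMD", "Control")}
    plan = [("AMD", i) for i in range(n_amd)] + [
        ("Control", i) for i in range(n_control)
    ]
    ages = rng.normal(age_mean, age_sd, size=len(plan))
    age_c = ages - np.mean(ages)
    for (group, i), age, ac in zip(plan, ages, age_c):
        is_amd = 1.0 if group == "AMD" else 0.0
        mu = (
            beta_intercept
            + beta_time * darks
            + beta_group * is_amd
            + beta_age * ac
            + beta_age_group * ac * is_amd
            + u[group]
        )
        amps = mu + rng.normal(0, noise_sd, size=len(darks))
        for k, (d, a) in enumerate(zip(darks, amps), start=1):
            rows.append(
                {
                    "subject_id": f"{group.lower()}_{i + 1:02d}",
                    "eye": "left",
                    "group": group,
                    "age_years": age,
                    "phase": "ramp",
                    "cycle_id": f"ramp_{k:02d}",
                    "dark_ms": d,
                    "d_max_mm": np.nan,
                    "d_min_mm": np.nan,
                    "amplitude": a,
                    "missing_reason": "",
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# recording CSV dialect: subject_id, eye, t_ms, diameter_mm, valid.
# Invalid samples carry an empty diameter field.

def write_recording(rec: PupilRecording, path) -> None:
    df = pd.DataFrame(
        {
            "subject_id": rec.subject_id,
            "eye": rec.eye,
            "t_ms": rec.t_ms,
            "diameter_mm": rec.diameter_mm,
            "valid": rec.valid,
        }
    )
    df.to_csv(path, index=False)


def read_recording(path, sample_rate_hz: float | None = None) -> PupilRecording:
    """Read a recording CSV; raises ValueError naming the first bad row.

    A file without a ``valid`` column is accepted as all-valid with a warning.
    """
    df = pd.read_csv(path)
    required = {"subject_id", "eye", "t_ms", "diameter_mm"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"recording file missing columns: {sorted(missing_cols)}")
    if len(df) == 0:
        raise ValueError("recording file has no samples")
    t = df["t_ms"].to_numpy()
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise ValueError(
            f"non-monotone t_ms at row {int(bad[0]) + 1} (t_ms={t[bad[0] + 1]})"
        )
    if "valid" in df.columns:
        valid = df["valid"].astype(bool).to_numpy()
    else:
        warnings.warn(
            "recording file has no 'valid' column; assuming all samples valid",
            stacklevel=2,
        )
        valid = np.ones(len(df), dtype=bool)
    if sample_rate_hz is None:
        steps = np.diff(t)
        sample_rate_hz = 1000.0 / float(steps[0]) if steps.size else 200.0
    diameter = df["diameter_mm"].to_numpy(dtype=float)
    if np.any(diameter[valid] <= 0):
        row = int(np.nonzero(valid & ~(diameter > 0))[0][0])
        raise ValueError(f"non-positive diameter at valid row {row}")
    return PupilRecording(
        subject_id=str(df["subject_id"].iloc[0]),
        eye=str(df["eye"].iloc[0]),  # type: ignore[arg-type]
        sample_rate_hz=sample_rate_hz,
        t_ms=t,
        diameter_mm=diameter,
        valid=valid,
    )


def subjects_to_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    """Subject table: id, group, age, seed and realised parameters."""
    rows = []
    for s in subjects:
        row = {
            "subject_id": s.subject_id,
            "group": s.group,
            "age_years": s.age_years,
            "seed": s.seed,
        }
        for name in (
            "tau_recovery_ms",
            "amp_max_mm",
            "age_slope_mm_per_year",
            "baseline_mm",
            "dark_gain_mm",
            "tau_dilation_ms",
            "kernel_peak_ms",
            "noise_sd_mm",
        ):
            row[name] = getattr(s.params, name)
        rows.append(row)
    return pd.DataFrame(rows)


def write_recordings_csv(recs: list[PupilRecording], path) -> None:
    """All recordings in one long-format CSV."""
    frames = [
        pd.DataFrame(
            {
                "subject_id": r.subject_id,
                "eye": r.eye,
                "t_ms": r.t_ms,
                "diameter_mm": r.diameter_mm,
                "valid": r.valid,
            }
        )
        for r in recs
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_recordings_csv(path, sample_rate_hz: float = 200.0) -> list[PupilRecording]:
    df = pd.read_csv(path)
    recs = []
    for (sid, eye), sub in df.groupby(["subject_id", "eye"], sort=False):
        buf = io.StringIO()
        sub.to_csv(buf, index=False)
        buf.seek(0)
        recs.append(read_recording(buf, sample_rate_hz=sample_rate_hz))
    return recs
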