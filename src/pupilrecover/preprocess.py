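"""Artifact handling for pupil traces: velocity spikes, blink gaps, smoothing.

The cleaning rules are deliberately conservative and fully pinned by
:class:`CleaningConfig`; cycles whose measurement windows remain invalid after
cleaning are dropped downstream rather than imputed.

All stages preserve the time grid and sample count; they only modify diameter
values and validity flags.  ``flag_artifacts`` and ``interpolate_gaps`` are
idempotent.  The combined :func:`clean` records a marker in the recording
metadata and is a no-op when applied again, so the full pipeline is idempotent
even with smoothing enabled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth import PupilRecording

__all__ = ["CleaningConfig", "flag_artifacts", "interpolate_gaps", "smooth", "clean"]


@dataclass(frozen=True)
class CleaningConfig:
    max_interp_gap_ms: float = 300.0
    velocity_limit_mm_per_s: float = 50.0
    smooth_window_ms: float = 25.0

    def __post_init__(self) -> None:
        for name in ("max_interp_gap_ms", "velocity_limit_mm_per_s", "smooth_window_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of ``mask`` as half-open (start, stop) pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[0::2], idx[1::2]))


def flag_artifacts(rec: PupilRecording, cfg: CleaningConfig) -> PupilRecording:
    """Mark physiologically implausible samples invalid.

    A sample is flagged when either adjacent first-difference velocity exceeds
    ``velocity_limit_mm_per_s``; each run of such samples is dilated by one
    sample on both sides.  Flags are derived from the diameter values only and
    unioned with pre-existing invalidity, so the operation is idempotent.
    """
    out = rec.copy()
    if cfg.velocity_limit_mm_per_s == 0 or rec.n_samples < 2:
        return out
    dt_s = np.diff(rec.t_ms.astype(float)) / 1000.0
    vel = np.abs(np.diff(rec.diameter_mm)) / dt_s  # vel[i]: between i and i+1
    with np.errstate(invalid="ignore"):
        exceed = vel > cfg.velocity_limit_mm_per_s
    spike = np.zeros(rec.n_samples, dtype=bool)
    spike[:-1] |= exceed
    spike[1:] |= exceed
    dilated = spike.copy()
    for lo, hi in _runs(spike):
        if lo > 0:
            dilated[lo - 1] = True
        if hi < rec.n_samples:
            dilated[hi] = True
    out.valid = rec.valid & ~dilated
    return out


def interpolate_gaps(rec: PupilRecording, cfg: CleaningConfig) -> PupilRecording:
    """Linearly bridge short invalid gaps.

    Gaps no longer than ``max_interp_gap_ms`` with valid samples on both sides
    are filled by linear interpolation between the boundary samples and marked
    valid; longer gaps and leading/trailing gaps are left untouched (never
    extrapolated).  Interpolated sample indices are recorded in
    ``rec.meta['interpolated']``.
    """
    out = rec.copy()
    invalid = ~rec.valid
    if not invalid.any():
        return out
    t = rec.t_ms.astype(float)
    interpolated: list[int] = []
    for lo, hi in _runs(invalid):
        if lo == 0 or hi == rec.n_samples:
            continue  # no extrapolation at the edges
        gap_ms = t[hi] - t[lo - 1]  # span between bounding valid samples
        if gap_ms - (t[hi] - t[hi - 1]) > cfg.max_interp_gap_ms:
            continue
        x0, x1 = t[lo - 1], t[hi]
        y0, y1 = rec.diameter_mm[lo - 1], rec.diameter_mm[hi]
        frac = (t[lo:hi] - x0) / (x1 - x0)
        out.diameter_mm[lo:hi] = y0 + frac * (y1 - y0)
        out.valid[lo:hi] = True
        interpolated.extend(range(lo, hi))
    prev = set(out.meta.get("interpolated", []))
    out.meta["interpolated"] = sorted(prev | set(interpolated))
    return out


def smooth(rec: PupilRecording, cfg: CleaningConfig) -> PupilRecording:
    """Centered moving average over valid samples; window 0 is the identity.

    Invalid samples stay invalid and keep their sentinel value; valid samples
    are averaged over the valid neighbours inside the window.
    """
    out = rec.copy()
    if cfg.smooth_window_ms == 0 or rec.n_samples == 0:
        return out
    dt_ms = 1000.0 / rec.sample_rate_hz
    half = int(round(cfg.smooth_window_ms / dt_ms)) // 2
    if half == 0:
        return out
    k = 2 * half + 1
    d = np.where(rec.valid, rec.diameter_mm, 0.0)
    w = rec.valid.astype(float)
    kernel = np.ones(k)
    num = np.convolve(d, kernel, mode="same")
    den = np.convolve(w, kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        avg = num / den
    out.diameter_mm = np.where(rec.valid, avg, rec.diameter_mm)
    return out


def clean(rec: PupilRecording, cfg: CleaningConfig | None = None) -> PupilRecording:
    """Full pipeline: flag -> interpolate -> smooth.

    Idempotent: a recording already carrying the ``cleaned`` marker is
    returned unchanged (smoothing must not be applied twice).
    """
    if cfg is None:
        cfg = CleaningConfig()
    if rec.meta.get("cleaned"):
        return rec.copy()
    out = flag_artifacts(rec, cfg)
    out = interpolate_gaps(out, cfg)
    out = smooth(out, cfg)
    out.meta["cleaned"] = True
    out.meta["cleaning"] = {
        "max_interp_gap_ms": cfg.max_interp_gap_ms,
        "velocity_limit_mm_per_s": cfg.velocity_limit_mm_per_s,
        "smooth_window_ms": cfg.smooth_window_ms,
        "n_flagged": int((~out.valid).sum() - len(out.meta.get("interpolated", []))),
        "n_interpolated": len(out.meta.get("interpolated", [])),
    }
    return out
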