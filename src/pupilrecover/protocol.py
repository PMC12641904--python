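"""Bright/dark stimulation schedule for the incremental dark-adaptation protocol.

The protocol alternates a 3 s bright screen (150 nits) with darkness (<1 nit),
where the dark duration grows by 100 ms per cycle over 50 "ramp" cycles
(100 ms ... 5000 ms), followed by three long "tail" darks (7, 10, 15 s) and a
10-cycle "repeat" block of 3 s bright / 100 ms dark pairs.  All analysis
downstream keys off the *re-onset* events: the dark -> bright transitions at
which the pupillary constriction is measured.

Times are integer milliseconds; epochs are half-open intervals
``[onset, onset + duration)`` so that every millisecond belongs to exactly one
epoch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, NamedTuple

import numpy as np

__all__ = [
    "StimulusEpoch",
    "StimulusProtocol",
    "ReonsetEvent",
    "build_protocol",
    "reonset_times",
    "luminance_at",
    "protocol_to_json",
    "protocol_from_json",
]

BRIGHT_MS = 3000
RAMP_CYCLES = 50
RAMP_INCREMENT_MS = 100
TAIL_DARK_MS = (7000, 10000, 15000)
REPEAT_CYCLES = 10
REPEAT_DARK_MS = 100

Phase = Literal["ramp", "tail", "repeat"]
Level = Literal["bright", "dark"]


@dataclass(frozen=True)
class StimulusEpoch:
    """One contiguous screen state: ``[onset_ms, onset_ms + duration_ms)``."""

    index: int
    phase: Phase
    level: Level
    onset_ms: int
    duration_ms: int
    cycle_id: str

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError(f"epoch {self.index}: duration must be positive")
        if self.onset_ms < 0:
            raise ValueError(f"epoch {self.index}: onset must be non-negative")

    @property
    def end_ms(self) -> int:
        return self.onset_ms + self.duration_ms


@dataclass(frozen=True)
class StimulusProtocol:
    """Ordered, gap-free sequence of bright/dark epochs.

    Luminance is carried as a two-level label; the nits values are metadata
    only (the analysis never uses absolute luminance).
    """

    epochs: tuple[StimulusEpoch, ...]
    bright_luminance_nits: float = 150.0
    dark_luminance_nits: float = 0.5
    sample_rate_hz: float = 200.0
    _onsets: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("protocol must contain at least one epoch")
        prev_end = self.epochs[0].onset_ms
        for ep in self.epochs:
            if ep.onset_ms != prev_end:
                raise ValueError(
                    f"epoch {ep.index} onset {ep.onset_ms} != previous end {prev_end}"
                )
            prev_end = ep.end_ms
        object.__setattr__(
            self, "_onsets", np.array([ep.onset_ms for ep in self.epochs])
        )

    @property
    def total_duration_ms(self) -> int:
        return self.epochs[-1].end_ms

    def epoch_at(self, t_ms: int) -> StimulusEpoch:
        if not 0 <= t_ms < self.total_duration_ms:
            raise ValueError(
                f"t_ms={t_ms} outside protocol span [0, {self.total_duration_ms})"
            )
        i = int(np.searchsorted(self._onsets, t_ms, side="right")) - 1
        return self.epochs[i]


class ReonsetEvent(NamedTuple):
    """A dark -> bright transition; the time origin for amplitude measurement."""

    time_ms: int
    preceding_dark_ms: int
    cycle_id: str
    phase: str


def build_protocol(final_bright: bool = True) -> StimulusProtocol:
    """Construct the full stimulation schedule.

    Ramp (50 cycles of 3 s bright + k*100 ms dark), then tail (3 s bright
    before each of 7 s, 10 s, 15 s dark), then the repeat block (10 cycles of
    3 s bright + 100 ms dark).  With ``final_bright`` a closing 3 s bright
    epoch follows the last repeat dark so that every dark epoch has a
    measurable re-onset; without it the protocol ends on the last dark.

    Deterministic: identical output on every call.
    """
    epochs: list[StimulusEpoch] = []
    t = 0

    def add(phase: Phase, level: Level, duration: int, cycle_id: str) -> None:
        nonlocal t
        epochs.append(
            StimulusEpoch(
                index=len(epochs),
                phase=phase,
                level=level,
                onset_ms=t,
                duration_ms=duration,
                cycle_id=cycle_id,
            )
        )
        t += duration

    for k in range(1, RAMP_CYCLES + 1):
        cid = f"ramp_{k:02d}"
        add("ramp", "bright", BRIGHT_MS, cid)
        add("ramp", "dark", RAMP_INCREMENT_MS * k, cid)
    for j, dark in enumerate(TAIL_DARK_MS, start=1):
        cid = f"tail_{j}"
        add("tail", "bright", BRIGHT_MS, cid)
        add("tail", "dark", dark, cid)
    for k in range(1, REPEAT_CYCLES + 1):
        cid = f"repeat_{k:02d}"
        add("repeat", "bright", BRIGHT_MS, cid)
        add("repeat", "dark", REPEAT_DARK_MS, cid)
    if final_bright:
        add("repeat", "bright", BRIGHT_MS, "end")
    return StimulusProtocol(epochs=tuple(epochs))


def reonset_times(protocol: StimulusProtocol) -> list[ReonsetEvent]:
    """All dark -> bright transitions, sorted by time.

    Each event is tagged with the cycle and phase of the *preceding dark*
    epoch (the measurement belongs to the cycle whose dark it terminates).
    A trailing dark with no following bright epoch produces no event.
    """
    events: list[ReonsetEvent] = []
    for prev, nxt in zip(protocol.epochs, protocol.epochs[1:]):
        if prev.level == "dark" and nxt.level == "bright":
            events.append(
                ReonsetEvent(
                    time_ms=nxt.onset_ms,
                    preceding_dark_ms=prev.duration_ms,
                    cycle_id=prev.cycle_id,
                    phase=prev.phase,
                )
            )
    return events


def luminance_at(protocol: StimulusProtocol, t_ms: int) -> str:
    """Screen level ('bright' or 'dark') at time ``t_ms``.

    Raises ValueError outside ``[0, total_duration_ms)``.
    """
    return protocol.epoch_at(t_ms).level


def protocol_to_json(protocol: StimulusProtocol, path: str | None = None) -> str:
    doc = {
        "metadata": {
            "bright_luminance_nits": protocol.bright_luminance_nits,
            "dark_luminance_nits": protocol.dark_luminance_nits,
            "sample_rate_hz": protocol.sample_rate_hz,
        },
        "epochs": [
            {
                "index": ep.index,
                "phase": ep.phase,
                "level": ep.level,
                "onset_ms": ep.onset_ms,
                "duration_ms": ep.duration_ms,
                "cycle_id": ep.cycle_id,
            }
            for ep in protocol.epochs
        ],
    }
    text = json.dumps(doc, indent=1)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def protocol_from_json(source: str) -> StimulusProtocol:
    """Load a protocol from a JSON string or file path."""
    if source.lstrip().startswith("{"):
        doc = json.loads(source)
    else:
        with open(source) as fh:
            doc = json.load(fh)
    meta = doc.get("metadata", {})
    epochs = tuple(
        StimulusEpoch(
            index=e["index"],
            phase=e["phase"],
            level=e["level"],
            onset_ms=e["onset_ms"],
            duration_ms=e["duration_ms"],
            cycle_id=e["cycle_id"],
        )
        for e in doc["epochs"]
    )
    return StimulusProtocol(
        epochs=epochs,
        bright_luminance_nits=meta.get("bright_luminance_nits", 150.0),
        dark_luminance_nits=meta.get("dark_luminance_nits", 0.5),
        sample_rate_hz=meta.get("sample_rate_hz", 200.0),
    )
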