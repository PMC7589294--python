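"""Core data records shared across the pipeline.

Time convention: t = 0 at the start of the constant-speed run phase.
The default profile is 600 s baseline, 120 s ramp-up, 600 s run, 120 s
ramp-down and 600 s recovery, i.e. baseline occupies [-720, -120) s and
recovery ends at +1320 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError

#: physiological channels handled by the pipeline (units in docstrings)
CHANNELS = ("HR", "MAP", "SV", "TPR", "CC", "cTSI", "CO")

CHANNEL_UNITS = {
    "HR": "bpm",
    "MAP": "mmHg",
    "SV": "ml",
    "TPR": "dyn.s.cm-5",
    "CC": "mm",
    "cTSI": "%",
    "CO": "l/min",
}


@dataclass(frozen=True)
class PhaseBoundaries:
    """Phase edges (s) of one centrifuge profile.

    Contiguous phases: baseline -> ramp-up -> run -> ramp-down -> recovery.
    """

    baseline_start: float = -720.0
    ramp_up_start: float = -120.0
    run_start: float = 0.0
    ramp_down_start: float = 600.0
    recovery_start: float = 720.0
    recovery_end: float = 1320.0

    def __post_init__(self):
        seq = (
            self.baseline_start,
            self.ramp_up_start,
            self.run_start,
            self.ramp_down_start,
            self.recovery_start,
            self.recovery_end,
        )
        if not all(a < b for a, b in zip(seq, seq[1:])):
            raise ConfigurationError(f"phase boundaries must be strictly increasing: {seq}")

    @property
    def baseline_end(self) -> float:
        return self.ramp_up_start

    @property
    def rotation_window(self) -> tuple[float, float]:
        """Ramp-up start through ramp-down end (= recovery start)."""
        return (self.ramp_up_start, self.recovery_start)

    def phase_of(self, t: float) -> str:
        if t < self.baseline_start:
            return "pre"
        if t < self.ramp_up_start:
            return "baseline"
        if t < self.run_start:
            return "ramp_up"
        if t < self.ramp_down_start:
            return "run"
        if t < self.recovery_start:
            return "ramp_down"
        if t < self.recovery_end:
            return "recovery"
        return "post"

    def to_dict(self) -> dict:
        return {
            "baseline_start": self.baseline_start,
            "ramp_up_start": self.ramp_up_start,
            "run_start": self.run_start,
            "ramp_down_start": self.ramp_down_start,
            "recovery_start": self.recovery_start,
            "recovery_end": self.recovery_end,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhaseBoundaries":
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class Event:
    """Timed symptom / protocol event attached to a run."""

    time: float
    label: str


@dataclass
class RunRecord:
    """One centrifuge run: multi-channel time series plus metadata.

    ``channels`` maps channel name to a ``(times, values)`` pair of 1-D
    arrays with strictly increasing times.
    """

    run_id: str
    participant: str
    position: str
    g_foot: float
    channels: dict[str, tuple[np.ndarray, np.ndarray]]
    phases: PhaseBoundaries = field(default_factory=PhaseBoundaries)
    events: list[Event] = field(default_factory=list)
    terminated: bool = False

    def channel(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        if name not in self.channels:
            raise KeyError(f"run {self.run_id} has no channel {name!r}")
        return self.channels[name]

    def channel_names(self) -> tuple[str, ...]:
        return tuple(self.channels)
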