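"""Synthetic short-arm-centrifuge trial generator.

Emulates the trial's structure — 15 participants, 3 rotation-axis
positions (P1 above head, P2 head apex, P3 heart level) x 3 foot-level
g-levels (1.0, 1.7, 2.4), each run a 600/120/600/120/600 s
baseline/ramp-up/run/ramp-down/recovery profile — with known ground
truth, so the preprocessing, classification and inference layers are
testable end to end.

Response model per channel: value(t) = baseline + participant intercept
+ effect * s(t) + noise, where s(t) rises exponentially (time constant
60 s) from ramp-up onset to a run-phase plateau of 1 and decays
(time constant 90 s) from ramp-down onset.  The configured effect is the
final-run-minute delta; defaults are the observed position-dependent
response magnitudes at +2.4 Gz (e.g. dHR 50/24/8 bpm, dCC
5.46/4.11/2.23 mm, dcTSI -2.85/-1.88/-0.95 % for P1/P2/P3).  Effects
scale proportionally with foot-level g (zero at zero spin).

Pre-syncope events are drawn per run from a logistic probability
increasing in g and decreasing from P1 to P3; a configurable fraction of
PSS+ runs receives a synthesized smooth concurrent HR+MAP decline so the
signal path of the classifier is exercised, the rest a symptom event or
a termination flag.

Cardiovascular channels (HR, MAP, SV, TPR, CO) are sampled beat-like at
~1 Hz with jittered intervals; CC and cTSI at 10 Hz.  Artifacts are
injected as out-of-range spikes at a configurable per-sample rate.  All
randomness flows from one root seed through named per-run substreams,
so every output is reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, logit

from .biomechanics import BodyLandmarks
from .exceptions import ConfigurationError
from .preprocess import DEFAULT_LIMITS, CC_BAND_MM
from .records import CHANNELS, Event, PhaseBoundaries, RunRecord

#: final-run-minute delta (mean, SD) per channel per position at 2.4 g
DEFAULT_EFFECTS = {
    "cTSI": {"P1": (-2.85, 1.86), "P2": (-1.88, 1.43), "P3": (-0.95, 1.32)},
    "CC": {"P1": (5.46, 2.09), "P2": (4.11, 2.44), "P3": (2.23, 1.63)},
    "HR": {"P1": (50.0, 15.5), "P2": (24.0, 11.62), "P3": (8.0, 7.75)},
    "SV": {"P1": (-37.7, 12.0), "P2": (-27.2, 9.30), "P3": (-19.4, 6.58)},
    "TPR": {"P1": (204.0, 290.0), "P2": (223.0, 205.0), "P3": (169.0, 136.0)},
    "MAP": {"P1": (4.43, 18.10), "P2": (4.60, 9.10), "P3": (-3.87, 3.25)},
    "CO": {"P1": (-0.64, 1.32), "P2": (-0.59, 0.77), "P3": (-0.69, 0.39)},
}

#: resting channel values
DEFAULT_BASELINES = {
    "HR": 65.0,      # bpm
    "MAP": 85.0,     # mmHg
    "SV": 75.0,      # ml
    "TPR": 1100.0,   # dyn.s.cm-5
    "CC": 370.0,     # mm (absolute calf circumference)
    "cTSI": 70.0,    # %
    "CO": 4.9,       # l/min
}

#: between-participant SD of resting values (random intercepts)
DEFAULT_INTERCEPT_SD = {
    "HR": 6.0, "MAP": 6.0, "SV": 8.0, "TPR": 150.0,
    "CC": 15.0, "cTSI": 3.0, "CO": 0.6,
}

#: measurement noise SD per sample
DEFAULT_NOISE_SD = {
    "HR": 2.0, "MAP": 3.0, "SV": 4.0, "TPR": 80.0,
    "CC": 0.15, "cTSI": 0.3, "CO": 0.35,
}

#: per-run PSS+ probability at the middle g-level (1.7 g)
DEFAULT_PSS_BASE = {"P1": 0.35, "P2": 0.18, "P3": 0.06}


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults are the emulated trial conditions."""

    n_participants: int = 15
    positions: tuple[str, ...] = ("P1", "P2", "P3")
    g_levels: tuple[float, ...] = (1.0, 1.7, 2.4)
    channels: tuple[str, ...] = CHANNELS
    phases: PhaseBoundaries = field(default_factory=PhaseBoundaries)
    baselines: dict = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    effects: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_EFFECTS.items()})
    intercept_sd: dict = field(default_factory=lambda: dict(DEFAULT_INTERCEPT_SD))
    noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    stature_mean: float = 1.73
    stature_sd: float = 0.08
    reference_g: float = 2.4
    tau_on: float = 60.0
    tau_off: float = 90.0
    beat_interval: float = 1.0
    beat_jitter: float = 0.05
    slow_rate: float = 10.0
    artifact_rate: float = 0.01
    pss_base_prob: dict = field(default_factory=lambda: dict(DEFAULT_PSS_BASE))
    pss_g_slope: float = 1.2
    drop_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 2:
            raise ConfigurationError("need n_participants >= 2")
        for ch in self.channels:
            if ch not in self.effects:
                raise ConfigurationError(f"no effect surface for channel {ch!r}")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class Participant:
    """Simulated participant: anthropometry plus channel intercepts."""

    pid: str
    stature: float
    body: BodyLandmarks
    intercepts: dict  # channel -> resting offset


@dataclass
class RunTruth:
    """Ground truth for one simulated run."""

    run_id: str
    participant: str
    position: str
    g_foot: float
    effects: dict  # channel -> true final-run-minute delta
    pss: bool
    criterion: str  # "hr_bp_drop" | "symptom" | "termination" | "none"
    pss_probability: float


@dataclass
class TrialData:
    """A full simulated trial with its ground truth."""

    config: SimConfig
    participants: list[Participant]
    runs: list[RunRecord]
    truths: list[RunTruth]


def _rng(seed_parts) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(seed_parts)))


def generate_cohort(config: SimConfig) -> list[Participant]:
    """Draw the cohort: statures around the trial mean, affinely scaled
    landmarks, and per-channel resting intercepts.  Deterministic per seed."""
    rng = _rng((config.seed, 0))
    out = []
    for i in range(config.n_participants):
        stature = float(
            np.clip(rng.normal(config.stature_mean, config.stature_sd), 1.40, 2.10)
        )
        intercepts = {
            ch: float(rng.normal(0.0, config.intercept_sd.get(ch, 0.0)))
            for ch in config.channels
        }
        out.append(
            Participant(
                pid=f"S{i + 1:02d}",
                stature=stature,
                body=BodyLandmarks.from_stature(stature),
                intercepts=intercepts,
            )
        )
    return out


def _response_shape(t: np.ndarray, phases: PhaseBoundaries, tau_on: float, tau_off: float) -> np.ndarray:
    """Normalized response trajectory: 0 in baseline, exponential approach
    to 1 from ramp-up onset, exponential return from ramp-down onset."""
    s = np.zeros_like(t)
    on = (t >= phases.ramp_up_start) & (t < phases.ramp_down_start)
    s[on] = 1.0 - np.exp(-(t[on] - phases.ramp_up_start) / tau_on)
    s_rd = 1.0 - np.exp(-(phases.ramp_down_start - phases.ramp_up_start) / tau_on)
    off = t >= phases.ramp_down_start
    s[off] = s_rd * np.exp(-(t[off] - phases.ramp_down_start) / tau_off)
    return s


def _beat_times(rng, phases: PhaseBoundaries, interval: float, jitter: float) -> np.ndarray:
    span = phases.recovery_end - phases.baseline_start
    n = int(span / interval * 1.3) + 10
    gaps = np.clip(rng.normal(interval, jitter, size=n), 0.3 * interval, 2.0 * interval)
    t = phases.baseline_start + np.concatenate([[0.0], np.cumsum(gaps)])
    return t[t <= phases.recovery_end]


def _artifact_limits(channel: str, clean0: float) -> tuple[float, float]:
    if channel == "CC":
        return (clean0 - CC_BAND_MM, clean0 + CC_BAND_MM)
    return DEFAULT_LIMITS.get(channel, (clean0 - 100.0, clean0 + 100.0))


def _inject_artifacts(rng, values: np.ndarray, channel: str, rate: float) -> np.ndarray:
    """Replace a random subset of samples (never the first) by
    out-of-range spikes, alternating above/below the plausibility band."""
    if rate <= 0 or values.size < 3:
        return values
    lo, hi = _artifact_limits(channel, float(values[0]))
    hits = np.flatnonzero(rng.random(values.size) < rate)
    hits = hits[hits > 0]
    out = values.copy()
    for k, i in enumerate(hits):
        out[i] = (hi + 50.0) if k % 2 == 0 else (lo - 50.0)
    return out


def _draw_pss(rng, config: SimConfig, position: str, g_foot: float) -> tuple[bool, str, float]:
    p = float(
        expit(logit(config.pss_base_prob[position]) + config.pss_g_slope * (g_foot - 1.7))
    )
    if rng.random() >= p:
        return False, "none", p
    u = rng.random()
    if u < config.drop_fraction:
        return True, "hr_bp_drop", p
    return True, ("symptom" if rng.random() < 0.5 else "termination"), p


def _drop_profile(t: np.ndarray, t0: float, duration: float, amplitude: float) -> np.ndarray:
    """Smooth transient dip: linear decline over ``duration``, 10 s hold,
    60 s linear recovery."""
    d = np.zeros_like(t)
    decline = (t >= t0) & (t < t0 + duration)
    d[decline] = -amplitude * (t[decline] - t0) / duration
    hold = (t >= t0 + duration) & (t < t0 + duration + 10.0)
    d[hold] = -amplitude
    rec = (t >= t0 + duration + 10.0) & (t < t0 + duration + 70.0)
    d[rec] = -amplitude * (1.0 - (t[rec] - t0 - duration - 10.0) / 60.0)
    return d


def generate_run(
    participant: Participant,
    position: str,
    g_foot: float,
    config: SimConfig,
    seed_parts: tuple | None = None,
) -> tuple[RunRecord, RunTruth]:
    """Generate one phase-structured multi-channel run with ground truth.

    ``seed_parts`` defaults to a substream named by (seed, participant,
    position, g); the same inputs always produce the identical run.
    """
    if position not in config.positions:
        raise ConfigurationError(f"unknown position {position!r}")
    if g_foot not in config.g_levels:
        raise ConfigurationError(f"unknown g level {g_foot!r}")
    if seed_parts is None:
        pi = int(participant.pid.lstrip("S"))
        seed_parts = (
            config.seed,
            1,
            pi,
            config.positions.index(position),
            config.g_levels.index(g_foot),
        )
    rng = _rng(seed_parts)
    phases = config.phases
    run_id = f"{participant.pid}-{position}-g{g_foot:g}"

    gain = g_foot / config.reference_g
    effects = {}
    for ch in config.channels:
        mean, sd = config.effects[ch][position]
        effects[ch] = float((mean + rng.normal(0.0, sd)) * gain)

    pss, criterion, p_pss = _draw_pss(rng, config, position, g_foot)

    # criterion-specific extras
    events: list[Event] = []
    terminated = False
    drop_t0 = None
    drop_dur = 25.0
    if criterion == "hr_bp_drop":
        drop_t0 = float(
            rng.uniform(phases.run_start + 120.0, phases.ramp_down_start - 150.0)
        )
    elif criterion == "symptom":
        t_ev = float(rng.uniform(phases.run_start + 60.0, phases.ramp_down_start))
        events.append(Event(t_ev, rng.choice(("nausea", "paleness", "dizziness"))))
    elif criterion == "termination":
        t_ev = float(rng.uniform(phases.run_start + 300.0, phases.ramp_down_start))
        events.append(Event(t_ev, "termination"))
        terminated = True

    channels = {}
    for ch in config.channels:
        if ch in ("CC", "cTSI"):
            t = np.arange(
                phases.baseline_start, phases.recovery_end, 1.0 / config.slow_rate
            )
        else:
            t = _beat_times(rng, phases, config.beat_interval, config.beat_jitter)
        base = config.baselines[ch] + participant.intercepts[ch]
        s = _response_shape(t, phases, config.tau_on, config.tau_off)
        noise = rng.normal(0.0, config.noise_sd.get(ch, 0.0), size=t.size)
        v = base + effects[ch] * s + noise
        if drop_t0 is not None and ch in ("HR", "MAP"):
            amp = 30.0 if ch == "HR" else 20.0
            v = v + _drop_profile(t, drop_t0, drop_dur, amp)
            # pre-syncopal decline modelled as smooth: suppress noise there
            quiet = (t >= drop_t0 - 5.0) & (t <= drop_t0 + drop_dur + 70.0)
            v[quiet] -= noise[quiet] * 0.98
        v = _inject_artifacts(rng, v, ch, config.artifact_rate)
        channels[ch] = (t, v)

    record = RunRecord(
        run_id=run_id,
        participant=participant.pid,
        position=position,
        g_foot=g_foot,
        channels=channels,
        phases=phases,
        events=events,
        terminated=terminated,
    )
    truth = RunTruth(
        run_id=run_id,
        participant=participant.pid,
        position=position,
        g_foot=g_foot,
        effects=effects,
        pss=pss,
        criterion=criterion,
        pss_probability=p_pss,
    )
    return record, truth


def generate_trial(config: SimConfig) -> TrialData:
    """One run per position x g-level per participant (9 runs each)."""
    cohort = generate_cohort(config)
    runs, truths = [], []
    for part in cohort:
        for position in config.positions:
            for g in config.g_levels:
                rec, tru = generate_run(part, position, g, config)
                runs.append(rec)
                truths.append(tru)
    return TrialData(config=config, participants=cohort, runs=runs, truths=truths)
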