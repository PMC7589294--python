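"""Pre-syncope (PSS) classification of centrifuge runs.

A run is PSS+ when any of three criteria is met, the first in time being
recorded: (i) a sustained (>15 s) concurrent decline of heart rate and
mean arterial pressure during rotation; (ii) a reported symptom of
nausea, paleness or dizziness; (iii) the participant requested run
termination.

Criterion (i) is operationalized as a maximal interval in which both
median-filtered 4 Hz signals decrease strictly sample-to-sample, lasting
more than ``min_duration`` seconds, with a net drop in each channel of
at least ``max(2 * residual SD, floor)`` (floor 5 bpm / 5 mmHg).  The
amplitude floor prevents noise-triggered positives; the strict-decline
requirement makes the duration criterion sharp (a 14 s drop bordered by
plateaus never qualifies, a 16 s drop of sufficient amplitude always
does).  Only the rotation window (ramp-up through ramp-down) is scanned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import medfilt

from .exceptions import UnclassifiableRunError
from .preprocess import CleanChannel
from .records import Event, RunRecord

SYMPTOM_LABELS = frozenset({"nausea", "paleness", "dizziness"})

MIN_DROP_DURATION_S = 15.0
HR_DROP_FLOOR = 5.0  # bpm
MAP_DROP_FLOOR = 5.0  # mmHg


@dataclass(frozen=True)
class PssResult:
    """Classification outcome for one run."""

    run_id: str
    label: str  # "PSS+" | "PSS-"
    criterion: str  # "hr_bp_drop" | "symptom" | "termination" | "none"
    trigger_time: float | None = None


def _window(ch: CleanChannel, t0: float, t1: float) -> tuple[np.ndarray, np.ndarray]:
    sel = (ch.times >= t0) & (ch.times <= t1)
    return ch.times[sel], ch.values[sel]


def _decline_mask(values: np.ndarray) -> np.ndarray:
    """Boolean per first-difference interval: strictly decreasing after a
    3-point median filter (suppresses single-sample noise spikes while
    preserving monotone runs)."""
    if values.size >= 3:
        values = medfilt(values, kernel_size=3)
    return np.diff(values) < 0


def _net_drop_ok(values: np.ndarray, i0: int, i1: int, floor: float) -> bool:
    """Amplitude test over samples [i0, i1]: net decrease >= max(2*resid SD, floor)."""
    seg = values[i0 : i1 + 1]
    x = np.arange(seg.size, dtype=float)
    coef = np.polyfit(x, seg, 1)
    resid_sd = float(np.std(seg - np.polyval(coef, x)))
    net = float(seg[0] - seg[-1])
    return net >= max(2.0 * resid_sd, floor)


def detect_concurrent_drop(
    hr: CleanChannel,
    map_: CleanChannel,
    window: tuple[float, float],
    min_duration: float = MIN_DROP_DURATION_S,
    hr_floor: float = HR_DROP_FLOOR,
    map_floor: float = MAP_DROP_FLOOR,
) -> float | None:
    """Earliest time at which a sustained concurrent HR+MAP drop qualifies.

    Returns the time the drop has persisted for ``min_duration`` seconds,
    or None.
    """
    t0, t1 = window
    th, vh = _window(hr, t0, t1)
    tm, vm = _window(map_, t0, t1)
    if th.size < 3 or tm.size < 3:
        return None
    # align MAP onto the HR grid (grids normally coincide; interpolation
    # is a no-op then)
    lo, hi = max(th[0], tm[0]), min(th[-1], tm[-1])
    sel = (th >= lo) & (th <= hi)
    t = th[sel]
    if t.size < 3:
        return None
    vh = vh[sel]
    vm = np.interp(t, tm, vm)

    both = _decline_mask(vh) & _decline_mask(vm)
    # maximal runs of concurrent decline
    i = 0
    n = both.size
    while i < n:
        if not both[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and both[j + 1]:
            j += 1
        # samples i .. j+1 decline; duration:
        dur = t[j + 1] - t[i]
        if dur > min_duration:
            if _net_drop_ok(vh, i, j + 1, hr_floor) and _net_drop_ok(vm, i, j + 1, map_floor):
                return float(t[i] + min_duration)
        i = j + 1
    return None


def classify_run(
    hr: CleanChannel | None,
    map_: CleanChannel | None,
    events: list[Event],
    terminated: bool,
    rotation_window: tuple[float, float],
    run_id: str = "",
    min_duration: float = MIN_DROP_DURATION_S,
) -> PssResult:
    """Classify one run as PSS+ or PSS- and record the first criterion met."""
    if hr is None or map_ is None:
        raise UnclassifiableRunError(f"run {run_id}: HR and MAP channels required")

    candidates: list[tuple[float, str]] = []
    drop_t = detect_concurrent_drop(hr, map_, rotation_window, min_duration=min_duration)
    if drop_t is not None:
        candidates.append((drop_t, "hr_bp_drop"))
    for ev in events:
        if ev.label in SYMPTOM_LABELS:
            candidates.append((ev.time, "symptom"))
        if ev.label == "termination":
            candidates.append((ev.time, "termination"))
    if terminated and not any(c == "termination" for _, c in candidates):
        candidates.append((rotation_window[1], "termination"))

    if not candidates:
        return PssResult(run_id=run_id, label="PSS-", criterion="none")
    t, crit = min(candidates, key=lambda x: x[0])
    return PssResult(run_id=run_id, label="PSS+", criterion=crit, trigger_time=t)


def classify_clean_run(
    run: RunRecord, clean: dict[str, CleanChannel], **kwargs
) -> PssResult:
    """Convenience: classify from a run record plus its cleaned channels."""
    return classify_run(
        clean.get("HR"),
        clean.get("MAP"),
        run.events,
        run.terminated,
        run.phases.rotation_window,
        run_id=run.run_id,
        **kwargs,
    )
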