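"""Artifact rejection, 4 Hz resampling and delta-epoch computation.

Cleaning follows the two-rule screen used for continuously recorded
cardiovascular signals: a sample is invalid if it lies outside
physiologically plausible limits, or if its change from the previous
valid sample exceeds a multiple of the whole-record standard deviation.
Validity is summarised over 10 s frames.  Channels that remain >95 %
valid are interpolated with a piecewise cubic spline and evaluated on a
uniform 4 Hz grid; channels at or below the gate are rejected outright.

Responses are expressed as mean 2 min changes (deltas) from the mean of
the final 5 min of the 10 min pre-run baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .exceptions import (
    ChannelRejectedError,
    ConfigurationError,
    EmptyInputError,
    InsufficientDataError,
)
from .records import PhaseBoundaries, RunRecord

#: default plausibility limits per channel (min, max).  Wide physiologic
#: envelopes intended to remove hardware glitches only.  "CC" is handled
#: relative to its starting value, see :func:`channel_limits`.
DEFAULT_LIMITS = {
    "HR": (25.0, 240.0),
    "MAP": (20.0, 200.0),
    "SV": (5.0, 200.0),
    "TPR": (100.0, 6000.0),
    "cTSI": (0.0, 100.0),
    "CO": (0.5, 15.0),
}

#: calf circumference may wander at most this far (mm) from its starting value
CC_BAND_MM = 30.0

DEFAULT_SD_MULTIPLE = 3.0
DEFAULT_RATE_HZ = 4.0
VALIDITY_GATE = 0.95
FRAME_S = 10.0
BASELINE_REF_S = 300.0
EPOCH_S = 120.0


def channel_limits(channel: str, values: np.ndarray, limits: dict | None = None):
    """Plausibility limits for a channel, resolving the relative CC band."""
    limits = {**DEFAULT_LIMITS, **(limits or {})}
    if channel in limits:
        return limits[channel]
    if channel == "CC":
        finite = values[np.isfinite(values)]
        if finite.size == 0:
            raise EmptyInputError("CC channel has no finite samples")
        v0 = float(finite[0])
        return (v0 - CC_BAND_MM, v0 + CC_BAND_MM)
    return (-np.inf, np.inf)


@dataclass
class ArtifactMask:
    """Per-sample validity flags plus a per-10 s-frame validity summary."""

    valid: np.ndarray
    frames: pd.DataFrame  # columns: frame_start, fraction_valid


def scan_artifacts(
    times: np.ndarray,
    values: np.ndarray,
    limits: tuple[float, float],
    max_sd_multiple: float = DEFAULT_SD_MULTIPLE,
    frame_s: float = FRAME_S,
) -> ArtifactMask:
    """Flag invalid samples by plausibility limits and SD-relative jumps.

    A sample is invalid if it is non-finite, outside ``limits``, or if
    its change from the previous *valid* sample exceeds
    ``max_sd_multiple`` times the whole-record SD (computed over
    limit-passing samples, so spikes do not inflate the yardstick).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size == 0:
        raise EmptyInputError("empty channel series")
    if max_sd_multiple <= 0:
        raise ConfigurationError("max_sd_multiple must be > 0")
    lo, hi = limits
    in_limits = np.isfinite(values) & (values >= lo) & (values <= hi)
    sd = float(np.std(values[in_limits])) if in_limits.any() else 0.0
    valid = in_limits.copy()
    thr = max_sd_multiple * sd
    # fast path: if no jump between consecutive in-limit samples exceeds
    # the threshold, the sequential previous-valid rule flags nothing more
    vv = values[in_limits]
    if vv.size > 1 and (np.abs(np.diff(vv)) > thr).any():
        prev = None
        for i in range(values.size):
            if not valid[i]:
                continue
            if prev is not None and abs(values[i] - prev) > thr:
                valid[i] = False
                continue
            prev = values[i]

    t0 = times[0]
    idx = np.floor((times - t0) / frame_s).astype(int)
    frames = (
        pd.DataFrame({"frame": idx, "valid": valid})
        .groupby("frame")["valid"]
        .mean()
        .rename("fraction_valid")
        .reset_index()
    )
    frames["frame_start"] = t0 + frames.pop("frame") * frame_s
    return ArtifactMask(valid=valid, frames=frames[["frame_start", "fraction_valid"]])


def validity_fraction(mask: ArtifactMask) -> float:
    """Fraction of samples flagged valid, in [0, 1]."""
    return float(np.mean(mask.valid))


@dataclass
class CleanChannel:
    """Uniformly resampled channel at ``rate`` Hz."""

    times: np.ndarray
    values: np.ndarray
    rate: float
    artifact_fraction: float

    @property
    def dt(self) -> float:
        return 1.0 / self.rate


def resample_clean(
    times: np.ndarray,
    values: np.ndarray,
    mask: ArtifactMask,
    rate: float = DEFAULT_RATE_HZ,
) -> CleanChannel:
    """Cubic-spline resample the valid samples onto a uniform grid.

    The spline passes through valid samples only and is evaluated on the
    uniform grid anchored at the first valid time; no extrapolation
    beyond the last valid sample.
    """
    frac = validity_fraction(mask)
    if frac <= VALIDITY_GATE:
        raise ChannelRejectedError(
            f"only {100 * frac:.1f}% of samples valid (gate > {100 * VALIDITY_GATE:.0f}%)"
        )
    t = np.asarray(times, dtype=float)[mask.valid]
    v = np.asarray(values, dtype=float)[mask.valid]
    # collapse duplicate time stamps, keep first
    t, uniq = np.unique(t, return_index=True)
    v = v[uniq]
    if t.size < 4:
        raise InsufficientDataError(f"{t.size} valid points; spline needs >= 4")
    spline = CubicSpline(t, v)
    dt = 1.0 / rate
    n = int(math.floor((t[-1] - t[0]) / dt + 1e-9)) + 1
    grid = t[0] + dt * np.arange(n)
    return CleanChannel(
        times=grid, values=spline(grid), rate=rate, artifact_fraction=1.0 - frac
    )


def baseline_reference(clean: CleanChannel, phases: PhaseBoundaries) -> float:
    """Mean of the final 5 min of the baseline phase."""
    if phases.baseline_end - phases.baseline_start < BASELINE_REF_S:
        raise ConfigurationError("baseline shorter than the 300 s reference window")
    sel = (clean.times >= phases.baseline_end - BASELINE_REF_S) & (
        clean.times < phases.baseline_end
    )
    if not sel.any():
        raise ConfigurationError("clean grid does not cover the baseline reference window")
    return float(np.mean(clean.values[sel]))


#: number of 2 min epochs tiling ramp-up(1) + run(5) + ramp-down(1) + recovery(5)
def epoch_edges(phases: PhaseBoundaries) -> np.ndarray:
    n = int(round((phases.recovery_end - phases.ramp_up_start) / EPOCH_S))
    return phases.ramp_up_start + EPOCH_S * np.arange(n + 1)


def epoch_deltas(clean: CleanChannel, phases: PhaseBoundaries) -> tuple[float, pd.DataFrame]:
    """Per-epoch mean changes from the baseline reference.

    Returns ``(baseline_ref, table)`` where the table has one row per
    2 min epoch from ramp-up start through recovery end with columns
    ``epoch, t_start, t_end, phase, n_samples, delta``.  Epochs without
    samples carry ``delta = NaN`` (missing marker), never a silent zero.
    """
    ref = baseline_reference(clean, phases)
    edges = epoch_edges(phases)
    rows = []
    for k, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
        sel = (clean.times >= a) & (clean.times < b)
        n = int(sel.sum())
        delta = float(np.mean(clean.values[sel]) - ref) if n else float("nan")
        rows.append(
            {
                "epoch": k,
                "t_start": a,
                "t_end": b,
                "phase": phases.phase_of((a + b) / 2.0),
                "n_samples": n,
                "delta": delta,
            }
        )
    return ref, pd.DataFrame(rows)


def final_run_delta(table: pd.DataFrame) -> float:
    """Delta of the final run-phase epoch (the 'minute 10' summary value)."""
    run_rows = table[table["phase"] == "run"]
    if run_rows.empty:
        raise ConfigurationError("no run-phase epochs in table")
    return float(run_rows.iloc[-1]["delta"])


def clean_run(
    run: RunRecord,
    limits: dict | None = None,
    max_sd_multiple: float = DEFAULT_SD_MULTIPLE,
    rate: float = DEFAULT_RATE_HZ,
) -> tuple[dict[str, CleanChannel], dict[str, str]]:
    """Clean and resample every channel of a run.

    Returns ``(clean_channels, rejected)`` where ``rejected`` maps the
    names of channels failing the validity gate (or with too few points)
    to the reason.  A rejected channel invalidates only itself.
    """
    out: dict[str, CleanChannel] = {}
    rejected: dict[str, str] = {}
    for name, (t, v) in run.channels.items():
        lim = channel_limits(name, v, limits)
        mask = scan_artifacts(t, v, lim, max_sd_multiple=max_sd_multiple)
        try:
            out[name] = resample_clean(t, v, mask, rate=rate)
        except (ChannelRejectedError, InsufficientDataError) as exc:
            rejected[name] = str(exc)
    return out, rejected


def run_epoch_table(
    run: RunRecord,
    clean: dict[str, CleanChannel],
) -> pd.DataFrame:
    """Long epoch-delta table for one run (all retained channels)."""
    parts = []
    for name, ch in clean.items():
        ref, table = epoch_deltas(ch, run.phases)
        table = table.assign(
            run=run.run_id,
            participant=run.participant,
            position=run.position,
            g_foot=run.g_foot,
            channel=name,
            baseline_ref=ref,
        )
        parts.append(table)
    if not parts:
        return pd.DataFrame(
            columns=[
                "epoch", "t_start", "t_end", "phase", "n_samples", "delta",
                "run", "participant", "position", "g_foot", "channel", "baseline_ref",
            ]
        )
    return pd.concat(parts, ignore_index=True)
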