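"""Hydrostatic biomechanics of short-arm human centrifugation.

A supine subject on a short-arm centrifuge lies along a radius of the
rotor, feet outward.  Every point of the body at radius ``r`` from the
rotation axis experiences a centripetal acceleration ``omega**2 * r``,
so a fluid column along the body axis develops the hydrostatic pressure
difference (relative to heart level)

    dP(p) = rho * k * omega**2 * (r_p**2 - r_heart**2) / 2     [mmHg]

which follows from integrating ``rho * omega**2 * r`` from the heart to
the point ``p`` (``rho`` blood density, ``k`` the Pa-to-mmHg conversion).
The profile is quadratic in radius and symmetric about the axis: when the
axis sits inside the body (heart-level rotation), pressure rises in *both*
directions away from it.  Upright standing in a uniform field ``g`` is the
linear limit

    dP(p) = -rho * k * g * g0 * (h_p - h_heart)

with ``h`` the height above the soles.  Signed g-levels follow the +Gz
aeromedical convention: positive footward (toward the feet), negative
headward, zero exactly on the axis.

Body coordinates are metres from the sole of the foot (foot = 0); the
rotation-axis position may exceed the stature (axis above the head).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import InvalidGeometryError, UndefinedGradientError

#: density of blood, kg/m^3
RHO_BLOOD = 1050.0
#: pascal -> mmHg conversion factor
PA_TO_MMHG = 0.0075
#: standard gravity, m/s^2 (exact configuration constant)
G0 = 9.81

#: landmark names, ordered foot -> crown
LANDMARKS = ("foot", "heart", "aortic", "carotid", "eye", "crown")

#: reference stature (m) to which default landmark heights belong
REFERENCE_STATURE = 1.73

#: conventional overhead offset (m) of the rotation axis above the crown
#: for the "axis above the head" position (foot radius 2.22 m at 1.73 m
#: stature)
DEFAULT_OVERHEAD_OFFSET = 0.49


@dataclass(frozen=True)
class BodyLandmarks:
    """Axial positions (m from the sole of the foot) of cardiovascular landmarks.

    Defaults are the reference 1.73 m body: heart 1.24, aortic
    baroreceptor 1.30, carotid baroreceptor 1.51, eye 1.62, crown 1.73.
    """

    heart: float = 1.24
    aortic: float = 1.30
    carotid: float = 1.51
    eye: float = 1.62
    crown: float = 1.73
    foot: float = 0.0

    def __post_init__(self):
        seq = [self.foot, self.heart, self.aortic, self.carotid, self.eye, self.crown]
        if not all(math.isfinite(x) for x in seq):
            raise InvalidGeometryError("landmark heights must be finite")
        if self.foot != 0.0:
            raise InvalidGeometryError("foot defines the origin and must be 0")
        if not all(a < b for a, b in zip(seq, seq[1:])):
            raise InvalidGeometryError(
                "landmarks must satisfy foot < heart < aortic < carotid < eye < crown"
            )

    @property
    def stature(self) -> float:
        return self.crown

    def height(self, landmark: str) -> float:
        if landmark not in LANDMARKS:
            raise KeyError(f"unknown landmark {landmark!r}; expected one of {LANDMARKS}")
        return getattr(self, landmark)

    @classmethod
    def reference(cls) -> "BodyLandmarks":
        """The reference 1.73 m body."""
        return cls()

    @classmethod
    def from_stature(cls, stature: float) -> "BodyLandmarks":
        """Scale every landmark affinely with stature from the reference body."""
        if not (stature > 0 and math.isfinite(stature)):
            raise InvalidGeometryError("stature must be positive and finite")
        s = stature / REFERENCE_STATURE
        ref = cls.reference()
        return cls(
            heart=ref.heart * s,
            aortic=ref.aortic * s,
            carotid=ref.carotid * s,
            eye=ref.eye * s,
            crown=stature,
        )


def omega_from_foot_g(g_foot: float, r_foot: float) -> float:
    """Angular velocity (rad/s) that produces ``g_foot`` (xg0) at foot radius ``r_foot``.

    Solves ``omega**2 * r_foot = g_foot * g0``.
    """
    if not r_foot > 0:
        raise InvalidGeometryError(f"foot radius must be positive, got {r_foot}")
    if g_foot < 0:
        raise InvalidGeometryError(f"foot g-level must be >= 0, got {g_foot}")
    return math.sqrt(g_foot * G0 / r_foot)


@dataclass(frozen=True)
class CentrifugeConfig:
    """Rotation geometry in body coordinates.

    ``axis_height`` is the axial position of the rotation axis measured
    from the sole of the foot; the foot radius is therefore
    ``|axis_height - 0|`` and the angular velocity is derived from the
    requested foot-level g.
    """

    axis_height: float
    g_foot: float
    label: str = ""

    def __post_init__(self):
        if not (math.isfinite(self.axis_height) and self.axis_height > 0):
            raise InvalidGeometryError("axis_height must be positive and finite")
        if self.g_foot < 0:
            raise InvalidGeometryError("g_foot must be >= 0")

    @property
    def r_foot(self) -> float:
        return abs(self.axis_height)

    @property
    def omega(self) -> float:
        """Angular velocity, rad/s."""
        return omega_from_foot_g(self.g_foot, self.r_foot)

    def radius(self, body: BodyLandmarks, landmark: str) -> float:
        """Distance (m) of a landmark from the rotation axis."""
        return abs(self.axis_height - body.height(landmark))

    @classmethod
    def for_position(
        cls,
        position: str,
        body: BodyLandmarks,
        g_foot: float,
        overhead_offset: float = DEFAULT_OVERHEAD_OFFSET,
    ) -> "CentrifugeConfig":
        """Standard rotation-axis positions.

        P1: axis ``overhead_offset`` above the crown; P2: axis at the
        crown; P3: axis at heart level.
        """
        axes = {
            "P1": body.stature + overhead_offset,
            "P2": body.stature,
            "P3": body.heart,
        }
        if position not in axes:
            raise InvalidGeometryError(f"unknown position {position!r}; expected P1|P2|P3")
        return cls(axis_height=axes[position], g_foot=g_foot, label=position)


def signed_g_at(config: CentrifugeConfig, body: BodyLandmarks, landmark: str) -> float:
    """Signed Gz (multiples of g0) at a landmark.

    Positive for landmarks footward of the axis, negative headward of it,
    exactly zero on the axis.
    """
    h = body.height(landmark)
    d = config.axis_height - h
    if d == 0.0:
        return 0.0
    sign = 1.0 if d > 0 else -1.0
    return sign * config.omega**2 * abs(d) / G0


def g_gradient(
    config: CentrifugeConfig, body: BodyLandmarks, head_landmark: str = "crown"
) -> float:
    """Head-to-foot g-gradient, percent: ``100 * (g_foot - g_head) / g_foot``.

    Uses the *signed* head-level g, so a headward (negative) head g yields
    a gradient above 100 %.  The head landmark defaults to the crown but
    is explicit because published summaries are not consistent about
    which head landmark they evaluate.
    """
    if config.g_foot == 0:
        raise UndefinedGradientError("g-gradient undefined at zero foot-level g")
    g_head = signed_g_at(config, body, head_landmark)
    return 100.0 * (config.g_foot - g_head) / config.g_foot


def hydrostatic_delta(config: CentrifugeConfig, body: BodyLandmarks, landmark: str) -> float:
    """Centrifuge hydrostatic pressure at a landmark relative to heart level (mmHg).

    ``dP = rho * k * omega**2 * (r_p**2 - r_heart**2) / 2`` — the closed
    form of the path integral of ``rho * omega**2 * r`` from heart to
    point.  Positive means pressure above heart-level pressure.
    """
    rp = config.radius(body, landmark)
    rh = config.radius(body, "heart")
    return RHO_BLOOD * PA_TO_MMHG * config.omega**2 * (rp**2 - rh**2) / 2.0


def standing_delta(body: BodyLandmarks, landmark: str, g: float = 1.0) -> float:
    """Upright-standing hydrostatic pressure relative to heart level (mmHg).

    Linear in height: ``dP = -rho * k * g * g0 * (h - h_heart)``;
    negative above the heart, positive below it.
    """
    if g < 0:
        raise InvalidGeometryError("g must be >= 0")
    h = body.height(landmark)
    return -RHO_BLOOD * PA_TO_MMHG * g * G0 * (h - body.heart)


@dataclass(frozen=True)
class PressureProfile:
    """Dense heart-referenced pressure curve along the body axis."""

    position_m: np.ndarray
    delta_p_mmhg: np.ndarray
    mode: str  # "centrifuge" | "standing"

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position_m": self.position_m, "delta_p_mmhg": self.delta_p_mmhg}
        )


def pressure_profile(
    body: BodyLandmarks,
    config: CentrifugeConfig | None = None,
    standing_g: float | None = None,
    n_samples: int = 200,
) -> PressureProfile:
    """Heart-referenced pressure over axial positions [0, stature].

    Provide either a centrifuge ``config`` or a uniform-field
    ``standing_g``.  Landmark evaluations of the returned curve agree
    exactly with :func:`hydrostatic_delta` / :func:`standing_delta`.
    """
    if (config is None) == (standing_g is None):
        raise InvalidGeometryError("provide exactly one of config or standing_g")
    if n_samples < 2:
        raise InvalidGeometryError("n_samples must be >= 2")
    pos = np.linspace(0.0, body.stature, n_samples)
    if config is not None:
        r = np.abs(config.axis_height - pos)
        rh = config.radius(body, "heart")
        dp = RHO_BLOOD * PA_TO_MMHG * config.omega**2 * (r**2 - rh**2) / 2.0
        return PressureProfile(pos, dp, "centrifuge")
    dp = -RHO_BLOOD * PA_TO_MMHG * standing_g * G0 * (pos - body.heart)
    return PressureProfile(pos, dp, "standing")


def lahc_comparator(g_foot: float, foot_radius: float = 8.00) -> CentrifugeConfig:
    """Long-arm comparator: feet at ``foot_radius`` from the axis."""
    return CentrifugeConfig(axis_height=foot_radius, g_foot=g_foot, label=f"LAHC {foot_radius:.2f} m")


def sahc_comparator(g_foot: float, foot_radius: float = 2.80) -> CentrifugeConfig:
    """Conventional short-arm comparator: feet at ``foot_radius`` from the axis."""
    return CentrifugeConfig(axis_height=foot_radius, g_foot=g_foot, label=f"SAHC {foot_radius:.2f} m")


def summarize_configs(
    configs, body: BodyLandmarks, head_landmark: str = "crown"
) -> pd.DataFrame:
    """Per-configuration head g, foot g, delta g and gradient (percent).

    The g-gradient column is NaN for zero-spin configurations, where it
    is undefined.
    """
    rows = []
    for cfg in configs:
        g_head = signed_g_at(cfg, body, head_landmark)
        row = {
            "label": cfg.label or f"axis {cfg.axis_height:.2f} m",
            "g_head": g_head,
            "g_foot": cfg.g_foot,
            "delta_g": cfg.g_foot - g_head,
            "gradient_pct": (
                g_gradient(cfg, body, head_landmark) if cfg.g_foot > 0 else float("nan")
            ),
        }
        rows.append(row)
    return pd.DataFrame(rows)
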