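"""Hydrostatic pressures along the body for the three rotation-axis positions.

Builds the reference 1.73 m body, spins it at 2.4 g (foot level) with the
axis above the head (P1), at the crown (P2) and at heart level (P3), and
prints the heart-referenced pressure at each cardiovascular landmark plus
the upright-standing comparison.  Positive mmHg = pressure above
heart-level pressure; the foot-level column shows why short-arm
centrifugation is a stronger footward fluid stressor than standing.
"""

from sahc import (
    BodyLandmarks,
    CentrifugeConfig,
    hydrostatic_delta,
    lahc_comparator,
    sahc_comparator,
    standing_delta,
    summarize_configs,
)

body = BodyLandmarks.reference()
landmarks = ("crown", "eye", "carotid", "aortic", "heart", "foot")

print("Heart-referenced hydrostatic pressure (mmHg), 2.4 g at the feet")
print(f"{'':10s}" + "".join(f"{lm:>10s}" for lm in landmarks))
for position in ("P1", "P2", "P3"):
    cfg = CentrifugeConfig.for_position(position, body, g_foot=2.4)
    row = [hydrostatic_delta(cfg, body, lm) for lm in landmarks]
    print(f"{position:10s}" + "".join(f"{v:10.1f}" for v in row))
row = [standing_delta(body, lm, g=1.0) for lm in landmarks]
print(f"{'standing':10s}" + "".join(f"{v:10.1f}" for v in row))

print("\nG-levels and head-to-foot g-gradients (head = crown):")
configs = [
    lahc_comparator(2.4),
    sahc_comparator(2.4),
    CentrifugeConfig.for_position("P1", body, 2.4),
    CentrifugeConfig.for_position("P2", body, 2.4),
    CentrifugeConfig.for_position("P3", body, 2.4),
]
print(summarize_configs(configs, body).to_string(index=False, float_format="%.2f"))
print(
    "\nA gradient of 100 % means the head experiences zero g (axis at the"
    "\ncrown); above 100 % the head is accelerated headward (axis inside"
    "\nthe body)."
)
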