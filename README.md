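# sahc — short-arm human centrifuge biomechanics and analysis

Artificial gravity delivered by a short-arm human centrifuge (SAHC)
places the supine body inside a steep centripetal-acceleration gradient:
the feet, far from the rotation axis, feel several g while the head may
feel little — or even be accelerated headward when the axis sits inside
the body.  Where the axis is placed (above the head, at the crown, or at
heart level) therefore decides how hard the cardiovascular system is
stressed at a given foot-level g, how much blood pools in the legs, how
well the brain stays perfused, and how likely a run is to end in
pre-syncope.

`sahc` is a Python library for scientists working on artificial-gravity
countermeasures and orthostatic physiology.  It provides:

- **Biomechanics** — a forward hydrostatic model of the rotating body.
  For a point at radius $r_p$ from the axis spinning at $\omega$,
  the blood-pressure offset from heart level is

  $$\Delta P = \rho\, k\, \omega^2 \left(r_p^2 - r_{heart}^2\right)/2$$

  (the integral of $\rho\,\omega^2 r$ from heart to point; $\rho$ =
  1050 kg m⁻³ blood density, $k$ = 0.0075 Pa→mmHg), with the upright
  standing limit $\Delta P = -\rho k g g_0 (h - h_{heart})$, signed
  g-levels (+Gz footward), and head-to-foot g-gradients
  $100\,(g_{foot}-g_{head})/g_{foot}$.
- **Preprocessing** — artifact rejection of physiological channels
  (plausibility limits plus an SD-relative jump rule, summarized over
  10 s frames), piecewise-cubic-spline resampling to 4 Hz gated at 95 %
  validity, and mean 2 min delta epochs referenced to the final 5 min of
  the 10 min pre-run baseline.
- **Pre-syncope classification** — PSS+/PSS− per run from a sustained
  (>15 s) concurrent heart-rate + blood-pressure decline, reported
  symptoms (nausea, paleness, dizziness), or requested termination.
- **Statistics** — random-intercept linear mixed models fitted by
  maximum likelihood with likelihood-ratio tests per effect
  (delta ~ time × position × foot-g), per-epoch one-way ANOVA with Tukey
  HSD, chi-squared tests of pre-syncope frequency by axis position, and
  Pearson correlations between delta responses.
- **Synthetic trials** — a generator producing phase-structured
  (10 min baseline, 120 s ramps, 10 min rotation, 10 min recovery)
  multi-channel runs for a 15-participant, 3-position × 3-g-level
  cohort with known ground truth, so the whole pipeline is testable at
  desk scale.

Channels handled: heart rate (HR), mean arterial pressure (MAP), stroke
volume (SV), total peripheral resistance (TPR), calf circumference (CC,
a central-hypovolaemia proxy), cerebral tissue saturation index (cTSI, a
cerebral-perfusion surrogate) and cardiac output (CO).

## Worked example

```python
from sahc import BodyLandmarks, CentrifugeConfig, hydrostatic_delta, standing_delta

body = BodyLandmarks.reference()          # 1.73 m reference body
for position in ("P1", "P2", "P3"):
    cfg = CentrifugeConfig.for_position(position, body, g_foot=2.4)
    print(position, round(hydrostatic_delta(cfg, body, "foot"), 1),
          round(hydrostatic_delta(cfg, body, "crown"), 1))
print("standing", round(standing_delta(body, "foot", 1.0), 1))
```

prints

```
P1 165.7 -30.1
P2 147.5 -12.9
P3 115.0 18.0
standing 95.8
```

i.e. with 2.4 g at the feet and the axis above the head (P1) the feet
sit ~166 mmHg above heart-level pressure while the crown sits 30 mmHg
below it; moving the axis to heart level (P3) softens the foot load to
115 mmHg and *raises* crown pressure (+18 mmHg), because above the axis
the acceleration points headward.  Standing at 1 g loads the feet by
only ~96 mmHg.

The `examples/` directory holds one narrative script per capability
(pressure profiles, simulate-and-recover, pre-syncope classification,
mixed-model analysis); each prints what it computes and what the numbers
mean.  A thin CLI mirrors the pipeline
(`sahc simulate | pressure-profile | summary | preprocess | classify |
analyze | report`).

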