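# Methods

## Hydrostatic model

The body is treated as a rigid fluid column lying along a radius of the
centrifuge, feet outward, with axial position measured in metres from
the sole of the foot (foot = 0).  The rotation-axis position may exceed
the stature (axis above the head).  A point at height $h$ has radius
$r = |h_{axis} - h|$ and experiences centripetal acceleration
$\omega^2 r$.  Integrating $\rho\,\omega^2 r$ along the column from the
heart gives the heart-referenced pressure

$$\Delta P(p) = \rho\, k\, \omega^2\, (r_p^2 - r_{heart}^2)/2 \quad [mmHg],$$

a quadratic in radius, symmetric about the axis.  Note the factor ½:
published tabulations of this quantity sometimes quote the formula
without it, but the printed pressure values themselves (e.g. ~166 mmHg
at the feet for a 2.22 m foot radius at 2.4 g) are only obtained *with*
the ½, which the integral requires; the implementation therefore
includes it.  Upright standing is the uniform-field limit
$\Delta P = -\rho k g g_0 (h - h_{heart})$, and the centrifuge profile
converges to it as the axis is moved far overhead at fixed foot g
(verified at 1000 m to <1 %).

Constants: $\rho$ = 1050 kg m⁻³ (blood), $k$ = 0.0075 Pa→mmHg,
$g_0$ = 9.81 m s⁻² exactly.  Spin rate is derived from the requested
foot-level g: $\omega^2 = g_{foot}\, g_0 / r_{foot}$.

Signed g-levels follow the +Gz convention: positive footward of the
axis, negative headward, exactly zero on the axis.  The head-to-foot
g-gradient is $100(g_{foot} - g_{head})/g_{foot}$ with the *signed* head
value, so an axis inside the body yields gradients above 100 %.  The
head landmark is an explicit parameter (default: crown) because
published summaries are not internally consistent about which head
landmark they evaluate — the conventional above-head axis matches the
crown, the heart-level axis matches eye level, and the quoted +81 %
gradient for the above-head axis is not reproducible from any single
landmark (crown geometry gives ~78 %).

The default body is the 1.73 m reference (heart 1.24, aortic
baroreceptor 1.30, carotid baroreceptor 1.51, eye 1.62, crown 1.73 m);
arbitrary anthropometries are accepted, and the cohort generator scales
landmark heights affinely with stature.  The "P1" axis sits 0.49 m above
the crown (foot radius 2.22 m at reference stature), matching the
apparatus geometry the pressure table was computed for.

## Preprocessing

Artifact screening applies two rules per channel: (i) physiologically
plausible limits — defaults HR 25–240 bpm, MAP 20–200 mmHg, SV
5–200 ml, TPR 100–6000 dyn·s·cm⁻⁵, cTSI 0–100 %, CO 0.5–15 l min⁻¹, and
calf circumference within ±30 mm of its starting value; (ii) a jump
rule flagging any sample whose change from the previous valid sample
exceeds 3.0 × the whole-record SD.  The SD is computed over
limit-passing samples so spikes do not inflate the yardstick, and the
whole-record SD (not the frame SD) is used; 10 s frames only scope the
validity reporting.  The published procedure quantifies neither the
limits nor the SD multiple; these defaults are explicit choices — wide
envelopes intended to remove hardware glitches, not physiology.  Note a
side effect: for channels whose record SD is dominated by white
measurement noise (no response trend), a 3 SD threshold sits at ~2.1 SD
of the sample-to-sample difference distribution and removes a few
percent of honest samples; occasional low-g runs therefore lose a
channel at the validity gate, which the pipeline handles by dropping
that channel only (pairwise deletion downstream).

Channels remaining >95 % valid are interpolated by a piecewise cubic
spline through the valid samples only and evaluated on a uniform 4 Hz
grid anchored at the first valid sample (no extrapolation); at or below
the gate the channel is rejected outright.  Masked samples never
influence the spline.

Deltas are mean 2 min epoch changes referenced to the mean of the final
5 min of the 10 min baseline.  Epochs tile ramp-up (1), rotation (5),
ramp-down (1) and recovery (5); empty epochs are marked missing (NaN),
never zero.  Time origin: t = 0 at the start of the constant-speed
phase, so the baseline occupies [-720, -120) s and ramp-up [-120, 0) s.

## Pre-syncope classification

A run is PSS+ on the first of: (i) sustained concurrent HR and MAP
decline during rotation; (ii) a nausea/paleness/dizziness event;
(iii) requested termination.  Criterion (i) is a duration rule ("drop
longer than 15 s"), and the natural sliding-window regression version
cannot distinguish a 14 s drop flanked by plateaus from a 15 s drop
inside a 15 s window; it is therefore implemented as a maximal run of
strictly decreasing samples (after a 3-point median filter that removes
single-sample noise spikes) concurrent in both channels, lasting
**more than 15 s**, with a net decrease in each channel of at least
max(2 × the within-interval residual SD, 5 bpm / 5 mmHg).  The
amplitude floor prevents noise-triggered positives, and the strict
decline makes the duration criterion sharp: a ≤14 s drop never
qualifies, a 16 s drop of sufficient amplitude always does.  Whether
"BP" meant systolic or mean pressure is unstated in the source
procedure; MAP is used as the recorded variable.  Only the rotation
window (ramp-up through ramp-down) is scanned.

## Statistics

Mixed models are random-intercept (per participant) linear models
fitted by **maximum likelihood**, not REML, because effects are tested
by likelihood-ratio tests between models differing in fixed effects.
The full model crosses time, position and foot-level g with all two- and
three-way interactions; the reduced model for an effect drops the
effect and every interaction containing it (df = fixed-parameter
difference).  Position is coded numerically as the axis offset from
heart level in multiples of the heart-to-crown distance (P3 = 0,
P2 = 1, P1 = 2).  The optimizer falls back from L-BFGS to Powell to
Nelder–Mead when the random-intercept variance hits the zero boundary,
where L-BFGS degenerates; at that boundary the fit provably reduces to
OLS (tested to 1e-6).  The ML log-likelihood is cross-checked against a
brute-force oracle that profiles both variances on a grid with GLS
fixed effects computed from first principles.

Per-epoch contrasts use one-way ANOVA followed by Tukey HSD
(studentized-range adjusted); no multiplicity adjustment beyond Tukey
is applied.  Pre-syncope frequency by position uses Pearson chi-squared
without continuity correction, df following the table shape (df = 2 for
three positions).  Delta–delta relationships use Pearson correlation on
final-run-epoch values paired by run.

## Synthetic trials

The generator emulates the trial structure: 15 participants (statures
N(1.73, 0.08) m, truncated to [1.40, 2.10]), 3 axis positions × 3 foot-g
levels (1.0/1.7/2.4), phases 600/120/600/120/600 s.  Channel model:
baseline + per-participant intercept + effect × s(t) + Gaussian noise,
where s(t) rises as 1 − exp(−t/60 s) from ramp-up onset and decays with
a 90 s constant from ramp-down onset.  The response shape is invented
(only epoch means are constrained by the emulated trial); the
calibrated quantity is the final-run-minute delta, whose defaults are
the observed position-dependent magnitudes at 2.4 g (HR 50/24/8 bpm,
CC 5.46/4.11/2.23 mm, cTSI −2.85/−1.88/−0.95 %, and the corresponding
SV/TPR/MAP/CO values, each with its between-participant SD).  Effects
scale proportionally with foot-level g (linear, zero at zero spin); the
dose dependence of the emulated responses shows no functional form, so
proportionality is the minimal one-parameter-free choice.

Beat-like channels (HR, MAP, SV, TPR, CO) are sampled at ~1 Hz with
jittered intervals; CC and cTSI at 10 Hz.  Artifacts are injected as
out-of-range spikes at a 1 % per-sample default rate (well below the
5 % gate).  Pre-syncope is drawn per run from a logistic probability —
base rates 0.35/0.18/0.06 for P1/P2/P3 at 1.7 g, slope 1.2 per g —
rather than a hazard over time; half of PSS+ runs receive a synthesized
concurrent HR+MAP decline (30 bpm / 20 mmHg over 25 s, with local noise
suppressed so the decline is smooth, as real vasovagal trajectories
are), the rest a symptom event or termination flag.  All randomness
derives from one root seed through named per-run substreams; identical
inputs reproduce runs bit for bit.

What the generator does **not** emulate: beat-to-beat waveform
morphology, baroreflex dynamics and autocorrelated physiological noise,
between-day session effects, early run termination (channels continue
after a termination event), and any coupling between channels beyond
the shared dose/position structure.  Passing recovery tests therefore
show that the pipeline is unbiased and calibrated under the stated
statistical structure, not that it is robust to every artifact of real
recordings.

## Validation problem sizes

The stochastic validation suites are sized for a desktop run: parameter
recovery uses 100 cohorts of 15 participants at 2.4 g with the HR/CC/
cTSI channels; type-I-error calibration uses 1000 null replicates of an
additive mixed model (15 participants × 9 runs × 2 epochs, df = 1 LRT
for position, a size chosen for asymptotic LRT calibration) and 1000
independence-simulated contingency tables; pre-syncope power uses 100
cohorts with HR/MAP.  Known numerical tolerances: spline resampling
reproduces cubics to 1e-9 and a 0.1 Hz sine sampled at 1 Hz to ~4e-3
(O(h⁴), worst at the not-a-knot boundary); the closed-form pressure
matches a 20 001-step trapezoid integral to <0.01 mmHg.

## Limitations

The hydrostatic model is static: no pulsatility, no arterial/venous
distinction, no baroreflex, no hydrostatic-indifference-point shift
with volume redistribution.  The published human-trial statistics
(fixed-effect tables, test statistics) are not reproducible without the
raw recordings; they enter only as generator calibration.  The
classifier's signal criterion is sharp on clean traces but, like any
strict-monotonicity rule, loses sensitivity on heavily noise-corrupted
declines; symptom and termination criteria are unaffected.
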