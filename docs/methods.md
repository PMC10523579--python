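# Methods

`ectpipe` reimplements the quantitative analysis stack of a wire-based 3D
engineered-cardiac-tissue (ECT) platform.  A tissue is suspended between two
flexible elastomer wires; its twitch force bends the wires, its Ca²⁺
handling is read out with a fluorescent dye, its electrophysiology with a
sharp electrode, its morphology from brightfield and confocal images, and
its molecular state from qPCR and concentration–response assays.  This note
describes the models, the tunable parameters that matter, the synthetic-data
generator that stands in for raw recordings, and the numerical choices.

## Trace models and per-beat fitting

**Twitch force.**  Each contraction is modeled as the product of a rising
and a falling logistic ("double sigmoid"):

    F(t) = B + A' * s((t - t_up)/tau_up) * s(-(t - t_down)/tau_down),
    s(z) = 1/(1 + e^-z)

with baseline `B` (µN), scale `A'`, edge positions `t_up < t_down` (s) and
edge time constants `tau_up`, `tau_down` (s).  Beats are first segmented by
prominence-based peak detection (`detect_twitches`; windows extend to the
midpoints between neighboring peaks, and peaks closer than the minimum
separation merge into the more prominent one).  Each window is fitted by
bounded least squares (`scipy.optimize.curve_fit`) with a deterministic
initialization — `B` from the 10th percentile, `A'` from the range, edge
positions from half-max crossings of a lightly smoothed copy, taus at 10%
of the half-max span — and up to five seeded, jittered restarts.  A window
with zero amplitude, or one that never converges, is returned flagged
rather than raising.

**Kinetic metrics are read from the fitted curve, never from raw samples**:
the curve is scanned on a dense grid (≥10× the sampling rate, at least
10 kHz) and each level crossing refined by bisection.  Amplitude is fitted
peak minus fitted baseline; twitch duration is the width at 50% of peak
above baseline (FWHM); contraction time is 10%-of-peak→peak and relaxation
time peak→10%-of-peak.  For any unimodal fit the 10–10% width ≥ FWHM ≥
90–90% width by construction.

**Ca²⁺ transients** use a biexponential pulse,

    F(t) = B + A' * (e^-(t-t0)/tau_decay - e^-(t-t0)/tau_rise),  t >= t0,

with `tau_decay > tau_rise` enforced structurally (the decay constant is
parameterized as `tau_rise + exp(u)`).  The fitted peak time obeys the
closed form `t0 + tau_d tau_r/(tau_d - tau_r) ln(tau_d/tau_r)`.  Rise time
is 10→90% on the ascent and decay time 90→10% on the descent; these level
conventions are a package choice (the field uses several) and are stated
here so results are comparable.  Transient duration is the 50% width.

## Contractility: wire tracking, calibration, FFR/PRP

Each video frame is reduced to a wire centerline in two passes: a coarse
per-column row-argmax of an along-wire-smoothed image, then a
background-subtracted intensity centroid inside a ±8 px band around the
coarse position (the band keeps off-wire noise out of the centroid; the
background and noise floor are estimated per frame from the median and
MAD).  A quadratic is fitted through the column centroids; the scalar
deflection is the maximal perpendicular distance between the curve and the
chord through its endpoints (a mid-span variant is selectable).  Frames
with fewer than half their columns usable are flagged and interpolated
from neighbors.

The displacement→force relationship is a property of the wire lot,
measured experimentally; it is therefore an input artifact (JSON) rather
than a constant: linear (µN/px), polynomial through the origin, or a
lookup table.  Monotonicity and f(0)=0 are verified at load; violating
calibrations are rejected.

Protocol analysis fits the last five beats of each paced segment and takes
their mean amplitude as steady state.  The force–frequency relationship
(FFR) divides each frequency's steady-state amplitude by the 1 Hz value; a
paced segment immediately following a rest gap is the post-rest probe, and
post-rest potentiation (PRP) is its first fitted beat amplitude over the
1 Hz value.  A protocol without a 1 Hz segment is an error because the
normalization is undefined.

## Ca²⁺ ROI logic

The ROI is built from the temporal-mean image: pixels between a low
percentile (background) and a high percentile (saturated artifacts) are
kept and specks removed by morphological opening.  The percentile cuts are
operator-facing parameters: the low cut should sit near the background's
area fraction of the field and the high cut below the artifact fraction
(defaults 10 and 99.5).  The per-frame ROI mean is reported as
ΔF = F − F₀ with F₀ the mean over the pre-stimulus frames; ΔF/F₀ is
available by flag but ΔF is the default amplitude convention.

## Action potentials

Sampling must be ≥1 kHz (the generator default is 10 kHz).  The derivative
is a Savitzky–Golay first derivative (0.5 ms window, order 2).  Upstroke
runs are samples whose derivative exceeds 20% of the global maximum; the
activation time is the *center of the contiguous run* of samples within 1%
of the beat's derivative maximum — for a linear upstroke this is the
upstroke midpoint regardless of the smoothing window, which is what makes
sub-sample APD accuracy possible.  RMP is the mean of the 50 ms window
ending just before the upstroke; amplitude is peak − RMP; APD_x runs from
activation to the first interpolated crossing of peak − x%·amplitude, with
one-sample hysteresis so single-sample noise dips do not terminate the
plateau early.  Repolarization levels are referenced to the amplitude
measured from RMP (the dominant convention), and APD30 ≤ APD50 ≤ APD90 is
asserted on every accepted beat.

## Morphometry

**Tissue area.**  The segmentation pipeline order is fixed: CLAHE contrast
adjustment (clip 0.01) → asymmetric Gaussian smoothing → min–max
normalization → adaptive local-mean threshold (block 101, offset 0.01 of
the dynamic range; tissue is the dark phase) → small-object removal →
morphological closing → hole fill → largest connected component.  The
asymmetric smoothing exists to suppress the thin bright wires: for a line
spanning the field only blurring *across* the wire attenuates it, so the
larger sigma is across the wires (default (4, 1) px rows×cols for
horizontal wires).  Area is pixel count × px_size².  A blank image or a
component hugging more than half the border is flagged "poor segmentation"
and reports no area, mirroring the manual QC step in which overlaid
contours are inspected and poor segmentations excluded.

**Sarcomeres.**  Z-discs are detected as connected components of the
thresholded scale-normalized Laplacian-of-Gaussian response (scales 1.5,
2.5, 4 px; threshold 20% of the response maximum), each contributing an
intensity-weighted centroid and a principal-axis orientation folded to
[0°, 180°).  Linking requires: center distance within 1.0–2.6 µm (the
physiological sarcomere range), disc orientations within 20°, and the
connecting vector within 30° of the discs' normal; each disc takes at most
one neighbor per side along its normal, kept when mutual.  Sarcomere
length is the center distance; sarcomere angle is the connecting vector's
direction.  Per image the median length and the angle SD are computed; the
angle SD centers angles on the axial (doubled-angle) circular mean and
takes a plain SD of the ±90°-folded deviations, so small and moderate
dispersions stay on the intuitive degree scale (beyond ~40° folding
compresses the value; recovery remains monotone).  Group values are means
of per-image values ± SEM.

## Dose–response and qPCR

The 4PL curve `y = bottom + (top − bottom)/(1 + (EC50/x)^hill)` is fitted
by least squares in log₁₀-concentration space with the Hill sign seeded
from the data's direction (Spearman correlation) — positive for agonists,
negative for inhibitors, so EC₅₀ and IC₅₀ share one parameterization.  A
constrained-bottom option serves full inhibitors.  Replicate tissues are
fitted individually and the potency aggregated as the geometric mean EC₅₀
(a pooled fit is available by flag).  The inverse map
`x = EC50·((top−bottom)/(y−bottom) − 1)^(−1/hill)` supports standard-curve
interpolation and is exact on the open response range.

ΔΔCt quantification averages duplicate wells, subtracts the arithmetic
mean Ct of the reference genes (GAPDH and RPL13A by default — equivalent
to their geometric mean in expression space, and provably identical to
using a single pseudo-reference with the mean Ct), references the
calibrator group's mean ΔCt per gene, and reports RQ = E^(−ΔΔCt) with
amplification efficiency E = 2 by default (configurable).  Duplicate
spreads above 0.5 cycles are flagged.  Group comparisons use a two-tailed
unpaired t-test for two groups and one-way ANOVA followed by pairwise
t-tests with Šidák adjustment p_adj = 1 − (1 − p)^m for more.

## Synthetic data: what it emulates and what it does not

Every generator returns a `GroundTruth` record (modality, full parameter
map, seed) from which the value each analysis stage should recover is
computable in closed form or via a stated dense-grid oracle.  All
randomness flows through `numpy.random.default_rng(seed)`; identical
parameters and seed give bit-identical artifacts.

* Traces (twitch, Ca²⁺, AP) are exact model waveforms on a stimulus
  schedule plus i.i.d. Gaussian noise; overlapping-tail protocols beyond a
  5% tolerance are rejected as unphysical.  The AP waveform is piecewise —
  flat RMP, linear upstroke, linear plateau decline, exponential
  repolarization — chosen so APD₃₀/₅₀/₉₀ and dV/dt_max have closed forms.
* The wire video renders a Gaussian-profile parabolic arc through two
  fixed anchors whose mid-span sag follows a commanded trace, over a flat
  background with Gaussian noise scaled by the requested SNR.
* The brightfield still is a dark ellipse (true area πab recorded) between
  two bright tangent wires on a noisy background.
* The sarcomere image tiles the field into domains; each domain holds
  parallel myofibrils of short anisotropic-Gaussian Z-disc bars at the
  requested spacing, with per-domain orientations drawn from a normal of
  the requested dispersion.  True centers, orientations and links are
  recorded.
* Dose–response tables sample the 4PL curve with multiplicative CV noise;
  Ct tables are built backwards from programmed RQs with a per-sample
  loading offset that cancels in ΔCt.

Not emulated: optical PSFs, photobleaching, motion of the tissue body,
ratiometric dyes, and non-Gaussian camera noise.  Passing tests therefore
demonstrate correctness of the computational pipeline under its stated
model assumptions, not robustness to every artifact of real microscopy.

## Validation conditions and problem sizes

The benchmark suite (`ectpipe.benchmarks`, driven by the test suite and by
`scripts/acceptance.py`) uses: 100 twitches spanning 5–100 µN and FWHM
80–200 ms at SNR 10; a 200-frame 256×64 px wire video at SNR 10 with a
10 µN/px linear calibration; 50 noisy Ca²⁺ transients at SNR 10; 1000
randomized AP waveforms; four ellipses spanning ≈0.5–1.9 mm²; eight Z-disc
lattices covering spacings 1.3–1.8 µm and dispersions 0–40°; 200 noisy 4PL
simulations (8 concentrations, triplicate, 5% CV).

Two sampling-rate choices deserve explanation.  Millisecond-scale accuracy
on contraction/relaxation times at SNR 10 is information-limited: even the
efficient estimator (least squares initialized at the truth) shows ~5–10 ms
95th-percentile errors at 1 kHz, so the twitch benchmark samples force
traces at 20 kHz, where the same estimator reaches ~1–2 ms.  Likewise the
Ca²⁺ benchmark samples at 500 Hz (a high-speed-imaging rate).  Both rates
are free parameters of the platform and are stated here as the package's
own study conditions.

## Known limitations

* The double-sigmoid peak position is weakly identified for plateau-topped
  pulses; contraction/relaxation times inherit that uncertainty.
* The angle-SD statistic compresses at dispersions approaching the axial
  folding limit (~50°).
* The adaptive local-mean threshold captures the tissue via its closed
  boundary ring plus hole-filling; silhouettes clipped by the image border
  segment poorly and should be flagged by the border QC rule.
* `fit_4pl` assumes homoscedastic noise; no weighting scheme is offered.
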