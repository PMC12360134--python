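# Methods

## The measurement model

A steadily swimming elongate fish propagates a lateral bending wave from
head to tail. Digitized dorsal-view video yields, per frame, a 200-point
body midline parameterized by arc length; lateral-view video yields four
anatomical landmarks (snout tip, pectoral-fin insertion, pectoral-fin tip,
pelvic-fin insertion), three of which are also visible dorsally so the two
orthogonal views can be fused into 3-D tracks. The package estimates the
standard undulatory-swimming variable set from one complete tail-beat
cycle per trial and compares the variables across imposed flow speeds.

All lengths are normalized by body length (BL, snout tip to tail tip);
speeds are in BL s⁻¹ unless a dimensionless number requires SI units.

## Per-trial estimators

**Cycle detection.** The tail-tip lateral trace is mean-centred by
harmonic regression: a fit of offset + linear drift + a sinusoid at the
dominant frequency (located on a 16×-zero-padded periodogram, since a
trace of only 2–3 cycles puts the raw DFT bins ~0.5 Hz apart), of which
only the offset and drift are subtracted. A plain linear detrend over a
non-integer number of cycles would bias the zero crossings; the harmonic
term absorbs the oscillation so the trend estimate is unbiased. The
centred trace is low-passed with a zero-phase moving average of width
fps/(10·f) and the first three zero crossings are taken: crossings one and
three share a direction and bracket exactly one oscillation. Crossings are
rounded to the nearest frame, so the period is quantized at 1/fps (0.1% of
a 2.5 Hz cycle at the 1000 fps of the reference recordings). A flat trace
(range < 10⁻⁶ BL) or fewer than three crossings is an error, not a
default.

**Amplitude.** Peak-to-peak tip excursion within the cycle, measured on a
cubic Savitzky–Golay-smoothed trace (window fps/(10·TBF)). A local
polynomial preserves the excursion extrema, whereas raw extrema of a noisy
trace are biased upward by roughly three noise standard deviations each.

**Wave speed and wavelength.** For each midline station the lateral
series over the cycle is least-squares fit with cos/sin terms at the TBF;
the station phase φ(u) is unwrapped from tail toward head and its slope
s = dφ/du estimated by least squares over the posterior half of the body
excluding the final 5% (u ∈ [0.50, 0.95]), where the traveling wave has
appreciable amplitude but tip digitizing noise does not dominate. Then
c = 2π·TBF/|s| and λ = c/TBF — both derive from the same slope, so
c = λ·TBF holds to machine precision. Stations with oscillation power
below 1% of the tip's are excluded. A slope below 0.5 rad/BL (a standing
wave) or of the wrong sign (tail-to-head propagation) raises an error.
The single-frequency phase-gradient estimator was chosen over
zero-crossing tracking because it uses every frame of a short, one-cycle
window and degrades gracefully with noise; both the fit region and the
thresholds are configurable.

**Curvature.** Each frame's midline is smoothed with a Savitzky–Golay
filter (default window 15 of 200 stations, order 3), and the parametric
curvature |x′y″ − y′x″|/(x′² + y′²)^{3/2} is evaluated from the filter's
own derivatives. Because the formula is invariant to the (uniform)
parameter spacing, index-space derivatives suffice; the result is scaled
to BL⁻¹. Against closed-form fixtures, circle arcs of radius 0.25–2 BL are
recovered within 2% at interior stations and the sine fixture
y = 0.1·sin(2πx) gives k_max within 2% of 0.1·(2π)² ≈ 3.948 BL⁻¹. The
reported k_max is the maximum over stations and cycle frames, with its
arc-length fraction.

**Posture angles.** Body angle: per frame, atan2(z₁ − z₄, |x₁ − x₄|)
between the snout and pelvic-insertion landmarks in the lateral view
(positive = snout up), averaged over the cycle. Angle of attack: per
frame, the inclination asin(|Δz|/‖Δ‖) of the 3-D pectoral-tip →
pelvic-insertion chord against the horizontal plane, signed by Δz
(positive when the pelvic insertion sits above the fin tip), averaged over
the cycle. The sign convention for AA is a package choice; only its
magnitude enters the cross-speed comparison in practice. Both require the
landmarks in at least half the cycle frames; missing merged 3-D tracks
make AA missing (NaN), never an invented value.

**Dimensionless numbers.** Re = U·BL/ν with ν = 10⁻⁶ m² s⁻¹; St = TBF·A/U.
With A in BL and U in BL s⁻¹, St equals fin effort (TBF·A) divided by
speed, and the code computes it through that identity so the two outputs
can never disagree. Undulatory propulsion is most efficient for
St ≈ 0.2–0.4, which is the band the St–Re table flags.

## View merging and file handling

The two camera views share the streamwise axis. The merged 3-D landmark is
(mean of the two views' x, dorsal y, lateral z); frames where the views'
x estimates disagree by more than 2% of BL are flagged and excluded.
Missing landmark detections stay masked — linear interpolation across gaps
of at most 3 frames exists but is opt-in, to avoid manufacturing
kinematics. Coordinate files are delimited text (comma or tab,
auto-detected), one row per frame, frame index first; calibration is a
single length-per-pixel scale. Files written by the package read back
bit-exactly (shortest round-trip float formatting).

## Cross-speed statistics

The design is repeated measures: every individual swims at (up to) every
speed, one analysed tail beat per cell. The "repeated-measures ANOVA" is
the additive fixed-effect model y ~ speed + individual fit by least
squares, with the speed F from sequential sums of squares (individual-only
vs. full model). On the reference design — 5 individuals, 11 speeds, 4
missing cells, 51 trials — this gives df = (10, 36), and in general
(k − 1, N − 1 − (k − 1) − (n − 1)). No interaction term exists (one
observation per cell), and no sphericity correction is applied.

Each variable passes through an assumption gate first: Levene's test
(median-centred) across speed groups and Shapiro–Wilk on the
additive-model residuals (residuals, not raw values, are what the
normality assumption concerns). If either rejects at α = 0.05, the
aligned-rank-transform (ART) ANOVA replaces the parametric one: the
response is aligned for the speed effect (full-model residual plus the
estimated speed effect), ranked with average ties, and the same blocked
ANOVA is run on the ranks. Under their respective nulls (normal for the
parametric test, log-normal for ART) both hold a 5% type-I error within
Monte-Carlo error, which the acceptance suite verifies at 10000
replicates.

Post hoc, all pairwise speed contrasts are taken from the fitted model
(estimates and standard errors adjusted for individual blocks and unequal
group sizes) with Tukey–Kramer adjustment via the studentized range at the
model's residual df. The compact letter display uses insert-and-absorb:
significantly different speeds never share a letter; non-different speeds
always share at least one.

The PCA z-scores each variable and decomposes the correlation structure by
SVD. The default variable set is the 8 independent variables (AA, BA, tail
amplitude, k_max and its location, Re, TBF, wave speed); wavelength, fin
effort and St are excluded as exact functions of the others. The
contribution of variable j to axis k is 100·loading²(j,k), axes are
oriented so their scores correlate positively with speed (a sign
convention only), and percent variance over all axes and contributions
within each axis both sum to 100 by construction.

## The synthetic swimmer

The generator exists to give every estimator a ground-truth target, and
its defaults are the reference study's conditions. The dorsal-view wave is

y(u, t) = (A_pp/2) · u^p · sin(2π(u/λ − f·t) + φ₀) + ε,  ε ~ N(0, σ²)

at arc-length fraction u, with the streamwise coordinate reconstructed so
the 200 sample points stay equally spaced in arc length (an inextensible
midline). The amplitude envelope u^p (default p = 2) is the simplest
smooth, monotone, single-parameter model of posterior amplitude growth.
The lateral view applies a rigid pitch to the anterior body axis (snout
and pectoral-insertion landmarks raised above the pelvic insertion by
their streamwise distance times tan BA), and the pectoral-tip landmark is
placed so the 3-D chord to the pelvic insertion (length 0.2 BL, 20°
horizontal sweep) has the prescribed pitch. The pelvic insertion sits at
arc-length fraction 0.45 and the pectoral insertion at 0.25 by default.
Noise is i.i.d. Gaussian per coordinate — digitizing jitter, the simplest
falsifiable model — at 0.002 BL (≈0.3 mm on a 16 cm fish) by default.

The cohort design defaults to the reference layout: 5 individuals (body
length 15.8 ± 0.8 cm), 11 speeds {0.5 … 6} BL s⁻¹, 4 cells missing for one
individual (51 trials), 1000 fps, 2.5 tail-beat cycles per trial. Speed
trends for TBF, wave speed, fin effort and body angle linearly interpolate
the published per-speed cohort means, so the end-to-end statistics see the
qualitative pattern of the original study; wavelength and amplitude are
derived as c/f and fin effort/f, making c = λ·f exact in the ground-truth
table. Individual offsets (SDs matched in magnitude to the published
per-speed SDs) are drawn once per individual; each trial adds jitter at
half that SD, since a single tail beat samples the fish's state noisily.
All per-cell randomness is drawn on the full design grid up front, so the
trial generated for a cell is independent of which other cells exist.

What the generator does **not** emulate: hydrodynamics (no self-propulsion
constraint, no fluid forces), non-sinusoidal or time-varying gaits,
body-wave asymmetry, autocorrelated tracking error, and the
view-foreshortening interplay between pitch and the dorsal midline.
Passing parameter-recovery tests therefore demonstrates estimator
correctness on idealized traveling waves with digitizing noise — not
robustness to every artifact of real video.

## Numerical and design choices

- Zero crossings are interpolated linearly between frames, then rounded to
  frames; the cycle period is exactly (end − start)/fps.
- The first complete cycle of the trace is analysed (one tail beat per
  trial, as in the reference design).
- Degenerate inputs fail loudly with typed errors (flat trace, standing
  wave, coincident landmarks, duplicate midline points, constant variable
  in the PCA) rather than returning silently wrong numbers; the pipeline
  driver records per-trial failures and continues, failing only if every
  trial fails.
- In the ART alignment, aligned values whose total range is below 10⁻⁹ of
  the response scale are treated as exactly tied before ranking, so
  floating-point dust cannot split a degenerate all-tied case into 51
  distinct ranks.
- The arc-length sanity check on input midlines (each frame within 10% of
  the stated body length) is evaluated on a lightly smoothed polyline,
  because the raw length of a 200-point polyline is biased upward by
  independent per-point noise.
- Whether the reference analysis used sequential or marginal sums of
  squares on the unbalanced table is not stated anywhere we could check;
  sequential (individual first, then speed) is used because it reproduces
  the published degrees of freedom and tests the within factor after
  removing block differences.

## Problem sizes

The test suite and the acceptance script use the reference conditions
directly where they are cheap (51-trial cohorts, 50-trial recovery sweeps
at 1000 fps, 10000-replicate calibration) and a coarser 250 fps frame rate
for pipeline smoke tests, where only the plumbing — not estimator
precision — is under test.
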