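# Methods

## The assay and what the pipeline measures

Negative geotaxis is the innate upward climb of flies after being knocked
to the bottom of their vial.  The instrumented assay films a rack of 12
vials (one genotype x sex per vial, the biological replicate) at 60 fps and
1280x720 while a motor taps the rack and pauses four times; each 15-second
pause is one climbing trial ("trim"), treated as a technical replicate.
The pipeline extracts, per vial and 0.5 s time step: mean climbing height
(cm), instantaneous climbing velocity (cm/s), and the percentage of flies
in the lower/middle/upper thirds of the vial (low/middle/high performers).

## Trial splitting

Motion energy per frame is the summed pixel area of moving foreground
regions that survive a 2,000 px^2 minimum-area filter ("movement units").
Foreground comes from a per-pixel background model applied frame by frame:

* **running Gaussian** (default): exponentially weighted mean and variance
  per pixel (window 500 frames, initial sd 15 grey levels); a pixel is
  foreground when its squared deviation exceeds 16x the modelled variance.
  This is the single-component member of the mixture-of-Gaussians family.
* **frame differencing** (pure-array test mode): absolute difference to the
  previous frame, threshold 16 grey levels.

Tap bursts are local maxima of the movement trace above 100,000 units
(`scipy.signal.find_peaks`, height criterion only).  A trial starts at the
first subsequent frame below the 30,000-unit inactivity threshold — this
aligns trial time zero with the end of tapping — and ends with the first
run of >= 270 consecutive sub-threshold frames, truncated at the next tap
peak and capped at 900 frames.  If more than four candidates emerge the
four with the highest preceding peaks are kept; fewer are passed through
with a warning.  A local-maximum search cannot mark the very first sample
of a trace, so synthetic protocol traces place the first tap a few frames
in (as the physical device does).

The area thresholds are pixel quantities defined at 1280x720.
`SplitterConfig.scaled(image_size)` rescales them by the pixel-area ratio
for reduced-resolution runs; frame-count parameters are time-based and stay
fixed.  All reduced-resolution analyses in this package use that scaling.

## Vial detection

The deployed detector interface is any callable `frame -> detections`; a
learned backend can be plugged in unchanged.  The shipped rule-based
backend exploits the scene structure: vials are tall, faintly dark vertical
strips on a white field.  Column-mean darkness (255 - grey) is thresholded
at 4 grey levels; contiguous column runs at least 4 px wide are candidate
strips, and each strip's vertical extent is read off its row-mean darkness
profile.  Confidence is the strip's mean darkness normalised by the
strongest strip, so a populated holder yields ~1.0 confidences and a blank
frame yields nothing.  Detections below 0.85 confidence are dropped, the
rest sorted by x1 and matched positionally to the metadata vial numbers
(leftmost = vial 1); metadata vials beyond the detection count raise an
error naming the missing vials.  When exactly as many detections survive as
metadata rows, positions map to the sorted metadata numbers directly, which
makes the matching idempotent on its own output and coincides with
positional numbering for a full rack.

Boxes use pixel coordinates, origin top-left, y downward, half-open
[x1,x2) x [y1,y2).  Evaluation pairs detections with ground truth greedily
by IoU; unmatched truth scores 0.

## Fly tracking and zoning

Per trim, the background is the per-pixel **maximum** of every frame's red
channel, normalised to [0,1] — flies are dark and transient, so the maximum
removes them.  Each frame's deficit (background - frame, clipped at 0) is
normalised by its own maximum and binarised at 0.12 above the image midline
and 0.18 below (the two chamber halves are lit differently); a frame whose
raw deficit never exceeds 0.10 contains no fly and yields nothing, which
also prevents noise amplification in empty scenes.  Connected components
between 4 and 400 px^2 become centroids; multi-fly clumps above the bound
are dropped rather than split (centroid-level counting, no identity
linking).  Each centroid is assigned to the containing vial box and to a
zone by height-from-bottom (y2 - y): LP below 1/3 of the vial height, HP at
or above 2/3, MP between.  The boundary fractions are configurable; thirds
are the symmetric default since nothing in the assay's definition fixes
them.  During the first 60 frames, centroids within 10% of the vial height
of the vial top are not counted (the "adder" guard against false positives
before flies are fully in view); both magnitudes are configuration.

Tracking covers the first 780 frames (13 s) of each trim; summaries sample
every 30th frame (2 Hz, 26 time points).  Height converts to cm as
`17 * adj / 720` — chamber holder height over vertical image resolution —
with `adj` the height-from-bottom plus an optional per-vial offset
(default 0); reduced-resolution runs substitute their own image height.
Zone percentages use detected flies as the denominator, which guarantees
the three zones sum to 100% whenever anything is detected; vials with no
detection at a time point are left missing rather than imputed.  Across the
four trims, means and standard errors (n-1 sd / sqrt(n)) are taken per time
point and vial; a single-trim cell reports SEM 0 with a warning so table
shapes stay stable.

## Aggregation

Folders are processed in lexicographic order.  Each metadata row becomes a
replicate labelled `<Genotype>_rep<N>`, N counting occurrences of that
genotype within the same sex **across the whole experiment** (continuous
counting keeps labels unique when genotypes recur across recordings).  Ten
wide tables result (2 sexes x 5 modalities); velocity is
`np.gradient(height, time)` per replicate — central differences inside,
one-sided at the ends, exact on linear series — computed before any
averaging.  Time grids merge on exact second values; unobserved cells stay
missing, no interpolation.

## Statistics

Per sex and modality the wide table is melted to (Genotype, Replicate,
Time, Measurement, Subject), restricted to the control, the selected
comparisons, and t <= Tmax (default 13 s).  The mixed model

    y_ijt = b0 + b_geno + b_time + b_genoxtime + u_j + u1_j * t + e_ijt

is fitted by REML (statsmodels `mixedlm`), with genotype treatment-coded
against the control, time categorical in the fixed effects, and a random
per-subject intercept plus slope on numeric time (the dual use of time is
deliberate: categorical fixed effects capture arbitrary trajectory shape,
the numeric random slope captures subject-level drift).  Fixed-effect
significance uses Wald z-tests.  For one comparison genotype the main
effect and its 25 interactions are combined with the unweighted harmonic
mean p-value, `min(1, r / sum 1/(p_i + 1e-12))`; the epsilon sits inside
each reciprocal because its only role is guarding p_i = 0.  HMP is
conservative and valid under the strong dependence among these Wald tests;
no further multiple-testing correction is applied across the per-timepoint
Mann-Whitney grid, which is reported as -log10(p) for visual salience only.
Mann-Whitney U tests are two-sided, exact when the combined sample is
tie-free and <= 20, tie-corrected normal otherwise; two identical groups
report p = 1 by convention.  Peak metrics are each replicate's maximum over
[0, Tmax], compared with the same U test.  Non-converged or singular LME
fits are flagged and reported rather than aborting a batch report.

Calibration (recomputed by the test suite): simulating from the model
equation with 20 subjects per genotype, 5 time points, sigma_b = 0.5 and
residual sd 0.3 gives a genotype main-effect type-I rejection rate of 0.06
at alpha = 0.05 over 200 runs, and >= 95% power at p < 0.001 under a
5-residual-sd genotype offset over 100 runs.  The simulation draws no
random slope; the fitted model still estimates one, so some fits sit at the
variance boundary and are flagged — p-values remain calibrated.

## The synthetic scene generator

`synthgen` emulates exactly the features downstream stages key on: a white
field; 12 slightly-tinted vial strips with dark walls; flies as dark filled
disks (radius 5 px at full scale); four cycles of a 5-frame tap burst
(global frame jitter plus blob scattering — producing the high-motion
spikes the splitter needs without modelling the lever) followed by a
climbing pause; Gaussian pixel noise (sd 2 grey levels by default).  Fly
size and contrast are free parameters of the artifact, not measured values.

The motion model: grounded flies start spread along the vial bottom
(stratified horizontal slots with jitter and a small vertical pile-up);
during a pause each fly climbs at a per-bout speed drawn from
N(climb_speed, speed_sd), resampling its behavioural state (climbing vs
stalled, and its bout speed and direction) about twice per second; flies
that reach the vial top wander up and down within the top quarter of the
vial rather than freezing — topped-out flies walking back down are a known
feature of the physical assay.  Optionally a fly slips: it falls instantly
to the vial bottom and resumes climbing at its normal speed, with a fixed
per-frame hazard that activates at a per-fly endurance onset drawn
uniformly from a configurable window.  Slips are the mechanism behind the
"collapse" scenario: they cap sustained height gain while leaving
instantaneous climbing velocity untouched, and the onset heterogeneity and
top-wandering are what give control and mutant replicates comparable
velocity variance — with a degenerate motion model (identical starts,
frozen top, synchronous collapse) the velocity comparison becomes
trivially significant and the assay's characteristic
position-significant/velocity-NS dissociation cannot occur.

Scenario presets: control and collapse lines share all parameters
(3.0 +/- 0.8 cm/s bouts, 20% stall fraction, 1.2 cm/s top-wander, slip
onset uniform in 3-13 s) and differ only in slip rate (one per 12 s vs one
per 3 s of active hazard).  These are fixed, documented choices in the
range reported for healthy climbing flies.

What the generator does **not** emulate: glare, condensation, shadows,
perspective, occlusion by vial plugs, fly identity or orientation, wing
posture, or the lever mechanics.  Passing tests therefore demonstrate the
correctness of the algorithms under the stated scene model, not robustness
to real-video artefacts.

## Determinism and problem sizes

All randomness flows from explicit integer seeds; a scene seed fans out via
`numpy.random.SeedSequence.spawn` into one stream per fly plus one for
scene noise, so recordings are bit-identical across runs and machines with
the same library stack.  Rendered analyses in the tests and the acceptance
script run at quarter resolution (320x180) with the splitter thresholds
area-rescaled and 3-6 flies per vial — sizes chosen so the full suite,
including the 300 mixed-model calibration fits and a complete two-recording
end-to-end experiment, completes in minutes while every code path runs at
the device's native geometry at least once (the detector benchmark and
vial matching run at full 1280x720).

## Known limitations

* The tracker counts centroids per frame; it does not link identities, so
  two touching flies are one blob (dropped if above the area bound).
* Percent-occupancy denominators use detected flies, not the metadata N;
  undetected flies (e.g. in clumps) are silently absent from percentages.
* The rule-based vial detector assumes the synthetic scene's contrast
  structure; on real video a learned backend plugged into the same
  interface is expected to be more robust.
* MP4/H264 input requires an external codec backend (imageio plugin or an
  `ffmpeg` binary for the transcode wrapper); frame directories always
  work.
* The trial-start rule (first sub-threshold frame after a peak) shifts
  trial time zero by the background model's settling time after the first
  tap of a recording, typically a fraction of a second.
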