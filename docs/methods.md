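# Methods

This note documents the models and numerical choices behind `redpupil`: what
the synthetic-data generator emulates (and what it does not), how each
pipeline stage is defined, the defaults that matter, and the known limits of
what passing tests demonstrate.

## The spectral model

The physical premise is that iris melanin absorbs strongly across most of the
visible spectrum but only weakly at its far-red edge (~630–700 nm), while the
pupil — an aperture into the absorbing interior of the eye — is dark at every
wavelength. A longpass-filtered RGB camera therefore sees a bright iris
around a dark pupil even for heavily pigmented eyes.

The simulator collapses wavelength-resolved absorption to one effective
Beer–Lambert coefficient per imaging band:

    iris_reflectance = iris_base_reflectance · exp(−melanin_load · μ_band)

with defaults μ(far_red) = 0.35 and, for the full-visible band rendered as
RGB, per-channel μ = (0.9, 1.5, 2.0) — red absorbs least, so the iris is
reddest in the red channel and red-channel extraction is meaningful in both
conditions. `melanin_load` is dimensionless; the presets 0.3 / 1.0 / 2.5
correspond to blue, light-brown and dark-brown irises. These four numbers are
chosen once to reproduce the *qualitative* behaviour that defines the method
— far-red contrast strictly exceeds full-visible contrast for any pigmented
iris, with the gain growing steeply with pigmentation (tens of percent for
blue irises, several hundred percent for dark-brown) — not to match any
particular measured cohort. Nothing downstream depends on their absolute
scale.

Frames are concentric regions (pupil disc, iris annulus, sclera) with a 1 px
linear edge ramp (which is what makes sub-pixel diameter recovery possible),
optional specular glare discs near the pupil boundary (the default two spots
mimic LED reflections), additive Gaussian sensor noise, and 8-bit
quantisation. Blinks occlude the eye region with a skin-toned eyelid band.
All randomness flows from one integer seed; rendering is a pure function of
(parameters, seed).

## Pupil kinetics

The PLR stimulus protocol is fixed: 1 s dark, 1 s flash, 3 s dark, recorded
at 60 Hz (300 frames). No standard closed-form law exists for the full
constriction/redilation waveform at this granularity, so the simulator uses
the simplest shape with the right phenomenology: baseline diameter D0 until
stimulus onset plus a latency L (default 0.2 s), mono-exponential
constriction toward D0·(1−A) with time constant 0.2 s, then from stimulus
offset (+L) an exponential redilation normalised to recover exactly
`redilation_fraction` (default 0.6) of the achieved constriction by the end
of the recording. Constriction amplitudes A of 0.15–0.4 span typical light
responses. These kinetics are a stand-in for testing the measurement chain;
no claim about physiological constriction speed is made from them.

## Pupil segmentation

The far-red design makes the pupil the darkest compact region of the frame
by construction, so the default detector is classical rather than learned
(the detector interface is a single function, so a learned backend can be
substituted):

1. red-channel extraction; optional integer downscale (default: none);
2. glare in-painting: pixels ≥ 240 are replaced by a grayscale morphological
   opening (disk radius 5) over a dilated neighbourhood;
3. global threshold at the deepest valley of the smoothed intensity
   histogram (Gaussian σ = 3 bins) between its two darkest modes. The
   histogram is zero-padded before smoothing so a mode at the edge of the
   intensity range (a near-black pupil) still registers as a peak; fewer
   than two modes means no detection;
4. binary closing + hole filling, then the largest dark connected component;
5. validity checks: area within [50 px, 40 % of frame], mean intensity at
   most 0.6× the surround (rejects eyelid-occluded frames), circularity
   `4πA/P²` ≥ 0.6;
6. diameter = diameter of the circle with the same area as the component's
   moment ellipse, `√(major·minor)`; center = centroid; confidence =
   circularity clipped to [0, 1].

Failure is a state (`valid = False`), never an exception, so blink frames
flow through video processing as flagged samples. The diameter convention
(equal-area circle) is pinned by tests; it is rotation-stable, unlike a
single ellipse axis.

## Contrast metrics

Contrast uses 15×15 pixel blocks (225 pixels): the pupil block centered on
the detection, the iris block at twice the pupil radius from the center
along one of the four 45°-diagonals. Glare avoidance is automated: the
diagonal whose block has minimum within-block variance wins, glare-free
candidates take precedence, and if every diagonal contains saturated pixels
the radial distance is shifted by ±0.25·radius. The block statistic is the
mean (a config switch allows the median); iris *luminance* is by definition
the **median** CIELAB L* over the block, computed with the standard sRGB
transfer function and D65 white point. Eye-colour labels are inputs
(self-assessed), never inferred from L*.

The percent increase `100·(C_far − C_full)/|C_full|` keeps the sign of the
numerator (negative values mean full-visible contrast was higher) and is
undefined (raised as a distinct error) when `C_full = 0`. In band
comparisons, block geometry is selected once on the far-red frame and reused
on the full-visible frame, mirroring a protocol in which the eye and camera
do not move between conditions.

Cross-device tables aggregate long-format (participant, device,
percent_increase) rows: per-participant mean and sample SD (n−1) across
devices, cohort grand mean over per-participant means, optionally restricted
to one eye-colour label. The bundled reference cohort ships the published
per-participant means verbatim; for some participants the published
mean/STD are not the arithmetic mean/sample-SD of the published per-device
cells, so aggregates are defined on the reported means as printed.

## Trace processing and agreement

- **Downsampling** 60→30 Hz averages non-overlapping sample pairs (a
  decimation backend exists as a config switch); a window containing any
  blink-flagged sample is blink-flagged. Mean-of-pairs was preferred over
  decimation for its noise suppression; for blink-free traces it commutes
  exactly with percent-change normalisation, so the order does not matter.
- **Blink flags** on prototype-style traces combine detector failures with a
  dropout filter: a sample deviating from the median of its 5-sample
  neighbourhood by more than 20 % of that median is flagged.
- **Percent change from mean** uses the mean over non-excluded samples only
  (a blink sample is a spurious diameter and would bias the reference).
- **Alignment** maximises Pearson correlation on a whole-sample lag grid
  within ±0.5 s (the scale of a button-press start offset); ties prefer the
  smaller |lag|, so identical traces align at lag 0. Fewer than 10 jointly
  valid overlapping samples is an error.
- **Joint exclusion**: a sample blink-flagged in either trace is removed
  from both before any statistic.
- **Agreement**: MAE in percentage points, Pearson r (constant inputs are a
  distinct error), Bland–Altman bias with limits bias ± 1.96·SD (sample SD,
  n−1). Cohort summaries are arithmetic means (and SD of MAE) over subjects.

## Synthetic validation cohort

`redpupil.pipeline.synthetic_cohort` renders 11 independent subjects with
baseline diameters uniform in 40–80 px, amplitudes 0.15–0.4, melanin loads
spanning blue to dark-brown, noise SD 2–5, up to two blinks per recording,
and the default 5 s × 60 Hz protocol — then scores each subject's measured
trace against the simulator ground truth processed through the identical
chain. The cohort size and parameter ranges reflect a typical device
validation study; the whole cohort runs in about 80 s on one CPU.

What passing this does and does not show: the synthetic frames have crisp
region boundaries, stationary gaze, radially symmetric geometry and purely
Gaussian noise, so cohort MAE well under 1 percentage point demonstrates the
*pipeline* is unbiased and internally consistent — not that a physical
prototype achieves that accuracy on real eyes, where eye movement, defocus,
eyelashes and non-ideal illumination dominate the error budget. Real-device
agreement must be established against a clinical pupillometer.

## Degenerate inputs and tie-breaks

Uniform frames (one histogram mode) and occluded frames (too large / not
dark enough / not round) yield `valid = False`. Empty traces, all-excluded
traces, zero full-spectrum contrast, constant inputs to Pearson, and
mismatched lengths are distinct errors. Block-selection order among the
diagonals is fixed (upper-right first) so exact ties are reproducible.
Intensities quantise to 8 bits, so closed-form intensity identities hold to
±1 grey level.

## Known limitations

- No eye movement, gaze change, defocus or photometric vignetting in the
  simulator; detector accuracy on real video will be lower.
- Absolute pupil size in millimeters is out of scope by design: a single
  camera cannot recover it without a camera-to-eye distance estimate, which
  is why all comparisons use percent change from mean.
- The spectral model is two effective bands, not per-nm radiometry; it
  supports ordering claims, not radiometric prediction.
- Full-visible frames with very dark irises can defeat the detector — that
  is the phenomenon the far-red method exists to avoid, and the package only
  asserts the contrast ordering there, not a particular failure mode.
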