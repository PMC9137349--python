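# Methods

## Measurement model

A radiometric thermal image is a matrix of calibrated temperatures in °C.
The quantity of clinical interest is the core–peripheral gradient
`G = T_canthus − T_nose_tip`: the inner canthus tracks core temperature,
the nose tip tracks peripheral perfusion, and a large positive `G`
indicates circulation centralising around the vital organs. `G` is a
*difference*, so it is invariant to any constant temperature offset of the
camera — absolute radiometric accuracy matters far less than landmark
placement, which is why the package's evaluation metric is the
manual-adjustment rate of the markers rather than a temperature error.

Temperatures are accepted in the range [−40, 60] °C (cold outdoor
backgrounds through fevers); values outside it almost always mean raw
digital numbers were read as °C and are rejected. The 16-bit dialects
quantise at the calibration scale (default 0.01 °C/DN, spanning
0–655 °C), so a write/read round trip moves a pixel by at most half a
scale step; CSV is lossless.

## Max-Min Template detection

The face template defines three search circles in normalised coordinates
(defaults: eyes at (0.38, 0.42) and (0.62, 0.42), radius 0.09; nose at
(0.50, 0.62), radius 0.08; all overridable via YAML). The canthus is the
robust hottest spot in either eye circle — the hotter of the two wins,
since both canthi are core proxies — and the nose tip is the robust
coldest spot in the nose circle restricted to rows strictly below the
eye-centre row.

Robust extremum (`percentile_centroid`, default q = 99): select the
masked pixels at or beyond the q-th percentile of masked temperatures and
take their centroid weighted by each pixel's temperature excess beyond
that threshold, rounded to the nearest pixel and clamped back into the
mask (nearest member pixel). The excess weighting matters in two corner
cases a plain centroid gets wrong: when temperature ties dominate the
percentile (a uniform ROI with one genuinely hot pixel), the tied pixels
carry zero weight and the unique extremum is returned; and it leaves the
ideal case untouched, because a symmetric thermal peak has a symmetric
selection with symmetric weights, so its centroid is the exact peak
centre. A fully uniform selection falls back to the unweighted centroid
(the ROI centre). `single_pixel` (the raw argmax/argmin) is retained as
the brute-force oracle; exact temperature ties break to the smallest row,
then the smallest column, everywhere.

Marker temperatures are sampled as the mean of an odd `window × window`
patch truncated at the image border. The detector default is
`window = 1`: the percentile centroid already suppresses single-pixel
noise, and averaging a 3×3 patch over a thermal spot of Gaussian width
σ ≈ 2.5 px attenuates the peak by ~10 % of the spot contrast — about
0.5 °C at a 5 °C gradient — a systematic bias with no compensating
benefit. Wider windows remain available for flat-field measurements.

A detection with a negative gradient (nose warmer than canthus) is
physiologically unexpected but not an error; it is returned with a
warning flag.

## RGB–thermal transfer

The visual-to-thermal transform is fitted by least squares from point
correspondences. Writing points as complex numbers z = x + iy, the
similarity model w = a·z + b (a = s·e^{iθ}) is linear in (a, b) and
solved in closed form from the 2×2 normal equations; the translation
model is the mean coordinate difference. Translation is the default: at a
fixed lens separation and roughly fixed triage distance the parallax is a
constant pixel shift. The fit reports its residual RMSE; coincident
calibration points make the similarity unidentifiable and raise an error.

Transferred landmarks are rounded to integer pixels and clamped into the
thermal frame (flagged when clamping occurred). With `refine_radius > 0`
(default 3 px) each transferred landmark is snapped to the hot/cold
percentile-centroid extremum within a disc of that radius — the mapped
point marks the neighbourhood, the thermal extremum inside it is the
physically correct sampling spot. Refinement corrects sub-pixel
calibration bias but, like the Max-Min rule, it presumes the local
extremum is the landmark; it is disabled (radius 0) when the transferred
coordinates themselves are trusted.

## Severity rating

The five-colour scale maps `G` through four strictly increasing
cut-points with left-closed intervals (a gradient exactly at a cut-point
takes the more severe colour); the mapping is total and monotone in `G`.
**The default cut-points (2, 4, 6, 8 °C) are placeholders.** No validated
thresholds exist for this measurement; establishing them is precisely the
prospective clinical question, and nothing in this package should be read
as clinical guidance.

## Synthetic faces

The generator emulates the statistical structure the detectors rely on,
not photorealism: a background plane (20 °C), a face oval at skin
temperature (33.5 °C), Gaussian spots (σ = 2.5 px) whose peak values are
exactly the specified canthus (36.2/36.0 °C) and nose-tip temperatures at
template ROI centres displaced by an integer jitter (±2 px, re-drawn
while outside the ROI), then optical blur (σ = 1 px) and i.i.d. Gaussian
pixel noise (σ = 0.1 °C), on a 120×160 grid (landscape thermal-sensor
aspect). Visual-frame landmark coordinates are the thermal ones minus a
planted parallax (default (6, 0) px). Everything is deterministic given
(spec, seed); cohort faces get per-face seeds derived from one master
seed.

Ground truth records the *pre-blur* peak pixels (blur attenuates a
symmetric peak but does not move it) and the true gradient computed from
the specified temperatures. Cohorts span a gradient range by varying the
nose-tip temperature against the fixed warmer canthus; a nose warmer than
the surrounding skin (a well-perfused, low-gradient patient) is modelled
as a warm bump. In that regime the Max-Min cold-spot rule is wrong *by
design* — the coldest spot below the eyes is then not the nose — so
gradient-recovery studies across the full 0–6 °C range use the
landmark-transfer detector, and Max-Min accuracy is assessed on its
cold-nose validity range (gradients above the canthus–skin contrast,
≈ 2.7 °C at the defaults).

What passing tests on these faces do **not** show: performance under pose
and expression variation, glasses or occlusion, ambient reflections,
weather-exposed skin (a patient arriving from the cold has a transiently
cold nose), multi-face frames, or realistic inter-patient temperature
variability — the cohort distributions here are configurable guesses.

## Evaluation protocol

A detection needs manual adjustment when the larger of the two landmark
errors — canthus distance to the *nearer* true canthus (either eye is
anatomically correct), nose distance to the true nose tip — exceeds a
pixel tolerance. The clinical judgement this emulates was visual, with no
published pixel criterion; the default tolerance of 3 px approximates the
marker-cross arm length at the synthetic resolution and is a free
parameter every evaluation states. Adjustment percentages round half away
from zero (matching the published table's rounding); precision is
100 − adjustment %; rank 1 is the lowest adjustment percentage, ties
going to the algorithm with more tests (more evidence wins — a documented
but arbitrary choice).

## Numerical and interface choices

* Coordinates are 0-based (row, col); normalised template coordinates are
  x/width, y/height; a pixel belongs to a shape iff its centre is inside.
* "Below the eyes" is a strict row inequality against the eye-centre row.
* Landmarks are integer pixels throughout (matching a movable-cross UI);
  no sub-pixel output is attempted.
* Problem sizes in the test-suite and acceptance script (100-face
  robustness cohorts, 50-face gradient cohorts, 200 oracle trials) keep
  full runs in the seconds range while leaving the measured margins far
  from their thresholds.
* The CLI writes outputs atomically (temp file + rename) and exits 1 on
  domain errors, 2 on usage errors.

## Known limitations

No vendor radiometric formats (FLIR RJPEG/EXIF payloads), no emissivity
or reflected-ambient correction, no visual-spectrum face detector (the
transfer path accepts landmarks from any external source), no automatic
template placement — capture-time alignment with the overlay is assumed,
as in the nurse-operated app this mirrors. The severity cut-points are
unvalidated placeholders.
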