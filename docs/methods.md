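# Methods

## Coordinate and unit conventions

Grid indices are 0-based `(row, col)`; physical coordinates are cell
centres: `x = (col + 0.5)·pitch_x` across the plate width (mediolateral),
`y = (row + 0.5)·pitch_y` along travel (cranio-caudal). The default plate is
44 × 160 sensors over 0.605 m × 2.122 m (pitch ≈ 13.8 × 13.3 mm) at 100 Hz.
All pressures are kPa. The activation threshold used for segmentation,
template isocontours and COP computation is 5 kPa.

## Synthetic pressure fields

Each footstep is a mixture of six isotropic Gaussians truncated at an
elliptical foot outline: five digit components on the cranial arc
(digit i most medial → digit v most lateral) and one broad central/caudal
pad component. The field is modulated in time by a raised-cosine stance
envelope `E(τ) = ½(1 − cos 2πτ)` (single-peaked total force), and the
mixture weights drift linearly in stance fraction τ:

| component | weight at τ | default |
| --- | --- | --- |
| pad | `2.2 − 2.0·τ` | dominates impact |
| lateral digits (iii–v) | `0.45 + 1.15·τ` | present at impact, dominant late |
| medial digits (i, ii) | `0.05 + 1.55·τ` | rise through stance |

This mechanism — plus a pad centre offset 0.035 m lateral of the foot
midline — produces the characteristic COP path: a monotone caudal-to-cranial
progression spanning ≈0.2 m with a ~1 cm lateral deviation at impact that
resolves medially by mid-stance. The lateral offset of the pad encodes that
elephants land on the lateral side of the foot while the pad carries the
early-stance load; the weight drift encodes the roll toward the digits.

Default geometry and magnitudes: outline semi-axes 0.16 × 0.18 m (fore) and
0.15 × 0.19 m (hind), consistent with adult foot circumferences of
1.05–1.25 m; digit σ = 0.018 m, pad σ = 0.065 m; fore digit amplitudes
(160, 175, 250, 230, 215) kPa with pad 95 kPa, hind amplitudes 7% lower.
These put per-step foot maxima near 250–305 kPa (the 200–320 kPa band of
adult per-subject means), the highest regional pressures on digit iii and
the lowest at the heel, and forefeet above hindfeet — the qualitative
pattern shared by African and Asian elephants. Sensor noise is i.i.d.
additive Gaussian per cell per frame, clipped at zero, default σ = 1 kPa:
the 5 kPa activation threshold then sits 5 s.d. above the noise floor, as
on a zeroed, calibrated plate. (A noise σ of ≳2 kPa would scatter enough
above-threshold voxels for the gap-bridging adjacency to percolate between
footfalls — real plates are operated so this cannot happen.)

The default gait plan is one stride at 1.2 m/s crossing the plate in +y:
four footfalls of 0.8 s stance, fore and hind prints of each body side
clustered in space (hind lands just caudal of the prior fore print) but
separated by ≥0.4 s, left and right feet on distinct tracks.

### Ground truth

* **Masks** — voxels of the noise-free sampled field ≥ 5 kPa; exact
  recovery by segmentation is expected (and tested) only on noise-free
  records.
* **COP** — pressure-weighted centroid of the continuous generating field,
  computed by dense numerical integration on a 4× oversampled grid with the
  same 5 kPa cut the measurement applies. Agreement with the pipeline is
  asserted to half a sensor pitch on interior frames; the first/last stance
  frames carry <1% of peak load (the cut acts on a handful of cells) and
  get a relaxed two-pitch bound — a resolution limit, not a defect.
* **Regional peaks** — the measured quantity is regional by definition
  (a 3 × 3, σ = 1 px kernel on the stance-maximum image), so the truth
  evaluates the same kernel functional analytically on the continuous
  stance-maximum field at grid-snapped loci. Digit loci are the generating
  digit centres; the mid-sole locus is the centroid of the ≥5 kPa region of
  the dense stance-maximum field and the heel locus its caudal-most midline
  point, matching the anatomical definitions a digitizer would apply to the
  image. A raw point maximum would disagree with any kernel extraction by
  ~15–20% at this pitch and would test nothing useful.

## Segmentation

Footsteps are connected components of the thresholded voxel set under a
gap-bridging adjacency: voxels are neighbours when they differ by at most
`spatial_gap_cells + 1` per in-plane axis and `temporal_gap_frames + 1` in
time (the 6-neighbourhood dilated by the configured gaps — a gap of up to
`spatial_gap_cells` empty cells or `temporal_gap_frames` empty frames is
bridged). Defaults: 2 cells ≈ 2.7 cm, 10 frames = 0.1 s, minimum cluster
20 voxels — adult prints never split, successive footfalls never merge.
The implementation collapses each cell's active frames into gap-merged
intervals and runs union-find over interval nodes; this is exactly
equivalent to voxel-level adjacency (within a merged interval consecutive
active frames are ≤ the temporal reach apart, so interval envelopes decide
adjacency correctly), and is verified against a brute-force all-pairs
union-find on small random records.

Completeness is operationalized as border/endpoint contact: a step is
spatially incomplete if any voxel touches the outermost sensor row/column,
temporally incomplete if active in the record's first or last frame.

Foot identity is heuristic with an explicit `unknown` escape: left/right
from the mediolateral position relative to the trackway centreline (median
x of step centroids, oriented by the walking direction), fore/hind from
footfall order within a spatial cluster of prints (the earlier print of a
clustered pair is the forefoot, since hind feet land near the preceding
ipsilateral forefoot print). Singleton or over-full clusters stay unknown.

## Registration

Peak images are aligned to the per-foot template (first spatio-temporally
complete step) by translation + rotation about the source's active-pixel
centroid (decoupling rotation from translation in the search). The
automatic mode minimizes mean squared difference over the union support by
exhaustive search (±10 cells step 1; ±20° step 2°) followed by a pattern
search shrinking to 0.1 cell / 0.25°; the bounded rotation window avoids
locking onto a symmetry flip of the near-symmetric print. Images are
resampled bilinearly with zero fill (nearest-neighbour available for mass
conservation checks); pure integer translations are applied losslessly.
Recovery of known transforms is within (0.5 cell, 0.5°). A manual mode
applies explicit (dx, dy, θ), reproducing keyboard-driven workflows. The
cost is evaluated on images cropped to the joint support bounding box plus
the search range, which leaves the optimum unchanged.

## ROI extraction

"Regional peak pressure" is the σ = 1 px Gaussian-kernel average over a
3 × 3 pixel window centred at the digitized ROI, weights renormalized over
the window (a constant image returns the constant). The window/σ pairing is
the only reading of a "3-pixel area with a σ = 1 px kernel" consistent with
four unit-offset sensitivity positions; window size is configurable.
Whole-image Gaussian smoothing exists for display only and is never applied
before extraction. Each ROI carries four sensitivity positions (±1 pixel in
each axis); downstream summaries consume the 5-position mean.

Auto-digitization (synthetic pipeline only) places roi1–roi5 at the five
cranial local maxima of the lightly smoothed (σ = 0.5 px) mean image
ordered medial→lateral, roi6 at the active-mask centroid, roi7 at the
caudal-most active row on the mask midline, and fails loudly (for manual
fallback) unless exactly five cranial maxima are found. Real data should
use manual points from a CSV.

## COP comparison

Per-frame COP uses cells ≥ threshold; trajectories are linearly resampled
at 101 uniform stance fractions (gait-analysis convention; configurable)
and averaged pointwise per foot. "Untransformed" comparisons centre each
trajectory on its centroid first — plate coordinates are arbitrary per
trial, and the centroid frame is the only frame two feet share; `x_r`/`y_r`
are Pearson correlations of the coordinate sequences and RMSE the root mean
squared point distance. Ordinary Procrustes superimposes the source onto
the fixed target (full, asymmetric OPA): both centred, rotation from the
SVD of the cross-covariance (determinant unconstrained when reflection is
allowed, +1 otherwise), least-squares scale when enabled. RMSD divides by
the number of points, so it reads as a mean per-point distance. The
implementation is verified against a dense rotation-grid oracle with
per-rotation closed-form scale.

## Pipeline

`run_pipeline` chains simulate → segment → register → roi → cop →
summarize, communicating only through written artifacts (restartable), with
a manifest (config, config hash, seed, version, artifact list). One
top-level seed fans out to per-stage child seeds via CRC32 of
`"{seed}:{stage}:{item}"` (always < 2³¹). Reruns are byte-identical. The
simulate stage jitters footfall placements per trial (±1 cm, ±4°) so
automatic registration does real work; the trial-exclusion hook of real
workflows (unsteady walking) is a configurable predicate defaulting to
"none excluded" for synthetic data.

## Scope and limitations

* The generator emulates geometry, loading pattern and noise — not tissue
  mechanics; amplitudes are realistic in scale, not fitted to any animal. A
  green recovery test establishes that the pipeline measures what the
  generator encodes, not that the generator matches a particular elephant.
* Inferential statistics (mixed models, ANOVA, post hoc tests) are out of
  scope; the ROI table is emitted in the long format those tools consume
  (random effect: subject; fixed effects: ROI, foot, placement position).
* Published per-subject Froude numbers cannot be recomputed from the
  bundled table (hip heights are not tabulated); `froude()` is validated
  analytically.
* Published between-feet comparison metrics are not numerically
  reproducible from a synthetic world (the underlying resampling and common
  frame of the original analysis are unstated); comparisons are therefore
  validated by oracle equivalence and invariances, and only the qualitative
  structure (conserved cranio-caudal progression, mirrored mediolateral
  deviation) is asserted end-to-end.
* Foot classification is a heuristic; on real data with irregular gait it
  will return `unknown` labels that need manual resolution.
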