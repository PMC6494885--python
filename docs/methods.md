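# Methods

This note documents the models, algorithms and numerical choices behind
`slicetrack`, and what the synthetic-data generator does and does not
emulate.

## Coordinate and unit conventions

Pixel indices are 0-based; physical coordinates are pixel index ×
pixel size (pixel centres), in micrometres; y increases downward
(image convention). Time is in hours; the first imaging session
conventionally sits at 24 h post transfection/infection (`t0_h`,
configurable). All tables carry µm and hours. Default voxel size is
0.3225 × 0.3225 × 0.5 µm (x, y, z); default frame interval 24 h.

## Image handling (imgio)

Series are held as (time, channel, z, y, x) arrays and written/read as
OME-TIFF with physical calibration in the metadata; files lacking
calibration fall back to the defaults above with a warning, and series
with fewer than five axes are promoted with singleton axes.

Everything downstream consumes per-timepoint **maximum projections**
along z. Mosaics are assembled from equal tiles with **linear feather
blending** in the overlap zones — any convex blend reconstructs a
split image exactly, and feathering additionally suppresses seam
artefacts when tiles disagree; the integer tile layout is solved
exactly from (extent, grid, overlap fraction) and an error is raised
when no exact tiling exists.

Alignment is **translation-only phase correlation** (10× upsampled,
sub-pixel) between consecutive frames, chained into cumulative shifts
relative to the first timepoint; frames are resampled with linear
interpolation. Rotation is out of scope: drift from repeated stage
return is small and translational. Two guards handle degenerate
inputs: constant images register at zero shift with a warning, and a
pairwise shift exceeding 25% of the smaller image dimension
(`max_shift_fraction`) is treated as a spurious correlation peak —
e.g. between featureless frames — and replaced by zero, with a
warning.

## Segmentation (segment)

"Normalised thresholding": intensities are divided by the image's
`normalize_percentile` (default 99.9) percentile and clipped to [0, 1],
making segmentation invariant to global intensity scaling (laser power,
exposure); the binary mask is `normalized ≥ threshold_fraction`
(default 0.2). An Otsu threshold is available behind `method="otsu"`
for comparison. Components are 8-connected (diagonal soma pixels merge,
reducing spurious splits), filtered by calibrated area
(`min_area_um2` default 20 µm² — a pipeline choice, not a measured
biological constant — to `max_area_um2`), and summarised with
**intensity-weighted centroids**, so bright somata dominate dim
neurites and tracking stays soma-centric.

Degenerate scenes: an all-zero image normalises to zero with a warning;
and when the thresholded foreground covers more than
`max_foreground_fraction` (default 0.5) of the image, segmentation
returns no objects with a warning — a noise-only field otherwise
normalises its own noise into [0, 1] and "segments" as one giant
component.

## Tracking (track)

The tracker is deliberately minimal. Objects at the first timepoint
get unique IDs. For each subsequent timepoint, each object scans all
previous-frame objects with a closest-distance variable initialised to
`initial_closest_distance_um` (by default unbounded; operationally the
longest image dimension) and updated whenever a closer object is found.
If the closest distance is ≤ `d_max_um` (default 64.5 µm — an
empirical bound on how far a cell travels between 24-h sessions) the
previous ID is inherited, otherwise a fresh ID is issued. The boundary
is inclusive: exactly 64.5 µm links. Exact ties go to the lowest
previous-frame label, which makes assignments independent of input
order.

The per-object closest-predecessor rule permits two next-frame objects
to claim one previous ID. With `one_to_one` on (default), competing
claims are resolved in ascending distance order and losers get fresh
IDs, because duplicated IDs would corrupt single-cell survival
bookkeeping; with `one_to_one` off the plain rule is applied, and the
property suite verifies it against an exhaustive all-pairs
nearest-neighbour search. There is no gap closing, motion model, or
lineage linking: a track whose ID goes unclaimed closes, reappearing
or newly arrived objects start new tracks, and a division appears as
one continuing track plus one new ID.

## Quantification (quantify)

Step distance is the Euclidean centroid distance between consecutive
detections; path length its sum; velocity path length over elapsed
time. **Soma length** is defined as the equivalent-circle diameter of
the track's *median* detection area (robust to neurite-driven area
swings); a cell is **motile** when its maximum centroid separation
over the whole track strictly exceeds two soma lengths ("more than").

"Mean distance travelled" trends are computed on **per-interval step
distances** (not cumulative path — a cumulative quantity could not
trend negative): steps are averaged per timepoint, the means regressed
on time (slope reported in nm/day), and the per-timepoint step
distributions compared by one-way ANOVA with Tukey HSD.

Intensity trends pool all observations of all traces into one OLS fit
of intensity vs time (per-cell means, not raw pixels — the
alternative pooling is a one-line change). ANCOVA between two groups
of series is the F-test on the group × time interaction in
`y ~ time * group`; it backs both the drift-vs-background comparison
and the puncta accumulation-rate comparison. Cell-count rates are OLS
slopes of the cumulative distinct-ID count vs days.

## Puncta (puncta)

Neuron masks are the union of components retained by the segmenter on
the morphology channel; reporter pixels outside the mask are zeroed
(idempotent by construction). The filtered image is linearly rescaled
to 8-bit — by its own min–max, or by an explicit `rescale_range`
shared across a series so dim frames stay dim — and pixels in the
inclusive window 5–255 become foreground. Components ≥ 10 µm²
(calibrated; a pixel-unit mode exists) become puncta, owned by the
cell whose mask-label dominates their pixels. Exactly 80 µm² classes
as **large**: "small" is defined strictly below 80 µm², and assigning
the boundary to large keeps the classes a partition.

Cumulative formation needs a puncta identity over time: a punctum at
*t* is "the same" as one at *t − 1* in the same cell when their
centroids are within `match_radius_um` (default 8 µm, one soma
radius), matched greedily by ascending distance; a punctum's first
observation is its formation time. Per-slice cumulative counts of
distinct small puncta are compared between groups by an endpoint
t-test and by ANCOVA on accumulation rates; a group with one slice
refuses the t-test.

## Survival (survival)

The automated death caller scores a cell dead at the first timepoint
where its morphology-channel mean intensity falls to within
`drop_to_background_k` (default 3) background standard deviations of
the background mean, sustained for `persistence_frames` (default 2)
consecutive frames (a drop that persists to the end of a short trace
counts), **or** when its track terminates before the end of the movie
(in rendered data a dead cell's signal vanishes, so the segmenter
loses it — termination is the usual signature). Otherwise the cell is
censored at its last observation. Manual annotation CSVs
(cell_id, death_time_h) override automated calls. Events on a 24-h
grid are recorded at the first session at which the loss is seen
(interval censoring approximated by the right endpoint).

Estimators: Kaplan–Meier product-limit per group; Gehan–Breslow–
Wilcoxon as the weighted log-rank test with weights equal to the
number at risk (early deaths weigh most); Cox proportional hazards
with **Efron's tie approximation** (24-h grids create heavy ties;
Efron is the less-biased standard), group as the sole covariate,
HR = exp(β̂) with Wald 95% CI; Nelson–Aalen cumulative hazards.
Complete separation is reported as an infinite HR with a warning.
Note that Efron's correction makes the fit only asymptotically
invariant to dataset duplication.

**Hazard linearity.** A constant hazard makes the cumulative hazard a
straight line through the origin. The baseline hazard cannot be tested
from the Cox partial likelihood (any common function of time cancels),
so linearity is tested parametrically: the exponential model is
embedded in a Weibull family with one shape parameter *k* shared
across groups and a free rate per group, and the profile likelihood at
the fitted shape is compared against *k* = 1 (likelihood-ratio χ²,
1 df). When event times sit on a sampling grid, pass
`frame_interval_h`: each event then contributes the interval mass
S(t − Δ) − S(t) instead of the density — with the continuous
likelihood, ceiling-discretisation alone mimics an increasing hazard
(no events can precede the first session). The test refuses datasets
with fewer than 5 events. Calibration was checked by simulation:
under exponential truth on a 24-h grid the test is non-significant in
19/20 replicates; under Weibull shape 2 with n = 300 it rejects in
20/20.

## Synthetic data (simulate)

The generator reproduces the statistical structure the analyses
assume, not the optics of a confocal microscope. Cells are soma disks
(radius 8 µm) rendered into three z-slices plus 1-px neurite strokes,
convolved with a Gaussian PSF proxy (σ = 1 px), over a constant
background (5 a.u.) with additive Gaussian noise (σ = 2 a.u.).
Neurites emanate from the soma boundary as opposite-ray pairs at
0.15× soma intensity: point symmetry keeps the rendered
intensity-weighted centroid on the ground-truth centroid (the
rendering-fidelity invariant holds to 1 px), and the low intensity
keeps them below the segmentation threshold so the soma defines the
object, mirroring the soma-centric tracking of the real pipeline.

Live-cell intensity rises linearly at 0.7 a.u./h (the measured
fluorophore-accumulation rate used as generating truth); death is a
hard step to background at the first frame after the event time
("abrupt loss"; a fade-rate knob exists, default 0). Deaths are
exponential with per-group hazards (`death_hazard_per_h`,
`group_log_hr`); arrivals of newly labelled cells and cell divisions
are Poisson processes, a daughter displaced one soma diameter in a
random direction (a crude mitotic-somal-translocation proxy — the
simplest event model that creates the ambiguities the tracker must
resolve). A configurable fraction of cells is motile with
fixed-length, random-direction steps per frame; the motile fraction is
a parameter rather than a constant because only a rare minority of
neurons in slices move far. Somata are placed uniformly with centre
separation ≥ 2 × radius **plus a 5-px PSF gap** (at exactly 2r,
somata abut and blur into one connected component, which would make
the perfect-segmentation ground truth ill-defined), with 100 retries
per cell before the configuration is rejected as overcrowded.

`simulate_detection_series` emits the same event structure as perfect
detections without rendering pixels; `simulate_survival` draws
two-group exponential event times discretised upward to the frame
grid and censored at the imaging horizon; `simulate_traces` draws
linear-drift traces plus flat background traces;
`simulate_step_decline_tracks` builds random walks whose step length
declines linearly in time.

Not emulated: light scattering and depth attenuation, spherical
aberration, neurite dynamics, photobleaching, uneven illumination,
cell shape change, and segmentation errors from touching cells.
Passing tests therefore show that the algorithms are correct on data
satisfying their stated assumptions — not that segmentation or
tracking would be error-free on real tissue.

## Problem sizes and reproducibility

Every generator is driven by one integer seed through a single
`numpy` Generator; identical configuration and seed give bit-identical
movies and tables, and the pipeline reproduces byte-identical CSVs.
The test suite and the acceptance script use deliberately modest sizes
chosen to keep statistical tolerances honest: 20 seeded replicates for
all recovery checks; 161/180 cells for survival recovery (the study's
group sizes); 12 traces × 17 timepoints for drift recovery; 20 daily
frames with 10 arrivals/day for count rates; 700 tracks for the
travel-distance trend; rendered test movies of 6–10 cells at
192–256 px. Large-sample consistency checks (e.g. Cox HR at
5000/group) use continuous-time grids where discretisation bias would
otherwise dominate.

## Known limitations

- Tracking is 2-D (max-projection centroids); z is never used for
  linking, and in-plane alignment assumes pure translation.
- The tracker has no gap closing: a single missed detection splits a
  track, which biases per-cell survival toward earlier "deaths" when
  segmentation is unstable. The death caller's track-termination rule
  inherits this.
- The linearity test is parametric (Weibull embedding); hazards that
  are non-monotone in a way Weibull cannot express may evade it.
- The ANCOVA treats observations as independent, ignoring within-cell
  autocorrelation; mixed-effects longitudinal models are out of scope.
- Puncta identity over time is a nearest-neighbour heuristic within
  one soma radius; merging/splitting inclusions are not modelled.
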