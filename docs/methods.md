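# Methods

## Scope and rationale

`vesicoloc` quantifies two things about intracellular vesicle imaging:

1. **Object-based colocalization** — what fraction of membrane-marker-positive
   endosomes (e.g. EGFP-tagged Rab GTPases, which decorate the endosome
   *surface* and image as rings) also contain a lumenal cargo (e.g. an
   mCherry-tagged viral envelope protein, which fills the *inside* of the
   vesicle). Because the two fluorophores occupy disjoint sub-structures of
   the same organelle, their signals barely overlap pixel-wise and classical
   pixel correlation underestimates their association; the correct unit of
   analysis is the vesicle, scored yes/no.
2. **Co-transport and motion** — in time-lapse data, whether punctate
   particles (e.g. EGFP-tagged immature retroviral capsids) travel with cargo
   vesicles, and whether those vesicles move by active (directed), diffusive
   or confined motion, judged from per-track mean squared displacement.

Because raw microscopy of this kind is rarely deposited, the package carries
a synthetic-data generator that emulates the relevant image formation with
known ground truth, so every downstream stage is validated quantitatively
rather than by eye.

## Synthetic image model

Each vesicle is a circle of radius *r* ~ Uniform(4, 7) px. The marker
channel receives a hard annulus of outer radius *r* and thickness 2 px; a
cargo-positive vesicle (Bernoulli with probability `coloc_fraction`)
receives a filled disk of radius *r* − thickness in the cargo channel —
strictly interior to the ring, reproducing the surface-vs-lumen geometry.
Attached puncta are point sources of `punctum_amplitude` integrated photons
deposited at the vesicle center (bilinear sub-pixel spreading). Shapes are
rasterized on a 4× supersampled grid, so sub-pixel centers are honored to
~1/16 pixel-area accuracy.

The optical and camera model is: isotropic Gaussian PSF (σ = 1.2 px,
`scipy.ndimage.gaussian_filter`), uniform background (100 photons/px),
Poisson shot noise, additive zero-mean Gaussian read noise (σ = 2 photons),
and clipping at zero. Defaults give a ring peak amplitude of 400 photons
over a background σ of ~10 photons — comfortably above an SNR of 10, which
is the regime the recovery guarantees below refer to. The acquisition
cadence defaults to one frame per second, matching common live-cell
protocols for this experiment class.

Vesicle centers are placed by uniform rejection sampling with a minimum
separation of 3× the maximum ring radius (so segmentation is unambiguous at
the reference conditions) and an edge margin of 2× the maximum radius. The
attempt budget is 10·n per vesicle; exceeding it raises an error naming the
density constraint rather than silently under-filling the field.

Motion models (per frame, Δt in frames):

- *directed*: constant speed (2 px/frame) along a random fixed heading; the
  heading is resampled until the whole path fits inside the edge margin, so
  every directed track has exactly constant step length (clamping would
  corrupt the model near borders).
- *diffusive*: 2-D random walk, per-axis step variance 2·D, i.e. mean
  squared per-frame displacement 4·D, with D = 1 px²/frame by default.
- *confined*: the same walk, radially reflected at `confinement_radius`
  (5 px) about the start point; diffusive/confined positions are clamped to
  the edge margin.

`position_noise_sigma` adds i.i.d. Gaussian localization jitter on top of
any class. Attached puncta copy their vesicle's position exactly in every
frame. D is configured in px²/frame; analysis results are reported in px²/s
using the frame interval (identical under the 1 s default).

What the generator does **not** emulate: non-uniform cellular background,
photobleaching, vesicle fusion/fission or shape change, z-drift, chromatic
offset between channels, and motion-blur within an exposure. Tests passing
on this generator therefore demonstrate correctness of the *measurement
machinery* under a fair image-formation model, not robustness to every
artifact of real acquisitions.

## Vesicle segmentation

The mask of vesicle ROIs is built from the marker channel by a
deterministic, parameter-light pipeline: difference-of-Gaussians band-pass
(σ_low = 1 px at the PSF scale, σ_high = 6 px at the vesicle scale) →
global Otsu threshold → binary hole filling → 4-connected labeling → area
filter (10–5000 px). Hole filling is essential, not cosmetic: the marker is
annular but the cargo is lumenal, so the ROI must cover the filled vesicle
or the wrong region is measured. ROIs touching the border are discarded by
default (partial objects bias intensity means); ROIs are ordered and
relabeled by centroid (row, col) so outputs are diff-stable.

Otsu on a signal-free noisy field would bisect the noise distribution and
emit spurious blobs, so a signal-presence guard requires the Otsu threshold
to sit at least 3 robust σ (1.4826·MAD) above the band-passed median; the
guard, like Otsu itself, is invariant under positive intensity scaling. On
vesicle-bearing fields at the default conditions the threshold sits 11–16 σ
above the floor, so the guard has a wide safety band on both sides.

Touching vesicles are not split (no watershed); at the simulated separation
this cannot occur, and on real data under-segmentation of adjacent
endosomes is a documented limitation.

## Punctum detection

Puncta are detected on the (sign-inverted, σ²-normalized)
Laplacian-of-Gaussian response at σ = 1.5 px. A candidate local maximum
must pass two robust gates of the form median + k·1.4826·MAD: one on the
raw peak intensity against the image background, and one on the LoG
response itself. The response gate rejects single-pixel shot-noise spikes
(which a matched filter averages away but a raw gate passes); the raw gate
covers the degenerate noise-free case where the response MAD collapses to
zero. k defaults to 7 because the expected maximum of the smoothed
background response over a ~10⁵-pixel field already reaches 4–5 robust σ
(extreme-value statistics), while genuine diffraction-limited puncta at any
workable SNR sit tens of σ above. Sub-pixel positions come from a
background-subtracted intensity-weighted centroid over the 3×3
neighborhood, exact for symmetric spots.

## Background model and the object call

"Background" is estimated robustly on the measured channel as
median + k·1.4826·MAD over all pixels outside the ROIs dilated by 3 px
(dilation excludes PSF bleed from bright objects; the median/MAD pair is
insensitive to the bright-vesicle tail that would corrupt a mean/SD).
An ROI is called cargo-positive when its **mean** cargo intensity strictly
exceeds the threshold with k = 3. The mean, not the max, is the right ROI
statistic for an extended lumenal signal — a max is driven by the noisiest
pixel. The strict inequality makes the degenerate MAD = 0 case conservative.
Raising k can only shrink the positive set (monotonicity), and k is exposed
because the positive call is inherently threshold-sensitive on dim data.

The percent-positive summary carries a Wilson 95% binomial interval
(via `statsmodels`); with zero objects the percentage is flagged undefined
rather than reported as 0.

## Pixel colocalization

Within a mask (typically the vesicle label map), Pearson's r is computed
from the standard centered product-moment formula, and Manders' M1/M2 as
the fraction of each channel's integrated intensity lying on pixels where
the *other* channel exceeds its threshold. Thresholds come from Otsu within
the mask, from the robust background model, or fixed values; automated
Costes thresholding and randomization p-values are out of scope, and the
background-model mode is the default stand-in. Degenerate inputs (zero
variance, zero integrated intensity) set explicit undefined flags instead
of raising.

## Tracking and motion classification

Linking is greedy nearest-neighbor: all candidate (track, detection) pairs
within `max_displacement` are processed in ascending distance order (ties
broken by lower track id, then detection (row, col) order — fully
deterministic); unmatched tracks persist through up to `max_gap` missed
frames with linear interpolation, counted per track; unmatched detections
found new tracks in (row, col) order. Greedy assignment is exact when
inter-particle spacing exceeds the per-frame displacement scale (verified:
point-for-point recovery at spacing ≥ 4× the max step) and is documented as
swappable where densities demand global assignment.

The time-averaged MSD uses all ordered pairs at each lag, with lags up to
one quarter of the track duration (longer lags are dominated by estimator
noise). The power law MSD ∝ τ^α is fitted in log-log space by weighted
least squares, with weights equal to the reciprocal of the relative
variance of the overlapping MSD estimator for a random walk,
(2τ² + 1)/(3τ(n − τ + 1)) with τ in frames. This variance grows roughly
linearly in τ, so unweighted fitting lets the noisiest lags tilt the slope;
the weights are exact only for pure diffusion but remain a sensible
precision proxy for the other classes, and on noise-free closed-form curves
the weighted fit is still exact. Classes: directed for α ≥ 1.4, diffusive
for 0.7 ≤ α < 1.4, confined for α < 0.7 — conventional cut points between
the theoretical exponents 2, 1 and 0. The diffusion coefficient is
exp(intercept)/4 (the exact inversion of MSD = 4Dτ at α = 1); directed
velocity is the through-origin slope of √MSD vs τ. Non-positive MSD values
are dropped; fewer than 3 usable lags flags the track unclassifiable.

At the reference conditions (50-frame tracks, v = 2 px/frame with 0.5 px
localization noise vs D = 1 px²/frame), the weighted fit assigns ≥ 95% of
tracks their generating class and recovers the median D within a few
percent; these numbers are recomputed, not quoted, by the test suite and
`scripts/acceptance.py`.

## Co-transport

The co-transport fraction asks, per cargo vesicle *tracked through time*,
whether a punctum travels with it. ROI centroids are linked across frames
(same linker) to establish identity; a vesicle is punctum-associated in a
frame when a punctum lies within `max_distance` (3 px) of its centroid or
inside its pixel set, and counted positive when associated in at least
`min_frames` (3) frames — the persistence requirement distinguishes
co-transport from transient coincidence. Interpolated gap frames do not
count as associated. The result is reported with the same Wilson-interval
summary as the still-image statistic.

## Problem sizes and numerical choices

Reference evaluations use 1024×1024 fields with 200 vesicles for the
colocalization recovery studies, 100 + 100 tracks of 50 frames for motion
classing, 200 tracks for diffusion recovery, and 20 particles × 50 frames
× 10 replicates for linking — sizes at which the binomial and estimator
noise floors are well below the quantities being checked. All randomness
flows through `numpy.random.default_rng` seeds carried in the configs;
identical (config, seed) pairs reproduce every output byte-for-byte,
including CSVs (fixed float format, fixed line terminator) and the
provenance record (config hash excludes the output directory and log
level). Supersampling is fixed at 4×; PSF convolution uses zero-padded
boundaries, conserving integrated intensity to <1% for objects ≥ 4σ from
the edge.

## Known limitations

- No watershed splitting: touching vesicles merge into one ROI.
- Greedy linking can mis-assign at densities where inter-particle spacing
  approaches the per-frame displacement.
- The MSD fit weights assume diffusive statistics; for strongly directed
  tracks they are conservative rather than optimal.
- The generator's uniform background flatters background estimation
  relative to real cells, where local background structure dominates the
  error budget of the yes/no call; on real data the `k` threshold and the
  mask source are the sensitive knobs and should be reported alongside any
  percentage.
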