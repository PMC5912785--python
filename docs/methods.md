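# Methods

## The simulated preparation

`wgquant.simulate` emulates a fixed, stained patch of the segmented
embryonic epidermis imaged on a scanning confocal. Cells are a rectangular
lattice (default 20 px ≈ 5 µm at 0.25 µm/px) with 1-px membrane lines; each
body segment is 6 cells (120 px) along the AP axis, anterior at low x. The
default field holds 5 segments of 10 cell rows in a (z, y, x) =
(10, 280, 680) stack with 1 µm Z steps, so the standard 8-µm projections
use 8 of 10 slices.

Per channel:

* **Junction marker** — uniform intensity on the membrane lattice.
* **Arm** — each cell's total Arm budget is the smooth periodic AP profile
  `T(x) = base + amplitude·bump(x)` integrated over the cell's pixels;
  a `junctional_fraction` share (default 0.70) is spread uniformly over the
  cell's membrane pixels, the rest over its interior. This makes the
  membrane share of total Arm equal the configured fraction exactly, per
  cell and globally, and makes the mean over a whole cell equal the local
  profile value, so box averages recover `amplitude` directly. `bump` is a
  trapezoid with cosine shoulders (flat top within 1/8 period of a stripe
  center, zero beyond 3/8 period): graded across the intermediate cells yet
  flat where the stripe and interstripe measurement boxes sit.
* **Wg** — cytoplasmic signal in the single Wg-expressing cell row per
  segment. Cells within one row of an expressing row are "Wg-ON"; the rest
  are "Wg-OFF" (half the field each with the default geometry).
* **GFP (destruction-complex puncta)** — one punctum per cell: in Wg-OFF
  cells a point emitter deep in the cytoplasm (≥4 px from the membrane), in
  Wg-ON cells within 2 px of the membrane. Per-punctum molecule counts are
  log-normal with regional means 260 (OFF) and 130 (ON), log-sd 0.45,
  clipped to 46–931; the clipped mixture mean is ≈195. A diffuse
  cytoplasmic term is elevated in ON cells (12 vs 4 counts/px/slice), which
  reproduces the brightness hierarchy probed by percentile thresholding.

Optics are a Gaussian PSF (σ = 1 px laterally and axially — about right for
a 1.4-NA objective at ~0.1 µm-scale sampling, and matching the discrete
axial kernel used throughout). The camera applies Poisson shot noise to
signal plus background offset (default 100 counts), Gaussian read noise
(sd 3), and a hard clip at 4095 (12-bit). `brightness_per_molecule` is 40
counts of integrated signal per GFP: a deliberate design point at which the
dim 58-molecule standard (2300 photons) clears the ~330-count aperture noise
of the prescribed 15×15/21×21 nested ROI. (At a few counts per molecule the
dual-standard protocol cannot work for any analysis — the standards
themselves would be at SNR ≈ 2.)

Yeast-like calibration standards are fields of well-separated spots with a
fixed molecules-per-structure (Ndc80-like 306, Mif2-like 58), rendered with
the same optics and camera. `render_spot_field` renders arbitrary per-spot
molecule counts for calibration-linearity studies. The En channel draws
En-positive cells as round nuclear blobs (radius 0.3 cells) in the
posterior `en_rows_per_segment` cell rows of each segment (2 in the wild
type), since En is a nuclear antigen and countability along a line requires
separated objects.

What the generator does **not** emulate: real epithelial geometry (curved,
irregular cells; the lattice's aligned membrane columns create a periodic
comb under column averaging that real tissue lacks), embryo curvature and
depth-dependent attenuation (an optional exponential term exists, default
off), spectral bleed-through, autofluorescence texture, and structured
antibody background. Recovery on these images therefore demonstrates the
correctness and calibration of the measurement chain, not robustness to
every real-tissue artifact.

## Membrane mask and pool separation

The junction segmenter is deterministic: Gaussian smooth (σ 1) → Sato ridge
filter (σ 1–1.5) → hysteresis threshold at 5%/20% of the maximum ridge
response → morphological closing → removal of components under 20 px.
The hysteresis support of a PSF-blurred 1-px junction is ≈3 px wide, i.e.
the mask tracks the blurred support of the junctional signal rather than
its 1-px geometric centerline. This width was chosen by a calibration study
on synthetic embryos: pool separation assigns to the membrane pool whatever
blurred junctional signal the mask covers plus whatever cytoplasmic signal
leaks under it, and at support width the two errors cancel — the recovered
membrane share is 70.4% at a true 70%. A further unconditional 1-px
dilation (width 5 px) overshoots to ~81%, and an ideal 1-px centerline mask
captures only ~38% of the blurred junctional signal; both were rejected on
that ground. The cancellation is exact only near the wild-type operating
point: across configured fractions 0.5–0.9 the recovered share is within
±0.07 and strictly monotone.

Pool separation itself is exact bookkeeping: background-subtracted ROI
intensity is split by mask membership, and intensity and area identities
(`membrane + cytoplasmic = total`, same for areas) hold to machine
precision by construction.

Profiles across segments are column means inside the ROI, resampled to 100
points per segment (the embryo-length adjustment) and valley-zeroed by
subtracting the global minimum. Two averaging modes exist: plot-profile
semantics (zeroed membrane pixels included) and unmasked-pixel averaging
(pass the mask), which removes the modulation that variable mask width
imposes; peak counting smooths over a tenth of a segment first so the
lattice comb does not register as peaks.

## Punctum detection, integration, counting

Detection: 3-D local maxima of a difference-of-Gaussians band-pass (σ 1 vs
6), thresholded at 5 robust standard deviations (MAD-based) of the
band-pass response, minimum separation 4 px, excluding 2 edge slices in Z
(where smoothing artifacts breed false maxima and depth integration is
impossible). On a default embryo this recovers ≥95% of true puncta at ≥98%
precision.

Depth of field (`z_slices`): symmetric ±k shells around the peak slice are
included while the shell-averaged band-pass amplitude at the centroid stays
above half the peak value. Averaging the two shell slices halves the noise
on the inclusion decision; an asymmetric per-slice rule measured on the raw
nested-ROI sums proved noise-coupled to the integrated signal itself and
biased dim structures upward by tens of percent. With σz = 1 the rule
settles on 3 slices, capturing a fixed ≈88% of a spot's light — identically
for samples and standards, so the capture fraction cancels in the
calibration ratio.

Integration is the prescribed nested-ROI rule: per slice, the 15×15 inner
sum minus inner-area × frame background, summed over `z_slices`, clipped at
zero with a warning. The frame background is the plain mean of the 21×21
frame pixels, excluding (value-blind) any pixel within 4 px of another
detected punctum: in crowded fields a neighbor falling on the frame
otherwise inflates the background and deflates the count by several
percent. Median and symmetric trimmed-mean estimators are available but are
not the default — their small shot-noise-skew bias (~0.15 counts/px) is
additive and therefore corrupts the dim standard five times more than the
bright one, breaking the ratio calibration.

Standards are measured as the mean integrated intensity over all usable
structures; detections dimmer than 25% of the median structure intensity
are dropped as noise maxima (standard structures are monodisperse). The
default workflow measures 4 fields × 60 structures per standard, putting
the per-molecule-intensity error near 1%; the ±15-molecule consistency rule
makes acceptance count-dependent once the two standards disagree by more
than ~15/N, so calibration accuracy — not per-punctum noise — controls both
the acceptance rate and the truncation bias of the accepted mean.

Compartment classification calls a punctum membrane-bound when its centroid
lies within 2 px of the membrane mask. Because the mask already spans the
~3-px junction support, 2 px cleanly separates the membrane-proximal
(≤2 px) from cytoplasmic (≥4 px) placement regimes.

Percentile-threshold ranking computes, for each "brightest fraction" f, the
(1−f) intensity quantile over in-embryo pixels only; masks are nested by
construction, and coverage is reported per ground-truth structure class.

## Fold arithmetic and statistics

Fold chains are composed by orienting each link (inverting as needed) so
its denominator matches the running label; the combined sd adds the links'
relative sds in quadrature — first-order propagation, which matches the
relative spread of a log-normal Monte-Carlo to within 10% even for the wide
blot-fold links. Folds above 5× or below 0.2× carry a `dilution_verified`
flag mirroring the serial-dilution verification rule; unverified extreme
folds warn. Printed folds round to the nearest integer ("~5x").

All tests are two-sided. The unpaired t test is classic pooled-variance by
default with Welch via a flag. Dunnett's multiple comparisons use the
standard multivariate-t adjustment; the test suite calibrates the implied
familywise error under a simulated global null (5 groups × n = 10, 10⁴
vectorized replicates against the implied max-|t| critical value) at
0.05 ± 0.01. The normality battery runs both the D'Agostino-Pearson omnibus
(n ≥ 8) and Shapiro-Wilk (n ≥ 3) tests, flagging degenerate samples.

## Study sizes and determinism

Default study sizes — 5 embryos (~1450 puncta) for the dual-standard
recovery, 4 + 4 standard fields, 20 noise realizations × 12 spots for the
single-standard cross-check, 20 seeds for the stripe-amplitude recovery —
give sampling errors several-fold smaller than the quantities' tolerance
bands. Every render is a pure function of its spec (seed included); all
workflow randomness derives from one user seed.

## Known limitations

* The lattice geometry makes membrane-column artifacts (the comb) worst-case
  relative to real tissue; conversely it makes stripe-box placement easier.
* The membrane-share calibration is validated at PSF σ = 1 px and 1-px
  junctions; substantially different optics would need the hysteresis
  thresholds re-examined against ground truth.
* Punctum centroids sit on integer voxels; sub-pixel localization is not
  modeled or needed for count calibration.
* The ±15-molecule rule is absolute at all count scales (per its
  definition), so with imperfect standards it preferentially rejects bright
  puncta; the accepted-mean bias this induces is ≲3% at the default
  standard sample sizes but grows quickly if standards are under-sampled.
* No attempt is made to model FRAP-style dynamics, super-resolution
  substructure, or spectral cross-talk.
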