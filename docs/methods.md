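# Methods

## The quantification model

A multichannel confocal z-stack is a non-negative intensity array
I[c, z, y, x] with one channel per fluorophore-tagged species, z = 0 at
the substratum. The pipeline estimates, per channel, the set of voxels
occupied by that species and reduces it to volume statistics. Four
assumptions underlie the chain:

1. **Linear bleed-through.** The signal a fluorophore contributes to a
   foreign channel is proportional to its own-channel signal:
   observed_j = Σ_i k[i→j] · signal_i with k[j→j] = 1. This holds when
   detectors are not saturated and autofluorescence is negligible (both
   out of scope).
2. **Shared intensity scale.** Channels are never rescaled on input; the
   ratio-based calibration is only meaningful if control and mixed stacks
   come off the detector with the same gain settings.
3. **One global threshold per channel per stack.** Thresholding precedes
   per-slice summation, so a single Li threshold is computed over all
   z-slices of a channel (a per-slice variant exists for stacks with
   strong depth attenuation, `segment_channel_per_slice`).
4. **Volume, not cells.** Composition shares are shares of segmented
   biovolume (voxel counts), not cell counts. Channels are segmented
   independently; a voxel claimed by several channels counts for each,
   and the overlap fraction is reported so this can be audited.

## Crosstalk estimation

For an ordered pair (populated i, unpopulated j), the per-voxel ratio
r = I_j / I_i is histogrammed over the foreground of channel i and the
coefficient is the histogram mode (center of the highest bin, ties toward
the lower bin). Numerical choices, each of which matters in practice:

- **Foreground restriction.** Ratios are formed only where the blurred
  populated channel exceeds its Li threshold. Unrestricted division is
  dominated by background 0/0 noise and near-zero denominators, and the
  mode becomes meaningless.
- **Ratios on blurred channels.** Both channels are blurred with the
  segmentation sigma before dividing. Because the same linear kernel is
  applied to numerator and denominator, a noise-free linear mixture keeps
  r = k exactly — including at object edges — while per-voxel read noise
  in the ratio shrinks roughly four-fold at the default sigma. Without
  this, at 5% noise the left tail of the ratio distribution clips at
  zero and the spurious pile-up at the first bin wins the mode, returning
  k ≈ 0.
- **Background subtraction** (on by default). The median intensity over
  the non-foreground voxels is subtracted from both channels first. A
  camera/background offset b otherwise inflates the estimate by
  ≈ b/brightness — 0.05 for the default imaging model, i.e. as large as a
  typical true coefficient. The off-foreground median automatically
  includes the bleed-through of the background itself, which is why the
  noise-free estimate becomes exact rather than approximately corrected.
- **Histogram.** Ratios are clipped to [0, 1.5] and binned into 256 bins
  whose centers sit on integer multiples of the bin width (first center
  exactly 0), so a bleed-free control yields a coefficient of exactly 0.
  Half a bin (≈0.003) is therefore the estimator's resolution floor.

Correction is subtractive by default — consistent with the pairwise way
the coefficients were calibrated — and clamps at zero. Full unmixing
(per-voxel linear solve of the mixing system) is available; for all
off-diagonal k ≤ 0.1 the two agree to first order (discrepancy ≤ k² ×
foreground intensity, checked in the tests).

Calibration requires dedicated single-label stacks, one per channel. The
synthetic module provides `calibration_controls` (a slab of each species
rendered alone under the study imaging model); deriving controls from a
mixed measurement is not supported, since a species may be absent from a
given condition.

## Segmentation

Gaussian blur (reflective boundaries; default sigma (0, 1, 1) voxels —
in-plane only, because confocal z-sampling is coarser than xy) followed by
Li minimum-cross-entropy thresholding. The threshold is found by the
Li–Tam fixed-point iteration t_{n+1} = (μ_b − μ_a)/(ln μ_b − ln μ_a),
with μ_b, μ_a the mean intensities at or below / above t, run on a
256-bin histogram of the blurred channel scaled to its own min–max range
and mapped back. Initialisation at the histogram mean; tolerance 0.5 gray
level; at most 100 iterations; ties broken toward the lower threshold;
gray levels are offset by 1e-9 in the logs so an all-zero background
class is handled. The tests verify, on generated two-level, bimodal and
skewed histograms, that the fixed point lands within one gray level of
the exhaustive minimizer of the cross-entropy criterion (computed with
the per-level log-ratio form; the expanded −Σ S ln μ form cancels
catastrophically), and cross-check against scikit-image's independent
implementation.

Two degenerate cases produce an empty mask plus a warning instead of an
error, so batch runs over many species combinations survive conditions
where one organism has vanished:

- a constant channel (nothing to threshold);
- a channel containing only noise around the background. Any automatic
  threshold bisects pure noise and claims about half the voxels, so a
  guard requires the mean above-threshold intensity to exceed
  `min_contrast` (default 2.0) × the mean below-threshold intensity.
  Genuine fluorescence foreground is typically 10–40× brighter than
  background; a noise split achieves a few percent. The default would
  misclassify a real channel only if its foreground were dimmer than
  twice the background, which also defeats ratio calibration and is
  outside the regime this pipeline is built for.

## Quantities

Per mask: f_z = occupied voxels in slice z / voxels per slice; total
fraction F = occupied / total voxels; physical volume = count × dz·dy·dx
(µm³). Composition share s_c = 100 · V_c / Σ V. Replicate summaries use
the arithmetic mean and the n−1 sample SD per slice and per total, with
n = 3 positions the documented default. Volume comparisons between
conditions use Welch's two-sample t-test (two-sided; delegated to
scipy). The layer descriptor assigns each channel its occupancy-weighted
mean z and its occupancy shares in the bottom/middle/top thirds of the
stack (`numpy.array_split` handles non-divisible Z); channels are ordered
by mean z, and a channel is flagged "sandwich" when its bottom- and
top-third shares both exceed its middle-third share. The thirds rule is a
deliberate, configurable operationalization of a qualitative microscopy
observation.

## The synthetic scene generator

`make_scene` composes per-species boolean occupancy from horizontal
layers (optionally restricted to a corner rectangle in-plane, which gives
exact fractional occupancies without sub-resolution speckle),
spherical microcolonies, and hyphae modelled as persistent-random-walk
tubes growing from the substratum, with satellite cells of another
species attached within one voxel of the tube surface at a set
probability — a minimal stand-in for bacteria colonizing fungal hyphae,
sufficient for imaging tests, not for morphology research. With
exclusivity on (default), species are laid down in order and never share
a voxel; explicitly overlapping full-density layers of different species
are rejected.

`render` maps occupancy to intensities: per-voxel brightness drawn
lognormally around the species mean (CV 0.1 by default, mimicking
expression heterogeneity), plus a background offset; linear mixing by the
true crosstalk matrix (mixing acts before the PSF, since emissions mix at
detection while blur is optical); anisotropic Gaussian PSF; additive
Gaussian read noise (optional Poisson shot noise); clipping at zero. All
randomness flows from explicit integer seeds and re-runs are
bit-identical.

Default imaging conditions used throughout the validation scenes:
foreground brightness 200 counts, background 10, crosstalk 0.05 per
ordered pair, PSF sigma (0, 1, 1) voxels, read noise sigma 10 counts (5%
of foreground). These are realistic mid-range values for 8–12-bit
confocal acquisition of well-expressed fluorescent proteins.

**What passing on synthetic data does and does not show.** The generator
reproduces the pipeline's own forward model (linearity, Gaussian blur,
Gaussian noise). Passing recovery tests therefore demonstrates internal
correctness and noise robustness, not robustness to what real stacks add:
depth-dependent attenuation and scattering, autofluorescence, detector
nonlinearity and saturation, drift, and biofilm matrix signal. The
slab-geometry scenes also make segmentation errors concentrate on object
boundaries; irregular real interfaces will show somewhat larger
per-voxel error at the same noise level.

## Validation problem sizes

Benchmark scenes in `scripts/acceptance.py` are 64 × 128 × 128 voxels
(about 1M voxels, 50 occupied slice-equivalents split 76/24, 7/93 and
0/100 between two species); calibration controls are 24 × 64 × 64 slabs.
The test suite runs the same chains at 32 × 64 × 64 and smaller — ample
for voxel-counting statistics while keeping the whole suite in seconds.
An interesting property of the default regime: in-plane blur leaves
residual noise (~3 counts) far below the foreground/background separation
(~200), so the segmented mask is determined by geometry alone and the
recovered shares are identical across noise seeds.

## Known limitations

- Pairwise subtractive correction is first-order; for off-diagonal
  k > 0.1 use the `unmix` method.
- The crosstalk mode estimator quantizes to the histogram bin width;
  coefficients below ~0.006 are indistinguishable from 0 at default
  settings.
- "Maximum of the distribution" is implemented as the mode of the ratio
  histogram; the literal maximum observed ratio is an unbounded noise
  statistic and is not offered.
- No correction for depth attenuation; for strongly attenuated stacks the
  per-slice thresholding variant is a partial workaround.
- Composition shares are volume shares; converting to cell numbers would
  require per-species cell-size calibration, which is out of scope.
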