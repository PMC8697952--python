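# Methods

## The verification problem

A dog's nose tip (rhinarium) carries a pattern of raised polygonal
*beads* separated by narrow sunken *grooves*.  The pattern is formed
early in life, is distinct between individuals, and is stable over
time, which makes it a candidate biometric marker analogous to a human
fingerprint or iris.  The pipeline in this package tests the
operational claim behind that idea: if every pair of nose images in a
cohort is compared with a fixed matcher, the distances of *genuine*
pairs (same dog) and *impostor* pairs (different dogs) should form two
populations separated cleanly enough that a single fixed threshold
decides identity with no errors.

Because no suitable nose-image dataset is publicly available, the
package ships a first-class synthetic cohort generator that emulates
the statistical structure such a study needs — a latent, time-invariant
per-subject texture re-captured several times under photometric and
geometric perturbation — and the whole pipeline is exercised end to end
on those synthetic cohorts.

## Synthetic nose textures

**Texture model.** One subject's latent pattern is a nearest-site
tessellation: `n` random site points on a canvas partition it into
convex polygonal cells.  For a pixel `p` with nearest-site distances
`d1 <= d2`, the quantity `(d2 - d1)/2` is its distance to the Voronoi
edge between the two nearest cells.  Pixels within half the groove
halfwidth of an edge are groove-dark; intensity then ramps up to the
bead plateau, which carries a gentle dome (`bead_relief`) so beads are
not flat.  Intensities are mapped to `[0.12, 0.95]`: keeping the
pattern off the 0/1 rails means moderate additive capture noise is not
distorted by clipping.

**Defaults and why.** Canvas 256x256 px; per-subject draws of
`n_sites ~ U{48..64}`, groove halfwidth `U(3, 5)` px, bead relief
`U(0.2, 0.4)`.  With ~56 sites the mean bead spacing is
`256/sqrt(56) ~ 34` px, i.e. ~8.5 px after resampling to the 64 px
analysis grid — inside the passband of the default Gabor bank.  The
per-subject ranges create inter-subject variation in texture scale and
contrast, as different breeds and nose sizes would.

**Capture model.** Each capture applies, in order: an affine warp
(rotation, translation, isotropic scale about the canvas centre), an
illumination tilt plane, contrast/brightness, Gaussian blur, and
additive Gaussian noise, with the result clipped to `[0, 1]`.  Default
sampling ranges per capture: rotation ±5 deg, translation ±4 px per
axis, scale 0.95–1.05, brightness ±0.10, contrast 0.85–1.15, blur sigma
0–1.2 px, noise sigma 0–0.03, tilt ±8e-4 intensity/px.  These model
careful hand-held re-photography of a cooperative animal across
sessions months apart.  A warp that pushes more than 20% of the ROI off
the canvas is rejected as an unusable capture.

**Seeding.** Every random stream derives from the cohort master seed
through `SeedSequence([master_seed, subject_index, counter])`, where
counter 0 is the subject's identity stream and counter `c+1` its
capture-`c` stream.  The cohort on disk is a pure function of its spec
(byte-identical rerun), and appending subjects never perturbs existing
subjects' images.

**What the generator does not emulate.** Photorealistic skin, wetness
and specular highlights, 3-D nose shape, nostril/philtrum geometry
(the synthetic image *is* the ROI), out-of-plane pose, and partial
occlusion.  Passing tests therefore demonstrate that the encoding and
matching machinery behaves as designed under controlled perturbation —
not that real dog noses separate at any particular margin.

## ROI normalization

ROIs are cropped by manifest rectangle (0-based, half-open), converted
to grayscale by unweighted channel mean, resampled bilinearly to the
64x64 analysis grid, and normalized to zero mean and unit variance
(the removed mean/std are kept as metadata).  The normalization makes
the sign code exactly invariant to affine intensity maps, which is why
brightness and contrast drift in the capture model do not move
distances.  A constant crop has no pattern and is rejected.  The
64x64 grid is a choice, not an observation: published work does not
state the ROI resolution.

## Binary template encoding

The ROI is correlated (reflect borders) with a bank of zero-mean
complex Gabor kernels — 4 orientations (0/45/90/135 deg) x wavelengths
{8, 16} px, envelope sigma = 0.5 x wavelength — and the responses are
sampled every 2 px, giving a 32x32 grid.  Each sampled response
contributes two bits, the signs of its real and imaginary parts
(`>= 0` encodes 1, so a tie at exactly zero is deterministic), for a
16 x 32 x 32 = 16,384-bit template.  A `real_only` mode (one bit per
filter) is retained for the stricter single-sign reading.  Correlation
is computed by FFT on a symmetric-padded image; an explicit-loop dense
convolution reproduces it to < 1e-9, and that equivalence is a test.

Templates serialize to a compact binary record (magic `CNT1`,
little-endian header with plane/grid/stride/bank-fingerprint, bit-packed
rows) stored as a directory of files plus an index CSV; round-trips are
bit-exact.

## Matching

The matching distance is the fractional Hamming distance: the fraction
of bit positions at which two templates differ.  Because captures carry
residual translation, the matcher searches integer grid shifts
`|dx|, |dy| <= max_shift` (default 3 cells = 6 px), computing the
distance over the overlapping region only; the overlap must retain at
least 50% of cells, and ties break toward the smallest `|dx|+|dy|`,
then lexicographic.  `max_shift = 0` is the literal fixed-template
comparison.  The all-pairs routine computes, per shift, one bit-count
matrix product over the whole gallery and is verified against the
per-pair path; an independent brute-force enumeration over shifts is
the oracle for the per-pair path itself.  No rotation search is
performed (see Limitations).

## Evaluation

All `N(N-1)/2` unordered pairs are labeled genuine or impostor; the
report contains per-population min / max / mean / sample (n-1) standard
deviation, normalized histograms (default bin width 0.01; densities
integrate to 1), decision counts at the threshold, FAR (impostors
accepted / impostors) and FRR (genuines rejected / genuines), the
separation margin (min impostor − max genuine), and an interpolated
equal-error rate.  The decision rule is strict: distance < threshold
declares *same dog*; a distance exactly at the threshold declares
*different dogs*.  Whether the population std should use `n` or `n-1`
is not settled in the source material; sample std was chosen and the
4-decimal report precision makes the difference invisible at these
population sizes.

## Study conditions and measured behavior

The reference cohort layouts are 60 subjects x 3 captures (180 images;
16,110 pairs = 180 genuine + 15,930 impostor) and the combined layout
of 70 subjects / 278 images (38,503 pairs = 612 genuine + 37,891
impostor; the extra 10 subjects carry 9–10 captures).  These sizes run
in seconds on one CPU, so nothing is scaled down: the acceptance
script and the end-to-end tests run the full layouts.

On the default 60x3 cohort with master seed 1 the pipeline measures
(values printed by `scripts/acceptance.py --seed 1`): genuine distances
0.0472–0.3851 (mean 0.2181), impostor distances 0.3870–0.4909 (mean
0.4515), separation margin +0.0019, FRR 0 and FAR 0.0006 at the 0.4
threshold, EER 0.  The two populations are far apart in the mean
(~0.23), and a zero-error threshold exists at the margin midpoint.

## Known limitations

- **Rotation is the binding constraint.**  A genuine pair can differ by
  up to 10 deg of relative rotation under the default ranges.  At
  wavelength 8 px on a 64 px grid, 10 deg displaces peripheral content
  by more than half a carrier period, so the worst-case genuine pairs
  reach distances ~0.43 — the impostor regime — while typical genuine
  pairs stay near 0.2.  The shift search cannot absorb a rotation
  field, so the *extreme-value* margin is near zero and its sign varies
  with the master seed, even though mean separation is wide and error
  rates at the 0.4 threshold stay below ~0.2% FAR / ~5% FRR.  Cohorts
  with many captures per subject (the combined layout) sample this
  worst case more often and typically show a small negative margin.
  A rotation search would remove the effect; it is deliberately out of
  scope to keep the matcher the plain shifted-Hamming comparison.
- Identification (1:N search), ROC benchmarking against keypoint
  matchers, and automatic ROI detection in unconstrained photographs
  are out of scope.
- Synthetic textures are stationary Voronoi fields; real nose patterns
  have spatially varying bead size and a philtrum, so absolute distance
  values here do not transfer to real images.
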