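# Methods

## Problem

Label-free two-photon imaging of the metabolic coenzymes NAD(P)H and FAD
reports on tissue metabolic state through two families of image-derived
metrics: the per-pixel optical redox ratio

    RR = FAD / (FAD + NAD(P)H),

summarised per optical section by its mean and interquartile range, and
the mitochondrial-clustering exponent `beta`, obtained by fitting an
inverse power law

    R(k) = A * k^(-beta)

to the radially averaged power spectral density (PSD) of the cytoplasmic
NAD(P)H intensity-fluctuation image (k is the magnitude of spatial
frequency in cycles/pixel).  Per stack, the mean and the sample variance
across depth of mean RR, RR IQR and beta form six summaries that carry
diagnostic information.  Single-frame acquisitions at clinically safe
power are noisy enough — a mix of Poisson shot noise and additive Gaussian
read noise — that beta in particular is badly corrupted; the package
restores these metrics by deep denoising, optionally performed per
wavelet sub-band (WU-Net), and quantifies recovery against frame-averaged
or clean references.

## Denoising model

`CAREDenoiser` is a residual U-Net in the content-aware image-restoration
lineage: a convolution expands the single-channel patch to
`base_channels`, an encoder halves resolution `levels` times while
doubling channel width, and a decoder mirrors it with nearest-neighbour
upsampling and skip concatenations.  The final 1x1 convolution predicts a
correction added to the input; it is zero-initialised so the untrained
network is the exact identity.  The reference geometry is a 256-pixel
input with six levels and 32 base channels; the shallower profile used
throughout the tests (3 levels, 16 base channels, one convolution per
block) is the documented desk-scale configuration.

`WUNetDenoiser` decomposes every patch with a single-level 2-D discrete
wavelet transform (default biorthogonal 1.1; biorthogonal, coiflet and
Daubechies families are supported) into approximation and
horizontal/vertical/diagonal detail bands, trains one U-Net per band
against the matching band of the ground truth, and reconstructs with the
inverse transform.  Each band trains independently with the same
schedule; losses are computed per band in the wavelet domain.  With
identity networks the architecture reduces to the DWT/iDWT round trip,
an exactly testable contract.  An image-domain joint objective through
the inverse transform is not implemented.

The networks, their autodiff engine, Adam optimiser and
reduce-on-plateau scheduler are implemented in NumPy inside
`wunet.nn` (convolution as im2col + BLAS matmul).  Training runs in
float32; inference adds the predicted correction in the caller's dtype so
identity contracts hold to machine precision.  Training is deterministic
under a fixed seed in single-threaded execution.

### Training objectives

MAE, MSE, an SSIM loss (1 minus mean local SSIM, Gaussian window 11,
sigma 1.5, k1 = 0.01, k2 = 0.03, borders cropped; the window shrinks to
fit small inputs), a focal frequency loss (spectrum-weighted squared
frequency-domain error; the weight `|F_p - F_t|^gamma`, normalised to
max 1 per image, is a stop-gradient factor, gamma defaults to 1), an R2
loss (one minus the coefficient of determination of the target explained
by the prediction, falling back to MSE for constant targets), and a
redox-ratio loss (mean absolute difference of RR computed on unmasked
channel pairs with an epsilon of 1e-6 of the data range in the
denominator).  Combined losses weight the SSIM term by `alpha`
(default 0.84) and the second term by `1 - alpha`.  Gradient checks
compare autodiff gradients against central finite differences in
float64; for FFL-containing objectives the spectrum weight is frozen at
the expansion point on both routes, matching its stop-gradient role.

### Optimisation schedule

Adam (default learning rate 1e-5 in the full-scale configuration, 300
epochs, plateau patience 20, factor 0.5, best-validation-loss weights
kept, no early stopping).  The desk-scale experiment uses learning rate
1e-3, 6 epochs, patience 3, batch 16 — sized so the whole end-to-end run
completes on one CPU at the problem sizes below while still converging
well past its acceptance margins.

## Synthetic data

No public paired clinical dataset exists for this acquisition, so the
generator is the canonical input.  One ROI is a two-channel z-stack
(default 4 um depth spacing, six frames per depth).  Each optical section
is a rounded-Voronoi cell mosaic (seeded centres, radius ~0.62 *
size/sqrt(n_cells), +-20% jitter) with dark nuclei (intensity scaled by
0.30, area fraction `nucleus_fraction` = 0.12) over a flat background
(0.12).  Cytoplasmic NAD(P)H texture is a power-law random field with the
depth's target exponent: Fourier amplitudes set deterministically to
k^(-beta/2) with random phases, standardised, scaled by a texture
contrast of 0.25 around unit mean.  The FAD channel is a per-cell scaling
of NAD(P)H with s = r/(1-r), where each cell's r is the depth's RR target
plus N(0, 0.015) jitter, so the clean pixelwise RR averages to the target
within the cytoplasm mask by construction.  Default depth profiles ramp
beta from 1.3 to 2.5 and RR from 0.35 to 0.60 across the stack,
emulating the differentiation gradient of a stratified squamous
epithelium; signal decays by 5% per depth step to mimic depth-dependent
SNR loss.

Noise: intensities are corrupted as Poisson(gain * I)/gain +
N(0, sigma^2) with gain 25 and sigma 0.15 by default, placing
single-frame PSNR near 19-20 dB — the low-SNR regime of interest.  These
are configuration values, not measured detector constants.  Negative
values are clamped to zero for raw/ground-truth stacks (detector counts
are non-negative).  Six independent corruptions per depth are averaged
into the ground truth; a seeded random frame becomes the raw input.
Cohorts perturb the depth profiles per stack (common shift plus
per-depth jitter of stack-specific amplitude) so stack-level summaries
genuinely vary and correlations against truth are estimable.  Cohorts
also vary acquisition SNR per stack — a lognormal noise-scale factor
(sigma of log 0.35) multiplies the read noise and divides the photon
gain by its square — yielding a raw-PSNR spread of roughly +-3 dB across
stacks, the regime clinical cohorts show.  Without this heterogeneity
the noise-induced bias of the clustering exponent would be identical in
every stack and raw-image metrics would correlate with truth almost
perfectly, leaving denoising nothing to restore at cohort level.

What the generator does **not** emulate: optics (PSF, scattering),
nuclear autofluorescence, acquisition drift, or any histology beyond a
cell mosaic.  Passing tests demonstrate that the algorithms recover the
statistics they are defined on, under the stated noise model — not
clinical performance.

## Metric extraction choices

* Cytoplasm masks: synthetic stacks supply exact masks; otherwise the
  default mask is pixels above the 25th percentile of the NAD(P)H
  section.  The threshold mask is a reproducible fallback, and with it
  the beta estimate carries mask-boundary leakage; quantitative recovery
  statements in the tests use exact masks.
* Fluctuation image: division by the in-mask mean; out-of-mask pixels
  are set to 1 (the post-normalisation mean) to suppress boundary
  leakage.  Metrics operate on non-negative intensities; slightly
  negative denoised excursions are clipped at zero at this boundary.
* PSD: |FFT|^2 / n_pixels, radially averaged in annuli one frequency
  sample wide, DC excluded.  Power-law fit: ordinary least squares of
  log10 PSD on log10 k over k in [3/N, 0.45] cycles/pixel (at least 8
  positive bins required); beta is minus the slope.
* IQR uses linear-interpolation percentiles; summaries use the n-1
  sample variance; both choices are stated so exact tests are possible.
* PSNR: 10 log10(range^2/MSE); the volumetric value uses a single MSE
  over the stack.  Range defaults to max minus min of the reference.
  SSIM: Gaussian window (11, sigma 1.5), 3-D window for stacks at least
  11 deep, otherwise the per-section mean.

## Statistics

Model comparisons transform Pearson correlations with Fisher's
z_r = arctanh(r) and compare two correlations with
Z = (z1 - z2)/sqrt(1/(n1-3) + 1/(n2-3)), two-tailed normal p-values, and
significance stars at 0.05/0.01/0.001.  n is always the explicit number
of stacks contributing pairs.  Correlations of exactly +-1 (possible in
synthetic perfect-recovery settings) are clipped to +-(1 - 1e-12) before
the transform.  Reports carry both r and r^2.  No multiple-testing
correction is applied.

## Desk-scale end-to-end experiment

`wunet.pipeline.run_end_to_end` simulates 60 training and 20 held-out
two-channel stacks (128x128, 8 depths, ~12 cells per field), splits
training sections 75/25 by ROI, trains the four-band wavelet denoiser on
the FAD channel (SSIM + R2 loss, alpha 0.84, biorthogonal 1.1), and
applies it to both channels of the held-out stacks (channel transfer).
It reports held-out mean PSNR against the clean reference for raw,
frame-averaged and denoised stacks, and the correlation across stacks of
the depth-variance of beta (denoised vs clean and raw vs clean).  These
problem sizes are the package's test configuration; every number the
README quotes is recomputed by `scripts/acceptance.py`.

## Numerical notes and limitations

* Wavelet boundary handling defaults to symmetric half-sample padding;
  for biorthogonal 1.1 on even sides the sub-bands are exactly half
  size.  Longer filters expand bands by a few pixels, which the sub-band
  networks require to be divisible by 2^levels — use periodization mode
  if that matters.
* The plateau scheduler reduces the rate when `patience` consecutive
  epochs fail to improve the best validation loss; with a constant
  validation loss it fires exactly once per patience window.
* The beta estimator is exact on exact power-law spectra and unbiased
  within ~0.05 on constructed fields at 256 pixels; bias grows at small
  field sizes and with aggressive masking.
* MAE is non-differentiable at exact ties; the gradient checker reports
  (not fails) evaluation near such points.
* The redox-ratio loss requires paired counterpart channels and is not
  available for per-band single-channel training.
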