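# wunet

Wavelet-domain deep denoising and metabolic-metric recovery for
label-free, two-photon NAD(P)H / FAD image stacks.

## Why

Two-photon autofluorescence of the coenzymes NAD(P)H and FAD reports on
tissue metabolism without labels.  Two read-outs carry most of the
diagnostic signal:

* the **optical redox ratio** per pixel,
  `RR = FAD / (FAD + NAD(P)H)`, summarised per optical section by its
  mean and interquartile range; and
* the **mitochondrial clustering exponent** `β` from the inverse
  power-law fit `R(k) = A·k^(−β)` to the radially averaged power
  spectral density of the cytoplasmic NAD(P)H intensity-fluctuation
  image.

At clinically safe excitation power, single-frame images are noisy
(mixed Poisson + Gaussian), and `β` — which lives in the high spatial
frequencies — is corrupted badly.  This package restores such images
with residual U-Nets, either applied directly to patches (CARE-style,
`CAREDenoiser`) or to the four sub-bands of a single-level discrete
wavelet transform with one network per band (**WU-Net**,
`WUNetDenoiser`), and then quantifies what matters: not only PSNR/SSIM,
but whether the six stack-level metabolic summaries (mean and
depth-variance of mean RR, RR IQR and β) computed from denoised stacks
track ground truth, compared across models with Fisher r-to-z tests.

A synthetic paired-stack generator (`wunet.synthetic`) provides clean /
single-frame / frame-averaged two-channel stacks with known per-depth β
and RR targets, so every stage of the pipeline has ground truth.

## Worked example

```python
import numpy as np
from wunet.synthetic import SyntheticConfig, generate_cohort
from wunet.pipeline import training_pairs, split_pairs_by_roi
from wunet.denoiser import WUNetDenoiser, denoise_stack
from wunet.metabolic import stack_metrics
from wunet.quality import psnr

cfg = SyntheticConfig(section_size=128, n_depths=8, cell_density=12)
stacks, manifest = generate_cohort(cfg, n_stacks=60, seed=111)

X, Y, rois = training_pairs(stacks, channel="FAD")
(Xtr, Ytr), (Xva, Yva), _ = split_pairs_by_roi(X, Y, rois, (0.75, 0.25), seed=5)

est = WUNetDenoiser(wavelet="bior1.1", loss="ssim_plus_r2", alpha=0.84,
                    levels=3, base_channels=16, learning_rate=1e-3,
                    max_epochs=6, plateau_patience=3, seed=3)
est.fit(Xtr, Ytr, X_val=Xva, y_val=Yva, channel="FAD")

test, _ = generate_cohort(cfg, n_stacks=1, seed=222)
ps = test[0]
den = denoise_stack(est.bundle_, ps.raw["NADPH"])   # channel transfer
clean = ps.clean["NADPH"].sections()
print(f"raw      {psnr(clean, ps.raw['NADPH'].sections()):.1f} dB")
print(f"denoised {psnr(clean, den.sections()):.1f} dB")
mp = stack_metrics(den, denoise_stack(est.bundle_, ps.raw["FAD"]),
                   masks=ps.masks)
print("beta per depth:", np.round(mp.beta, 2))
```

On the seeded desk-scale experiment this package ships
(`wunet.pipeline.run_end_to_end`, seed 1: 60 training + 20 held-out
128×128×8 stacks, single-frame NAD(P)H PSNR in the high-teens of dB
with a ±3 dB spread across stacks), the FAD-trained four-band denoiser
applied to both channels prints a held-out mean PSNR of 24.24 dB
against the clean reference versus 20.62 dB for the raw frames
(+3.61 dB; the six-frame average sits at 28.25 dB), and raises the
cohort correlation of the depth-variance of β against clean truth from
r = 0.648 (raw) to r = 0.678 (denoised), with the mean-β correlation
rising from 0.329 to 0.364 — image quality improves, and the
mitochondrial-organisation metrics that noise degrades most recover
with it.

A CLI mirrors the library:

```bash
wunet simulate --out data --n-stacks 8 --seed 3
wunet train --data-dir data --out bundle --mode wunet --channel FAD
wunet denoise --bundle bundle --in data/roi-3-000_NADPH_raw.tif --out den.tif
wunet metrics --nadph den.tif --fad fad_den.tif --out metrics.csv
wunet run --out rundir --seed 1        # full pipeline + hashed manifest
```

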