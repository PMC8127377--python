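# destreak

Self-calibrating multiscale removal of streak noise from tomographic
sinograms — and hence of ring artifacts from the reconstructions built from
them.

Streak noise is nearly constant along the angular dimension of a sinogram.
`destreak` models it as additive stationary spatially correlated noise in
the log domain (vertically constant, horizontally white correlation kernel)
and attenuates it with a two-stage collaborative filter (block matching,
3-D transform, hard-threshold / Wiener shrinkage, weighted aggregation)
that uses exact transform-domain noise variances derived from the noise
power spectral density. Because a fixed block size cannot span wide
streaks, filtering runs coarse-to-fine over a pyramid of horizontally
binned scales, with iterative spline debinning carrying coarse estimates
back to finer scales. The streak noise level is self-calibrated per scale
and per 39-pixel horizontal segment with a detail filter (vertical Gaussian
low-pass × horizontal db3 high-pass) and a median-absolute-deviation
estimator. Extreme streaks from defective detector pixels are detected on
the angular median map by local bivariate-cubic fits and repaired by
windowed medians before filtering.

## Library quick start

```python
import numpy as np
from destreak import make_phantom_sinogram, corrupt, multiscale_denoise, snr_db

pair = corrupt(make_phantom_sinogram(), sigma_streak=0.02, peak=2560, seed=0)
estimate, calibration = multiscale_denoise(pair.Z)   # angle x displacement
print(snr_db(pair.Z, pair.Y), "->", snr_db(estimate, pair.Y))
```

For raw projection stacks (angle × detector-row × detector-column) with
bright/dark fields, `destreak.destreak_stack(P_raw, I_B, I_D, cfg)` runs
the full pipeline: normalization, log transform, extreme-streak repair and
per-sinogram multiscale filtering. Output stays in the log domain (a naive
`exp` inversion is biased; use an exact unbiased inverse if you must leave
the log domain).

## Command line

```sh
destreak simulate out/ --sigma 0.02 --peak 2560 --seed 7   # phantom pair + JSON sidecar
destreak denoise scan.tif out.tif --bright bright.tif      # raw stack -> log-domain estimate
destreak denoise sino_stack.tif out.tif --log-domain       # already log-transformed
destreak calibrate sinogram.tif --out calib.json           # noise levels per scale/segment
destreak evaluate --reps 3 --out table.csv                 # phantom benchmark grid
```

Inputs may be multipage TIFF, HDF5 (dataset names and on-disk axis order
configurable) or a directory of per-angle TIFFs. All knobs live in a YAML
config (`--config`); defaults reproduce the published settings (8×8 blocks,
39×39 search, ~64-row vertical binning, 39-pixel calibration segments,
19×19 defect-detection window).

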