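# wavenuc

Wavelet-based 3D nuclei segmentation for fluorescence microscopy z-stacks,
with a synthetic benchmark generator, three conventional baseline
segmenters, evaluation metrics, and nuclear morphometrics.

## Who this is for

Quantitative developmental biologists and image analysts who need to count,
localize and measure thousands of nuclei in 3D confocal stacks (e.g. whole
zebrafish embryos) without hand-tuning intensity thresholds per image. The
segmenter's single required parameter is the expected nucleus radius in
pixels; it needs no preprocessing and is robust to heavy impulse noise and
intensity-attenuation gradients.

## The method

Each z-slice `f(x, y)` is correlated with dilated copies of the 2D
Mexican-hat wavelet

    K(s, a, b) = s^(-1/2) Σ_{x,y} f(x, y) ψ((x − a)/s, (y − b)/s),
    ψ(x, y)    = (1/πσ₀²) (1 − (x² + y²)/(2σ₀²)) e^(−(x² + y²)/σ₀²),

over scales `{r − 1, r, r + 1}` bracketing the nucleus radius `r`. A
nucleus shows up as a response extremum co-located at every scale whose
zero-level contour has nearly the same area at every scale — real objects
are scale-stable, while noise structure inherits the kernel footprint and
grows like `s²`. The surviving per-slice masks are chained across adjacent
z-planes (≥ 80% overlap of the smaller mask, intensity ≥ 20% of the seed
centre), merged objects are divided laterally (multiple co-located extrema,
or a centre shift larger than `r/3` between slices) and axially (two
qualifying extrema in both the XZ and YZ coefficient planes), and objects
smaller than 20% of the expected nucleus volume are dropped.

Alongside the segmenter the package provides:

* `wavenuc.synthetic` — 3D Gaussian-blob nuclei with minimum-spacing or
  forced-overlap placement, plus white/Gaussian/salt-and-pepper/attenuation
  noise, with exact ground truth;
* `wavenuc.baselines` — point-wise, multilevel-Otsu and Derivatives-Sum
  reference segmenters sharing the same result type;
* `wavenuc.evaluation` — mutual-nearest-neighbour matching, TP rate /
  Precision / FN rate, voxel-level Jaccard accuracy;
* `wavenuc.morphometrics` — per-nucleus size, density, neighbour distance,
  depth level, thickness, height sorting, enveloping-layer flags, and
  cell-cycle shape classification (spherical / irregular / elliptical /
  dividing);
* `wavenuc.estimators` — scikit-learn-style estimator classes
  (`WaveletSegmenter(...).fit(volume)`) over all four methods;
* a `wavenuc` command-line tool (`simulate`, `segment`, `evaluate`,
  `features`, `classify`, `compare`).

## Worked example

```python
import numpy as np
from wavenuc import SyntheticSpec, NoiseSpec, generate_dataset, segment, evaluate

spec = SyntheticSpec(
    dims=(128, 128, 40), n_nuclei=20, radius=9, intensity=1000,
    radius_randomness=0.2, intensity_randomness=0.2,
    noise=NoiseSpec(kind="salt_pepper", nd=0.10), seed=7,
)
volume, truth = generate_dataset(spec)          # volume[z, y, x], float
result = segment(volume, radius=9)              # the one required parameter
report = evaluate(result, truth, max_dist=9)    # mutual-NN matching, cap = r

print(len(result.nuclei), report.tp_rate, report.precision)
print(np.round(result.centroids[0], 1))
```

Output:

```
20 1.0 1.0
[ 98.3 108.   24. ]
```

All 20 nuclei are recovered with no false positives despite 10% of all
voxels being replaced by salt-and-pepper impulses; the first nucleus's
centroid (x, y, z) lands within a pixel of its true centre. The same run
from the shell:

```sh
wavenuc simulate --n 20 --radius 9 --noise salt_pepper --nd 0.10 --seed 7 --out data/
wavenuc segment data/image.tif --radius 9 --out data/labels.tif
wavenuc evaluate --seg data/labels.tif --truth data/truth.csv --max-dist 9
wavenuc features --seg data/labels.tif --radius 9 --out data/features.csv
```

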