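# paddyflower

Detection and diurnal quantification of flowering rice panicles in
fixed-camera canopy image time series.

When a rice spikelet opens, its extruded anthers form a bright speckled
texture on the panicle for a few hours around the daily flowering burst.
`paddyflower` finds that texture with the classical recognition stack —
dense multi-scale SIFT descriptors, a k-means visual-word vocabulary
(k = 600), and a χ²-kernel SVM made linear through the homogeneous kernel
map — applied over non-overlapping 140 px sliding windows. Two counts
summarize each image:

* **FBN** — flowering block number: windows classified as containing
  flowering panicle parts;
* **FCBN** — flowering connected-block number: connected regions of those
  windows, a proxy for the number of flowering panicles.

Per-image counts become time series (images every 5 minutes, 08:00–16:00),
from which the package locates daily flowering peaks and validates the
automated counts against manually counted panicles (**FPN**) by Pearson
correlation. The χ² kernel is K(x,y) = Σᵢ 2xᵢyᵢ/(xᵢ+yᵢ) on L1-normalized
bag-of-visual-words histograms; its feature map expands each bin x into
√(xL), √(2xL·sech(πjL))·cos(jL log x), √(2xL·sech(πjL))·sin(jL log x) for
j = 1..n.

A seeded synthetic canopy generator (leaf-stroke background, curvilinear
panicle arcs, bright anther speckles, Poisson diurnal flowering schedule)
makes every stage testable without field imagery — including end-to-end
recovery of a known flowering schedule. It is first-class, tested code.

The package targets plant-phenotyping researchers who run fixed field
cameras and want flowering onset, daily amount and diurnal peak timing
without manual counting.

## Worked example

```python
from datetime import time
import numpy as np

from paddyflower import (
    CanopySpec, render_canopy, sample_patches, simulate_series,
    dense_multiscale_sift, train_codebook, train_model, detect,
    build_series, daily_peak, pearson_r, CountAnnotation,
)
from paddyflower.vocabulary import nonzero_descriptors

# 1. a training canopy with known flowering panicles, and 30+30 patches
img, gt = render_canopy(CanopySpec(n_flowering=12, seed=101))
patches = sample_patches(img, gt, n_pos=30, n_neg=30, seed=11)

# 2. vocabulary and model
descs = np.vstack([nonzero_descriptors(dense_multiscale_sift(p.patch.luminance))
                   for p in patches])
codebook = train_codebook(descs, k=600, n_restarts=8, seed=5)
model = train_model(patches, codebook, seed=7)

# 3. one simulated acquisition day, detection on a 25-minute subsample
series_items = simulate_series(1, time(12, 0), amplitude=12, seed=3)[::6]
fpn, fcbn = [], []
detections, annotations = [], []
for frame, ts, truth in series_items:
    result = detect(frame, model, codebook)
    fpn.append(truth.fpn); fcbn.append(result.fcbn)
    detections.append((ts, result))
    annotations.append(CountAnnotation(timestamp=ts, fpn=truth.fpn))

series = build_series(detections, annotations)
print("FPN :", fpn)
print("FCBN:", fcbn)
print("r(FPN, FCBN) =", round(pearson_r(fpn, fcbn), 3))
print("daily FCBN peak:", daily_peak(series, series_items[0][1].date(), "fcbn"))
```

Output:

```
FPN : [0, 0, 0, 0, 1, 2, 7, 7, 12, 11, 8, 2, 1, 0, 0, 0, 0]
FCBN: [0, 0, 0, 0, 1, 2, 6, 6, 6, 5, 4, 2, 1, 0, 0, 0, 0]
r(FPN, FCBN) = 0.938
daily FCBN peak: 2013-08-23 11:00:00
```

The detected connected-region count follows the true flowering count
closely (r ≈ 0.94 on this subsample); FCBN sits slightly below FPN near
the midday burst because adjacent flowering panicles merge into shared
regions. The day's detected peak lands within the late-morning flowering
window around the configured 12:00 maximum.

The same pipeline is scriptable from the shell: `paddyflower simulate`,
`train`, `detect`, `scan-series` and `experiment` (see `paddyflower
--help`); every CSV output records the configuration hash and seed.

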