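# aggrekit

Batch quantification of protein aggregates imaged by single-molecule
microscopy. The package serves labs characterizing amyloid and other
aggregates (e.g. Aβ in Alzheimer's research) with three assays:

- **counting** diffraction-limited aggregate spots in pull-down images,
- **membrane-permeabilization** measurement of per-liposome calcium influx,
- **morphometrics** of super-resolved (PAINT-style) aggregates — area, convex
  hull, axis, eccentricity and skeleton-based length,

plus two ground-truth **simulators** used to validate counting and sizing
accuracy without any experimental data.

## The core quantities

Spot detection is a matched filter: a frame is top-hat filtered, convolved
with a zero-sum Ricker wavelet (or Gaussian) kernel, thresholded at
mean + k·σ of the convolved-pixel histogram, opened, and 8-connected regions
away from the image edge are counted. Counting accuracy against a simulated
field with N_true resolvable dots is

    Accuracy = (1 − |N_measured − N_true| / N_true) × 100%.

Per-liposome calcium influx from blank/sample/ionomycin frame triplets is

    %Influx = (F_sample − F_blank) / (F_ionomycin − F_blank) × 100%,

integrated over a radius-3-px disk around each liposome peak. Super-resolved
aggregates are clustered with DBSCAN (ε, minPts) on localization coordinates
in nm; each cluster's length is the total branch length of its 20 nm/px
rendered, skeletonized image.

## Worked example

Simulate one 512×512 field of 300 dots at a 2× signal-to-background ratio
(dot peak mean 4000 counts over a 2000-count baseline) and count it back:

```python
from aggrekit.sim.diffraction import DLSimParams, simulate_dl, snr_to_peak_mean
from aggrekit.detect import DetectionParams, detect_spots, counting_accuracy

p = DLSimParams(n_dots=300, peak_mean=snr_to_peak_mean(2.0), snr_mask=True, seed=7)
ideal, noisy, truth = simulate_dl(p)
ps = detect_spots(noisy, DetectionParams())   # Ricker kernel, k=2, erosion 1
print("true_count:", truth.true_count)
print("measured:", ps.count)
print("accuracy: %.1f" % counting_accuracy(ps.count, truth.true_count))
```

```
true_count: 287
measured: 282
accuracy: 98.3
```

287 of the 300 simulated dots are resolvable (the rest overlap into shared
intensity peaks, which is why the ground truth is defined by
prominence-thresholded maxima, not by the number drawn); the detector finds
282 of them, a 98.3% counting accuracy. The same machinery is available from
the shell:

```sh
aggrekit simulate-dl --n-dots 300 --snr 2 --n-fovs 9 --seed 1 --out-dir fovs/
aggrekit count fovs/ counts.csv --glob "*_noisy.tif"
aggrekit validate --seed 1 --out validation.csv   # full SNR x density grid
```

and `aggrekit simulate-sr | localize | driftcorrect | cluster` run the
super-resolution chain from a blinking stack to a per-aggregate metrics CSV.

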