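# chromarg

Spectral-temporal typing and dendritic morphometrics of larval zebrafish
retinal ganglion cells (RGCs).

Zebrafish larvae have four cone types (red, green, blue, UV), and their
RGCs combine these channels in diverse ways across the eye.  `chromarg`
implements the full analysis path for population calcium imaging under
tetrachromatic binary noise:

- **Spectral kernels** by event-triggered reverse correlation: calcium
  transients are detected on the derivative of each ROI's trace
  (threshold 0.7 baseline SDs at 500 Hz) and the kernel is the
  steepness-weighted average stimulus,
  `F(l, tau) = (1/M) sum_i c'(t_i) S(l, t_i + tau)`,
  on a 649-sample lag grid (dt = 2 ms, from -973.5 ms), z-scored to the
  first 50 ms of lag.
- **Wiring and opponency**: each ROI maps to a ternary state over
  {On, Off, not connected} per cone channel (3^4 = 81 states; 50
  opponent, 15 + 15 non-opponent, 1 disconnected), with simple vs
  complex opponency by the number of spectral zero crossings along
  R -> G -> B -> UV, plus On-Off indices
  `OOi = (nOn - nOff) / (nOn + nOff)` and spectral centroids.
- **Eye-IPL maps**: statistics binned into 8 eye-position x 20
  IPL-depth bins (somata in bin 1, bin 2 an empty barrier, dendrites in
  bins 3-20) with circular binomial smoothing.
- **Functional clustering**: per-colour scaling, per-colour PCA
  (>= 99% variance), and a Gaussian-mixture sweep over component counts
  and four covariance structures with 20 replicates per cell and
  minimum-BIC model selection.
- **Morphometrics**: dendritic point-cloud summaries (y_span, y_mean,
  num_pts, convex-hull xz_area), two-stage hierarchical clustering
  (city-block/average linkage, cophenetic validation), and dendritic
  tilt in soma-centred spherical coordinates with two-sample KS and
  Kuiper statistics.

A synthetic-data generator with known ground truth (planted kernels,
cluster structure, stratification and tilt) makes every stage testable
without any external download.  See `docs/methods.md` for the models
and design choices.

## Worked example

```python
import numpy as np
from chromarg import (make_noise_stimulus, make_kernel_template,
                      GroundTruthROI, SimulationConfig, simulate_trace,
                      estimate_kernels, ternary_state, opponency_class)

stim = make_noise_stimulus(seed=1)               # 1651 frames x 4 LEDs
tmpl = make_kernel_template("On", "biphasic", 0.12, (1.0, 0.7, 0.3, 0.5))
trace = simulate_trace(GroundTruthROI(true_kernels=tmpl), stim,
                       SimulationConfig(seed=3))
ks = estimate_kernels(trace, stim)
print("quality:", ks.quality.round(1))
print("polarity:", ks.polarity)
state = ternary_state(ks)
print("ternary state:", state.state, "->", opponency_class(state).category)
for c in range(4):
    print(f"channel {c}: r = {np.corrcoef(ks.kernels[c], tmpl[c])[0,1]:.3f}")
```

prints

```
quality: [307.2 169.1  47.9 498.1]
polarity: ('On', 'On', 'On', 'On')
ternary state: ('On', 'On', 'On', 'On') -> non_opponent_on
channel 0: r = 0.900
channel 1: r = 0.901
channel 2: r = 0.825
channel 3: r = 0.865
```

The planted On kernel is recovered on all four channels (Pearson r
0.83-0.90 against ground truth), every channel clears the 10-SD
inclusion gate by a wide margin, and the ROI is classified as a
non-opponent On cell.

An end-to-end synthetic run (simulate -> kernels -> classify -> maps ->
cluster -> morphology, with a manifest and per-stage outputs):

```sh
chromarg run --seed 1 --out runs/demo
```

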