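# Methods

`chromarg` re-implements, as a tested pipeline, the analysis path from
calcium traces of larval zebrafish retinal ganglion cells (RGCs) recorded
under tetrachromatic binary noise to spectral-temporal functional types
and dendritic morphometrics.  Every stage can be exercised on synthetic
data with known ground truth; this note documents the models, the
defaults, and the choices made where the design was genuinely open.

## Stimulus and kernel model

The noise stimulus is four LEDs (R, G, B, UV) flickered independently in
a binary sequence at 6.4 Hz for 258 s; the frame count is
`floor(duration x rate)` = 1651 and the fractional final frame is
dropped.  The LED state is held between flips (zero-order hold).
"Natural white" photon weights (100/50/13/6%) are carried as metadata
only: reverse correlation operates on the raw binary sequence.

A spectral kernel is the event-triggered average stimulus

    F(l, tau) = (1/M) * sum_i  c'(t_i) * S(l, t_i + tau)

where t_i are calcium event times on a 500 Hz alignment clock and the
weights c'(t_i) are the trace-derivative values at the events.  Kernels
live on a fixed lag grid of 649 samples, dt = 2 ms, starting at
-973.5 ms (matching the deposited-data format, spanning roughly -1000 to
+350 ms).  Each channel is z-scored against the mean and SD of the first
50 ms of lag (the 25 earliest samples); kernel quality is the
peak-to-peak amplitude in those baseline-SD units.

### Estimation chain

1. **Detrend**: high-pass above 0.1 Hz, realised as subtraction of a
   moving-average baseline with window 1/cutoff (no filter design is
   prescribed by the source methods).
2. **Z-normalise** against the 1-6 s window at the start of the
   recording.  A zero-variance window flags the trace degenerate.
3. **Derivative**: forward differences placed at sample midpoints,
   linearly interpolated onto the 500 Hz clock.  Midpoint placement
   keeps transient timing unbiased; central differences would smear
   events by an extra trace frame.
4. **Event detection**: every 500 Hz sample whose derivative exceeds
   0.7 x the baseline-window SD becomes one event weighted by its
   derivative value.  No peak grouping -- the kernel equation weights
   each sample by the steepness of the transient.  The "baseline noise"
   is the derivative SD inside the same 1-6 s window, the only baseline
   the pre-processing defines.
5. **Triggered average** on the lag grid.  Events whose lag window exits
   the stimulus span are dropped (M decremented) rather than
   zero-padded, avoiding biased edges.  For large M the sum is evaluated
   by FFT cross-correlation on a 2 kHz grid that the 500 Hz event clock
   and the 2 ms lag grid both divide exactly; the result is identical
   (to machine precision) to the direct per-event gather, which the
   tests assert.

### Forward model (synthetic ROIs)

The generator inverts this chain: the planted kernels' causal part
drives a rectified linear response to the centred binary stimulus; a
Bernoulli event train is drawn on the 500 Hz clock at rate
`event_rate_scale x max(drive, 0)` (default 0.35, giving roughly
0.5-1 events/s for unit-amplitude templates); events are convolved with
a single-exponential indicator (default decay 0.4 s, a GCaMP6f-like
fixture choice, not a claim about the data); the result is sampled at
15.625 Hz (the 64 ms scan frame) and Gaussian noise (default SD 0.15 in
indicator units) is added.  Under these defaults the full estimation
chain recovers planted kernels with mean Pearson r ~ 0.88 over 200 ROIs
and >= 95% polarity accuracy; the residual error is dominated by the
+-32 ms event-timing jitter of the 15.625 Hz trace sampling, not by the
additive noise.

### A structural note on null-kernel quality

Because the LED state is held between 6.4 Hz flips, two lags 2 ms apart
almost always sample the same stimulus frame: a stimulus-independent
(null) kernel is block-correlated over ~156 ms and contains only ~8
independent values across the 1.3 s lag window.  The 50 ms baseline
window therefore underestimates the kernel-wide SD, and the
peak-to-peak quality of null kernels has median ~16 baseline SDs --
independent of the number of events, of the weight distribution, and of
whether events are detected or drawn uniformly at random.  A null
quality below 10 "in >= 95% of shuffles" would require a stimulus white
at the lag resolution.  The 10-SD inclusion gate still does its job:
responsive synthetic ROIs sit at quality > 100, an order of magnitude
above the null, and the package's tests assert that separation.  The
acceptance script reports the measured null pass fraction rather than
asserting the idealised bound.

## Spectral typing

Polarity follows the kernel's dominant trajectory: maximum before
minimum -> Off, minimum before maximum -> On.  The ternary rule (sign of
the largest transition) is operationalised as the signed difference
between the temporally earlier and later global extremum, which makes
the two stated rules coincide; whether local extrema were intended is
unknowable from the text, so the global reading is used.  Channels with
quality < 10 are "not connected" (NR).  The 3^4 = 81 wiring states are
enumerated exhaustively; opponency counts sign changes along the fixed
wavelength order R -> G -> B -> UV with NR channels skipped (not treated
as zeros): 0 changes -> non-opponent, 1 -> simple opponent with the
flanking channel pair recorded, >1 -> complex opponent.  The base-3
state index (R most significant; NR=0, On=1, Off=2) is an internal
convention.  The spectral centroid is the amplitude-weighted mean of
the positive-frequency Fourier magnitudes of the mean-subtracted
kernel.

## Eye-IPL maps

Eye position (-pi..pi, circular) is split into eight pi/4 bins and the
IPL into 20 depth bins: all somata go to bin 1 regardless of depth in
the GCL, bin 2 is a permanently empty visual barrier, dendrites fill
bins 3-20 by relative depth (depth 0 = GCL border = bin 3; depth 1 =
INL border = bin 20).  Per-bin statistics are arithmetic means (scalars
or time series).  Smoothing uses a binomial (1,2,1)/4 kernel --
circular along the eye axis for all rows, and +-1 depth bin restricted
to bins 3-20 with a reflecting boundary (the published "pi/3 binomial"
and "5% of IPL depth" filters give no taps; (1,2,1)/4 on pi/4-wide bins
has full width pi/2 ~ the stated scale).  Fully finite maps are
smoothed mass-conservingly; maps with missing bins exclude them with
weight renormalisation (the published treatment of empty bins is
unstated).  The On-Off index per bin is (nOn - nOff)/(nOn + nOff).

## Functional clustering

ROIs pass a kernel-quality gate of 5, where clustering quality is the
maximum SD through time across the four colours (a separate, weaker
gate than the 10-SD ternary threshold; channels failing the 10-SD gate
still contribute their kernels here).  Each colour block is divided by
one pooled SD (over time and ROIs), each colour is reduced separately
by mean-centred PCA keeping the fewest components explaining >= 99% of
variance, and the scores are concatenated (R, G, B, UV).  Gaussian
mixtures are swept over k = 1..k_max and four covariance structures
(shared-diagonal, unshared-diagonal, shared-full, unshared-full), 20
replicates per cell seeded k-means++ style (replicate r uses seed
base + r), regularisation 1e-5, max 10^4 EM iterations; the best
log-likelihood per cell is kept and BIC = -2 logL + p ln(n) selects the
model, with p counted per structure.  Ties break toward smaller k, then
toward the structure listed earlier.  scikit-learn provides 'diag',
'tied' and 'full'; shared-diagonal is a constrained M-step (the
responsibility-weighted average of the per-component diagonal
covariances, the exact EM update for that model).  A fixed-k override
mirrors the protocol used when BIC gives no clean answer.  Clusters
below the minimum membership (default 10) are dropped and their ROIs
marked unassigned.

The synthetic cluster fixture plants template kernels with temporally
smooth Gaussian variability (50 ms correlation scale, per-sample SD
0.3).  White noise would be wrong here: it has no low-dimensional
structure, so the >= 99%-variance rule would retain hundreds of
components, whereas real kernel variability is smooth and yields tens
of components per colour -- the regime the published protocol operates
in (8-36 components per colour).  At the synthetic scale (n ~ 300 rows,
d ~ 60 features) full-covariance components are over-parameterised and
their regularised likelihood diverges, so the kernel-route tests sweep
the diagonal structures; the full four-structure sweep is exercised at
feature dimensions where it is well-posed.  k_max defaults to 20 in
tests and the pipeline (the published sweep to 100 is configurable);
problem sizes throughout (200 ROIs, 10 sweep seeds, 140 morphology
clouds) were chosen as the smallest that give stable statistics.

## Morphology

Point clouds are (x, y, z) with y linearly rescaled so the IPL spans
[0, 10] (GCL-side border -> 0, INL-side -> 10; INL/GCL processes fall
outside).  Summaries: y_span (max - min), y_mean, num_pts, and xz_area
(2-D convex hull; fewer than 3 non-collinear points give area 0 rather
than an error).  Clustering standardises (y_span, y_mean, num_pts) with
the n-1 SD convention (the source is silent on the denominator), then
runs agglomerative clustering with city-block distance and average
linkage: stage 1 cuts at 18 clusters; the two largest (by default --
the published choice was by visual inspection, so explicit cluster ids
can be supplied) are re-clustered on y_span alone into 6 and 3
subclusters, giving 25 clusters before the minimum-membership filter
(default 4).  The cophenetic correlation coefficient validates each
tree.

Dendritic tilt is the spherical position (r, theta, phi) of the
dendritic centre of mass (soma excluded) relative to the soma, with the
polar angle theta measured from the +y axis (perpendicular to the
retinal plane; y and z swap roles relative to the textbook convention)
so theta = 0 means no tilt; phi = atan2(z, x) in [0, 2pi), with the
zero direction configurable per dataset since retinotopic orientation
differs between fields.  Group comparisons use the two-sample
Kolmogorov-Smirnov test (asymptotic p) for r and theta, and a
hand-implemented two-sample Kuiper test for the 2pi-periodic phi:
V = max(F_a - F_b) + max(F_b - F_a) over the pooled sample (invariant
to common rotation), p-value from the standard asymptotic series with
effective size n_a n_b / (n_a + n_b) and Stephens' finite-sample
correction.  Monte-Carlo calibration at n = 60/60: null rejection 4-5%
at alpha = 0.05 for both tests; power ~100% against opposite von Mises
modes with kappa = 2.

The cloud generator samples y uniformly over the planted span and x, z
as Gaussians, then recentres so the dendritic CoM sits exactly at the
planted spherical offset; tilt recovery on synthetic clouds is
therefore exact by construction, and the tilt tests probe the
coordinate conventions, not estimator noise.  The generator emulates
stratification depth/width, point count, and tilt; it does not emulate
branch topology, neurite connectivity, or the spatial anisotropy of
real arbors, so passing tests say nothing about segmentation or tracing
quality on real image stacks.

## What the synthetic data does not show

Synthetic runs cannot reproduce dataset-level results of the recorded
population (cluster counts, opponent percentages, regional CCC values):
those depend on the biological type distribution.  The deposited-data
importer validates external tables against the canonical grids (4 x 649
kernels at 2 ms; 2,499-sample chirps at 1 ms) for that purpose.  The
chirp waveform defaults are a configurable stand-in (the published
parameters live in earlier work); nothing in the pipeline depends on
its exact shape.
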