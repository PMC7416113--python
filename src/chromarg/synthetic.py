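"""Synthetic data with known ground truth.

Everything downstream of two-photon acquisition is exercised on data from
this module: tetrachromatic binary noise, planted spectral kernels, a
linear-nonlinear + calcium-indicator forward model, planted functional
cluster structure, chirp trials, and dendritic point clouds with planted
stratification and tilt.  All generators are pure functions of their
configuration and seed.

The forward model is deliberately the inverse of the estimation chain in
:mod:`chromarg.kernels`: a rectified linear drive from the planted kernels
produces a Bernoulli event train on the 500 Hz alignment clock, which is
convolved with a single-exponential indicator (GCaMP6f-like, 0.4 s default
decay -- a fixture choice), sampled at the trace rate, and corrupted with
additive Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import fftconvolve, lfilter

from .core import (
    ALIGN_RATE,
    CHIRP_N,
    CHIRP_RATE,
    LAG_DT,
    LAG_N,
    N_CHANNELS,
    NATURAL_WHITE_WEIGHTS,
    NOISE_DURATION_S,
    NOISE_FRAME_RATE,
    TRACE_RATE,
    FluorescenceTrace,
    Stimulus,
    lag_grid,
)

__all__ = [
    "SimulationConfig",
    "GroundTruthROI",
    "ClusterSpec",
    "ChirpConfig",
    "MorphGenConfig",
    "MorphPointCloud",
    "make_noise_stimulus",
    "make_chirp_stimulus",
    "make_kernel_template",
    "simulate_trace",
    "make_population",
    "make_kernel_population",
    "make_morph_cloud",
]


# ---------------------------------------------------------------------------
# configuration containers


@dataclass(frozen=True)
class SimulationConfig:
    """Forward-model parameters for one synthetic recording.

    ``event_rate_scale`` converts rectified linear drive (dimensionless,
    order one for unit-amplitude templates) into an event rate in
    events/s; the default yields roughly 0.5-1 events/s.
    """

    n_rois: int = 1
    seed: int = 0
    event_rate_scale: float = 0.35
    indicator_decay: float = 0.4
    noise_sd: float = 0.15
    trace_rate: float = TRACE_RATE
    duration: float = NOISE_DURATION_S

    def __post_init__(self) -> None:
        for name in ("n_rois", "event_rate_scale", "indicator_decay",
                     "trace_rate", "duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class GroundTruthROI:
    """Planted parameters for one synthetic ROI."""

    true_kernels: np.ndarray  # 4 x 649 on the canonical lag grid
    eye_position: float = 0.0
    compartment: str = "dendrite"
    ipl_depth: float | None = 0.5
    cluster_label: int = 0

    def __post_init__(self) -> None:
        self.true_kernels = np.asarray(self.true_kernels, dtype=float)
        if self.true_kernels.shape != (N_CHANNELS, LAG_N):
            raise ValueError(f"kernels must be {N_CHANNELS} x {LAG_N}")
        if self.compartment not in ("dendrite", "soma"):
            raise ValueError("compartment must be 'dendrite' or 'soma'")
        if self.compartment == "dendrite" and self.ipl_depth is None:
            raise ValueError("dendritic ROI requires an IPL depth")


@dataclass(frozen=True)
class ClusterSpec:
    """One planted functional cluster: kernel templates plus anatomy.

    ``eye_range`` and ``depth_range`` are uniform sampling intervals;
    ``gain_jitter`` is the SD of a multiplicative log-normal-ish gain
    perturbation applied per ROI (0 disables it).
    """

    kernels: np.ndarray
    proportion: float
    eye_range: tuple[float, float] = (-np.pi, np.pi)
    depth_range: tuple[float, float] = (0.0, 1.0)
    compartment: str = "dendrite"
    gain_jitter: float = 0.1


@dataclass(frozen=True)
class ChirpConfig:
    """Segment layout of the full-field chirp stimulus.

    The published waveform parameters live in earlier work; these defaults
    are a configurable stand-in whose total duration matches the fixed
    2,499 ms response window at 1 kHz.
    """

    baseline_s: float = 0.3
    step_s: float = 0.6
    freq_sweep_s: float = 0.8
    contrast_sweep_s: float = 0.6
    f_start_hz: float = 1.0
    f_end_hz: float = 8.0
    contrast_freq_hz: float = 4.0
    contrast: float = 1.0
    rate: float = CHIRP_RATE
    total_samples: int = CHIRP_N


# ---------------------------------------------------------------------------
# stimuli


def make_noise_stimulus(
    seed: int,
    duration_s: float = NOISE_DURATION_S,
    frame_rate: float = NOISE_FRAME_RATE,
    weights: tuple[float, ...] = NATURAL_WHITE_WEIGHTS,
) -> Stimulus:
    """Independent 4-channel binary noise (i.i.d. Bernoulli(0.5) per frame).

    The fractional final frame is dropped: ``floor(duration * rate)``
    frames (1651 for the default 258 s at 6.4 Hz).
    """
    if duration_s <= 0 or frame_rate <= 0:
        raise ValueError("duration and frame rate must be positive")
    n_frames = int(np.floor(duration_s * frame_rate))
    rng = np.random.default_rng(seed)
    values = rng.integers(0, 2, size=(n_frames, N_CHANNELS), dtype=np.uint8)
    return Stimulus(values=values, frame_rate=frame_rate,
                    channel_weights=tuple(weights))


def make_chirp_stimulus(config: ChirpConfig = ChirpConfig()) -> np.ndarray:
    """Deterministic single-channel chirp luminance waveform in [0, 1].

    Baseline at mid-grey, a full-contrast step, an accelerating frequency
    sweep, and an amplitude (contrast) sweep, padded with mid-grey to
    ``config.total_samples``.
    """
    dt = 1.0 / config.rate
    segs = []
    segs.append(np.full(int(round(config.baseline_s / dt)), 0.5))
    segs.append(np.full(int(round(config.step_s / dt)), 0.5 + 0.5 * config.contrast))
    t = np.arange(int(round(config.freq_sweep_s / dt))) * dt
    if t.size:
        # linear frequency ramp -> quadratic phase
        f0, f1 = config.f_start_hz, config.f_end_hz
        phase = 2 * np.pi * (f0 * t + 0.5 * (f1 - f0) / config.freq_sweep_s * t**2)
        segs.append(0.5 + 0.5 * config.contrast * np.sin(phase))
    t = np.arange(int(round(config.contrast_sweep_s / dt))) * dt
    if t.size:
        env = t / config.contrast_sweep_s
        segs.append(0.5 + 0.5 * config.contrast * env
                    * np.sin(2 * np.pi * config.contrast_freq_hz * t))
    wave = np.concatenate(segs) if segs else np.empty(0)
    n = config.total_samples
    if wave.size >= n:
        return wave[:n]
    return np.concatenate([wave, np.full(n - wave.size, 0.5)])


# ---------------------------------------------------------------------------
# kernel templates


def make_kernel_template(
    polarity: str,
    shape: str = "biphasic",
    time_const: float = 0.12,
    channel_gains: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0),
) -> np.ndarray:
    """Planted 4 x 649 kernel set on the canonical lag grid.

    An ``On`` biphasic template has a positive lobe peaking at
    ``-time_const`` seconds preceded by a weaker negative lobe, so the
    minimum precedes the maximum on the lag axis, matching the timing
    rule used for polarity classification; ``Off`` is its negation.
    Monophasic templates keep only the late lobe.  Smaller ``time_const``
    compresses the waveform and raises its spectral centroid.
    """
    if polarity not in ("On", "Off"):
        raise ValueError("polarity must be 'On' or 'Off'")
    if shape not in ("monophasic", "biphasic"):
        raise ValueError("shape must be 'monophasic' or 'biphasic'")
    gains = np.asarray(channel_gains, dtype=float)
    if gains.shape != (N_CHANNELS,) or (gains < 0).any():
        raise ValueError(f"channel_gains must be {N_CHANNELS} non-negative values")
    if time_const <= 0:
        raise ValueError("time_const must be positive")

    tau = lag_grid()
    main = np.exp(-0.5 * ((tau + time_const) / (0.45 * time_const)) ** 2)
    wave = main.copy()
    if shape == "biphasic":
        trough = np.exp(-0.5 * ((tau + 2.4 * time_const) / (0.7 * time_const)) ** 2)
        wave = main - 0.55 * trough
    wave[tau >= 0] = 0.0  # causal: stimulus only before the event
    if wave.max() > 0:
        wave = wave / np.abs(wave).max()
    # snap the numerically dead tail to exact zero so the flat region
    # ties at 0 and extrema ordering encodes the declared polarity
    wave[np.abs(wave) < 1e-9] = 0.0
    if polarity == "Off":
        wave = -wave
    return gains[:, None] * wave[None, :]


# ---------------------------------------------------------------------------
# forward model


def _drive_500hz(kernels: np.ndarray, stim: Stimulus, n500: int) -> np.ndarray:
    """Rectifiable linear drive of planted kernels on the 500 Hz clock."""
    t500 = np.arange(n500) / ALIGN_RATE
    s = stim.state_at(t500).astype(float) - 0.5
    tau = lag_grid()
    past = tau < 0
    drive = np.zeros(n500)
    for c in range(N_CHANNELS):
        # filter taps indexed by time-into-the-past u = -tau
        taps = kernels[c, past][::-1]
        drive += fftconvolve(s[:, c], taps, mode="full")[: n500]
    return drive


def simulate_trace(
    truth: GroundTruthROI,
    stim: Stimulus,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    return_events: bool = False,
):
    """Simulate one fluorescence trace from planted kernels.

    Rectified linear drive -> Bernoulli event train on the 500 Hz clock ->
    exponential indicator convolution -> sampling at ``cfg.trace_rate`` ->
    additive Gaussian noise.  With ``return_events`` the ground-truth
    event times (seconds) are returned alongside the trace.
    """
    duration = min(cfg.duration, stim.duration)
    if duration <= 0:
        raise ValueError("stimulus and simulation spans do not overlap")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    dt = 1.0 / ALIGN_RATE
    n500 = int(np.floor(duration * ALIGN_RATE))
    drive = _drive_500hz(truth.true_kernels, stim, n500)
    rate = cfg.event_rate_scale * np.clip(drive, 0.0, None)
    p = np.clip(rate * dt, 0.0, 1.0)
    events = rng.random(n500) < p

    # single-exponential indicator as a first-order IIR filter
    decay = np.exp(-dt / cfg.indicator_decay)
    calcium = lfilter([1.0], [1.0, -decay], events.astype(float))
    n_trace = int(np.floor(duration * cfg.trace_rate))
    idx = np.floor(np.arange(n_trace) / cfg.trace_rate * ALIGN_RATE).astype(int)
    samples = calcium[idx]
    if cfg.noise_sd > 0:
        samples = samples + rng.normal(0.0, cfg.noise_sd, n_trace)
    trace = FluorescenceTrace(samples=samples, rate=cfg.trace_rate)
    if return_events:
        return trace, np.flatnonzero(events) * dt
    return trace


def make_population(
    cfg: SimulationConfig,
    cluster_spec: list[ClusterSpec],
    stim: Stimulus | None = None,
) -> list[tuple[GroundTruthROI, FluorescenceTrace]]:
    """Planted-cluster population of (ground truth, trace) pairs.

    Cluster labels follow the spec proportions (multinomial draw); each
    ROI's kernels are its cluster template with an optional per-ROI gain
    jitter; anatomy is sampled uniformly from the cluster's ranges.
    """
    props = np.array([c.proportion for c in cluster_spec], dtype=float)
    if not np.isclose(props.sum(), 1.0, atol=1e-8):
        raise ValueError("cluster proportions must sum to 1")
    rng = np.random.default_rng(cfg.seed)
    if stim is None:
        stim = make_noise_stimulus(seed=int(rng.integers(2**31)),
                                   duration_s=cfg.duration)
    labels = rng.choice(len(cluster_spec), size=cfg.n_rois, p=props)
    out = []
    for lab in labels:
        spec = cluster_spec[lab]
        gain = 1.0
        if spec.gain_jitter > 0:
            gain = float(np.exp(rng.normal(0.0, spec.gain_jitter)))
        kernels = gain * np.asarray(spec.kernels, dtype=float)
        depth = None
        if spec.compartment == "dendrite":
            depth = float(rng.uniform(*spec.depth_range))
        truth = GroundTruthROI(
            true_kernels=kernels,
            eye_position=float(rng.uniform(*spec.eye_range)),
            compartment=spec.compartment,
            ipl_depth=depth,
            cluster_label=int(lab),
        )
        trace = simulate_trace(truth, stim, cfg, rng=rng)
        out.append((truth, trace))
    return out


def make_kernel_population(
    seed: int,
    templates: list[np.ndarray],
    proportions: list[float],
    n_rois: int,
    noise_sd: float = 0.3,
    noise_scale_s: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Planted kernel sets (n x 4 x 649) with smooth Gaussian variability.

    A lighter fixture than the full forward model, for exercising the
    feature-extraction and mixture-model stages directly on kernels with
    known cluster labels.  Per-ROI perturbations are temporally
    correlated (Gaussian process with ``noise_scale_s`` correlation
    scale, per-sample SD ``noise_sd``), emulating the smooth waveform
    variability of real kernel estimates rather than white noise.
    """
    props = np.asarray(proportions, dtype=float)
    if not np.isclose(props.sum(), 1.0, atol=1e-8):
        raise ValueError("proportions must sum to 1")
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(templates), size=n_rois, p=props)
    kernels = np.stack([np.asarray(templates[v], dtype=float) for v in labels])
    if noise_sd > 0:
        sigma = noise_scale_s / LAG_DT
        white = rng.normal(0.0, 1.0, kernels.shape)
        smooth = gaussian_filter1d(white, sigma=sigma, axis=-1,
                                   mode="constant")
        # restore unit per-sample SD, then scale to noise_sd
        impulse = np.zeros(LAG_N)
        impulse[LAG_N // 2] = 1.0
        taps = gaussian_filter1d(impulse, sigma=sigma, mode="constant")
        kernels += smooth * (noise_sd / np.linalg.norm(taps))
    return kernels, labels


# ---------------------------------------------------------------------------
# morphology


@dataclass(frozen=True)
class MorphGenConfig:
    """Planted dendritic point-cloud parameters.

    ``y`` is in IPL-scaled units (IPL spans [0, 10]); ``x`` and ``z`` in
    micrometres.  The tilt offset (``tilt_r``, ``tilt_theta``,
    ``tilt_phi``) is the soma-centred spherical position of the dendritic
    centre of mass, with the polar angle measured from the +y axis.
    ``y_mean +- y_span/2`` may exceed [0, 10]: processes entering the INL
    or GCL are legitimate.
    """

    n_points: int = 200
    y_mean: float = 5.0
    y_span: float = 2.0
    tilt_r: float = 6.0
    tilt_theta: float = 0.3
    tilt_phi: float = 1.0
    xz_spread: float = 10.0
    seed: int = 0


@dataclass
class MorphPointCloud:
    """Soma coordinate plus dendritic points; soma excluded from statistics."""

    soma: np.ndarray
    points: np.ndarray
    region: str | None = None

    def __post_init__(self) -> None:
        self.soma = np.asarray(self.soma, dtype=float).reshape(3)
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 1 or self.points.shape[1] != 3:
            raise ValueError("points must be N x 3 with N >= 1")


def spherical_to_cartesian(r: float, theta: float, phi: float) -> np.ndarray:
    """Soma-centred spherical -> Cartesian with the polar axis along +y."""
    return np.array([
        r * np.sin(theta) * np.cos(phi),
        r * np.cos(theta),
        r * np.sin(theta) * np.sin(phi),
    ])


def make_morph_cloud(cfg: MorphGenConfig, region: str | None = None) -> MorphPointCloud:
    """Generate a dendritic point cloud with planted stratification and tilt.

    Points are recentred after sampling so the dendritic centre of mass
    sits exactly at ``(0, y_mean, 0) + offset(tilt)`` relative to the
    derived soma position; the y extent approximates ``y_span`` (uniform
    stratification profile) and xz scatter is Gaussian with SD
    ``xz_spread``.
    """
    if cfg.n_points < 1:
        raise ValueError("n_points must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    pts = np.column_stack([
        rng.normal(0.0, cfg.xz_spread, cfg.n_points),
        rng.uniform(-cfg.y_span / 2, cfg.y_span / 2, cfg.n_points),
        rng.normal(0.0, cfg.xz_spread, cfg.n_points),
    ])
    pts -= pts.mean(axis=0)  # exact centre of mass
    center = np.array([0.0, cfg.y_mean, 0.0])
    offset = spherical_to_cartesian(cfg.tilt_r, cfg.tilt_theta, cfg.tilt_phi)
    soma = center - offset
    return MorphPointCloud(soma=soma, points=pts + center, region=region)
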