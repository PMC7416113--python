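"""Canonical grids, channel conventions, and shared containers.

All kernel-domain code in the package operates on a single fixed lag grid:
649 samples spaced 2 ms apart, starting at -973.5 ms relative to the calcium
event.  Negative lags index stimulus history before the event; the short
positive tail absorbs indicator-induced spread.  Event detection and
stimulus alignment run on a 500 Hz clock, whose 2 ms tick equals the lag
grid spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Spectral channel order, decreasing wavelength.
CHANNELS: tuple[str, ...] = ("R", "G", "B", "UV")
N_CHANNELS = 4

#: Relative photon weights of the four LEDs under "natural white".
NATURAL_WHITE_WEIGHTS: tuple[float, ...] = (1.0, 0.50, 0.13, 0.06)

#: Lag grid: 649 points, dt = 2 ms, starting at -973.5 ms.
LAG_N = 649
LAG_DT = 0.002
LAG_START = -0.9735

#: Stimulus-alignment clock for event detection and triggered averaging.
ALIGN_RATE = 500.0

#: Chirp responses are resampled to this fixed length at 1 kHz.
CHIRP_N = 2499
CHIRP_RATE = 1000.0

#: Default noise-stimulus parameters: binary flicker at 6.4 Hz for 258 s.
NOISE_FRAME_RATE = 6.4
NOISE_DURATION_S = 258.0

#: Default trace sampling rate (64 ms scan frame).
TRACE_RATE = 15.625


def lag_grid() -> np.ndarray:
    """Return the canonical 649-point lag axis in seconds."""
    return LAG_START + LAG_DT * np.arange(LAG_N)


@dataclass(frozen=True)
class Stimulus:
    """Tetrachromatic binary noise stimulus.

    ``values`` is a frames x 4 matrix of per-channel on/off states; the
    LED state persists between frame updates (zero-order hold).  Channel
    weights are carried as metadata only -- reverse correlation operates
    on the raw binary sequence.
    """

    values: np.ndarray
    frame_rate: float
    channel_weights: tuple[float, ...] = NATURAL_WHITE_WEIGHTS
    channel_order: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[1] != N_CHANNELS:
            raise ValueError(f"stimulus must be frames x {N_CHANNELS}")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("stimulus entries must be binary")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if any(w <= 0 for w in self.channel_weights):
            raise ValueError("channel weights must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    def state_at(self, times: np.ndarray) -> np.ndarray:
        """Binary LED state at arbitrary instants (zero-order hold)."""
        idx = np.floor(np.asarray(times) * self.frame_rate).astype(int)
        if (idx < 0).any() or (idx >= self.n_frames).any():
            raise ValueError("query times outside stimulus span")
        return self.values[idx]


@dataclass
class FluorescenceTrace:
    """A single ROI's fluorescence over time.

    The first seconds of each recording, ``baseline_window`` (default
    1-6 s), anchor z-normalisation and the derivative noise estimate.
    """

    samples: np.ndarray
    rate: float
    baseline_window: tuple[float, float] = (1.0, 6.0)
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.rate


@dataclass
class ROIRecord:
    """One ROI's trace plus anatomical metadata.

    ``compartment`` is ``"dendrite"`` or ``"soma"``; dendrites carry an
    IPL depth in [0, 1] (0 = GCL border, 1 = INL border), somata do not.
    Eye position is an angle in [-pi, pi).
    """

    roi_id: int
    trace: FluorescenceTrace | None
    compartment: str
    eye_position: float
    ipl_depth: float | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.compartment not in ("dendrite", "soma"):
            raise ValueError("compartment must be 'dendrite' or 'soma'")
        if self.compartment == "dendrite" and self.ipl_depth is None:
            raise ValueError("dendritic ROI requires an IPL depth")
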