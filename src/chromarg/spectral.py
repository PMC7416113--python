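"""Polarity, ternary wiring states, chromatic opponency, OOi, centroid.

A kernel's polarity follows its dominant trajectory in time: if the
minimum precedes the maximum on the lag axis the kernel is On, and Off
vice versa.  Each ROI's four kernels map onto a ternary wiring state over
{On, Off, not-connected} per cone channel -- 3^4 = 81 combinations -- and
states are classified as non-opponent, simple opponent (one spectral zero
crossing along R -> G -> B -> UV) or complex opponent (more than one).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .core import CHANNELS, LAG_DT, N_CHANNELS

__all__ = [
    "TernaryState",
    "OpponencyLabel",
    "OOIndex",
    "classify_polarity",
    "ternary_state",
    "state_from_index",
    "opponency_class",
    "enumerate_wiring_space",
    "ooi",
    "spectral_centroid",
]

#: Ternary quality gate: channels below 10 baseline SDs peak-to-peak are
#: treated as not connected.
TERNARY_THRESHOLD = 10.0

_STATE_DIGIT = {"NR": 0, "On": 1, "Off": 2}
_DIGIT_STATE = {v: k for k, v in _STATE_DIGIT.items()}


@dataclass(frozen=True)
class TernaryState:
    """Per-channel wiring over {On, Off, NR} with its base-3 index.

    The index encodes (R, G, B, UV) as base-3 digits (R most significant)
    with NR=0, On=1, Off=2 -- an internal convention that makes the
    tuple <-> index map a bijection over 0..80.
    """

    state: tuple[str, str, str, str]

    def __post_init__(self) -> None:
        if len(self.state) != N_CHANNELS or any(
                s not in _STATE_DIGIT for s in self.state):
            raise ValueError("state must be a 4-tuple over {'On','Off','NR'}")

    @property
    def index(self) -> int:
        idx = 0
        for s in self.state:
            idx = idx * 3 + _STATE_DIGIT[s]
        return idx


def state_from_index(index: int) -> TernaryState:
    """Inverse of :attr:`TernaryState.index`."""
    if not 0 <= index < 3**N_CHANNELS:
        raise ValueError("index must be in 0..80")
    digits = []
    for _ in range(N_CHANNELS):
        digits.append(_DIGIT_STATE[index % 3])
        index //= 3
    return TernaryState(state=tuple(reversed(digits)))


@dataclass(frozen=True)
class OpponencyLabel:
    """Opponency category of a ternary state.

    ``crossing_pair`` names the two responsive channels flanking the
    single zero crossing (simple opponency only).
    """

    category: str
    n_sign_changes: int
    crossing_pair: tuple[str, str] | None = None


@dataclass(frozen=True)
class OOIndex:
    """On-Off index (nOn - nOff) / (nOn + nOff) of a set of kernels."""

    value: float
    n_on: int
    n_off: int

    @property
    def defined(self) -> bool:
        return self.n_on + self.n_off > 0


# ---------------------------------------------------------------------------


def classify_polarity(kernel: np.ndarray) -> str:
    """On/Off by timing of the global extrema on the lag axis.

    Maximum before minimum -> Off; minimum before maximum -> On.
    """
    kernel = np.asarray(kernel, dtype=float)
    imax = int(np.argmax(kernel))
    imin = int(np.argmin(kernel))
    if imax == imin:
        raise ValueError("constant kernel has no polarity")
    return "Off" if imax < imin else "On"


def ternary_state(kernel_set, threshold: float = TERNARY_THRESHOLD) -> TernaryState:
    """Ternary wiring state of a kernel set.

    Channels with peak-to-peak quality below ``threshold`` (10 baseline
    SDs) are not connected (NR); the rest are labelled by the sign of the
    largest transition in the kernel -- the signed difference between the
    temporally earlier and later global extremum, which coincides with
    the timing rule of :func:`classify_polarity`.
    """
    state = []
    for c in range(N_CHANNELS):
        q = kernel_set.quality[c]
        if q < threshold or q == 0:
            state.append("NR")
        else:
            state.append(classify_polarity(kernel_set.kernels[c]))
    return TernaryState(state=tuple(state))


def opponency_class(state: TernaryState) -> OpponencyLabel:
    """Categorise a wiring state by its spectral zero crossings.

    NR channels are skipped; sign changes are counted along the fixed
    wavelength order R -> G -> B -> UV.  Zero responsive channels ->
    ``none_connected``; zero crossings -> non-opponent On or Off; one ->
    simple opponent with the flanking channel pair; more -> complex.
    """
    responsive = [(CHANNELS[i], s) for i, s in enumerate(state.state)
                  if s != "NR"]
    if not responsive:
        return OpponencyLabel(category="none_connected", n_sign_changes=0)
    signs = [1 if s == "On" else -1 for _, s in responsive]
    changes = [i for i in range(len(signs) - 1) if signs[i] != signs[i + 1]]
    n = len(changes)
    if n == 0:
        cat = "non_opponent_on" if signs[0] > 0 else "non_opponent_off"
        return OpponencyLabel(category=cat, n_sign_changes=0)
    if n == 1:
        i = changes[0]
        pair = (responsive[i][0], responsive[i + 1][0])
        return OpponencyLabel(category="simple_opponent", n_sign_changes=1,
                              crossing_pair=pair)
    return OpponencyLabel(category="complex_opponent", n_sign_changes=n)


def enumerate_wiring_space() -> pd.DataFrame:
    """Exhaustive table of all 3^4 = 81 wiring states with opponency labels."""
    rows = []
    for combo in product(("NR", "On", "Off"), repeat=N_CHANNELS):
        st = TernaryState(state=combo)
        lab = opponency_class(st)
        rows.append({
            "index": st.index,
            **{ch: s for ch, s in zip(CHANNELS, combo)},
            "category": lab.category,
            "n_sign_changes": lab.n_sign_changes,
            "crossing_pair": "/".join(lab.crossing_pair)
            if lab.crossing_pair else "",
            "opponent": lab.category in ("simple_opponent",
                                         "complex_opponent"),
        })
    return pd.DataFrame(rows).sort_values("index").reset_index(drop=True)


def ooi(n_on: int, n_off: int) -> OOIndex:
    """On-Off index (nOn - nOff) / (nOn + nOff); NaN when both are zero."""
    if n_on < 0 or n_off < 0:
        raise ValueError("counts must be non-negative")
    if n_on + n_off == 0:
        return OOIndex(value=float("nan"), n_on=0, n_off=0)
    return OOIndex(value=(n_on - n_off) / (n_on + n_off),
                   n_on=n_on, n_off=n_off)


def spectral_centroid(kernel: np.ndarray, dt: float = LAG_DT) -> float:
    """Central frequency: amplitude-weighted mean of the Fourier magnitude
    spectrum of the mean-subtracted kernel, over positive frequencies.

    Returns NaN for a zero spectrum (flat kernel).
    """
    kernel = np.asarray(kernel, dtype=float)
    x = kernel - kernel.mean()
    amp = np.abs(np.fft.rfft(x))[1:]
    freq = np.fft.rfftfreq(x.size, d=dt)[1:]
    total = amp.sum()
    if total == 0:
        return float("nan")
    return float((freq * amp).sum() / total)
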