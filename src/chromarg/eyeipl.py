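"""Eye-IPL maps: 8 eye-position bins x 20 depth bins.

Eye position (-pi..pi, circular) is divided into eight pi/4 bins.  Depth
bins are 1-based: somata all go to bin 1 regardless of their depth in the
GCL, bin 2 is a permanently empty visual barrier between GCL and IPL, and
dendritic ROIs are spread over bins 3-20 by their relative IPL depth.
Maps are smoothed with a binomial (1,2,1)/4 filter: circularly along the
eye axis, and across +-1 depth bin restricted to the dendritic bins 3-20.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral import ooi

__all__ = ["EyeIPLMap", "bin_roi", "aggregate_map", "smooth_map", "ooi_map"]

N_EYE_BINS = 8
N_DEPTH_BINS = 20
SOMA_BIN = 1
BARRIER_BIN = 2
FIRST_DENDRITE_BIN = 3

_TAPS = np.array([1.0, 2.0, 1.0]) / 4.0


@dataclass
class EyeIPLMap:
    """Binned grid of a per-ROI statistic.

    ``grid`` is 8 x 20 (or 8 x 20 x T for time-resolved statistics) with
    NaN marking empty bins; ``counts`` holds the number of contributing
    ROIs per bin.  Depth axis index d corresponds to depth bin d+1.
    """

    grid: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.grid.shape[:2] != (N_EYE_BINS, N_DEPTH_BINS):
            raise ValueError(
                f"grid must be {N_EYE_BINS} x {N_DEPTH_BINS} [x T]")
        if self.counts.shape != (N_EYE_BINS, N_DEPTH_BINS):
            raise ValueError("counts must match the spatial grid")


def bin_roi(eye_position: float, ipl_depth: float | None,
            compartment: str) -> tuple[int, int]:
    """Map one ROI to (eye_bin 0..7, depth_bin 1..20).

    eye_bin = floor((theta + pi) / (pi/4)) mod 8.  Somata -> depth bin 1;
    dendrites at relative depth d -> bin 3 + floor(18 d), clamped to 20.
    """
    if not np.isfinite(eye_position):
        raise ValueError("eye position must be finite")
    eye_bin = int(np.floor((eye_position + np.pi) / (np.pi / 4))) % N_EYE_BINS
    if compartment == "soma":
        return eye_bin, SOMA_BIN
    if compartment != "dendrite":
        raise ValueError("compartment must be 'dendrite' or 'soma'")
    if ipl_depth is None or not 0.0 <= ipl_depth <= 1.0:
        raise ValueError("dendritic ROI requires ipl_depth in [0, 1]")
    depth_bin = FIRST_DENDRITE_BIN + int(np.floor(ipl_depth * 18))
    return eye_bin, min(depth_bin, N_DEPTH_BINS)


def aggregate_map(rois, value_extractor) -> EyeIPLMap:
    """Arithmetic per-bin mean of ``value_extractor(roi)`` over ROIs.

    Values may be scalars or equal-length 1-D arrays (time-resolved maps).
    Empty bins are NaN.  ROIs must expose ``eye_position``, ``ipl_depth``
    and ``compartment`` attributes.
    """
    rois = list(rois)
    values = [np.asarray(value_extractor(r), dtype=float) for r in rois]
    extra = values[0].shape if values else ()
    if any(v.shape != extra for v in values):
        raise ValueError("all extracted values must share a shape")
    acc = np.zeros((N_EYE_BINS, N_DEPTH_BINS) + extra)
    counts = np.zeros((N_EYE_BINS, N_DEPTH_BINS), dtype=int)
    for roi, val in zip(rois, values):
        e, d = bin_roi(roi.eye_position, roi.ipl_depth, roi.compartment)
        acc[e, d - 1] += val
        counts[e, d - 1] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        grid = acc / np.where(counts == 0, np.nan,
                              counts)[..., *([None] * len(extra))]
    return EyeIPLMap(grid=grid, counts=counts)


def _smooth_axis(grid: np.ndarray, axis: int, circular: bool) -> np.ndarray:
    """NaN-aware (1,2,1)/4 smoothing along one axis.

    Fully finite input uses a plain convolution (exactly mass
    conserving); otherwise missing bins are excluded with weight
    renormalisation.  Non-circular axes reflect at the boundary.
    """
    g = np.moveaxis(grid, axis, 0)
    n = g.shape[0]
    if circular:
        idx = [(np.arange(n) - 1) % n, np.arange(n), (np.arange(n) + 1) % n]
    else:
        idx = [np.clip(np.arange(n) - 1, 0, n - 1), np.arange(n),
               np.clip(np.arange(n) + 1, 0, n - 1)]
        # reflect: the out-of-range neighbour folds back onto the edge bin
    finite = np.isfinite(g)
    if finite.all():
        out = sum(w * g[i] for w, i in zip(_TAPS, idx))
    else:
        filled = np.where(finite, g, 0.0)
        num = sum(w * filled[i] for w, i in zip(_TAPS, idx))
        den = sum(w * finite[i] for w, i in zip(_TAPS, idx))
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(den > 0, num / den, np.nan)
    return np.moveaxis(out, 0, axis)


def smooth_map(m: EyeIPLMap) -> EyeIPLMap:
    """Binomial smoothing: circular along eye, +-1 bin within depth 3-20.

    The soma bin (1) and the barrier bin (2) are untouched by depth
    smoothing and receive no mass from the dendritic bins.
    """
    grid = m.grid.copy()
    grid = _smooth_axis(grid, axis=0, circular=True)
    dend = slice(FIRST_DENDRITE_BIN - 1, N_DEPTH_BINS)
    grid[:, dend] = _smooth_axis(grid[:, dend], axis=1, circular=False)
    return EyeIPLMap(grid=grid, counts=m.counts.copy())


def ooi_map(entries) -> EyeIPLMap:
    """Per-bin On-Off index.

    ``entries`` iterates over ROIs exposing ``eye_position``,
    ``ipl_depth``, ``compartment`` and ``polarities`` (an iterable of
    'On'/'Off'/'NR' labels, one per responsive kernel).  Bins with no
    responsive kernel are NaN.
    """
    n_on = np.zeros((N_EYE_BINS, N_DEPTH_BINS), dtype=int)
    n_off = np.zeros_like(n_on)
    counts = np.zeros_like(n_on)
    for roi in entries:
        e, d = bin_roi(roi.eye_position, roi.ipl_depth, roi.compartment)
        pols = roi.polarities
        if isinstance(pols, str):
            pols = [pols]
        counts[e, d - 1] += 1
        for p in pols:
            if p == "On":
                n_on[e, d - 1] += 1
            elif p == "Off":
                n_off[e, d - 1] += 1
    grid = np.full((N_EYE_BINS, N_DEPTH_BINS), np.nan)
    for e in range(N_EYE_BINS):
        for d in range(N_DEPTH_BINS):
            idx = ooi(n_on[e, d], n_off[e, d])
            if idx.defined:
                grid[e, d] = idx.value
    return EyeIPLMap(grid=grid, counts=counts)
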