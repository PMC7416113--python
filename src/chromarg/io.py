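"""File formats: HDF5 for stimuli/traces/kernels, CSV for tables and
point clouds, SWC import for external morphologies."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import CHANNELS, FluorescenceTrace, ROIRecord, Stimulus, lag_grid
from .kernels import SpectralKernelSet
from .synthetic import MorphPointCloud

__all__ = [
    "save_stimulus", "load_stimulus",
    "save_traces", "load_traces",
    "save_kernels", "load_kernels", "kernels_to_csv",
    "save_point_cloud", "load_point_cloud", "load_swc",
]


def save_stimulus(path, stim: Stimulus) -> None:
    with h5py.File(path, "a") as f:
        if "stimulus" in f:
            del f["stimulus"]
        g = f.create_group("stimulus")
        g.create_dataset("values", data=stim.values, dtype="u1")
        g.attrs["frame_rate"] = stim.frame_rate
        g.attrs["channel_weights"] = list(stim.channel_weights)
        g.attrs["channel_order"] = list(stim.channel_order)


def load_stimulus(path) -> Stimulus:
    with h5py.File(path, "r") as f:
        g = f["stimulus"]
        return Stimulus(
            values=g["values"][()],
            frame_rate=float(g.attrs["frame_rate"]),
            channel_weights=tuple(g.attrs["channel_weights"]),
            channel_order=tuple(str(c) for c in g.attrs["channel_order"]),
        )


def save_traces(path, rois: list[ROIRecord]) -> None:
    with h5py.File(path, "a") as f:
        if "roi" in f:
            del f["roi"]
        g = f.create_group("roi")
        for roi in rois:
            gr = g.create_group(str(roi.roi_id))
            gr.create_dataset("trace", data=roi.trace.samples)
            gr.attrs["rate"] = roi.trace.rate
            gr.attrs["compartment"] = roi.compartment
            gr.attrs["eye_position"] = roi.eye_position
            gr.attrs["ipl_depth"] = (np.nan if roi.ipl_depth is None
                                     else roi.ipl_depth)


def load_traces(path) -> list[ROIRecord]:
    out = []
    with h5py.File(path, "r") as f:
        for key in sorted(f["roi"], key=int):
            gr = f["roi"][key]
            depth = float(gr.attrs["ipl_depth"])
            comp = str(gr.attrs["compartment"])
            out.append(ROIRecord(
                roi_id=int(key),
                trace=FluorescenceTrace(samples=gr["trace"][()],
                                        rate=float(gr.attrs["rate"])),
                compartment=comp,
                eye_position=float(gr.attrs["eye_position"]),
                ipl_depth=None if np.isnan(depth) else depth,
            ))
    return out


def save_kernels(path, kernel_sets: dict[int, SpectralKernelSet]) -> None:
    with h5py.File(path, "a") as f:
        if "kernels" in f:
            del f["kernels"]
        g = f.create_group("kernels")
        for roi_id, ks in kernel_sets.items():
            gr = g.create_group(str(roi_id))
            gr.create_dataset("values", data=ks.kernels)
            gr.create_dataset("quality", data=ks.quality)
            gr.attrs["polarity"] = list(ks.polarity)
            gr.attrs["n_events"] = ks.n_events


def load_kernels(path) -> dict[int, SpectralKernelSet]:
    out = {}
    with h5py.File(path, "r") as f:
        for key in sorted(f["kernels"], key=int):
            gr = f["kernels"][key]
            out[int(key)] = SpectralKernelSet(
                kernels=gr["values"][()],
                quality=gr["quality"][()],
                polarity=tuple(str(p) for p in gr.attrs["polarity"]),
                n_events=int(gr.attrs["n_events"]),
            )
    return out


def kernels_to_csv(path, kernel_sets: dict[int, SpectralKernelSet]) -> None:
    """Tidy long-format kernel export (roi_id, channel, lag_s, value)."""
    lag = lag_grid()
    rows = []
    for roi_id, ks in kernel_sets.items():
        for c, ch in enumerate(CHANNELS):
            rows.append(pd.DataFrame({
                "roi_id": roi_id, "channel": ch, "lag_s": lag,
                "value": ks.kernels[c]}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def save_point_cloud(path, cloud: MorphPointCloud) -> None:
    n = cloud.points.shape[0]
    df = pd.DataFrame({
        "point_id": np.arange(n + 1),
        "x_um": np.concatenate([[cloud.soma[0]], cloud.points[:, 0]]),
        "y_um": np.concatenate([[cloud.soma[1]], cloud.points[:, 1]]),
        "z_um": np.concatenate([[cloud.soma[2]], cloud.points[:, 2]]),
        "is_soma": [1] + [0] * n,
    })
    if cloud.region is not None:
        df["region"] = cloud.region
    df.to_csv(path, index=False)


def load_point_cloud(path) -> MorphPointCloud:
    df = pd.read_csv(path)
    soma = df[df["is_soma"] == 1]
    dend = df[df["is_soma"] == 0]
    if len(soma) != 1:
        raise ValueError("point cloud must contain exactly one soma row")
    region = None
    if "region" in df.columns and df["region"].notna().any():
        region = str(df["region"].iloc[0])
    return MorphPointCloud(
        soma=soma[["x_um", "y_um", "z_um"]].to_numpy()[0],
        points=dend[["x_um", "y_um", "z_um"]].to_numpy(),
        region=region,
    )


def load_swc(path) -> MorphPointCloud:
    """Import an SWC morphology as a point cloud.

    Node type 1 marks the soma (first such node used); every other node
    becomes a dendritic point.  Radii and topology are ignored beyond
    the soma/dendrite distinction.
    """
    soma = None
    pts = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 7:
            raise ValueError(f"malformed SWC line: {line!r}")
        ntype = int(fields[1])
        xyz = [float(fields[2]), float(fields[3]), float(fields[4])]
        if ntype == 1 and soma is None:
            soma = xyz
        else:
            pts.append(xyz)
    if soma is None:
        raise ValueError("SWC file has no soma (type 1) node")
    if not pts:
        raise ValueError("SWC file has no dendritic nodes")
    return MorphPointCloud(soma=np.array(soma), points=np.array(pts))
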