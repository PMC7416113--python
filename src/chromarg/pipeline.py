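"""End-to-end orchestration: simulate -> kernels -> classify -> maps ->
cluster -> report.

A single :class:`PipelineConfig` (YAML- or dict-backed, strictly
validated) carries every stage's parameters and the one seed from which
all randomness flows; a run directory receives each stage's artefacts
plus a manifest echoing the resolved configuration, so identical configs
give bit-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .cluster import (finalize_clusters, gmm_sweep, pca_per_color, qc_filter,
                      scale_per_color, select_model)
from .core import CHANNELS, ROIRecord
from .eyeipl import ooi_map
from .kernels import NoEventsError, estimate_kernels
from .morphology import compute_tilt, summary_table, two_stage_cluster
from .spectral import opponency_class, spectral_centroid, ternary_state
from .synthetic import (ClusterSpec, MorphGenConfig, SimulationConfig,
                        make_kernel_template, make_morph_cloud,
                        make_noise_stimulus, make_population)

__all__ = ["PipelineConfig", "run_pipeline", "import_deposited"]

STAGES = ("simulate", "kernels", "classify", "maps",
          "cluster_functional", "cluster_morph")


@dataclass
class PipelineConfig:
    """Resolved parameters for a full synthetic run."""

    seed: int = 1
    n_rois: int = 200
    n_clouds: int = 50
    dataset: str = "PR-IPL"
    noise_sd: float = 0.15
    event_rate_scale: float = 0.35
    threshold_sd: float = 0.7          # event detection
    ternary_threshold: float = 10.0    # per-channel inclusion gate
    qc_threshold: float = 5.0          # clustering quality gate
    k_max: int = 20
    replicates: int = 20
    min_members: int = 10
    cluster_mode: str = "bic"
    fixed_k: int | None = None
    stage1_k: int = 18
    morph_min_members: int = 4

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _default_cluster_spec() -> list[ClusterSpec]:
    """Three planted functional types spanning polarity and tempo."""
    return [
        ClusterSpec(kernels=make_kernel_template(
            "On", "biphasic", 0.12, (1.0, 0.8, 0.2, 0.3)), proportion=0.4),
        ClusterSpec(kernels=make_kernel_template(
            "Off", "biphasic", 0.16, (0.9, 0.9, 0.5, 0.2)), proportion=0.35),
        ClusterSpec(kernels=make_kernel_template(
            "On", "monophasic", 0.08, (0.3, 0.4, 0.3, 1.0)), proportion=0.25),
    ]


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Execute all stages into ``outdir``; returns the run directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}}
    counts: dict = {}

    # --- simulate -------------------------------------------------------
    stim = make_noise_stimulus(seed=config.seed)
    sim_cfg = SimulationConfig(n_rois=config.n_rois, seed=config.seed,
                               noise_sd=config.noise_sd,
                               event_rate_scale=config.event_rate_scale)
    population = make_population(sim_cfg, _default_cluster_spec(), stim=stim)
    rois = [ROIRecord(roi_id=i, trace=tr, compartment=gt.compartment,
                      eye_position=gt.eye_position, ipl_depth=gt.ipl_depth,
                      extras={"cluster_label": gt.cluster_label})
            for i, (gt, tr) in enumerate(population)]
    rng = np.random.default_rng(config.seed + 77_003)
    clouds = [make_morph_cloud(MorphGenConfig(
        n_points=int(rng.integers(100, 400)),
        y_mean=float(rng.uniform(1, 9)),
        y_span=float(rng.uniform(0.5, 4.0)),
        tilt_r=float(rng.uniform(2, 10)),
        tilt_theta=float(rng.uniform(0, np.pi / 2)),
        tilt_phi=float(rng.uniform(0, 2 * np.pi)),
        seed=int(rng.integers(2**31))),
        region="SZ" if i < config.n_clouds // 2 else "N")
        for i in range(config.n_clouds)]
    stim_path = out / "stimulus.h5"
    traces_path = out / "traces.h5"
    stim_path.unlink(missing_ok=True)
    traces_path.unlink(missing_ok=True)
    cio.save_stimulus(stim_path, stim)
    cio.save_traces(traces_path, rois)
    cloud_dir = out / "clouds"
    cloud_dir.mkdir(exist_ok=True)
    for i, cl in enumerate(clouds):
        cio.save_point_cloud(cloud_dir / f"cell_{i:03d}.csv", cl)
    manifest["stages"]["simulate"] = {
        "outputs": ["stimulus.h5", "traces.h5", "clouds/"],
        "n_rois": config.n_rois, "n_clouds": config.n_clouds}

    # --- kernels --------------------------------------------------------
    kernel_sets = {}
    for roi in rois:
        try:
            kernel_sets[roi.roi_id] = estimate_kernels(
                roi.trace, stim, threshold_sd=config.threshold_sd)
        except NoEventsError:
            continue
    kernels_path = out / "kernels.h5"
    kernels_path.unlink(missing_ok=True)
    cio.save_kernels(kernels_path, kernel_sets)
    counts["rois_with_kernels"] = len(kernel_sets)
    manifest["stages"]["kernels"] = {
        "outputs": ["kernels.h5"], "n_in": len(rois),
        "n_out": len(kernel_sets)}

    # --- classify -------------------------------------------------------
    rows = []
    roi_by_id = {r.roi_id: r for r in rois}
    for roi_id, ks in kernel_sets.items():
        st = ternary_state(ks, threshold=config.ternary_threshold)
        lab = opponency_class(st)
        responsive = any(s != "NR" for s in st.state)
        rows.append({
            "roi_id": roi_id,
            "eye_position": roi_by_id[roi_id].eye_position,
            "ipl_depth": roi_by_id[roi_id].ipl_depth,
            "compartment": roi_by_id[roi_id].compartment,
            "ternary_index": st.index,
            "category": lab.category,
            "crossing_pair": "/".join(lab.crossing_pair)
            if lab.crossing_pair else "",
            "responsive": responsive,
            **{f"state_{ch}": s for ch, s in zip(CHANNELS, st.state)},
            **{f"quality_{ch}": ks.quality[c]
               for c, ch in enumerate(CHANNELS)},
            **{f"centroid_hz_{ch}": spectral_centroid(ks.kernels[c])
               for c, ch in enumerate(CHANNELS)},
        })
    classified = pd.DataFrame(rows)
    classified.to_csv(out / "classified.csv", index=False)
    n_resp = int(classified["responsive"].sum()) if len(classified) else 0
    counts["rois_responsive_10sd"] = n_resp
    manifest["stages"]["classify"] = {
        "outputs": ["classified.csv"], "n_in": len(kernel_sets),
        "n_out": n_resp}

    # --- maps -----------------------------------------------------------
    class _Entry:
        def __init__(self, row):
            self.eye_position = row.eye_position
            self.ipl_depth = (None if pd.isna(row.ipl_depth)
                              else row.ipl_depth)
            self.compartment = row.compartment
            self.polarities = [getattr(row, f"state_{ch}")
                               for ch in CHANNELS]
    omap = ooi_map(_Entry(r) for r in classified.itertuples())
    pd.DataFrame(omap.grid).to_csv(out / "ooi_map.csv", index=False)
    manifest["stages"]["maps"] = {"outputs": ["ooi_map.csv"]}

    # --- functional clustering -----------------------------------------
    ids = np.array(sorted(kernel_sets))
    kmat = np.stack([kernel_sets[i].kernels for i in ids])
    keep = qc_filter(kmat, config.qc_threshold)
    counts["rois_pass_qc5"] = int(keep.size)
    scaled, _ = scale_per_color(kmat[keep])
    feats = pca_per_color(scaled)
    sweep = gmm_sweep(feats, k_max=min(config.k_max, keep.size - 1),
                      replicates=config.replicates, seed=config.seed)
    model, k_sel, cov_sel = select_model(
        sweep, mode=config.cluster_mode, fixed_k=config.fixed_k,
        fixed_covariance="unshared_diagonal"
        if config.cluster_mode == "fixed_k" else None)
    labels, kept_sizes = finalize_clusters(model.predict(feats.scores),
                                           config.min_members)
    pd.DataFrame({"roi_id": ids[keep], "cluster": labels}).to_csv(
        out / "assignments.csv", index=False)
    sweep.bic.to_csv(out / "bic_table.csv")
    manifest["stages"]["cluster_functional"] = {
        "outputs": ["assignments.csv", "bic_table.csv"],
        "n_in": int(keep.size), "selected_k": int(k_sel),
        "covariance": cov_sel, "n_clusters_kept": len(kept_sizes)}

    # --- morphology -----------------------------------------------------
    table = summary_table(clouds)
    stage1_k = min(config.stage1_k, len(clouds))
    morph = two_stage_cluster(table, stage1_k=stage1_k,
                              min_members=config.morph_min_members)
    table["cluster"] = morph.labels
    tilt_rows = []
    for i, cl in enumerate(clouds):
        t = compute_tilt(cl)
        tilt_rows.append({"cell_id": i, "region": cl.region, "r_um": t.r,
                          "theta_rad": t.theta, "phi_rad": t.phi})
    table.to_csv(out / "morph_summaries.csv", index=False)
    pd.DataFrame(tilt_rows).to_csv(out / "tilt.csv", index=False)
    manifest["stages"]["cluster_morph"] = {
        "outputs": ["morph_summaries.csv", "tilt.csv"],
        "n_total_clusters": morph.n_total,
        "n_presentation": len(morph.presentation),
        "ccc_stage1": morph.ccc_stage1}

    # --- manifest -------------------------------------------------------
    manifest["counts"] = counts
    manifest["hashes"] = {
        p.name: _hash_file(p) for p in sorted(out.glob("*.csv"))}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


# ---------------------------------------------------------------------------
# deposited-data import


def import_deposited(kernel_files=(), chirp_files=()) -> dict:
    """Load deposited kernel/chirp tables, validating the canonical grids.

    Kernel CSVs must have 4 x 649 values per record (one row per
    channel, 649 columns, or flat rows of 649); chirp CSVs 2,499 values
    per row.  Rows of the wrong length are reported with their index.
    """
    from .core import CHIRP_N, LAG_N

    out: dict = {"kernels": [], "chirps": [], "errors": []}
    for path in kernel_files:
        arr = pd.read_csv(path, header=None).to_numpy(dtype=float)
        for i, row in enumerate(arr):
            if row.size != LAG_N:
                out["errors"].append(
                    f"{path}: row {i} has {row.size} values, expected {LAG_N}")
            else:
                out["kernels"].append(row)
    for path in chirp_files:
        arr = pd.read_csv(path, header=None).to_numpy(dtype=float)
        for i, row in enumerate(arr):
            if row.size != CHIRP_N:
                out["errors"].append(
                    f"{path}: row {i} has {row.size} values, "
                    f"expected {CHIRP_N}")
            else:
                out["chirps"].append(row)
    if out["errors"]:
        raise ValueError("; ".join(out["errors"]))
    out["kernels"] = np.array(out["kernels"])
    out["chirps"] = np.array(out["chirps"])
    return out
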