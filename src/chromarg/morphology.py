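"""Dendritic point-cloud morphometrics, clustering, and tilt statistics.

Clouds are (x, y, z) point sets with y scaled so the IPL spans [0, 10]
(values outside that interval mark INL/GCL processes); the soma is stored
alongside but excluded from all dendritic statistics.  Four summaries
describe each cell -- y_span, y_mean, num_pts, and the convex-hull
xz_area -- of which the first three drive a two-stage agglomerative
clustering (city-block distance, average linkage) validated by the
cophenetic correlation coefficient.  Dendritic tilt is the soma-centred
spherical position (r, theta, phi) of the dendritic centre of mass, with
the polar angle theta measured from the +y axis (perpendicular to the
retinal plane), so theta = 0 means no tilt.  Group comparisons use the
two-sample Kolmogorov-Smirnov test for r and theta and a two-sample
Kuiper test for the 2pi-periodic phi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from scipy.stats import ks_2samp

from .synthetic import MorphPointCloud

__all__ = [
    "MorphSummary",
    "TiltCoordinates",
    "TwoStageResult",
    "scale_ipl_depth",
    "summarize_morphology",
    "summary_table",
    "standardize_stats",
    "hier_cluster",
    "two_stage_cluster",
    "compute_tilt",
    "ks_two_sample",
    "kuiper_two_sample",
]

CLUSTER_COLUMNS = ("y_span", "y_mean", "num_pts")


@dataclass(frozen=True)
class MorphSummary:
    """Summary statistics of one dendritic tree."""

    y_span: float
    y_mean: float
    num_pts: int
    xz_area: float


@dataclass(frozen=True)
class TiltCoordinates:
    """Soma-centred spherical position of the dendritic centre of mass."""

    r: float
    theta: float
    phi: float

    @property
    def defined(self) -> bool:
        return self.r > 0


@dataclass
class TwoStageResult:
    """Outcome of the two-stage morphology clustering."""

    labels: np.ndarray            # final cluster id per cell (0-based)
    n_total: int                  # clusters before the min-member filter
    presentation: list[int]       # cluster ids with >= min_members cells
    stage1_labels: np.ndarray
    split_targets: tuple[int, ...]
    ccc_stage1: float
    ccc_splits: tuple[float, ...]


# ---------------------------------------------------------------------------
# summaries


def scale_ipl_depth(points: np.ndarray, soma: np.ndarray,
                    ipl_inner: float, ipl_outer: float,
                    region: str | None = None) -> MorphPointCloud:
    """Rescale raw y so the GCL-side IPL border maps to 0 and the
    INL-side border to 10; x and z are unchanged.

    Points beyond the borders legitimately land outside [0, 10].
    """
    if ipl_inner == ipl_outer:
        raise ValueError("IPL borders must differ")
    pts = np.atleast_2d(np.asarray(points, dtype=float)).copy()
    soma = np.asarray(soma, dtype=float).copy()
    scale = 10.0 / (ipl_outer - ipl_inner)
    pts[:, 1] = (pts[:, 1] - ipl_inner) * scale
    soma[1] = (soma[1] - ipl_inner) * scale
    return MorphPointCloud(soma=soma, points=pts, region=region)


def _hull_area(xz: np.ndarray) -> float:
    """Convex-hull area of 2-D points; degenerate inputs give 0."""
    if xz.shape[0] < 3:
        return 0.0
    try:
        return float(ConvexHull(xz).volume)   # 2-D "volume" is the area
    except QhullError:
        return 0.0


def summarize_morphology(cloud: MorphPointCloud) -> MorphSummary:
    """y_span, y_mean, num_pts, and convex-hull xz_area of one cloud."""
    y = cloud.points[:, 1]
    return MorphSummary(
        y_span=float(y.max() - y.min()),
        y_mean=float(y.mean()),
        num_pts=int(cloud.points.shape[0]),
        xz_area=_hull_area(cloud.points[:, [0, 2]]),
    )


def summary_table(clouds: list[MorphPointCloud]) -> pd.DataFrame:
    """Summaries of many clouds as a DataFrame (one row per cell)."""
    rows = []
    for i, c in enumerate(clouds):
        s = summarize_morphology(c)
        rows.append({"cell_id": i, "region": c.region, "y_span": s.y_span,
                     "y_mean": s.y_mean, "num_pts": s.num_pts,
                     "xz_area": s.xz_area})
    return pd.DataFrame(rows)


def standardize_stats(table: pd.DataFrame,
                      columns: tuple[str, ...] = CLUSTER_COLUMNS) -> pd.DataFrame:
    """Z-score the given columns (sample SD, n-1 denominator)."""
    if len(table) < 2:
        raise ValueError("need at least two cells")
    out = table.copy()
    for col in columns:
        sd = table[col].std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"column {col!r} has zero variance")
        out[col] = (table[col] - table[col].mean()) / sd
    return out


# ---------------------------------------------------------------------------
# clustering


def hier_cluster(
    table: pd.DataFrame,
    columns: tuple[str, ...],
    n_clusters: int,
    metric: str = "cityblock",
    linkage_method: str = "average",
) -> tuple[np.ndarray, float, np.ndarray]:
    """Agglomerative clustering cut at ``n_clusters``.

    Returns (labels 0-based, cophenetic correlation coefficient, linkage
    matrix).  City-block distance with average linkage is the default, as
    it is for the published morphology analysis.
    """
    X = table.loc[:, list(columns)].to_numpy(dtype=float)
    if n_clusters > X.shape[0]:
        raise ValueError("more clusters requested than cells")
    d = pdist(X, metric=metric)
    Z = linkage(d, method=linkage_method)
    ccc = float(cophenet(Z, d)[0]) if d.size > 1 else 1.0
    labels = fcluster(Z, t=n_clusters, criterion="maxclust") - 1
    return labels, ccc, Z


def two_stage_cluster(
    table: pd.DataFrame,
    stage1_k: int = 18,
    split_spec: dict[int, int] | None = None,
    min_members: int = 4,
) -> TwoStageResult:
    """Two-stage morphology clustering.

    Stage 1 clusters standardized (y_span, y_mean, num_pts) into
    ``stage1_k`` groups.  ``split_spec`` maps stage-1 cluster ids to
    sub-cluster counts for a second round on y_span alone; by default the
    two largest stage-1 clusters are split into 6 and 3 subclusters,
    giving stage1_k - 2 + 9 = 25 clusters for the defaults before the
    minimum-member filter.
    """
    std = standardize_stats(table, CLUSTER_COLUMNS)
    s1, ccc1, _ = hier_cluster(std, CLUSTER_COLUMNS, stage1_k)
    if split_spec is None:
        ids, sizes = np.unique(s1, return_counts=True)
        order = ids[np.argsort(-sizes, kind="stable")]
        split_spec = {int(order[0]): 6}
        if len(order) > 1:
            split_spec[int(order[1])] = 3
    for cid in split_spec:
        if cid not in s1:
            raise ValueError(f"split target {cid} absent from stage 1")

    final = np.full(len(table), -1, dtype=int)
    nxt = 0
    ccc_splits = []
    for cid in np.unique(s1):
        members = np.flatnonzero(s1 == cid)
        if cid in split_spec:
            sub_k = split_spec[cid]
            if sub_k > members.size:
                raise ValueError(
                    f"cannot split cluster {cid} ({members.size} cells) "
                    f"into {sub_k} subclusters")
            sub_tab = standardize_stats(table.iloc[members], ("y_span",)) \
                if members.size > 1 else table.iloc[members]
            sub, ccc_s, _ = hier_cluster(sub_tab, ("y_span",), sub_k)
            ccc_splits.append(ccc_s)
            for s_id in np.unique(sub):
                final[members[sub == s_id]] = nxt
                nxt += 1
        else:
            final[members] = nxt
            nxt += 1
    sizes = np.bincount(final, minlength=nxt)
    presentation = [c for c in range(nxt) if sizes[c] >= min_members]
    return TwoStageResult(labels=final, n_total=nxt,
                          presentation=presentation, stage1_labels=s1,
                          split_targets=tuple(split_spec),
                          ccc_stage1=ccc1, ccc_splits=tuple(ccc_splits))


# ---------------------------------------------------------------------------
# tilt


def compute_tilt(cloud: MorphPointCloud) -> TiltCoordinates:
    """Spherical (r, theta, phi) of the dendritic CoM relative to the soma.

    theta is the angle from the +y axis (the y and z axes swap roles
    relative to the textbook convention); phi = atan2(z, x) in [0, 2pi).
    A CoM coincident with the soma has undefined tilt (r = 0, angles
    NaN, ``defined`` False).
    """
    com = cloud.points.mean(axis=0) - cloud.soma
    r = float(np.linalg.norm(com))
    if r == 0:
        return TiltCoordinates(r=0.0, theta=float("nan"), phi=float("nan"))
    theta = float(np.arccos(np.clip(com[1] / r, -1.0, 1.0)))
    phi = float(np.arctan2(com[2], com[0]) % (2 * np.pi))
    return TiltCoordinates(r=r, theta=theta, phi=phi)


# ---------------------------------------------------------------------------
# two-sample tests


def ks_two_sample(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p-value)."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    res = ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def kuiper_two_sample(angles_a: np.ndarray,
                      angles_b: np.ndarray) -> tuple[float, float]:
    """Two-sample Kuiper test for circular (2pi-periodic) data.

    V = max(F_a - F_b) + max(F_b - F_a) over the pooled sample, which is
    invariant to a common rotation of both samples.  The p-value uses the
    standard asymptotic series with the effective sample size
    n_e = n_a n_b / (n_a + n_b) and Stephens' finite-sample correction.
    """
    a = np.sort(np.asarray(angles_a, dtype=float) % (2 * np.pi))
    b = np.sort(np.asarray(angles_b, dtype=float) % (2 * np.pi))
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    pooled = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pooled, side="right") / a.size
    cdf_b = np.searchsorted(b, pooled, side="right") / b.size
    d = cdf_a - cdf_b
    v = float(max(d.max(), 0.0) - min(d.min(), 0.0))
    ne = a.size * b.size / (a.size + b.size)
    p = _kuiper_fpp(v, ne)
    return v, p


def _kuiper_fpp(v: float, ne: float) -> float:
    """Asymptotic false-positive probability of the Kuiper statistic."""
    lam = (np.sqrt(ne) + 0.155 + 0.24 / np.sqrt(ne)) * v
    if lam < 0.4:
        return 1.0
    j = np.arange(1, 101)
    terms = (4.0 * j**2 * lam**2 - 1.0) * np.exp(-2.0 * j**2 * lam**2)
    return float(np.clip(2.0 * terms.sum(), 0.0, 1.0))
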