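"""Functional clustering of ROIs on their four spectral kernels.

The protocol: gate ROIs at kernel quality >= 5 (maximum SD across the
four colours), scale each colour block by a single pooled SD so every
colour weighs equally, reduce each colour separately by PCA keeping the
minimum number of components explaining >= 99% of variance, concatenate
the scores, and sweep Gaussian mixture models over component counts and
four covariance structures (shared-diagonal, unshared-diagonal,
shared-full, unshared-full), 20 replicates per cell, best log-likelihood
kept, model selected by minimum BIC (or a fixed-k override).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture
from sklearn.mixture._gaussian_mixture import _compute_precision_cholesky

from .core import LAG_N, N_CHANNELS

__all__ = [
    "FeatureMatrix",
    "GMMSweepResult",
    "COVARIANCE_TYPES",
    "clustering_quality",
    "qc_filter",
    "scale_per_color",
    "pca_per_color",
    "gmm_sweep",
    "select_model",
    "finalize_clusters",
    "cluster_profiles",
]

#: Covariance structures in sweep order.  Keys are package names; values
#: are the sklearn covariance types used to realise them.
COVARIANCE_TYPES: tuple[str, ...] = (
    "shared_diagonal", "unshared_diagonal", "shared_full", "unshared_full")

_SKLEARN_COV = {
    "shared_diagonal": "diag",      # tied via the constrained M-step below
    "unshared_diagonal": "diag",
    "shared_full": "tied",
    "unshared_full": "full",
}

#: Default quality gate for clustering (max per-colour SD of the kernel).
QC_THRESHOLD = 5.0


@dataclass
class FeatureMatrix:
    """Concatenated per-colour PCA scores plus bookkeeping."""

    scores: np.ndarray
    n_components: tuple[int, ...]
    explained: tuple[float, ...]

    @property
    def n_features(self) -> int:
        return self.scores.shape[1]


@dataclass
class GMMSweepResult:
    """BIC table over (k, covariance) with the winning fit per cell."""

    bic: pd.DataFrame           # index k, columns covariance names
    loglik: pd.DataFrame        # best replicate log-likelihood per cell
    models: dict                # (k, covariance) -> fitted GaussianMixture
    n_samples: int
    seed: int
    failures: list = field(default_factory=list)


class _SharedDiagGMM(GaussianMixture):
    """GMM with one diagonal covariance shared across components.

    sklearn has no tied-diagonal structure; the EM M-step for it is the
    responsibility-weighted average of the per-component diagonal
    covariances, so we constrain an unshared-diagonal fit after each
    M-step.
    """

    def _m_step(self, X, log_resp, **kwargs):
        super()._m_step(X, log_resp, **kwargs)
        cov = np.asarray(self.covariances_)
        pooled = np.einsum("k,kd->d", np.asarray(self.weights_), cov)
        self.covariances_ = np.tile(pooled, (self.n_components, 1))
        self.precisions_cholesky_ = _compute_precision_cholesky(
            self.covariances_, "diag")


# ---------------------------------------------------------------------------
# feature extraction


def clustering_quality(kernels: np.ndarray) -> np.ndarray:
    """Per-ROI kernel quality: maximum SD through time across the colours.

    ``kernels`` is n x 4 x 649 in baseline z-score units.
    """
    kernels = np.asarray(kernels, dtype=float)
    if kernels.ndim != 3 or kernels.shape[1:] != (N_CHANNELS, LAG_N):
        raise ValueError(f"kernels must be n x {N_CHANNELS} x {LAG_N}")
    return kernels.std(axis=2).max(axis=1)


def qc_filter(kernels: np.ndarray,
              quality_threshold: float = QC_THRESHOLD) -> np.ndarray:
    """Indices of ROIs whose clustering quality reaches the threshold."""
    keep = np.flatnonzero(clustering_quality(kernels) >= quality_threshold)
    if keep.size == 0:
        raise ValueError("no ROI passes the kernel quality threshold")
    return keep


def scale_per_color(kernels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Divide each colour block by one pooled SD (over time and ROIs).

    Equalises the weight of the four colours; returns the scaled
    n x 4 x 649 array and the four scale factors.
    """
    kernels = np.asarray(kernels, dtype=float)
    if kernels.shape[0] < 2:
        raise ValueError("need at least two ROIs")
    scales = kernels.std(axis=(0, 2))
    if (scales == 0).any():
        raise ValueError("zero-variance colour block")
    return kernels / scales[None, :, None], scales


def pca_per_color(scaled: np.ndarray,
                  var_target: float = 0.99) -> FeatureMatrix:
    """Per-colour PCA keeping the fewest components explaining the target
    variance; scores concatenated in channel order R, G, B, UV."""
    scaled = np.asarray(scaled, dtype=float)
    if scaled.shape[0] < 2:
        raise ValueError("need at least two ROIs")
    blocks, n_comp, explained = [], [], []
    for c in range(N_CHANNELS):
        pca = PCA().fit(scaled[:, c, :])
        cum = np.cumsum(pca.explained_variance_ratio_)
        if var_target >= 1.0:
            k = int((pca.explained_variance_ > 1e-12).sum())
        else:
            k = int(np.searchsorted(cum, var_target) + 1)
        k = max(1, min(k, cum.size))
        blocks.append(pca.transform(scaled[:, c, :])[:, :k])
        n_comp.append(k)
        explained.append(float(cum[k - 1]))
    return FeatureMatrix(scores=np.hstack(blocks),
                         n_components=tuple(n_comp),
                         explained=tuple(explained))


# ---------------------------------------------------------------------------
# mixture-model sweep


def _n_params(k: int, d: int, covariance: str) -> int:
    base = (k - 1) + k * d
    return base + {
        "shared_diagonal": d,
        "unshared_diagonal": k * d,
        "shared_full": d * (d + 1) // 2,
        "unshared_full": k * d * (d + 1) // 2,
    }[covariance]


def _fit_cell(X, k, covariance, replicates, reg, max_iter, base_seed):
    cls = _SharedDiagGMM if covariance == "shared_diagonal" else GaussianMixture
    best, best_ll = None, -np.inf
    failures = 0
    for r in range(replicates):
        gm = cls(n_components=k, covariance_type=_SKLEARN_COV[covariance],
                 reg_covar=reg, max_iter=max_iter, n_init=1,
                 init_params="k-means++", random_state=base_seed + r)
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                gm.fit(X)
            except ConvergenceWarning:
                failures += 1
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    gm.fit(X)
            except ValueError:
                failures += 1
                continue
        ll = gm.score(X) * X.shape[0]
        if ll > best_ll:
            best, best_ll = gm, ll
    return best, best_ll, failures


def gmm_sweep(
    features: np.ndarray | FeatureMatrix,
    k_max: int = 20,
    covariance_set: tuple[str, ...] = COVARIANCE_TYPES,
    replicates: int = 20,
    reg: float = 1e-5,
    max_iter: int = 10_000,
    seed: int = 0,
) -> GMMSweepResult:
    """Fit GMMs for every (k, covariance) cell and tabulate BIC.

    Each cell runs ``replicates`` fits initialised with k-means++ seeding
    from seeds ``seed*10007 + cell offset + r`` and keeps the best
    log-likelihood.  BIC = -2 logL + p ln(n) with p counted per
    covariance structure.  Non-convergent fits are recorded, not fatal.
    """
    X = features.scores if isinstance(features, FeatureMatrix) else \
        np.asarray(features, dtype=float)
    n, d = X.shape
    if n <= k_max:
        raise ValueError("need more rows than k_max")
    unknown = set(covariance_set) - set(COVARIANCE_TYPES)
    if unknown:
        raise ValueError(f"unknown covariance structure(s): {sorted(unknown)}")
    bic = pd.DataFrame(index=np.arange(1, k_max + 1),
                       columns=list(covariance_set), dtype=float)
    loglik = bic.copy()
    models, failures = {}, []
    for ci, cov in enumerate(covariance_set):
        for k in range(1, k_max + 1):
            base = (seed % 2**20) * 10_007 + ci * k_max * 1_000 + k * 31
            gm, ll, nfail = _fit_cell(X, k, cov, replicates, reg,
                                      max_iter, base)
            if nfail:
                failures.append((k, cov, nfail))
            if gm is None:
                continue
            models[(k, cov)] = gm
            loglik.loc[k, cov] = ll
            bic.loc[k, cov] = -2.0 * ll + _n_params(k, d, cov) * np.log(n)
    return GMMSweepResult(bic=bic, loglik=loglik, models=models,
                          n_samples=n, seed=seed, failures=failures)


def select_model(
    sweep: GMMSweepResult,
    mode: str = "bic",
    fixed_k: int | None = None,
    fixed_covariance: str | None = None,
):
    """Pick the model minimising BIC, or a requested (k, covariance) cell.

    BIC ties break toward smaller k, then toward the covariance structure
    listed earlier in the sweep.  Returns (model, k, covariance).
    """
    if mode == "fixed_k":
        if fixed_k is None:
            raise ValueError("fixed_k mode requires fixed_k")
        cov = fixed_covariance or "unshared_diagonal"
        if (fixed_k, cov) not in sweep.models:
            raise ValueError(f"sweep has no cell (k={fixed_k}, {cov})")
        return sweep.models[(fixed_k, cov)], fixed_k, cov
    if mode != "bic":
        raise ValueError("mode must be 'bic' or 'fixed_k'")
    best = (np.inf, None)
    for k in sweep.bic.index:
        for cov in sweep.bic.columns:
            val = sweep.bic.loc[k, cov]
            if np.isfinite(val) and val < best[0]:
                best = (float(val), (int(k), cov))
    if best[1] is None:
        raise ValueError("sweep produced no finite BIC")
    k, cov = best[1]
    return sweep.models[(k, cov)], k, cov


def finalize_clusters(assignments: np.ndarray,
                      min_members: int = 10) -> tuple[np.ndarray, list[int]]:
    """Drop clusters below ``min_members``; re-index survivors by size.

    Returns (labels, kept_sizes): labels re-numbered 0.. by decreasing
    size, dropped ROIs marked -1.
    """
    assignments = np.asarray(assignments)
    ids, sizes = np.unique(assignments, return_counts=True)
    order = ids[np.argsort(-sizes, kind="stable")]
    labels = np.full(assignments.size, -1, dtype=int)
    kept_sizes = []
    nxt = 0
    for cid in order:
        members = assignments == cid
        if members.sum() >= min_members:
            labels[members] = nxt
            kept_sizes.append(int(members.sum()))
            nxt += 1
    return labels, kept_sizes


def cluster_profiles(
    labels: np.ndarray,
    kernels: np.ndarray,
    chirps: np.ndarray | None = None,
) -> dict[int, dict[str, np.ndarray]]:
    """Per-cluster mean +- SD kernels (and chirps), plus max-scaled means.

    Unassigned ROIs (label -1) are skipped.  SD uses the population
    convention (ddof 0), so singleton clusters report SD 0.
    """
    labels = np.asarray(labels)
    kernels = np.asarray(kernels, dtype=float)
    out: dict[int, dict[str, np.ndarray]] = {}
    for cid in np.unique(labels[labels >= 0]):
        m = labels == cid
        mean_k = kernels[m].mean(axis=0)
        peak = np.abs(mean_k).max(axis=1, keepdims=True)
        prof = {
            "n": int(m.sum()),
            "kernel_mean": mean_k,
            "kernel_sd": kernels[m].std(axis=0),
            "kernel_max_scaled": np.divide(
                mean_k, peak, out=np.zeros_like(mean_k), where=peak > 0),
        }
        if chirps is not None:
            ch = np.asarray(chirps, dtype=float)[m]
            prof["chirp_mean"] = ch.mean(axis=0)
            prof["chirp_sd"] = ch.std(axis=0)
        out[int(cid)] = prof
    return out
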