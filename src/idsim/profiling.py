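"""ROI evidence profiles: Ward clustering and MAP-shrunken cluster means.

ROIs are clustered on their probit-transformed p* profiles (one z value
per regressor group) with Ward's minimum-variance criterion. Cluster-level
ΔR² profiles are then summarized with normal–normal MAP estimates under a
zero-centered prior, so that small or heterogeneous clusters are shrunk
toward zero while large, consistent clusters keep their raw mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score


@dataclass
class ClusterSolution:
    K: int
    assignment: dict[int, int]  # roi_id -> cluster label (1..K)
    linkage: np.ndarray
    silhouette_by_k: dict[int, float] | None = None


@dataclass(frozen=True)
class ShrinkageParams:
    """Normal-normal hyperparameters: prior variance of cluster means (tau2)
    and within-cluster observation variance (sigma2)."""

    tau2: float
    sigma2: float

    def __post_init__(self) -> None:
        if self.tau2 < 0 or self.sigma2 < 0:
            raise ValueError("tau2 and sigma2 must be nonnegative")
        if self.tau2 == 0 and self.sigma2 == 0:
            raise ValueError("tau2 and sigma2 cannot both be zero")


def ward_cluster(
    z_matrix: pd.DataFrame | np.ndarray,
    k: int | None = None,
    roi_ids: Sequence[int] | None = None,
) -> ClusterSolution:
    """Agglomerative Ward clustering of ROI z-profiles (Euclidean).

    ``z_matrix`` rows are ROIs, columns regressor groups. With ``k=None``
    the silhouette-maximizing K in 2..min(10, n-1) is chosen (ties break
    toward the smaller K). Deterministic given the input.
    """
    if isinstance(z_matrix, pd.DataFrame):
        ids = [int(i) for i in z_matrix.index] if roi_ids is None else list(roi_ids)
        X = z_matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(z_matrix, dtype=float)
        ids = list(roi_ids) if roi_ids is not None else list(range(1, len(X) + 1))
    if not np.all(np.isfinite(X)):
        raise ValueError("z matrix contains non-finite entries")
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 ROIs to cluster")
    Z = linkage(X, method="ward")
    sil: dict[int, float] | None = None
    if k is None:
        sil = {}
        for kk in range(2, min(10, n - 1) + 1):
            labels = fcluster(Z, t=kk, criterion="maxclust")
            if len(np.unique(labels)) < 2:
                continue
            sil[kk] = float(silhouette_score(X, labels))
        if not sil:
            k = n
        else:
            best = max(sil.values())
            k = min(kk for kk, s in sil.items() if s == best)
    if not 2 <= k <= n:
        raise ValueError(f"K must be in [2, {n}], got {k}")
    labels = fcluster(Z, t=k, criterion="maxclust")
    # relabel clusters 1..K in order of first appearance for determinism
    remap: dict[int, int] = {}
    for lab in labels:
        if lab not in remap:
            remap[lab] = len(remap) + 1
    assignment = {rid: remap[lab] for rid, lab in zip(ids, labels)}
    return ClusterSolution(K=len(remap), assignment=assignment, linkage=Z, silhouette_by_k=sil)


def map_shrink(values: Sequence[float], params: ShrinkageParams) -> float:
    """MAP estimate of a cluster's mean under a zero-centered normal prior.

    shrunken mean = x̄ · n·tau2 / (n·tau2 + sigma2). Larger clusters and
    smaller within-cluster variance shrink less; the estimate never
    exceeds the raw mean in magnitude and never flips sign.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot shrink an empty cluster")
    xbar = float(v.mean())
    n = v.size
    if np.isinf(params.tau2):
        return xbar
    denom = n * params.tau2 + params.sigma2
    if denom == 0:
        return xbar
    return xbar * (n * params.tau2) / denom


def estimate_shrinkage_params(groups_values: Mapping[int, np.ndarray]) -> ShrinkageParams:
    """Moment estimates of (tau2, sigma2) from per-cluster value arrays.

    sigma2 pools the within-cluster variance across clusters; tau2 is the
    variance of the raw cluster means minus its sampling contribution
    (sigma2 · mean(1/n_k)), floored at 0. With a single cluster there is
    no between-cluster information and the prior is left flat.
    """
    arrays = [np.asarray(v, dtype=float) for v in groups_values.values()]
    if not arrays:
        raise ValueError("no clusters supplied")
    n_total = sum(a.size for a in arrays)
    k = len(arrays)
    if k < 2:
        return ShrinkageParams(tau2=np.inf, sigma2=0.0)
    within_ss = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    dof = max(n_total - k, 1)
    sigma2 = within_ss / dof
    means = np.array([a.mean() for a in arrays])
    mean_inv_n = float(np.mean([1.0 / a.size for a in arrays]))
    tau2 = max(float(means.var(ddof=1)) - sigma2 * mean_inv_n, 0.0)
    if tau2 == 0.0 and sigma2 == 0.0:
        return ShrinkageParams(tau2=np.inf, sigma2=0.0)
    return ShrinkageParams(tau2=tau2, sigma2=sigma2)


def cluster_profiles(
    delta_r2: pd.DataFrame,
    solution: ClusterSolution,
    params: ShrinkageParams | None = None,
) -> pd.DataFrame:
    """Per-cluster variable profiles: raw mean ΔR² and MAP-shrunken mean.

    ``delta_r2`` is ROI x group (index roi_id). Hyperparameters default to
    per-variable moment estimates across clusters; an explicit
    ``ShrinkageParams`` overrides them for every variable.
    """
    missing = [rid for rid in delta_r2.index if int(rid) not in solution.assignment]
    if missing:
        raise ValueError(f"ROIs missing a cluster assignment: {missing}")
    labels = pd.Series({rid: solution.assignment[int(rid)] for rid in delta_r2.index})
    rows = []
    for col in delta_r2.columns:
        by_cluster = {
            lab: delta_r2.loc[labels[labels == lab].index, col].to_numpy(dtype=float)
            for lab in sorted(labels.unique())
        }
        p = params if params is not None else estimate_shrinkage_params(by_cluster)
        for lab, vals in by_cluster.items():
            rows.append(
                {
                    "cluster": lab,
                    "group": col,
                    "n_rois": len(vals),
                    "raw_mean": float(np.mean(vals)),
                    "map_mean": map_shrink(vals, p),
                }
            )
    return pd.DataFrame(rows).sort_values(["cluster", "group"]).reset_index(drop=True)


def strength_table(pstar_df: pd.DataFrame, threshold: float = 0.05) -> pd.DataFrame:
    """High-evidence variable hits: per ROI, the groups with p* < threshold.

    Rows are ordered by roi_id, then ascending p* within ROI, mirroring a
    'variables with high strength of evidence' listing.
    """
    hits = pstar_df[pstar_df["pstar"] < threshold].copy()
    cols = ["roi_id", "group", "delta_r2_pct", "pstar"]
    hits = hits[[c for c in cols if c in hits.columns]]
    return hits.sort_values(["roi_id", "pstar"], kind="stable").reset_index(drop=True)
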