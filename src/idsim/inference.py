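"""Strength-of-evidence p*-values for unique variance under a subject-level null.

Pair-level similarity values are not independent: each subject
contributes n-1 pairs to every similarity vector. Naive row-wise
permutation of pairs therefore breaks the dyadic dependence structure and
is anticonservative. The null here instead resamples at the subject
level: the focal group's underlying subject data are relabeled by a
random permutation (Mantel-style; or resampled with replacement in
bootstrap mode), the group's pair-level similarity columns are recomputed
from the relabeled data, and the group's ΔR² over the unchanged remainder
of the design is recorded. The resulting one-tailed pseudo p-value is

    p* = (1 + #{ΔR²_null >= ΔR²_observed}) / (B + 1),

and its probit transform z = Φ⁻¹(1 - p*) is the clustering feature.

The subject-intercept group has no subject-level data to relabel —
permuting its columns leaves their span invariant — so no p* is defined
for it; it still receives ΔR² credit in the round robin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .regression import ProjectedDelta, RegressorGroup, assemble_design
from .similarity import PairIndex, SimilarityVector, permute_similarity

METHODS = ("subject_permutation", "subject_bootstrap")


@dataclass(frozen=True)
class ResamplingConfig:
    method: str = "subject_permutation"
    B: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown resampling method {self.method!r}; expected one of {METHODS}")
        if self.B < 19:
            raise ValueError(f"B must be >= 19, got {self.B}")


@dataclass
class PStarResult:
    roi_id: int
    group: str
    observed_delta_r2: float
    pstar: float
    z: float
    B: int
    seed: int
    method: str


def pstar(observed: float, null_draws: Sequence[float]) -> float:
    """One-tailed pseudo p-value with the +1 correction (never exactly 0)."""
    draws = np.asarray(null_draws, dtype=float)
    if draws.size == 0:
        raise ValueError("empty null distribution")
    return float((1 + np.sum(draws >= observed)) / (draws.size + 1))


def z_transform(p: float, B: int) -> float:
    """Probit of 1 - p*, with p* clipped into [1/(B+1), 1 - 1/(B+1)]."""
    lo = 1.0 / (B + 1)
    p = min(max(p, lo), 1.0 - lo)
    return float(stats.norm.ppf(1.0 - p))


def _rng_for(seed: int, roi_id: int, group_pos: int) -> np.random.Generator:
    # independent, reproducible substream per (ROI, group) cell
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(roi_id + 1, group_pos)))


def null_resample(
    members: Sequence[SimilarityVector],
    index: PairIndex,
    rng: np.random.Generator,
) -> list[SimilarityVector]:
    """One permutation draw: relabel the focal group's subjects, recompute columns.

    All member vectors of a group share one permutation — they summarize
    the same underlying subject data, so their dependence must survive.
    """
    perm = rng.permutation(index.n_subjects)
    return [permute_similarity(vec, index, perm) for vec in members]


def _member_matrix(members: Sequence[SimilarityVector]) -> np.ndarray:
    return np.column_stack([np.asarray(v.values, dtype=float) for v in members])


def compute_pstars(
    groups: Sequence[RegressorGroup],
    response: SimilarityVector,
    index: PairIndex,
    config: ResamplingConfig,
    roi_id: int = -1,
    include_subints: bool = True,
    focal_groups: Sequence[str] | None = None,
) -> list[PStarResult]:
    """p* per regressor group for one ROI's response.

    For each focal group, all other columns (and the response) are held
    fixed; only the focal group's similarity columns are regenerated from
    relabeled subject data, and its ΔR² over the fixed design is compared
    with the observed ΔR².
    """
    design = assemble_design(groups, index, include_subints=include_subints)
    y = np.asarray(response.values, dtype=float)
    col_groups = np.asarray(design.column_groups)
    wanted = [g for g in groups if focal_groups is None or g.name in focal_groups]
    results: list[PStarResult] = []
    for g in wanted:
        pos = next(i for i, gg in enumerate(groups) if gg.name == g.name)
        fixed = design.X[:, col_groups != g.name]
        proj = ProjectedDelta(fixed, y)
        observed = proj.delta_r2(_member_matrix(g.members))
        rng = _rng_for(config.seed, roi_id, pos)
        draws = np.empty(config.B)
        if config.method == "subject_permutation":
            for b in range(config.B):
                permuted = null_resample(g.members, index, rng)
                draws[b] = proj.delta_r2(_member_matrix(permuted))
        else:
            draws = _bootstrap_draws(g, groups, design, y, index, config, rng, include_subints)
        p = pstar(observed, draws)
        results.append(
            PStarResult(
                roi_id=roi_id, group=g.name, observed_delta_r2=observed, pstar=p,
                z=z_transform(p, config.B), B=config.B, seed=config.seed, method=config.method,
            )
        )
    return results


def _bootstrap_draws(
    focal: RegressorGroup,
    groups: Sequence[RegressorGroup],
    design,
    y: np.ndarray,
    index: PairIndex,
    config: ResamplingConfig,
    rng: np.random.Generator,
    include_subints: bool,
) -> np.ndarray:
    """Sensitivity mode: resample the focal group's subjects with replacement.

    A resampled pair whose two positions map to the same original subject
    is a self-pair (distance 0 by construction) and is dropped from the
    fit; full and reduced models are recomputed on the surviving rows, so
    ΔR² >= 0 still holds by nesting.
    """
    from scipy.spatial.distance import squareform

    col_groups = np.asarray(design.column_groups)
    fixed_cols = design.X[:, col_groups != focal.name]
    i, j = index.pairs[:, 0], index.pairs[:, 1]
    mats = [squareform(np.asarray(v.values, dtype=float), checks=False) for v in focal.members]
    draws = np.empty(config.B)
    for b in range(config.B):
        draw = rng.integers(0, index.n_subjects, size=index.n_subjects)
        keep = draw[i] != draw[j]
        if keep.sum() < fixed_cols.shape[1] + len(mats):
            draws[b] = 0.0
            continue
        Z = np.column_stack([m[draw[i[keep]], draw[j[keep]]] for m in mats])
        proj = ProjectedDelta(fixed_cols[keep], y[keep])
        if np.any(Z.std(axis=0) == 0):
            draws[b] = 0.0
            continue
        draws[b] = proj.delta_r2(Z)
    return draws


def pstar_frame(results: Sequence[PStarResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "roi_id": r.roi_id, "group": r.group, "delta_r2_pct": 100.0 * r.observed_delta_r2,
                "pstar": r.pstar, "z": r.z, "B": r.B, "seed": r.seed, "method": r.method,
            }
            for r in results
        ]
    )
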