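"""Round-robin unique-variance (ΔR²) partitioning of pattern similarity.

Each ROI's pairwise pattern-distance vector is regressed, by ordinary
least squares, on the full complement of explanatory similarity vectors
plus participant-specific intercepts. Credit is assigned per named group
of regressors: the group's unique variance is the drop in R² when its
columns are removed (ΔR² >= 0 by nesting). What the full model explains
beyond the sum of unique contributions is the shared variance, which may
be negative under suppression.

The design is rank deficient by construction (the global intercept is
collinear with the subject-intercept block, whose row sums are the
constant 2); R² depends only on the column space, so a minimum-norm
least-squares solve makes this harmless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .similarity import PairIndex, SimilarityVector

logger = logging.getLogger(__name__)

CATEGORIES = ("neural", "intrinsic", "psa", "control", "unexplained")
SUBINTS = "subints"

#: group -> category for the packaged default model.
DEFAULT_CATEGORIES: dict[str, str] = {
    "wbFxnSim": "neural",
    "ROIneur": "neural",
    "MJrisk": "intrinsic",
    "SSscore": "intrinsic",
    "Compliance": "intrinsic",
    "pMSV": "psa",
    "pAS": "psa",
    "AdLike": "psa",
    "pos": "psa",
    "neg": "psa",
    "ThVal": "psa",
    SUBINTS: "unexplained",
}


@dataclass(frozen=True)
class RegressorGroup:
    """A named set of similarity vectors sharing round-robin credit."""

    name: str
    members: tuple[SimilarityVector, ...]
    category: str

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"group {self.name!r} has no member vectors")
        if self.category not in CATEGORIES:
            raise ValueError(f"group {self.name!r}: unknown category {self.category!r}")


@dataclass
class DesignMatrix:
    """Assembled design: global intercept, z-scored regressors, subject intercepts."""

    X: np.ndarray
    column_groups: tuple[str, ...]  # per column: "_const", a group name, or "subints"
    column_names: tuple[str, ...]
    index: PairIndex


@dataclass
class RoundRobinResult:
    roi_id: int
    r2_full: float
    delta_r2: dict[str, float]
    shared: float

    @property
    def residual(self) -> float:
        return 1.0 - self.r2_full


def subject_intercepts(index: PairIndex) -> np.ndarray:
    """0/1 block with one column per subject; pair (i, j) has ones at i and j."""
    Z = np.zeros((index.n_pairs, index.n_subjects))
    rows = np.arange(index.n_pairs)
    Z[rows, index.pairs[:, 0]] = 1.0
    Z[rows, index.pairs[:, 1]] = 1.0
    return Z


def assemble_design(
    groups: Sequence[RegressorGroup],
    index: PairIndex,
    include_subints: bool = True,
) -> DesignMatrix:
    """Stack group member columns (z-scored) with intercept blocks.

    A constant member column carries no pairwise information and is an
    error rather than a silently dropped regressor.
    """
    names = [g.name for g in groups]
    if len(set(names)) != len(names):
        raise ValueError("group names are not unique")
    cols = [np.ones(index.n_pairs)]
    col_groups = ["_const"]
    col_names = ["_const"]
    for g in groups:
        for vec in g.members:
            v = np.asarray(vec.values, dtype=float)
            if len(v) != index.n_pairs:
                raise ValueError(f"{vec.name}: length {len(v)} != {index.n_pairs} pairs")
            sd = v.std()
            if sd == 0:
                raise ValueError(f"constant (zero-variance) regressor: {vec.name!r} in group {g.name!r}")
            cols.append((v - v.mean()) / sd)
            col_groups.append(g.name)
            col_names.append(vec.name)
    if include_subints:
        Z = subject_intercepts(index)
        for k in range(index.n_subjects):
            cols.append(Z[:, k])
            col_groups.append(SUBINTS)
            col_names.append(f"subint_{index.subject_ids[k]}")
    X = np.column_stack(cols)
    return DesignMatrix(X=X, column_groups=tuple(col_groups), column_names=tuple(col_names), index=index)


def fit_r2(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Least-squares fit; returns (R², minimum-norm coefficients).

    R² = 1 - SSE/SST with SST about the response mean. Rank deficiency is
    resolved by the minimum-norm solution; R² depends only on the column
    space, so the choice is inert.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != len(y):
        raise ValueError(f"design has {X.shape[0]} rows but response has {len(y)}")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to fit")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("response has zero variance")
    r2 = 1.0 - float(resid @ resid) / sst
    return r2, beta


def _orth_basis(X: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Orthonormal basis of the column space (SVD, rank-revealing)."""
    if X.shape[1] == 0:
        return np.empty((X.shape[0], 0))
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(s > tol * s[0])) if s.size else 0
    return U[:, :rank]


class ProjectedDelta:
    """ΔR² of a focal column block over a fixed design, via projection.

    Precomputes an orthonormal basis Q of the fixed columns; then for any
    focal block Z, ΔR² = ||fit of (I-QQ')y on (I-QQ')Z||² / SST. Used for
    the observed ΔR² and for every resampling draw, where only the focal
    columns change.
    """

    def __init__(self, X_fixed: np.ndarray, y: np.ndarray):
        y = np.asarray(y, dtype=float)
        self.Q = _orth_basis(np.asarray(X_fixed, dtype=float))
        self.sst = float(np.sum((y - y.mean()) ** 2))
        if self.sst == 0:
            raise ValueError("response has zero variance")
        self.resid_y = y - self.Q @ (self.Q.T @ y)
        sse_reduced = float(self.resid_y @ self.resid_y)
        self.r2_reduced = 1.0 - sse_reduced / self.sst

    def delta_r2(self, Z: np.ndarray) -> float:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.shape[0] != len(self.resid_y):
            Z = Z.T
        Rz = Z - self.Q @ (self.Q.T @ Z)
        coef, *_ = np.linalg.lstsq(Rz, self.resid_y, rcond=None)
        fitted = Rz @ coef
        return max(float(fitted @ fitted) / self.sst, 0.0)


def round_robin(
    groups: Sequence[RegressorGroup],
    response: SimilarityVector,
    index: PairIndex,
    roi_id: int = -1,
    include_subints: bool = True,
) -> RoundRobinResult:
    """Full-model R² and per-group unique ΔR² (subject intercepts included).

    ΔR²_g = R²_full - R² of the model with group g's columns removed;
    shared = R²_full - Σ_g ΔR²_g (negative values are reported, not
    clamped, with a warning — suppression is real).
    """
    design = assemble_design(groups, index, include_subints=include_subints)
    y = np.asarray(response.values, dtype=float)
    r2_full, _ = fit_r2(design.X, y)
    col_groups = np.asarray(design.column_groups)
    group_names = [g.name for g in groups] + ([SUBINTS] if include_subints else [])
    deltas: dict[str, float] = {}
    for name in group_names:
        keep = col_groups != name
        r2_red, _ = fit_r2(design.X[:, keep], y)
        deltas[name] = max(r2_full - r2_red, 0.0)
    shared = r2_full - sum(deltas.values())
    if shared < -1e-10:
        logger.warning("roi %s: negative shared variance (%.4g); suppression present", roi_id, shared)
    return RoundRobinResult(roi_id=roi_id, r2_full=r2_full, delta_r2=deltas, shared=shared)


def results_frame(results: Sequence[RoundRobinResult]) -> pd.DataFrame:
    """Long-form ΔR² table in percent: roi_id, group, delta_r2_pct."""
    rows = [
        {"roi_id": r.roi_id, "group": g, "delta_r2_pct": 100.0 * d}
        for r in results
        for g, d in r.delta_r2.items()
    ]
    return pd.DataFrame(rows)


def summary_frame(results: Sequence[RoundRobinResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"roi_id": r.roi_id, "r2_full": r.r2_full, "shared": r.shared, "residual": r.residual}
            for r in results
        ]
    )


def category_summary(
    results: Mapping[int, RoundRobinResult],
    roi_specs: Sequence,
    categories: Mapping[str, str] = DEFAULT_CATEGORIES,
) -> pd.DataFrame:
    """Mean per-category summed ΔR² over ROIs within each source bucket.

    Per ROI the category score is the sum of its groups' unique ΔR²
    (computed without shrinkage); shared, unexplained (subject
    intercepts) and residual are carried as their own columns. Rows are
    the ROI source buckets (a_priori, exploratory, confirmatory).
    """
    rows = []
    for spec in roi_specs:
        if spec.id not in results:
            raise ValueError(f"missing round-robin result for ROI {spec.id}")
        res = results[spec.id]
        row: dict[str, float | str | int] = {"roi_id": spec.id, "roi_source_group": spec.source}
        sums = {"neural": 0.0, "intrinsic": 0.0, "psa": 0.0, "control": 0.0}
        for g, d in res.delta_r2.items():
            cat = categories.get(g)
            if cat is None:
                raise ValueError(f"group {g!r} has no declared category")
            if cat == "unexplained":
                row["unexplained"] = d
            else:
                sums[cat] += d
        row.update(sums)
        row.setdefault("unexplained", 0.0)
        row["shared"] = res.shared
        row["residual"] = res.residual
        rows.append(row)
    per_roi = pd.DataFrame(rows)
    value_cols = [c for c in per_roi.columns if c not in ("roi_id", "roi_source_group")]
    return per_roi.groupby("roi_source_group", sort=True)[value_cols].mean()
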