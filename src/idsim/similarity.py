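"""Pairwise similarity vectors over unordered subject pairs.

Every regressor and the regressand live on the same index of unordered
subject pairs (i < j, lexicographic). Neural patterns are compared by
Euclidean distance; univariate scores by absolute difference; per-video
rating profiles by three components (Pearson r of the 32-video profiles,
absolute difference of profile means, absolute difference of profile
standard deviations).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

DISTANCE = "distance"
SIMILARITY = "similarity"


@dataclass(frozen=True)
class PairIndex:
    """Lexicographic unordered pairs over n subjects.

    ``pairs`` holds 0-based positions into ``subject_ids``; each subject
    appears in exactly n-1 pairs.
    """

    subject_ids: tuple[str, ...]
    pairs: np.ndarray = field(repr=False)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def build_pair_index(subject_ids: Sequence) -> PairIndex:
    """All unordered pairs (i, j), i < j, in lexicographic position order."""
    n = len(subject_ids)
    if n < 2:
        raise ValueError(f"need at least 2 subjects, got {n}")
    if len(set(subject_ids)) != n:
        raise ValueError("subject ids are not unique")
    pairs = np.array([(i, j) for i in range(n) for j in range(i + 1, n)], dtype=int)
    pairs.setflags(write=False)
    return PairIndex(subject_ids=tuple(str(s) for s in subject_ids), pairs=pairs)


@dataclass(frozen=True)
class SimilarityVector:
    """One regressor's value per unordered pair, with orientation metadata."""

    name: str
    orientation: str
    values: np.ndarray = field(repr=False)
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.orientation not in (DISTANCE, SIMILARITY):
            raise ValueError(f"orientation must be distance|similarity, got {self.orientation!r}")
        vals = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite values in similarity vector {self.name!r}")
        object.__setattr__(self, "values", vals)
        vals.setflags(write=False)


def pattern_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Euclidean distance between two activity patterns."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"pattern length mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


def pattern_similarity(
    patterns: np.ndarray, index: PairIndex, name: str, provenance: str = ""
) -> SimilarityVector:
    """Pairwise Euclidean distances between the rows of ``patterns``.

    ``patterns`` is (n_subjects, n_voxels) in PairIndex subject order;
    the condensed pdist order coincides with the lexicographic pair order.
    """
    patterns = np.asarray(patterns, dtype=float)
    if patterns.shape[0] != index.n_subjects:
        raise ValueError(
            f"{name}: expected {index.n_subjects} subject rows, got {patterns.shape[0]}"
        )
    return SimilarityVector(name=name, orientation=DISTANCE, values=pdist(patterns), provenance=provenance)


def univariate_similarity(
    scores: Sequence[float], index: PairIndex, name: str, provenance: str = ""
) -> SimilarityVector:
    """|score_i - score_j| per pair (the intrinsic-measure similarity)."""
    s = np.asarray(scores, dtype=float)
    if len(s) != index.n_subjects:
        raise ValueError(f"{name}: expected {index.n_subjects} scores, got {len(s)}")
    if np.any(np.isnan(s)):
        raise ValueError(f"{name}: missing score; imputation must precede similarity")
    i, j = index.pairs[:, 0], index.pairs[:, 1]
    return SimilarityVector(name=name, orientation=DISTANCE, values=np.abs(s[i] - s[j]), provenance=provenance)


def rating_profile_similarity(
    ratings: np.ndarray | pd.DataFrame, index: PairIndex, name: str
) -> tuple[SimilarityVector, SimilarityVector, SimilarityVector]:
    """Three-way similarity of per-video rating profiles.

    Per pair: Pearson r of the two video profiles (similarity-oriented),
    |Δ profile mean| and |Δ profile sd| (distance-oriented; sd uses the
    n-1 denominator). Profiles must be complete; a zero-variance profile
    has no defined correlation and is an error.
    """
    mat = np.asarray(ratings, dtype=float)
    if mat.shape[0] != index.n_subjects:
        raise ValueError(f"{name}: expected {index.n_subjects} subject rows, got {mat.shape[0]}")
    if mat.shape[1] < 3:
        raise ValueError(f"{name}: need at least 3 videos, got {mat.shape[1]}")
    if np.any(np.isnan(mat)):
        raise ValueError(f"{name}: missing ratings; imputation must precede similarity")
    sds = mat.std(axis=1, ddof=1)
    if np.any(sds == 0):
        bad = index.subject_ids[int(np.flatnonzero(sds == 0)[0])]
        raise ValueError(f"{name}: zero-variance rating profile for subject {bad}")
    i, j = index.pairs[:, 0], index.pairs[:, 1]
    corr = np.corrcoef(mat)
    r = SimilarityVector(
        name=f"{name}_r", orientation=SIMILARITY, values=corr[i, j], provenance=f"{name} profile correlation"
    )
    means = mat.mean(axis=1)
    dmean = SimilarityVector(
        name=f"{name}_dmean", orientation=DISTANCE, values=np.abs(means[i] - means[j]),
        provenance=f"{name} |difference of profile means|",
    )
    dsd = SimilarityVector(
        name=f"{name}_dsd", orientation=DISTANCE, values=np.abs(sds[i] - sds[j]),
        provenance=f"{name} |difference of profile sds|",
    )
    return r, dmean, dsd


def orient(vec: SimilarityVector) -> SimilarityVector:
    """Map similarity-oriented vectors to distance orientation (r -> 1 - r).

    Distance-oriented vectors pass through unchanged. The transform is
    affine, so unique-variance partitions downstream are unaffected; it
    exists so every reported regressor reads as a dissimilarity.
    """
    if vec.orientation == DISTANCE:
        return vec
    return replace(
        vec,
        orientation=DISTANCE,
        values=1.0 - vec.values,
        provenance=(vec.provenance + "; oriented as 1-r").strip("; "),
    )


def permute_similarity(vec: SimilarityVector, index: PairIndex, perm: np.ndarray) -> SimilarityVector:
    """Similarity vector after relabeling subjects by permutation ``perm``.

    ``perm[k]`` is the subject (position) whose data subject k receives.
    Because every similarity here depends only on the unordered pair of
    subject-level data, reindexing the symmetric pair matrix is exactly
    equivalent to recomputing the similarity from permuted subject data.
    """
    perm = np.asarray(perm, dtype=int)
    if sorted(perm.tolist()) != list(range(index.n_subjects)):
        raise ValueError("perm is not a permutation of the subject positions")
    mat = squareform(vec.values, checks=False)
    permuted = mat[np.ix_(perm, perm)]
    i, j = index.pairs[:, 0], index.pairs[:, 1]
    return replace(vec, values=permuted[i, j])


def similarity_frame(vectors: Sequence[SimilarityVector], index: PairIndex) -> pd.DataFrame:
    """Serialize similarity vectors to long form: pair_i, pair_j, name, value, orientation."""
    rows = []
    ids = index.subject_ids
    for vec in vectors:
        for (i, j), v in zip(index.pairs, vec.values):
            rows.append(
                {"pair_i": ids[i], "pair_j": ids[j], "name": vec.name, "value": v, "orientation": vec.orientation}
            )
    return pd.DataFrame(rows)
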