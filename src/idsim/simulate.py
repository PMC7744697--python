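"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates the study design this pipeline targets: 28
subjects viewing 32 PSAs, 23 ROIs of 25 voxels each on a 5 mm MNI-like
grid, a whole-brain contrast map with the ROI patterns embedded in a
noise field, control-condition and structural maps, Likert-bounded
per-video ratings with completely-at-random missingness, and item-level
intrinsic scale responses — plus a controllable latent-trait → pattern
coupling so that parameter recovery and null calibration are testable.

The coupling model per ROI r with driver variable v is

    pattern_s = template_r + γ_v · t_s · direction_r + ε,   ε ~ N(0, σ² I),

with t_s the subject's standardized latent trait and direction_r a unit
vector, so the expected squared pair distance is γ²(t_i − t_j)² + 2σ²V.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import measures as me
from .roi_patterns import (
    GridSpec,
    ROISpec,
    VoxelMap,
    build_roi_mask,
    load_voxel_map_nifti,
    load_voxel_map_tsv,
    mm_to_voxel,
    read_roi_table,
    save_voxel_map_nifti,
    save_voxel_map_tsv,
    write_roi_table,
)

#: latent variables the generator knows how to couple to patterns
INTRINSIC_VARIABLES = ("MJrisk", "SSscore", "Compliance")
RATING_VARIABLES = ("pMSV", "pAS", "AdLike", "pos", "neg", "ThVal")
ALL_VARIABLES = INTRINSIC_VARIABLES + RATING_VARIABLES

DEFAULT_GRID = GridSpec.from_origin(
    origin_mm=(-90.0, -126.0, -72.0), voxel_size=(5.0, 5.0, 5.0), dims=(36, 44, 36)
)

_SCALE_BY_NAME = {s.name: s for s in me.DEFAULT_SCALES}


@dataclass(frozen=True)
class SyntheticConfig:
    """Conditions of the emulated study; defaults mirror its design."""

    n_subjects: int = 28
    n_videos: int = 32
    roi_specs: tuple[ROISpec, ...] | None = None  # None -> packaged 23-ROI table
    mask_radius: int = 2  # 25 voxels per ROI
    wholebrain_voxels: int = 4000
    trait_effects: Mapping[str, float] = field(default_factory=dict)
    rating_effects: Mapping[str, float] = field(default_factory=dict)
    drivers: Mapping[int, str] = field(default_factory=dict)  # roi_id -> variable
    noise_sd: float = 1.0
    missing_rate: float = 0.02
    grid: GridSpec = DEFAULT_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2 or self.n_videos < 3:
            raise ValueError("need n_subjects >= 2 and n_videos >= 3")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.missing_rate <= 0.2:
            raise ValueError("missing_rate must be in [0, 0.2]")
        if self.mask_radius < 0:
            raise ValueError("mask_radius must be >= 0")
        for rid, var in self.drivers.items():
            if var not in ALL_VARIABLES:
                raise ValueError(f"unknown driver variable {var!r} for ROI {rid}")
        bad = [v for v in {**self.trait_effects, **self.rating_effects} if v not in ALL_VARIABLES]
        if bad:
            raise ValueError(f"unknown effect variable(s): {bad}")

    def effect_size(self, variable: str) -> float:
        if variable in self.trait_effects:
            return float(self.trait_effects[variable])
        return float(self.rating_effects.get(variable, 0.0))


@dataclass
class SyntheticCohort:
    """A complete generated dataset plus its ground truth."""

    config: SyntheticConfig
    subject_ids: tuple[str, ...]
    roi_specs: tuple[ROISpec, ...]
    grid: GridSpec
    maps: dict[str, dict[str, VoxelMap]]  # map_kind -> subject_id -> map
    brain_mask: np.ndarray  # (m, 3) voxel coordinates used for whole-brain vectors
    intrinsic_items: pd.DataFrame  # subject x item responses
    ratings: pd.DataFrame  # long format with NaN for missing
    latent_traits: pd.DataFrame  # subject x variable (standardized ground truth)
    ground_truth: dict


def gamma_for_variance_fraction(fraction: float, noise_sd: float, n_voxels: int) -> float:
    """Effect size at which the trait explains ``fraction`` of pattern variance.

    Signal variance across subjects is γ² (unit direction); noise variance
    totals V·σ². Solving γ²/(γ² + Vσ²) = fraction gives the returned γ.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    return noise_sd * np.sqrt(n_voxels * fraction / (1.0 - fraction))


def expected_pair_distance(gamma: float, t_i: float, t_j: float, sigma: float, n_voxels: int) -> float:
    """√E[squared pair distance] = √(γ²(t_i − t_j)² + 2σ²V)."""
    if sigma < 0 or n_voxels < 1:
        raise ValueError("need sigma >= 0 and n_voxels >= 1")
    return float(np.sqrt(gamma**2 * (t_i - t_j) ** 2 + 2.0 * sigma**2 * n_voxels))


def _standardize(u: np.ndarray) -> np.ndarray:
    return (u - u.mean()) / u.std()


def _clip(x: np.ndarray, bounds: tuple[float, float]) -> np.ndarray:
    return np.clip(x, bounds[0], bounds[1])


def _gen_intrinsic_items(rng: np.random.Generator, u: Mapping[str, np.ndarray], n: int) -> pd.DataFrame:
    """Integer item responses whose scale score recovers the latent trait."""
    cols = {}
    for name in INTRINSIC_VARIABLES:
        scale = _SCALE_BY_NAME[name]
        lo, hi = scale.response_range
        mid = (lo + hi) / 2.0
        for item in scale.item_ids:
            raw = mid + 0.8 * u[name] + rng.normal(0.0, 0.6, size=n)
            cols[item] = np.clip(np.round(raw), lo, hi).astype(float)
    return pd.DataFrame(cols)


def _gen_ratings(
    rng: np.random.Generator, u: Mapping[str, np.ndarray], config: SyntheticConfig
) -> pd.DataFrame:
    """Long-format rating table (continuous values clipped to Likert bounds)."""
    n, n_vid = config.n_subjects, config.n_videos
    rows: list[tuple[int, int, str, str, float]] = []

    def emit(measure: str, item: str, values: np.ndarray) -> None:
        for s in range(n):
            for k in range(n_vid):
                rows.append((s, k + 1, measure, item, values[s, k]))

    def profile(subject_effect: np.ndarray, center: float, bounds: tuple[float, float]) -> np.ndarray:
        video = rng.normal(0.0, 0.5, size=n_vid)
        noise = rng.normal(0.0, 0.7, size=(n, n_vid))
        return _clip(center + subject_effect[:, None] + video[None, :] + noise, bounds)

    emit("pMSV", "", profile(0.8 * u["pMSV"], 3.0, me.RATING_BOUNDS["pMSV"]))
    emit("pAS", "", profile(0.8 * u["pAS"], 3.0, me.RATING_BOUNDS["pAS"]))
    emit("AdLike", "", profile(0.8 * u["AdLike"], 4.0, me.RATING_BOUNDS["AdLike"]))
    for item in me.POSITIVE_EMOTION_ITEMS:
        emit("emotion", item, profile(0.5 * u["pos"], 2.5, me.RATING_BOUNDS["emotion"]))
    for item in me.NEGATIVE_EMOTION_ITEMS:
        emit("emotion", item, profile(0.5 * u["neg"], 2.5, me.RATING_BOUNDS["emotion"]))
    for item in me.UNUSED_EMOTION_ITEMS:
        emit("emotion", item, profile(np.zeros(n), 2.5, me.RATING_BOUNDS["emotion"]))
    emit("thought", "stay_away", profile(0.6 * u["ThVal"], 4.0, me.RATING_BOUNDS["thought"]))
    emit("thought", "want_try", profile(-0.6 * u["ThVal"], 4.0, me.RATING_BOUNDS["thought"]))

    df = pd.DataFrame(rows, columns=["subject_pos", "video_id", "measure", "item", "value"])
    if config.missing_rate > 0:
        miss = rng.random(len(df)) < config.missing_rate
        df.loc[miss, "value"] = np.nan
    return df


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Draw one complete cohort. Bit-identical for a fixed config/seed."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.n_subjects
    subject_ids = tuple(f"S{i + 1:02d}" for i in range(n))
    roi_specs = tuple(config.roi_specs) if config.roi_specs is not None else tuple(read_roi_table())
    grid = config.grid
    sigma = config.noise_sd

    # latent traits: one standard-normal latent per variable, standardized
    u_raw = {v: rng.normal(size=n) for v in ALL_VARIABLES}
    traits = {v: _standardize(u_raw[v]) for v in ALL_VARIABLES}

    intrinsic = _gen_intrinsic_items(rng, u_raw, n)
    intrinsic.index = pd.Index(subject_ids, name="subject_id")
    ratings = _gen_ratings(rng, u_raw, config)
    ratings["subject_id"] = [subject_ids[s] for s in ratings.pop("subject_pos")]
    ratings = ratings[["subject_id", "video_id", "measure", "item", "value"]]

    # ROI masks on the grid
    masks = {spec.id: build_roi_mask(mm_to_voxel(spec.center_mm, grid), config.mask_radius) for spec in roi_specs}
    V = len(next(iter(masks.values()))) if masks else 0

    # brain mask: all ROI voxels plus random in-grid voxels up to the target count
    roi_voxels = (
        np.unique(np.vstack(list(masks.values())), axis=0) if masks else np.empty((0, 3), dtype=int)
    )
    total = int(np.prod(grid.dims))
    roi_flat = set(np.ravel_multi_index(roi_voxels.T, grid.dims).tolist()) if len(roi_voxels) else set()
    extra_needed = max(config.wholebrain_voxels - len(roi_flat), 0)
    candidates = np.setdiff1d(np.arange(total), np.fromiter(roi_flat, dtype=int, count=len(roi_flat)))
    chosen = rng.choice(candidates, size=min(extra_needed, len(candidates)), replace=False)
    brain_flat = np.sort(np.concatenate([np.fromiter(roi_flat, dtype=int, count=len(roi_flat)), chosen]))
    brain_mask = np.column_stack(np.unravel_index(brain_flat, grid.dims)).astype(int)

    # per-ROI templates and signal directions
    templates = {rid: rng.normal(0.0, 1.0, size=V) for rid in masks}
    directions = {}
    for rid in masks:
        d = rng.normal(size=V)
        directions[rid] = d / np.linalg.norm(d)

    # contrast maps: whole-brain noise field with ROI patterns embedded
    contrast = rng.normal(0.0, sigma, size=(n,) + grid.dims)
    planted: dict[int, dict] = {}
    for spec in roi_specs:
        rid = spec.id
        mask = masks[rid]
        var = config.drivers.get(rid)
        gamma = config.effect_size(var) if var else 0.0
        t = traits[var] if var else np.zeros(n)
        pat = templates[rid][None, :] + gamma * t[:, None] * directions[rid][None, :] + rng.normal(
            0.0, sigma, size=(n, V)
        )
        contrast[:, mask[:, 0], mask[:, 1], mask[:, 2]] = pat
        if var and gamma > 0:
            planted[rid] = {"variable": var, "gamma": gamma}

    # control-condition and structural maps: no trait coupling
    scram_t = rng.normal(0.0, 1.0, size=grid.dims)
    blank_t = rng.normal(0.0, 1.0, size=grid.dims)
    scrambled = scram_t[None] + rng.normal(0.0, sigma, size=(n,) + grid.dims)
    blank = blank_t[None] + rng.normal(0.0, sigma, size=(n,) + grid.dims)
    gm_template = rng.uniform(0.2, 0.8, size=grid.dims)  # gray-matter probability field
    structural = np.clip(gm_template[None] + rng.normal(0.0, 0.1, size=(n,) + grid.dims), 0.0, 1.0)

    maps: dict[str, dict[str, VoxelMap]] = {k: {} for k in ("contrast_msvxas", "control_scrambled", "control_blank", "structural_seg")}
    arrays = {
        "contrast_msvxas": contrast,
        "control_scrambled": scrambled,
        "control_blank": blank,
        "structural_seg": structural,
    }
    for kind, arr in arrays.items():
        for s, sid in enumerate(subject_ids):
            maps[kind][sid] = VoxelMap(subject_id=sid, map_kind=kind, grid=grid, values=arr[s])

    ground_truth = {
        "seed": config.seed,
        "n_subjects": n,
        "n_videos": config.n_videos,
        "noise_sd": sigma,
        "voxels_per_roi": V,
        "planted_effects": {str(rid): info for rid, info in sorted(planted.items())},
        "latent_traits": {v: traits[v].tolist() for v in ALL_VARIABLES},
    }
    return SyntheticCohort(
        config=config,
        subject_ids=subject_ids,
        roi_specs=roi_specs,
        grid=grid,
        maps=maps,
        brain_mask=brain_mask,
        intrinsic_items=intrinsic,
        ratings=ratings,
        latent_traits=pd.DataFrame(traits, index=list(subject_ids)),
        ground_truth=ground_truth,
    )


def miniature_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A fast, small configuration: 8 subjects, 4 ROIs, 8 videos.

    One ROI per source bucket plus an extra exploratory ROI; used for
    smoke tests and examples where the study-scale cohort would be slow.
    """
    specs = tuple(s for s in read_roi_table() if s.id in (1, 6, 13, 22))
    defaults = dict(
        n_subjects=8,
        n_videos=8,
        roi_specs=specs,
        wholebrain_voxels=400,
        missing_rate=0.02,
        seed=seed,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


# ---------------------------------------------------------------------------
# fixture IO


def write_fixture(cohort: SyntheticCohort, directory: str | Path, map_format: str = "tsv") -> None:
    """Write a cohort to disk in the pipeline's input formats.

    map_format 'tsv' writes plain-text maps with JSON sidecars; 'nifti'
    writes .nii.gz. Ground truth goes to ground_truth.json.
    """
    directory = Path(directory)
    (directory / "maps").mkdir(parents=True, exist_ok=True)
    if map_format not in ("tsv", "nifti"):
        raise ValueError(f"unknown map format {map_format!r}")
    for kind, by_subject in cohort.maps.items():
        for sid, vmap in by_subject.items():
            if map_format == "tsv":
                save_voxel_map_tsv(vmap, directory / "maps" / f"{sid}_{kind}.tsv")
            else:
                save_voxel_map_nifti(vmap, directory / "maps" / f"{sid}_{kind}.nii.gz")
    write_roi_table(cohort.roi_specs, directory / "roi_table.tsv")
    cohort.intrinsic_items.to_csv(directory / "intrinsic_items.csv")
    cohort.ratings.to_csv(directory / "ratings.csv", index=False)
    np.savetxt(directory / "brain_mask.tsv", cohort.brain_mask, fmt="%d", delimiter="\t")
    meta = {
        "subject_ids": list(cohort.subject_ids),
        "map_format": map_format,
        "mask_radius": cohort.config.mask_radius,
        "n_videos": cohort.config.n_videos,
        "grid": {
            "dims": list(cohort.grid.dims),
            "voxel_size": list(cohort.grid.voxel_size),
            "affine": cohort.grid.affine.tolist(),
        },
    }
    (directory / "cohort.json").write_text(json.dumps(meta, indent=1))
    (directory / "ground_truth.json").write_text(json.dumps(cohort.ground_truth, indent=1))


def read_fixture(directory: str | Path) -> SyntheticCohort:
    """Read a written fixture back into a cohort object."""
    directory = Path(directory)
    meta = json.loads((directory / "cohort.json").read_text())
    grid = GridSpec(
        dims=tuple(meta["grid"]["dims"]),
        voxel_size=tuple(meta["grid"]["voxel_size"]),
        affine=np.asarray(meta["grid"]["affine"]),
    )
    subject_ids = tuple(meta["subject_ids"])
    roi_specs = tuple(read_roi_table(directory / "roi_table.tsv"))
    maps: dict[str, dict[str, VoxelMap]] = {}
    for kind in ("contrast_msvxas", "control_scrambled", "control_blank", "structural_seg"):
        maps[kind] = {}
        for sid in subject_ids:
            if meta["map_format"] == "tsv":
                vmap = load_voxel_map_tsv(directory / "maps" / f"{sid}_{kind}.tsv")
            else:
                vmap = load_voxel_map_nifti(directory / "maps" / f"{sid}_{kind}.nii.gz", sid, kind)
            maps[kind][sid] = vmap
    intrinsic = pd.read_csv(directory / "intrinsic_items.csv", index_col="subject_id")
    ratings = pd.read_csv(
        directory / "ratings.csv", dtype={"item": str}, keep_default_na=True
    )
    ratings["item"] = ratings["item"].fillna("")
    brain_mask = np.loadtxt(directory / "brain_mask.tsv", dtype=int, delimiter="\t").reshape(-1, 3)
    ground_truth = json.loads((directory / "ground_truth.json").read_text())
    config = SyntheticConfig(
        n_subjects=len(subject_ids),
        n_videos=int(meta["n_videos"]),
        roi_specs=roi_specs,
        mask_radius=int(meta["mask_radius"]),
        wholebrain_voxels=len(brain_mask),
        noise_sd=float(ground_truth.get("noise_sd", 1.0)),
        grid=grid,
        seed=int(ground_truth.get("seed", 0)),
    )
    traits = ground_truth.get("latent_traits", {})
    return SyntheticCohort(
        config=config,
        subject_ids=subject_ids,
        roi_specs=roi_specs,
        grid=grid,
        maps=maps,
        brain_mask=brain_mask,
        intrinsic_items=intrinsic,
        ratings=ratings,
        latent_traits=pd.DataFrame(traits, index=list(subject_ids)) if traits else pd.DataFrame(index=list(subject_ids)),
        ground_truth=ground_truth,
    )
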