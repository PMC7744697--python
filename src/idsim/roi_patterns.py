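"""ROI masks and per-subject activity-pattern extraction.

Regions of interest are small Manhattan-distance balls around peak
coordinates (given in MNI mm); patterns are the map values at the mask
voxels, in a fixed voxel order shared across subjects, so that pairwise
pattern distances are well defined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MAP_KINDS = ("contrast_msvxas", "control_scrambled", "control_blank", "structural_seg")
ROI_SOURCES = ("a_priori", "exploratory", "confirmatory")


class CoordinateOutsideGridError(ValueError):
    """An mm coordinate or mask voxel falls outside the voxel grid."""


@dataclass(frozen=True)
class GridSpec:
    """A 3-D voxel grid with an affine mapping voxel indices to mm.

    Parameters
    ----------
    dims:
        Number of voxels along each axis.
    voxel_size:
        Voxel edge length in mm along each axis (strictly positive).
    affine:
        4x4 homogeneous affine taking 0-based voxel indices to mm
        coordinates. A 3x4 array is accepted and promoted.
    """

    dims: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    affine: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        if len(dims) != 3 or any(d <= 0 for d in dims):
            raise ValueError(f"dims must be 3 positive integers, got {self.dims!r}")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be strictly positive, got {self.voxel_size!r}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape == (3, 4):
            aff = np.vstack([aff, [0.0, 0.0, 0.0, 1.0]])
        if aff.shape != (4, 4):
            raise ValueError(f"affine must be 3x4 or 4x4, got shape {aff.shape}")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine 3x3 part is singular")
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "voxel_size", vs)
        object.__setattr__(self, "affine", aff)
        aff.setflags(write=False)

    @classmethod
    def from_origin(
        cls,
        origin_mm: Sequence[float],
        voxel_size: Sequence[float],
        dims: Sequence[int],
    ) -> "GridSpec":
        """Axis-aligned grid: voxel (0,0,0) maps to ``origin_mm``."""
        vs = [float(v) for v in voxel_size]
        aff = np.diag(vs + [1.0])
        aff[:3, 3] = [float(o) for o in origin_mm]
        return cls(dims=tuple(int(d) for d in dims), voxel_size=tuple(vs), affine=aff)

    def voxel_to_mm(self, ijk: Sequence[float]) -> np.ndarray:
        v = np.asarray(ijk, dtype=float)
        return self.affine[:3, :3] @ v + self.affine[:3, 3]

    def contains(self, ijk: Sequence[int]) -> bool:
        v = np.asarray(ijk)
        return bool(np.all(v >= 0) and np.all(v < np.asarray(self.dims)))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GridSpec):
            return NotImplemented
        return (
            self.dims == other.dims
            and self.voxel_size == other.voxel_size
            and np.allclose(self.affine, other.affine)
        )

    def __hash__(self) -> int:
        return hash((self.dims, self.voxel_size, self.affine.tobytes()))


@dataclass(frozen=True)
class ROISpec:
    """One region-of-interest peak: id, provenance bucket, MNI mm center."""

    id: int
    source: str
    center_mm: tuple[float, float, float]
    label: str = ""

    def __post_init__(self) -> None:
        if self.source not in ROI_SOURCES:
            raise ValueError(f"unknown ROI source {self.source!r}; expected one of {ROI_SOURCES}")


@dataclass
class VoxelMap:
    """One subject's values on a shared grid (contrast, control, or structural)."""

    subject_id: str
    map_kind: str
    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.map_kind not in MAP_KINDS:
            raise ValueError(f"unknown map_kind {self.map_kind!r}; expected one of {MAP_KINDS}")
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != self.grid.dims:
            raise ValueError(f"values shape {vals.shape} does not match grid dims {self.grid.dims}")
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite values in map {self.map_kind!r} of {self.subject_id!r}")
        self.values = vals


@dataclass(frozen=True)
class ROIPattern:
    """One subject's activity pattern inside one ROI mask (fixed voxel order)."""

    subject_id: str
    roi_id: int
    values: np.ndarray


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # numpy's round() is banker's rounding; ties here must break away from zero
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def mm_to_voxel(coord_mm: Sequence[float], grid: GridSpec) -> tuple[int, int, int]:
    """Map an mm coordinate to the nearest 0-based lattice point of ``grid``.

    Raises :class:`CoordinateOutsideGridError` if the rounded point falls
    outside the grid.
    """
    mm = np.asarray(coord_mm, dtype=float)
    inv = np.linalg.inv(grid.affine)
    ijk = _round_half_away(inv[:3, :3] @ mm + inv[:3, 3]).astype(int)
    if not grid.contains(ijk):
        raise CoordinateOutsideGridError(
            f"coordinate outside grid: {tuple(mm.tolist())} mm -> voxel {tuple(ijk.tolist())}, "
            f"grid dims {grid.dims}"
        )
    return tuple(int(i) for i in ijk)


def manhattan_ball_size(radius: int) -> int:
    """Closed-form voxel count of the L1 ball: (2r+1)(2r^2+2r+3)/3."""
    r = int(radius)
    return (2 * r + 1) * (2 * r * r + 2 * r + 3) // 3


def build_roi_mask(center_voxel: Sequence[int], radius: int) -> np.ndarray:
    """All lattice points within L1 distance ``radius`` of the center.

    Returned as an (m, 3) int array ordered lexicographically by offset
    (dx, dy, dz), so the voxel order is identical for every subject and
    every center. radius=2 gives the 25-voxel mask used throughout.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    c = np.asarray(center_voxel, dtype=int)
    offsets = []
    r = int(radius)
    for dx in range(-r, r + 1):
        for dy in range(-r + abs(dx), r - abs(dx) + 1):
            rem = r - abs(dx) - abs(dy)
            for dz in range(-rem, rem + 1):
                offsets.append((dx, dy, dz))
    return c + np.array(sorted(offsets), dtype=int)


def extract_pattern(vmap: VoxelMap, mask: np.ndarray, roi_id: int = -1) -> ROIPattern:
    """Read the map values at the mask voxels, in mask order.

    A mask voxel outside the grid is an error; masks are never clipped,
    because clipping would silently change pattern dimensionality.
    """
    mask = np.asarray(mask, dtype=int)
    dims = np.asarray(vmap.grid.dims)
    if np.any(mask < 0) or np.any(mask >= dims):
        bad = mask[np.any((mask < 0) | (mask >= dims), axis=1)][0]
        raise CoordinateOutsideGridError(
            f"mask exceeds grid: voxel {tuple(bad.tolist())} outside dims {vmap.grid.dims}"
        )
    vals = vmap.values[mask[:, 0], mask[:, 1], mask[:, 2]]
    return ROIPattern(subject_id=vmap.subject_id, roi_id=roi_id, values=np.asarray(vals, dtype=float))


def roi_mask_for_spec(spec: ROISpec, grid: GridSpec, radius: int = 2) -> np.ndarray:
    """Mask for one ROI: mm peak -> voxel center -> L1 ball."""
    center = mm_to_voxel(spec.center_mm, grid)
    return build_roi_mask(center, radius)


# ---------------------------------------------------------------------------
# IO


def read_roi_table(path: str | Path | None = None) -> list[ROISpec]:
    """Read the ROI peak table (TSV: id, source, x, y, z, label).

    With no path, the packaged 23-ROI table of peak coordinates is used.
    """
    if path is None:
        with resources.as_file(resources.files("idsim.data") / "roi_table.tsv") as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    required = {"id", "source", "x", "y", "z", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ROI table missing column(s): {sorted(missing)}")
    specs = [
        ROISpec(
            id=int(row.id),
            source=str(row.source),
            center_mm=(float(row.x), float(row.y), float(row.z)),
            label=str(row.label),
        )
        for row in df.itertuples()
    ]
    if len({s.id for s in specs}) != len(specs):
        raise ValueError("ROI ids are not unique")
    return specs


def write_roi_table(specs: Iterable[ROISpec], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {"id": s.id, "source": s.source, "x": s.center_mm[0], "y": s.center_mm[1], "z": s.center_mm[2], "label": s.label}
            for s in specs
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def save_voxel_map_nifti(vmap: VoxelMap, path: str | Path) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(vmap.values.astype(np.float64), vmap.grid.affine)
    nib.save(img, str(path))


def load_voxel_map_nifti(path: str | Path, subject_id: str, map_kind: str) -> VoxelMap:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    aff = np.asarray(img.affine, dtype=float)
    vs = tuple(float(v) for v in np.sqrt((aff[:3, :3] ** 2).sum(axis=0)))
    grid = GridSpec(dims=data.shape, voxel_size=vs, affine=aff)
    return VoxelMap(subject_id=subject_id, map_kind=map_kind, grid=grid, values=data)


def save_voxel_map_tsv(vmap: VoxelMap, path: str | Path) -> None:
    """Plain-text map: flattened values (C order) + sidecar JSON with the grid."""
    path = Path(path)
    np.savetxt(path, vmap.values.reshape(-1, 1), fmt="%.10g")
    sidecar = {
        "dims": list(vmap.grid.dims),
        "voxel_size": list(vmap.grid.voxel_size),
        "affine": vmap.grid.affine.tolist(),
        "subject_id": vmap.subject_id,
        "map_kind": vmap.map_kind,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_voxel_map_tsv(path: str | Path) -> VoxelMap:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    grid = GridSpec(
        dims=tuple(sidecar["dims"]),
        voxel_size=tuple(sidecar["voxel_size"]),
        affine=np.asarray(sidecar["affine"], dtype=float),
    )
    values = np.loadtxt(path).reshape(grid.dims)
    return VoxelMap(
        subject_id=sidecar["subject_id"],
        map_kind=sidecar["map_kind"],
        grid=grid,
        values=values,
    )
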