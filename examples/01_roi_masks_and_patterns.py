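"""ROI masks and pattern extraction.

Builds the Manhattan-ball mask used for every region of interest, maps an
MNI mm peak to voxel indices, and extracts one subject's activity pattern.
"""

import numpy as np

from idsim import build_roi_mask, extract_pattern, mm_to_voxel, read_roi_table
from idsim.roi_patterns import VoxelMap
from idsim.simulate import DEFAULT_GRID

for radius in range(5):
    print(f"Manhattan radius {radius}: {len(build_roi_mask((0, 0, 0), radius)):3d} voxels")
# radius 2 gives the 25-voxel mask used for every ROI

specs = read_roi_table()
spec = next(s for s in specs if s.label == "Striatum")
center = mm_to_voxel(spec.center_mm, DEFAULT_GRID)
print(f"\nROI {spec.id} ({spec.label}): peak {spec.center_mm} mm -> voxel {center}")

rng = np.random.default_rng(0)
vmap = VoxelMap("S01", "contrast_msvxas", DEFAULT_GRID, rng.normal(size=DEFAULT_GRID.dims))
pattern = extract_pattern(vmap, build_roi_mask(center, 2), roi_id=spec.id)
print(f"extracted pattern: {len(pattern.values)} voxel values, first three {pattern.values[:3].round(3)}")
print("(one such vector per subject per ROI is what enters the pairwise distances)")
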