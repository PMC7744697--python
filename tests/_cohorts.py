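"""Shared synthetic-cohort configurations for the test suite."""

from idsim.roi_patterns import GridSpec, ROISpec
from idsim.simulate import SyntheticConfig

#: compact grid for simulation-heavy tests: 20^3 voxels, 5 mm, centered on 0
SMALL_GRID = GridSpec.from_origin((-50.0, -50.0, -50.0), (5.0, 5.0, 5.0), (20, 20, 20))

SMALL_ROIS = (
    ROISpec(1, "a_priori", (0.0, 0.0, 0.0), "toy-apriori"),
    ROISpec(2, "exploratory", (20.0, 20.0, 20.0), "toy-exploratory"),
    ROISpec(3, "confirmatory", (-20.0, -20.0, 10.0), "toy-confirmatory"),
)


def small_cohort_config(seed: int, **overrides) -> SyntheticConfig:
    """Study-sized subject count on a compact grid; fast to generate."""
    defaults = dict(
        roi_specs=SMALL_ROIS,
        wholebrain_voxels=400,
        grid=SMALL_GRID,
        missing_rate=0.02,
        seed=seed,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)
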