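"""The seven published segmentation/merging parameter groups.

Groups differ in the gradient and region-growing band weights (order
density/height/classification); two priority-function schedules and
competition thresholds are in use (groups 1-4 one pair, groups 5-7 the
other); the four-round merging thresholds, maximum area (50 000 m^2)
and minimum mapping unit (500 m^2) are shared by all groups.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from lidarstands.segmentation import MergeParams, SegmentationParams


def load_parameter_file(path: str | Path | None = None, text: str | None = None) -> tuple[SegmentationParams, MergeParams]:
    """Load a (SegmentationParams, MergeParams) pair from a YAML file."""
    if text is None:
        with open(path) as fh:  # type: ignore[arg-type]
            text = fh.read()
    doc = yaml.safe_load(text)
    seg = doc["segmentation"]
    mrg = doc["merging"]
    seg_params = SegmentationParams(
        gradient_band_weights=tuple(seg["gradient_band_weights"]),
        region_growing_band_weights=tuple(seg["region_growing_band_weights"]),
        priority_function=tuple(seg["priority_function"]),
        competition_threshold=float(seg["competition_threshold"]),
        growth_scaling=seg.get("growth_scaling", "level_indexed"),
        metric=seg.get("metric", "l1"),
    )
    merge_params = MergeParams(
        rounds=tuple(
            (tuple(r["mean"]), tuple(r["std"])) for r in mrg["rounds"]
        ),
        band_weights=tuple(mrg["band_weights"]),
        maximum_area=float(mrg["maximum_area"]),
        small_segment_area=float(mrg["small_segment_area"]),
    )
    return seg_params, merge_params


def load_parameter_group(number: int) -> tuple[SegmentationParams, MergeParams]:
    """Load published parameter group 1..7."""
    if not 1 <= number <= 7:
        raise ValueError("parameter groups are numbered 1..7")
    text = resources.files(__package__).joinpath(f"group{number}.yaml").read_text()
    return load_parameter_file(text=text)
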