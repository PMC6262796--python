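"""Per-image tissue readouts: counts, clone ratios, marker ratios, spots.

Ratios with a zero denominator are reported as missing (None / NaN),
never coerced to 0; downstream statistics drop missing values per group.
"Area" ratios are computed on the full 3-D voxel volume by default, with
an optional max-projection 2-D mode for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from gutcount.core import ImageStack
from gutcount.segmentation import NucleusRecord

SUMMARY_COLUMNS = [
    "image_id",
    "group",
    "n_total",
    "n_clone",
    "clone_cell_ratio",
    "n_small_clone",
    "marker_cell_ratio",
    "positive_volume_ratio",
    "n_spots",
]


@dataclass
class SpotParams:
    threshold: float
    min_volume_um3: float = 0.0
    max_volume_um3: float = float("inf")

    def __post_init__(self) -> None:
        if self.min_volume_um3 > self.max_volume_um3:
            raise ValueError(
                f"min spot volume {self.min_volume_um3} exceeds max {self.max_volume_um3}"
            )


@dataclass
class TissueSummary:
    image_id: str
    group: str = ""
    n_total: int = 0
    n_clone: int = 0
    clone_cell_ratio: float | None = None
    n_small_clone: int = 0
    marker_cell_ratio: float | None = None
    positive_volume_ratio: float | None = None
    n_spots: int | None = None


def _kept(records: list[NucleusRecord]) -> list[NucleusRecord]:
    for r in records:
        if r.depth_kept is None:
            raise ValueError(
                f"nucleus {r.id} has no depth_kept flag; run the depth filter "
                "(or mark_all_kept) before counting"
            )
    return [r for r in records if r.depth_kept]


def count_cells(records: list[NucleusRecord]) -> tuple[int, int, int]:
    """(n_total, n_clone, n_small_clone) over depth-kept records only."""
    kept = _kept(records)
    for r in kept:
        if r.size_class is None or r.clone is None:
            raise ValueError(
                f"nucleus {r.id} is unclassified; run classify_size and "
                "classify_clone before counting"
            )
    n_total = len(kept)
    n_clone = sum(r.clone for r in kept)
    n_small_clone = sum(r.clone and r.size_class == "small" for r in kept)
    return n_total, n_clone, n_small_clone


def positive_volume_ratio(
    stack: ImageStack,
    positive_channel: str,
    tissue_channel: str = "all",
    positive_threshold: float = 0.0,
    tissue_threshold: float = 0.0,
    projection_2d: bool = False,
) -> float | None:
    """Positive-voxel count / tissue-voxel count (voxel volume cancels).

    ``tissue_channel="all"`` uses the whole domain as the tissue mask;
    otherwise the tissue mask is the thresholded tissue channel.  An
    empty tissue mask yields None with a warning.
    """
    positive = stack.channel(positive_channel) > positive_threshold
    if tissue_channel == "all":
        tissue = np.ones(stack.shape_zyx, dtype=bool)
    else:
        tissue = stack.channel(tissue_channel) > tissue_threshold
    if projection_2d:
        positive = positive.any(axis=0)
        tissue = tissue.any(axis=0)
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        warnings.warn("empty tissue mask; positive_volume_ratio undefined", stacklevel=2)
        return None
    return int((positive & tissue).sum()) / n_tissue


def marker_cell_ratio(
    records: list[NucleusRecord], marker_channel: str, threshold: float
) -> float | None:
    """Fraction of depth-kept nuclei whose marker mean is >= threshold."""
    kept = _kept(records)
    if not kept:
        return None
    n_pos = sum(r.mean_intensity[marker_channel] >= threshold for r in kept)
    return n_pos / len(kept)


def count_spots(stack: ImageStack, channel: str, spot_params: SpotParams) -> int:
    """Connected components of the thresholded channel whose volume lies
    in [min, max].  Spots fused below resolution count once."""
    mask = stack.channel(channel) > spot_params.threshold
    labels, n = ndimage.label(mask)
    if n == 0:
        return 0
    counts = np.bincount(labels.ravel())[1:]
    volumes = counts * stack.voxel_volume_um3
    return int(
        np.sum(
            (volumes >= spot_params.min_volume_um3)
            & (volumes <= spot_params.max_volume_um3)
        )
    )


def summarize(
    records: list[NucleusRecord],
    image_id: str,
    group: str = "",
    stack: ImageStack | None = None,
    positive_channel: str | None = None,
    tissue_channel: str = "all",
    positive_threshold: float = 0.0,
    marker_channel: str | None = None,
    marker_threshold: float = 0.0,
    spot_channel: str | None = None,
    spot_params: SpotParams | None = None,
) -> TissueSummary:
    """Assemble a TissueSummary from classified records and optional
    channel-level readouts."""
    n_total, n_clone, n_small_clone = count_cells(records)
    summary = TissueSummary(
        image_id=image_id,
        group=group,
        n_total=n_total,
        n_clone=n_clone,
        clone_cell_ratio=(n_clone / n_total) if n_total else None,
        n_small_clone=n_small_clone,
    )
    if marker_channel is not None:
        summary.marker_cell_ratio = marker_cell_ratio(
            records, marker_channel, marker_threshold
        )
    if stack is not None and positive_channel is not None:
        summary.positive_volume_ratio = positive_volume_ratio(
            stack, positive_channel, tissue_channel, positive_threshold
        )
    if stack is not None and spot_channel is not None and spot_params is not None:
        summary.n_spots = count_spots(stack, spot_channel, spot_params)
    return summary
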