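"""Size class, clone membership and depth filtering for measured nuclei.

The volume cut between small (progenitor-like) and big (enterocyte-like)
nuclei defaults to 90 um3 but can be optimised per image, as can the
green-intensity cut for clone membership.  Ties classify upward: a
nucleus exactly at a threshold is big / clone-positive.

Depth filtering keeps only nuclei whose centroid lies in the
coverslip-proximal half of the physical z extent, to avoid
depth-dependent signal loss; the midplane itself is excluded
(half-open interval).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from gutcount.core import ImageStack
from gutcount.segmentation import NucleusRecord

AUTO_METHODS = ("otsu_1d", "kmeans2")
FALLBACK_VOLUME_THRESHOLD_UM3 = 90.0


class ThresholdError(ValueError):
    """1-D threshold optimisation is impossible on the given values."""


@dataclass
class ClassifierParams:
    volume_threshold_um3: float | str = "auto"  # "auto" or a number; fallback 90.0
    clone_intensity_threshold: float | str = "auto"
    # used when per-image auto optimisation is impossible (e.g. an image
    # whose nuclei are all clone or all non-clone); None re-raises
    clone_fallback_threshold: float | None = None
    size_auto_method: str = "kmeans2"  # applied to log-volumes
    clone_auto_method: str = "otsu_1d"
    depth_filter: bool = True

    def __post_init__(self) -> None:
        for name in ("volume_threshold_um3", "clone_intensity_threshold"):
            v = getattr(self, name)
            if isinstance(v, str):
                if v != "auto":
                    raise ValueError(f"{name} must be a number or 'auto', got {v!r}")
            elif v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        for name in ("size_auto_method", "clone_auto_method"):
            if getattr(self, name) not in AUTO_METHODS:
                raise ValueError(
                    f"{name} must be one of {AUTO_METHODS}, got {getattr(self, name)!r}"
                )


def optimize_threshold_1d(values, method: str = "kmeans2") -> float:
    """Two-class threshold over a 1-D sample.

    ``otsu_1d`` exhaustively maximises the between-class variance over
    all midpoints between consecutive sorted distinct values.
    ``kmeans2`` runs deterministic 1-D Lloyd iterations initialised at
    the sample min and max and returns the midpoint of the two final
    cluster means.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size < 2 or np.unique(x).size < 2:
        raise ThresholdError(
            "need at least 2 distinct values to optimise a threshold; "
            "use the fixed fallback instead"
        )
    if method == "otsu_1d":
        xs = np.sort(x)
        n = xs.size
        best_cut, best_var = None, -np.inf
        for i in range(1, n):
            if xs[i] == xs[i - 1]:
                continue
            lo, hi = xs[:i], xs[i:]
            w0, w1 = lo.size / n, hi.size / n
            var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
            if var > best_var:
                best_var = var
                best_cut = 0.5 * (xs[i - 1] + xs[i])
        return float(best_cut)
    if method == "kmeans2":
        c0, c1 = float(x.min()), float(x.max())
        for _ in range(100):
            assign = np.abs(x - c0) <= np.abs(x - c1)
            n0, n1 = float(c0), float(c1)
            if assign.any():
                n0 = float(x[assign].mean())
            if (~assign).any():
                n1 = float(x[~assign].mean())
            if n0 == c0 and n1 == c1:
                break
            c0, c1 = n0, n1
        return 0.5 * (c0 + c1)
    raise ValueError(f"unknown method {method!r}; expected one of {AUTO_METHODS}")


def classify_size(
    records: list[NucleusRecord], params: ClassifierParams
) -> tuple[list[NucleusRecord], float]:
    """Assign size_class in place; returns (records, threshold used).

    ``big`` when volume >= threshold, else ``small``.  With "auto" the
    cut is optimised on this image's log-volumes; the optimisation falls
    back to the fixed 90 um3 anchor when it fails or lands outside the
    data range.
    """
    if not records:
        return records, _resolve_volume_threshold([], params)
    volumes = np.array([r.volume_um3 for r in records])
    threshold = _resolve_volume_threshold(volumes, params)
    for r in records:
        r.size_class = "big" if r.volume_um3 >= threshold else "small"
    return records, threshold


def _resolve_volume_threshold(volumes, params: ClassifierParams) -> float:
    if params.volume_threshold_um3 != "auto":
        return float(params.volume_threshold_um3)
    volumes = np.asarray(volumes, dtype=np.float64)
    if volumes.size:
        try:
            cut = math.exp(
                optimize_threshold_1d(np.log(volumes), params.size_auto_method)
            )
            if volumes.min() < cut <= volumes.max():
                return cut
        except ThresholdError:
            pass
    return FALLBACK_VOLUME_THRESHOLD_UM3


def classify_clone(
    records: list[NucleusRecord],
    green_channel: str,
    params: ClassifierParams,
) -> tuple[list[NucleusRecord], float]:
    """Assign clone flag in place; returns (records, threshold used).

    ``clone=True`` when the mean green intensity >= threshold (fixed, or
    per-image Otsu over the per-nucleus means for "auto").
    """
    if not records:
        if params.clone_intensity_threshold == "auto":
            raise ThresholdError("cannot auto-optimise a clone threshold on 0 records")
        return records, float(params.clone_intensity_threshold)
    means = np.array([r.mean_intensity[green_channel] for r in records])
    if params.clone_intensity_threshold == "auto":
        try:
            threshold = optimize_threshold_1d(means, params.clone_auto_method)
        except ThresholdError:
            if params.clone_fallback_threshold is None:
                raise
            threshold = float(params.clone_fallback_threshold)
    else:
        threshold = float(params.clone_intensity_threshold)
    for r, m in zip(records, means):
        r.clone = bool(m >= threshold)
    return records, threshold


def filter_depth(
    records: list[NucleusRecord], stack: ImageStack
) -> list[NucleusRecord]:
    """Set depth_kept: True iff the centroid z lies in the
    coverslip-proximal half of the physical z extent (half-open)."""
    if stack.coverslip_end not in ("low_z", "high_z"):
        raise ValueError(f"coverslip_end unset or invalid: {stack.coverslip_end!r}")
    half = stack.z_extent_um / 2.0
    for r in records:
        z = r.centroid_zyx_um[0]
        r.depth_kept = z < half if stack.coverslip_end == "low_z" else z >= half
    return records


def mark_all_kept(records: list[NucleusRecord]) -> list[NucleusRecord]:
    """Depth filter disabled: every nucleus counts."""
    for r in records:
        r.depth_kept = True
    return records
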