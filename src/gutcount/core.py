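"""Core voxel-grid data structures shared by all pipeline stages.

Conventions
-----------
* Image data is indexed ``(channel, z, y, x)``; label maps are ``(z, y, x)``.
* Physical coordinates are micrometres.  The centre of voxel ``i`` along an
  axis with spacing ``s`` lies at ``(i + 0.5) * s``, so an axis with ``n``
  voxels spans the physical interval ``[0, n * s)``.
* Label 0 is background everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VALID_COVERSLIP_ENDS = ("low_z", "high_z")


@dataclass
class ImageStack:
    """A multi-channel 3D image with physical voxel geometry.

    Parameters
    ----------
    voxels : ndarray, shape (C, Z, Y, X)
        Non-negative intensities.
    voxel_size_zyx : tuple of float
        Micrometres per voxel along (z, y, x).
    channel_names : list of str
        One name per channel, e.g. ``["dna", "gfp"]``.
    coverslip_end : {"low_z", "high_z"}
        Which z extreme is nearest the coverslip.
    """

    voxels: np.ndarray
    voxel_size_zyx: tuple[float, float, float]
    channel_names: list[str] = field(default_factory=list)
    coverslip_end: str = "low_z"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim == 3:
            self.voxels = self.voxels[np.newaxis]
        if self.voxels.ndim != 4:
            raise ValueError(
                f"expected (C, Z, Y, X) voxel grid, got ndim={self.voxels.ndim}"
            )
        self.voxel_size_zyx = tuple(float(v) for v in self.voxel_size_zyx)
        if len(self.voxel_size_zyx) != 3 or any(v <= 0 for v in self.voxel_size_zyx):
            raise ValueError(f"voxel sizes must be three positive values, got {self.voxel_size_zyx}")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.voxels.shape[0])]
        if len(self.channel_names) != self.voxels.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.voxels.shape[0]} channels"
            )
        if self.coverslip_end not in VALID_COVERSLIP_ENDS:
            raise ValueError(
                f"coverslip_end must be one of {VALID_COVERSLIP_ENDS}, got {self.coverslip_end!r}"
            )
        if np.issubdtype(self.voxels.dtype, np.floating) and not np.all(
            np.isfinite(self.voxels)
        ):
            raise ValueError("voxel intensities must be finite")

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.voxels.shape[1:]

    @property
    def voxel_volume_um3(self) -> float:
        z, y, x = self.voxel_size_zyx
        return z * y * x

    @property
    def z_extent_um(self) -> float:
        """Physical span of the z axis in micrometres."""
        return self.shape_zyx[0] * self.voxel_size_zyx[0]

    def channel(self, name: str) -> np.ndarray:
        """Return the 3D (z, y, x) array for a named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"no channel {name!r}; available: {self.channel_names}"
            ) from None
        return self.voxels[idx]


@dataclass
class LabelMap:
    """Integer-labelled 3D segmentation sharing an ImageStack's geometry."""

    labels: np.ndarray
    voxel_size_zyx: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"label map must be 3-D, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError(f"label map must be integer, got dtype={self.labels.dtype}")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.voxel_size_zyx = tuple(float(v) for v in self.voxel_size_zyx)
        if len(self.voxel_size_zyx) != 3 or any(v <= 0 for v in self.voxel_size_zyx):
            raise ValueError(f"voxel sizes must be three positive values, got {self.voxel_size_zyx}")

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume_um3(self) -> float:
        z, y, x = self.voxel_size_zyx
        return z * y * x

    @property
    def ids(self) -> np.ndarray:
        """Sorted positive label ids present in the map."""
        u = np.unique(self.labels)
        return u[u > 0]

    def compact(self) -> "LabelMap":
        """Relabel so positive ids form {1..K} with no gaps."""
        ids = self.ids
        if ids.size == 0:
            return LabelMap(self.labels.copy(), self.voxel_size_zyx)
        lut = np.zeros(int(ids.max()) + 1, dtype=self.labels.dtype)
        lut[ids] = np.arange(1, ids.size + 1, dtype=self.labels.dtype)
        return LabelMap(lut[self.labels], self.voxel_size_zyx)


def check_same_geometry(labels: LabelMap, stack: ImageStack) -> None:
    """Raise ValueError unless label map and stack share shape and voxel size."""
    if tuple(labels.shape_zyx) != tuple(stack.shape_zyx):
        raise ValueError(
            f"shape mismatch: labels {labels.shape_zyx} vs stack {stack.shape_zyx}"
        )
    if not np.allclose(labels.voxel_size_zyx, stack.voxel_size_zyx):
        raise ValueError(
            f"voxel size mismatch: {labels.voxel_size_zyx} vs {stack.voxel_size_zyx}"
        )
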