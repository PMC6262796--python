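"""TIFF, CSV and YAML input/output.

Stacks are stored as multi-page TIFF with plane order channel-first
(all z planes of channel 0, then channel 1, ...).  Geometry (voxel size,
channel names, coverslip end) travels in a JSON payload inside the TIFF
ImageDescription tag, so round-trips are self-contained; ImageJ-style
``spacing`` metadata is honoured on read when our payload is absent.
The reader never guesses geometry: a file without voxel-size metadata
and without an explicit override is an error.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from gutcount.core import ImageStack, LabelMap

_DESCRIPTION_KEY = "gutcount"

RECORD_COLUMNS = [
    "id",
    "z_um",
    "y_um",
    "x_um",
    "volume_um3",
    "size_class",
    "clone",
    "depth_kept",
]


class GeometryError(ValueError):
    """Voxel geometry missing or inconsistent with the file contents."""


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as a 16-bit multi-page TIFF (channel-first planes)."""
    data = stack.voxels
    if np.issubdtype(data.dtype, np.floating):
        data = np.clip(np.rint(data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    meta = {
        _DESCRIPTION_KEY: {
            "voxel_size_zyx": list(stack.voxel_size_zyx),
            "channel_names": list(stack.channel_names),
            "coverslip_end": stack.coverslip_end,
            "n_channels": stack.n_channels,
        }
    }
    tifffile.imwrite(
        Path(path),
        data.reshape(-1, *stack.shape_zyx[1:]),
        description=json.dumps(meta),
        photometric="minisblack",
    )


def _parse_metadata(tif: tifffile.TiffFile) -> dict | None:
    desc = tif.pages[0].description
    if desc:
        try:
            payload = json.loads(desc)
            if isinstance(payload, dict) and _DESCRIPTION_KEY in payload:
                return payload[_DESCRIPTION_KEY]
        except (json.JSONDecodeError, TypeError):
            pass
    if tif.imagej_metadata and "spacing" in tif.imagej_metadata:
        # ImageJ stores z spacing; xy resolution comes from the TIFF tags
        page = tif.pages[0]
        res = page.tags.get("XResolution")
        xy = 1.0
        if res is not None and res.value[0]:
            xy = res.value[1] / res.value[0]
        return {"voxel_size_zyx": [float(tif.imagej_metadata["spacing"]), xy, xy]}
    return None


def read_stack(
    path: str | Path,
    voxel_size_override: tuple[float, float, float] | None = None,
    channel_names: list[str] | None = None,
    coverslip_end: str | None = None,
) -> ImageStack:
    """Read a TIFF stack written by :func:`write_stack` or compatible.

    ``voxel_size_override`` is required when the file carries no voxel
    size metadata; when given it always wins over file metadata.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"no such TIFF: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            meta = _parse_metadata(tif) or {}
    except tifffile.TiffFileError as exc:
        raise OSError(f"unreadable TIFF {path}: {exc}") from exc

    voxel_size = voxel_size_override or meta.get("voxel_size_zyx")
    if voxel_size is None:
        raise GeometryError(
            f"{path} carries no voxel-size metadata; pass voxel_size_override"
        )

    n_channels = meta.get("n_channels")
    if data.ndim == 2:
        data = data[np.newaxis, np.newaxis]
    elif data.ndim == 3:
        if n_channels and n_channels > 1:
            if data.shape[0] % n_channels:
                raise GeometryError(
                    f"{path}: {data.shape[0]} planes not divisible by "
                    f"{n_channels} channels"
                )
            data = data.reshape(n_channels, data.shape[0] // n_channels, *data.shape[1:])
        else:
            data = data[np.newaxis]
    elif data.ndim != 4:
        raise GeometryError(f"{path}: cannot interpret array of ndim {data.ndim}")

    names = channel_names or meta.get("channel_names")
    if names is not None and len(names) != data.shape[0]:
        raise GeometryError(
            f"{path}: {len(names)} channel names for {data.shape[0]} channels"
        )
    return ImageStack(
        data,
        voxel_size_zyx=tuple(voxel_size),
        channel_names=list(names) if names else [],
        coverslip_end=coverslip_end or meta.get("coverslip_end", "low_z"),
    )


def write_labels(labels: LabelMap, path: str | Path) -> None:
    """Write a label map as a single-channel integer TIFF."""
    data = labels.labels
    dtype = np.uint16 if data.max(initial=0) < 2**16 else np.uint32
    meta = {_DESCRIPTION_KEY: {"voxel_size_zyx": list(labels.voxel_size_zyx)}}
    tifffile.imwrite(
        Path(path),
        data.astype(dtype),
        description=json.dumps(meta),
        photometric="minisblack",
    )


def read_labels(
    path: str | Path,
    voxel_size_override: tuple[float, float, float] | None = None,
) -> LabelMap:
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = _parse_metadata(tif) or {}
    voxel_size = voxel_size_override or meta.get("voxel_size_zyx")
    if voxel_size is None:
        raise GeometryError(
            f"{path} carries no voxel-size metadata; pass voxel_size_override"
        )
    return LabelMap(data.astype(np.int64), tuple(voxel_size))


def records_to_frame(records: list) -> pd.DataFrame:
    """NucleusRecord list -> DataFrame with the stable column order."""
    rows = []
    for r in records:
        row = {
            "id": r.id,
            "z_um": r.centroid_zyx_um[0],
            "y_um": r.centroid_zyx_um[1],
            "x_um": r.centroid_zyx_um[2],
            "volume_um3": r.volume_um3,
            "size_class": r.size_class if r.size_class is not None else "",
            "clone": "" if r.clone is None else r.clone,
            "depth_kept": "" if r.depth_kept is None else r.depth_kept,
        }
        for ch, mean in r.mean_intensity.items():
            row[f"mean_{ch}"] = mean
        rows.append(row)
    frame = pd.DataFrame(rows)
    if frame.empty:
        frame = pd.DataFrame(columns=RECORD_COLUMNS)
    ordered = RECORD_COLUMNS + [c for c in frame.columns if c not in RECORD_COLUMNS]
    return frame.reindex(columns=ordered)


def write_records(records: list, path: str | Path) -> None:
    """Write nucleus records to CSV (units carried in header names)."""
    records_to_frame(records).to_csv(Path(path), index=False, float_format="%.6f")


def read_records(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
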