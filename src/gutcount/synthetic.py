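"""Ground-truthed synthetic 3D multi-channel stack generator.

Emulates the confocal imaging regime the pipeline targets: two
nuclear-volume populations (small progenitor-like vs big
enterocyte-like nuclei), a clone-positive subpopulation with elevated
green-channel intensity, optional deliberately fused nucleus pairs,
anisotropic voxels, PSF-like Gaussian blur and additive or Poisson
noise.  Every stack comes with an exact voxel-level label map and a
per-nucleus truth table, so downstream stages can be validated against
known ground truth.

Nuclei are axis-aligned ellipsoids with bounded anisotropy (max/min
semi-axis ratio <= 2).  Touching pairs are built by placing two
ellipsoids with centre distance 0.8 x (sum of their semi-axes along the
joining axis), which guarantees a single fused connected component
before watershed splitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from gutcount.core import ImageStack, LabelMap

NOISE_MODELS = ("none", "gaussian", "poisson")
MAX_PLACEMENT_ATTEMPTS = 10_000

TRUTH_COLUMNS = [
    "id",
    "z_um",
    "y_um",
    "x_um",
    "volume_um3",
    "size_class",
    "clone",
    "touching",
]


class PlacementError(RuntimeError):
    """Raised when nuclei cannot be placed at the requested density."""


@dataclass
class SimulationParams:
    """Parameters of one synthetic stack.

    Volumes are micrometres cubed, voxel sizes and blur sigmas are
    micrometres, intensities are arbitrary units.
    """

    shape_zyx: tuple[int, int, int] = (30, 128, 128)
    voxel_size_zyx: tuple[float, float, float] = (1.0, 0.31, 0.31)
    n_small: int = 10
    n_big: int = 5
    small_volume_range: tuple[float, float] = (20.0, 60.0)
    big_volume_range: tuple[float, float] = (120.0, 400.0)
    clone_fraction: float = 0.5
    clone_intensity: float = 200.0
    nonclone_intensity: float = 10.0
    nuclear_intensity: float = 200.0
    n_touching_pairs: int = 0
    blur_sigma_zyx: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_model: str = "none"
    noise_scale: float = 10.0
    marker_fraction: float = 0.0
    marker_intensity: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape_zyx = tuple(int(n) for n in self.shape_zyx)
        self.voxel_size_zyx = tuple(float(v) for v in self.voxel_size_zyx)
        self.blur_sigma_zyx = tuple(float(v) for v in self.blur_sigma_zyx)
        if len(self.shape_zyx) != 3 or any(n <= 0 for n in self.shape_zyx):
            raise ValueError(f"shape_zyx must be three positive counts, got {self.shape_zyx}")
        if any(v <= 0 for v in self.voxel_size_zyx):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size_zyx}")
        for name in ("n_small", "n_big", "n_touching_pairs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("small_volume_range", "big_volume_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a positive interval, got {(lo, hi)}")
        if self.small_volume_range[1] >= self.big_volume_range[0]:
            raise ValueError(
                "small_volume_range must lie strictly below big_volume_range"
            )
        if not 0.0 <= self.clone_fraction <= 1.0:
            raise ValueError(f"clone_fraction must be in [0, 1], got {self.clone_fraction}")
        if not 0.0 <= self.marker_fraction <= 1.0:
            raise ValueError(f"marker_fraction must be in [0, 1], got {self.marker_fraction}")
        if any(v < 0 for v in self.blur_sigma_zyx):
            raise ValueError("blur sigmas must be >= 0")
        if self.noise_model not in NOISE_MODELS:
            raise ValueError(
                f"unknown noise_model {self.noise_model!r}; expected one of {NOISE_MODELS}"
            )


@dataclass
class GroundTruth:
    """True segmentation and per-nucleus table for one synthetic stack."""

    label_map: LabelMap
    truth_table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=TRUTH_COLUMNS)
    )

    @property
    def n_nuclei(self) -> int:
        return len(self.truth_table)


def _sample_semiaxes(rng: np.random.Generator, volume_um3: float) -> np.ndarray:
    """Semi-axes (z, y, x) in um of an ellipsoid with the given volume.

    Per-axis log-uniform jitter, renormalised to the exact target volume;
    the max/min semi-axis ratio stays below 2.
    """
    r = (3.0 * volume_um3 / (4.0 * math.pi)) ** (1.0 / 3.0)
    jitter = np.exp(rng.uniform(-0.17, 0.17, size=3))
    jitter /= jitter.prod() ** (1.0 / 3.0)
    return r * jitter


def _ellipsoid_mask(
    center_um: np.ndarray,
    semiaxes_um: np.ndarray,
    shape_zyx: tuple[int, int, int],
    voxel_size: np.ndarray,
) -> tuple[tuple[slice, slice, slice], np.ndarray]:
    """Rasterise an ellipsoid; returns (bounding slices, boolean mask)."""
    lo = np.maximum(np.floor((center_um - semiaxes_um) / voxel_size - 0.5), 0).astype(int)
    hi = np.minimum(
        np.ceil((center_um + semiaxes_um) / voxel_size - 0.5) + 1, shape_zyx
    ).astype(int)
    slc = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    grids = np.meshgrid(
        *[(np.arange(a, b) + 0.5) * s for a, b, s in zip(lo, hi, voxel_size)],
        indexing="ij",
    )
    d2 = sum(((g - c) / ax) ** 2 for g, c, ax in zip(grids, center_um, semiaxes_um))
    return slc, d2 <= 1.0


class _Placer:
    """Incremental nucleus placement with a 1-voxel exclusion halo."""

    def __init__(self, params: SimulationParams, rng: np.random.Generator):
        self.params = params
        self.rng = rng
        self.shape = params.shape_zyx
        self.voxel_size = np.asarray(params.voxel_size_zyx)
        self.voxel_volume = float(np.prod(self.voxel_size))
        self.labels = np.zeros(self.shape, dtype=np.int32)
        # forbidden = 1-voxel dilation of all placed nuclei
        self.forbidden = np.zeros(self.shape, dtype=bool)
        self.next_id = 1
        self.rows: list[dict] = []

    def _sample_center(self, semiaxes_um: np.ndarray, extra_um: np.ndarray) -> np.ndarray:
        """Uniform centre such that ellipsoid + extra margin fits interior."""
        extent = np.asarray(self.shape) * self.voxel_size
        margin = semiaxes_um + extra_um + self.voxel_size  # keep 1 voxel off the border
        if np.any(extent - 2 * margin <= 0):
            raise PlacementError(
                f"domain extent {tuple(extent)} um too small for nucleus of "
                f"semi-axes {tuple(np.round(semiaxes_um, 2))} um"
            )
        return self.rng.uniform(margin, extent - margin)

    def _commit(self, pieces: list[tuple[tuple[slice, ...], np.ndarray]],
                size_classes: list[str], touching: bool) -> None:
        ids = []
        for slc, mask in pieces:
            self.labels[slc][mask] = self.next_id
            ids.append(self.next_id)
            self.next_id += 1
        for slc, mask in pieces:
            pad = tuple(
                slice(max(s.start - 1, 0), min(s.stop + 1, n))
                for s, n in zip(slc, self.shape)
            )
            region = self.labels[pad] > 0
            self.forbidden[pad] |= ndimage.binary_dilation(region)
        for lab, cls in zip(ids, size_classes):
            self.rows.append({"id": lab, "size_class": cls, "touching": touching})

    def place_single(self, size_class: str) -> None:
        lo, hi = (
            self.params.small_volume_range
            if size_class == "small"
            else self.params.big_volume_range
        )
        for _ in range(MAX_PLACEMENT_ATTEMPTS):
            target = self.rng.uniform(lo, hi)
            semiaxes = _sample_semiaxes(self.rng, target)
            center = self._sample_center(semiaxes, np.zeros(3))
            slc, mask = _ellipsoid_mask(center, semiaxes, self.shape, self.voxel_size)
            realised = mask.sum() * self.voxel_volume
            if not lo <= realised <= hi:
                continue  # discretisation pushed the voxel volume out of class
            if self.forbidden[slc][mask].any():
                continue
            self._commit([(slc, mask)], [size_class], touching=False)
            return
        self._fail()

    def place_pair(self) -> None:
        """Two fused small-population ellipsoids joined along y or x."""
        lo, hi = self.params.small_volume_range
        for _ in range(MAX_PLACEMENT_ATTEMPTS):
            axes_a = _sample_semiaxes(self.rng, self.rng.uniform(lo, hi))
            axes_b = _sample_semiaxes(self.rng, self.rng.uniform(lo, hi))
            join_axis = int(self.rng.choice([1, 2]))
            dist = 0.8 * (axes_a[join_axis] + axes_b[join_axis])
            offset = np.zeros(3)
            offset[join_axis] = dist
            center_a = self._sample_center(axes_a, offset + axes_b)
            center_b = center_a + offset
            slc_a, mask_a = _ellipsoid_mask(center_a, axes_a, self.shape, self.voxel_size)
            slc_b, mask_b = _ellipsoid_mask(center_b, axes_b, self.shape, self.voxel_size)
            if self.forbidden[slc_a][mask_a].any() or self.forbidden[slc_b][mask_b].any():
                continue
            # overlap voxels go to the nearer centre (ellipsoidal metric)
            union = tuple(
                slice(min(a.start, b.start), max(a.stop, b.stop))
                for a, b in zip(slc_a, slc_b)
            )
            full_a = np.zeros(tuple(s.stop - s.start for s in union), dtype=bool)
            full_b = full_a.copy()
            rel = lambda s, u: tuple(  # noqa: E731
                slice(si.start - ui.start, si.stop - ui.start) for si, ui in zip(s, u)
            )
            full_a[rel(slc_a, union)] = mask_a
            full_b[rel(slc_b, union)] = mask_b
            overlap = full_a & full_b
            if overlap.any():
                zz, yy, xx = np.nonzero(overlap)
                pos = (np.stack([zz, yy, xx], axis=1)
                       + [u.start for u in union] + 0.5) * self.voxel_size
                da = (((pos - center_a) / axes_a) ** 2).sum(axis=1)
                db = (((pos - center_b) / axes_b) ** 2).sum(axis=1)
                to_b = db < da
                full_a[zz[to_b], yy[to_b], xx[to_b]] = False
                full_b[zz[~to_b], yy[~to_b], xx[~to_b]] = False
            self._commit(
                [(union, full_a), (union, full_b)], ["small", "small"], touching=True
            )
            return
        self._fail()

    def _fail(self) -> None:
        placed = self.next_id - 1
        raise PlacementError(
            f"could not place nucleus after {MAX_PLACEMENT_ATTEMPTS} attempts; "
            f"{placed} nuclei fit in a {self.shape} voxel domain at voxel size "
            f"{tuple(self.voxel_size)} um — reduce counts or enlarge the domain"
        )


def place_nuclei(params: SimulationParams) -> GroundTruth:
    """Place ellipsoidal nuclei and return the true label map + table.

    Deterministic given ``params.seed``.  Non-pair nuclei are separated
    from every other nucleus by at least one voxel of background; each
    touching pair forms a single fused connected component.  Clone flags
    are i.i.d. Bernoulli(``clone_fraction``).
    """
    rng = np.random.default_rng([params.seed, 0])
    placer = _Placer(params, rng)
    for _ in range(params.n_touching_pairs):
        placer.place_pair()
    for _ in range(params.n_big):
        placer.place_single("big")
    for _ in range(params.n_small):
        placer.place_single("small")

    label_map = LabelMap(placer.labels, params.voxel_size_zyx)
    if not placer.rows:
        return GroundTruth(label_map, pd.DataFrame(columns=TRUTH_COLUMNS))

    table = pd.DataFrame(placer.rows).sort_values("id").reset_index(drop=True)
    ids = table["id"].to_numpy()
    counts = ndimage.sum_labels(
        np.ones_like(placer.labels, dtype=np.int64), placer.labels, ids
    )
    centroids = np.asarray(ndimage.center_of_mass(
        np.ones_like(placer.labels, dtype=np.float64), placer.labels, ids
    ))
    centroids = (centroids + 0.5) * np.asarray(params.voxel_size_zyx)
    table["volume_um3"] = counts * label_map.voxel_volume_um3
    table[["z_um", "y_um", "x_um"]] = centroids
    table["clone"] = rng.random(len(table)) < params.clone_fraction
    return GroundTruth(label_map, table[TRUTH_COLUMNS])


def marker_positive_ids(truth: GroundTruth, params: SimulationParams) -> np.ndarray:
    """Deterministic subset of nucleus ids carrying the marker channel.

    The first ``round(marker_fraction * n)`` ids in sorted order; exact
    and reproducible so tests can predict the marker-positive fraction.
    """
    ids = np.sort(truth.truth_table["id"].to_numpy())
    k = int(round(params.marker_fraction * len(ids)))
    return ids[:k]


def render_channels(truth: GroundTruth, params: SimulationParams) -> ImageStack:
    """Render DNA / green (clone) / optional marker channels from truth.

    The DNA channel is ``nuclear_intensity`` on the label support and 0
    outside; the green channel is ``clone_intensity`` inside
    clone-positive labels and ``nonclone_intensity`` inside the rest.
    Channels are then Gaussian-blurred (sigma in um, converted to voxels
    per axis) and corrupted by the configured noise model.  Deterministic
    given ``params.seed``.
    """
    labels = truth.label_map.labels
    if tuple(labels.shape) != tuple(params.shape_zyx):
        raise ValueError(
            f"truth geometry {labels.shape} does not match params {params.shape_zyx}"
        )
    if params.noise_model not in NOISE_MODELS:
        raise ValueError(f"unknown noise_model {params.noise_model!r}")

    table = truth.truth_table
    max_id = int(labels.max()) if labels.size else 0
    dna = np.where(labels > 0, float(params.nuclear_intensity), 0.0)

    green_lut = np.zeros(max_id + 1)
    if len(table):
        ids = table["id"].to_numpy()
        green_lut[ids] = np.where(
            table["clone"].to_numpy(), params.clone_intensity, params.nonclone_intensity
        )
    green = green_lut[labels]

    channels = [dna, green]
    names = ["dna", "gfp"]
    if params.marker_fraction > 0 and len(table):
        marker_lut = np.zeros(max_id + 1)
        marker_lut[marker_positive_ids(truth, params)] = params.marker_intensity
        channels.append(marker_lut[labels])
        names.append("marker")

    sigma_vox = np.asarray(params.blur_sigma_zyx) / np.asarray(params.voxel_size_zyx)
    if np.any(sigma_vox > 0):
        channels = [ndimage.gaussian_filter(c, sigma=sigma_vox) for c in channels]

    rng = np.random.default_rng([params.seed, 1])
    if params.noise_model == "gaussian":
        channels = [
            np.clip(c + rng.normal(0.0, params.noise_scale, size=c.shape), 0.0, None)
            for c in channels
        ]
    elif params.noise_model == "poisson":
        channels = [rng.poisson(np.clip(c, 0.0, None)).astype(np.float64) for c in channels]

    return ImageStack(
        np.stack(channels),
        voxel_size_zyx=params.voxel_size_zyx,
        channel_names=names,
    )


def simulate(params: SimulationParams) -> tuple[ImageStack, GroundTruth]:
    """Convenience: place nuclei and render channels in one call."""
    truth = place_nuclei(params)
    return render_channels(truth, params), truth


def generate_area_phantom(
    shape_zyx: tuple[int, int, int],
    voxel_size_zyx: tuple[float, float, float],
    positive_fraction: float,
    seed: int = 0,
) -> tuple[ImageStack, float]:
    """Stack whose positive channel covers a known voxel fraction.

    The tissue channel is uniformly positive over the whole domain; the
    positive channel fills the first ``round(f * n_voxels)`` voxels in
    raster order (a half-plane split at f=0.5 on even grids).  Returns
    the stack and the exact realised fraction, which may differ from the
    request by discretisation.  ``seed`` is accepted for interface
    uniformity; the phantom is fully deterministic.
    """
    if not 0.0 <= positive_fraction <= 1.0:
        raise ValueError(f"positive_fraction must be in [0, 1], got {positive_fraction}")
    shape = tuple(int(n) for n in shape_zyx)
    total = int(np.prod(shape))
    k = int(round(positive_fraction * total))
    positive = np.zeros(total)
    positive[:k] = 100.0
    tissue = np.full(shape, 100.0)
    stack = ImageStack(
        np.stack([tissue, positive.reshape(shape)]),
        voxel_size_zyx=voxel_size_zyx,
        channel_names=["tissue", "positive"],
    )
    return stack, k / total
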