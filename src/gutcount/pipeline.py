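"""End-to-end orchestration: simulate, quantify, compare.

Stage order follows the analysis recipe: segment -> watershed ->
measure -> size classes -> clone classes -> depth restriction -> counts.
Every run writes a frozen copy of its resolved configuration and a
plain-text log recording each per-image auto-chosen threshold, since
per-image optimised thresholds are analysis parameters that must stay
auditable.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from gutcount import io as gio
from gutcount.classification import (
    ClassifierParams,
    classify_clone,
    classify_size,
    filter_depth,
    mark_all_kept,
)
from gutcount.quantification import SUMMARY_COLUMNS, SpotParams, summarize
from gutcount.segmentation import SegmentationParams, measure_nuclei, segment_nuclei
from gutcount.stats import GroupComparison, group_compare
from gutcount.synthetic import SimulationParams, place_nuclei, render_channels

METRICS = [
    "n_total",
    "n_clone",
    "clone_cell_ratio",
    "n_small_clone",
    "marker_cell_ratio",
    "positive_volume_ratio",
    "n_spots",
]


@dataclasses.dataclass
class QuantifyConfig:
    """Resolved configuration of one quantification run."""

    images: list[dict]  # each: {id, path, group}
    nuclear_channel: str = "dna"
    green_channel: str = "gfp"
    segmentation: SegmentationParams = dataclasses.field(default_factory=SegmentationParams)
    classification: ClassifierParams = dataclasses.field(default_factory=ClassifierParams)
    positive_channel: str | None = None
    tissue_channel: str = "all"
    positive_threshold: float = 0.0
    marker_channel: str | None = None
    marker_threshold: float = 0.0
    spot_channel: str | None = None
    spot: SpotParams | None = None
    voxel_size_override: tuple[float, float, float] | None = None
    seed: int = 0

    @classmethod
    def from_dict(cls, cfg: dict) -> "QuantifyConfig":
        images = []
        for i, entry in enumerate(cfg.get("images", [])):
            images.append(
                {
                    "id": str(entry.get("id", f"image{i}")),
                    "path": entry["path"],
                    "group": str(entry.get("group", "")),
                }
            )
        spot_cfg = cfg.get("spot")
        return cls(
            images=images,
            nuclear_channel=cfg.get("nuclear_channel", "dna"),
            green_channel=cfg.get("green_channel", "gfp"),
            segmentation=SegmentationParams(**cfg.get("segmentation", {})),
            classification=ClassifierParams(**cfg.get("classification", {})),
            positive_channel=cfg.get("positive_channel"),
            tissue_channel=cfg.get("tissue_channel", "all"),
            positive_threshold=cfg.get("positive_threshold", 0.0),
            marker_channel=cfg.get("marker_channel"),
            marker_threshold=cfg.get("marker_threshold", 0.0),
            spot_channel=cfg.get("spot_channel"),
            spot=SpotParams(**spot_cfg) if spot_cfg else None,
            voxel_size_override=(
                tuple(cfg["voxel_size_override"]) if cfg.get("voxel_size_override") else None
            ),
            seed=int(cfg.get("seed", 0)),
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.voxel_size_override:
            d["voxel_size_override"] = list(self.voxel_size_override)
        return d


def _image_seed(base_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([base_seed, index]).generate_state(1)[0])


def run_simulate(config: dict, out_dir: str | Path, seed: int) -> pd.DataFrame:
    """Generate stacks + ground truth from a simulation config.

    Config layout: ``defaults`` (SimulationParams fields) and ``images``
    (list of {id, group, overrides}); a missing ``images`` list yields a
    single image.  Writes per image the rendered stack, the true label
    map and the truth table, plus a manifest consumable by quantify.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    defaults = dict(config.get("defaults", {}))
    entries = config.get("images") or [{"id": "image0", "group": ""}]
    manifest_rows = []
    for i, entry in enumerate(entries):
        image_id = str(entry.get("id", f"image{i}"))
        fields = {**defaults, **dict(entry.get("overrides", {}))}
        fields["seed"] = _image_seed(seed, i)
        params = SimulationParams(**fields)
        truth = place_nuclei(params)
        stack = render_channels(truth, params)
        stack_path = out / f"{image_id}.tif"
        gio.write_stack(stack, stack_path)
        gio.write_labels(truth.label_map, out / f"{image_id}_labels.tif")
        truth.truth_table.to_csv(
            out / f"{image_id}_truth.csv", index=False, float_format="%.6f"
        )
        manifest_rows.append(
            {"id": image_id, "path": str(stack_path), "group": str(entry.get("group", ""))}
        )
    manifest = pd.DataFrame(manifest_rows, columns=["id", "path", "group"])
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


class StageError(RuntimeError):
    def __init__(self, image_id: str, stage: str, cause: Exception):
        super().__init__(f"[{image_id}] stage {stage!r} failed: {cause}")
        self.image_id = image_id
        self.stage = stage
        self.cause = cause


def quantify_image(
    stack: "gio.ImageStack", image_id: str, group: str, config: QuantifyConfig
) -> tuple[list, "gio.pd.DataFrame", dict]:
    """Run segment -> measure -> classify -> depth filter -> summarise
    on one stack.  Returns (records, summary row dict, log dict)."""
    labels = segment_nuclei(stack, config.nuclear_channel, config.segmentation)
    records = measure_nuclei(labels, stack)
    records, vol_thr = classify_size(records, config.classification)
    records, clone_thr = classify_clone(records, config.green_channel, config.classification)
    if config.classification.depth_filter:
        records = filter_depth(records, stack)
    else:
        records = mark_all_kept(records)
    summary = summarize(
        records,
        image_id=image_id,
        group=group,
        stack=stack,
        positive_channel=config.positive_channel,
        tissue_channel=config.tissue_channel,
        positive_threshold=config.positive_threshold,
        marker_channel=config.marker_channel,
        marker_threshold=config.marker_threshold,
        spot_channel=config.spot_channel,
        spot_params=config.spot,
    )
    log = {
        "image_id": image_id,
        "n_labels": len(records),
        "volume_threshold_um3": vol_thr,
        "clone_intensity_threshold": clone_thr,
    }
    return records, summary, log


def run_quantify(config: QuantifyConfig, out_dir: str | Path) -> tuple[pd.DataFrame, list[StageError]]:
    """Quantify every image in the manifest; failures are reported per
    image and do not stop the remaining images."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config_resolved.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    summary_rows: list[dict] = []
    log_lines: list[str] = []
    errors: list[StageError] = []
    for entry in config.images:
        image_id, group = entry["id"], entry["group"]
        stage = "read"
        try:
            stack = gio.read_stack(
                entry["path"], voxel_size_override=config.voxel_size_override
            )
            stage = "quantify"
            records, summary, log = quantify_image(stack, image_id, group, config)
            gio.write_records(records, out / f"nuclei_{image_id}.csv")
            summary_rows.append(dataclasses.asdict(summary))
            log_lines.append(
                f"{image_id}: n={log['n_labels']} "
                f"volume_threshold_um3={log['volume_threshold_um3']:.6g} "
                f"clone_intensity_threshold={log['clone_intensity_threshold']:.6g}"
            )
        except Exception as exc:  # noqa: BLE001 — per-image isolation is the contract
            err = StageError(image_id, stage, exc)
            errors.append(err)
            log_lines.append(f"{image_id}: ERROR in stage {stage!r}: {exc}")

    summaries = pd.DataFrame(summary_rows, columns=SUMMARY_COLUMNS)
    summaries.to_csv(out / "summaries.csv", index=False, float_format="%.6f")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return summaries, errors


def run_compare(
    summaries: pd.DataFrame | str | Path,
    metric: str,
    mode: str = "auto",
    out_dir: str | Path | None = None,
) -> GroupComparison:
    """Group-comparison statistics on a summaries table.

    Groups come from the ``group`` column; missing metric values are
    dropped per group.  Writes JSON + text report when out_dir is given.
    """
    if not isinstance(summaries, pd.DataFrame):
        summaries = pd.read_csv(summaries)
    if metric not in summaries.columns or metric not in METRICS:
        raise ValueError(
            f"unknown metric {metric!r}; available: "
            f"{[m for m in METRICS if m in summaries.columns]}"
        )
    groups = {
        str(name): sub[metric].tolist()
        for name, sub in summaries.groupby("group", sort=False)
    }
    result = group_compare(groups, metric=metric, mode=mode)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / f"compare_{metric}.json", "w") as fh:
            json.dump(result.to_dict(), fh, indent=2)
        (out / f"compare_{metric}.txt").write_text(result.format_table() + "\n")
    return result
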