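"""End-to-end frame and sequence processing.

A frame goes through: detect → select tray → crop to the tray ROI → segment
plate and food items → estimate depth for the ROI → normalize polarity →
sample the food-free plate rim → fit the base plane → subtract and clip →
integrate each item's volume → (optionally) convert volumes to grams with
per-class density models.  A sequence is a manifest of frames grouped into
rotation blocks; per-block and pooled CV statistics summarize robustness.

All processing is deterministic given (inputs, config): re-running a
sequence writes byte-identical JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry
from .backends import Detection, MockBackend, PerceptionBackend, RoiTransform, select_tray
from .calibration import DensityModel, estimate_weight
from .geometry import (
    BinaryMask,
    DepthMap,
    PlaneModel,
    Polarity,
    RimUnavailableError,
    VolumeEstimate,
)
from .stats import RotationBlock, SequenceReport

logger = logging.getLogger("trayvol")

__all__ = ["PipelineConfig", "FrameResult", "process_frame", "process_sequence",
           "frame_result_to_dict", "report_to_dict", "write_sequence_outputs"]

SCHEMA_VERSION = 1

#: Detection labels that are scene furniture, not food.
NON_FOOD_LABELS = ("tray", "plate")


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable pipeline parameters.

    band_width
        Width in pixels of the rim band sampled for the base-plane fit.
    clip
        Zero out negative corrected depth before integration (positive-part
        rule); disabling is only useful for diagnostics.
    pixel_area
        Area per pixel ``s**2`` in arbitrary squared units; scales every
        volume linearly.
    polarity
        Polarity of incoming depth rasters; maps are normalized to
        higher-is-elevated before plane correction.
    stats_item
        Food label whose per-frame volume feeds the sequence statistics;
        ``None`` pools the total food volume per frame.
    """

    backend: str = "mock"
    band_width: int = 5
    clip: bool = True
    pixel_area: float = 1.0
    polarity: str = Polarity.HIGHER_IS_ELEVATED.value
    max_rim_points: int | None = geometry.MAX_RIM_POINTS
    stats_item: str | None = None
    calibration_file: str | None = None
    output_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.band_width < 1:
            raise ValueError("band_width must be >= 1")
        if self.pixel_area <= 0:
            raise ValueError("pixel_area must be positive")
        Polarity(self.polarity)  # validate

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass(frozen=True)
class FrameResult:
    """Per-frame outcome: tray, plane, per-item volumes and optional weights."""

    frame_id: str
    tray: Detection | None = None
    volumes: tuple[VolumeEstimate, ...] = ()
    weights: dict[str, float] = field(default_factory=dict)
    plane: PlaneModel | None = None
    warnings: tuple[str, ...] = ()
    failed: bool = False
    failure_reason: str | None = None

    @property
    def total_volume(self) -> float:
        return sum(v.volume for v in self.volumes)

    def volume_of(self, label: str) -> float | None:
        for v in self.volumes:
            if v.label == label:
                return v.volume
        return None


def process_frame(
    frame_ref: str,
    config: PipelineConfig,
    backend: PerceptionBackend,
    density_models: dict[str, DensityModel] | None = None,
) -> FrameResult:
    """Run the full per-frame pipeline; failures are typed, never silent.

    A frame without a tray detection, or whose plate rim is unusable (no
    plate mask, rim fully covered by food), returns a failed
    :class:`FrameResult` carrying the reason.
    """
    detections = backend.detect(frame_ref)
    tray = select_tray(detections)
    if tray is None:
        logger.warning("frame %s: no tray detected", frame_ref)
        return FrameResult(frame_id=frame_ref, failed=True, failure_reason="no tray")

    roi = RoiTransform.from_bbox(tray.bbox)
    x0, y0 = int(tray.bbox[0]), int(tray.bbox[1])
    w, h = int(tray.bbox[2]) - x0, int(tray.bbox[3]) - y0

    def crop(mask: BinaryMask) -> BinaryMask:
        return BinaryMask(
            mask.values[y0 : y0 + h, x0 : x0 + w], label=mask.label, frame_id=frame_ref
        )

    plate_det = next((d for d in detections if d.label == "plate"), None)
    if plate_det is None:
        return FrameResult(
            frame_id=frame_ref, tray=tray, failed=True, failure_reason="rim unavailable"
        )
    plate_mask = crop(backend.segment(frame_ref, plate_det))

    food_dets = [d for d in detections if d.label not in NON_FOOD_LABELS]
    food_masks = [crop(backend.segment(frame_ref, d)) for d in food_dets]

    depth = backend.estimate_depth(frame_ref, roi)
    depth = DepthMap(depth.values, pixel_area=config.pixel_area, polarity=depth.polarity)
    depth = geometry.normalize_polarity(depth, Polarity.HIGHER_IS_ELEVATED)

    try:
        plane = geometry.fit_base_plane(
            depth,
            plate_mask,
            band_width=config.band_width,
            exclusion_masks=food_masks,
            max_points=config.max_rim_points,
        )
    except (RimUnavailableError, geometry.DegeneratePlaneFitError) as exc:
        logger.warning("frame %s: %s", frame_ref, exc)
        return FrameResult(
            frame_id=frame_ref, tray=tray, failed=True, failure_reason=str(exc)
        )

    corrected = geometry.correct_depth(depth, plane, clip=config.clip)

    warnings_list: list[str] = []
    volumes = []
    for mask in food_masks:
        if mask.is_empty():
            warnings_list.append(f"empty mask for {mask.label!r}")
            volumes.append(
                VolumeEstimate(0.0, label=mask.label, frame_id=frame_ref, n_pixels=0)
            )
            continue
        volumes.append(geometry.integrate_volume(corrected, mask))

    weights: dict[str, float] = {}
    if density_models:
        for est in volumes:
            model = density_models.get(est.label)
            if model is not None:
                weights[est.label] = estimate_weight(est.volume, model)

    return FrameResult(
        frame_id=frame_ref,
        tray=tray,
        volumes=tuple(volumes),
        weights=weights,
        plane=plane,
        warnings=tuple(warnings_list),
    )


def process_sequence(
    frames: list[dict],
    config: PipelineConfig,
    backend: PerceptionBackend,
    density_models: dict[str, DensityModel] | None = None,
) -> tuple[SequenceReport, list[FrameResult]]:
    """Process a manifest of frames grouped into rotation blocks.

    ``frames`` is a list of ``{"frame_id": ..., "block_id": ...}`` entries in
    manifest order.  Failed frames are excluded from the statistics and
    counted in the report.  The statistic tracked per frame is the volume of
    ``config.stats_item`` (or the total food volume when unset).
    """
    if not frames:
        raise ValueError("sequence manifest lists no frames")

    results = [
        process_frame(entry["frame_id"], config, backend, density_models)
        for entry in frames
    ]

    block_volumes: dict[str, list[float]] = {}
    failures: list[str] = []
    for entry, result in zip(frames, results):
        if result.failed:
            failures.append(f"{result.frame_id}: {result.failure_reason}")
            continue
        if config.stats_item is not None:
            volume = result.volume_of(config.stats_item)
            if volume is None:
                failures.append(
                    f"{result.frame_id}: item {config.stats_item!r} not present"
                )
                continue
        else:
            volume = result.total_volume
        block_volumes.setdefault(str(entry["block_id"]), []).append(volume)

    blocks = [
        RotationBlock(block_id=bid, volumes=tuple(vols))
        for bid, vols in block_volumes.items()
        if len(vols) >= 2
    ]
    if blocks:
        report = SequenceReport.from_blocks(
            blocks, n_failed=len(failures), failures=tuple(failures)
        )
    else:
        report = SequenceReport(
            blocks=(), global_cv_percent=float("nan"), n_frames=0,
            n_failed=len(failures), failures=tuple(failures),
        )
    return report, results


# --- serialization -----------------------------------------------------------

def _round_trip_float(x: float) -> float:
    return float(x)


def frame_result_to_dict(result: FrameResult) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "frame_id": result.frame_id,
        "failed": result.failed,
        "failure_reason": result.failure_reason,
        "tray": None
        if result.tray is None
        else {"bbox": list(result.tray.bbox), "confidence": result.tray.confidence},
        "plane": None
        if result.plane is None
        else {
            "a": result.plane.a,
            "b": result.plane.b,
            "c": result.plane.c,
            "n_points": result.plane.n_points,
            "rms_residual": result.plane.rms_residual,
        },
        "volumes": [
            {"label": v.label, "volume": v.volume, "n_pixels": v.n_pixels}
            for v in result.volumes
        ],
        "weights_g": dict(sorted(result.weights.items())),
        "warnings": list(result.warnings),
    }


def report_to_dict(report: SequenceReport) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "blocks": [
            {
                "block_id": b.block_id,
                "n_frames": len(b.volumes),
                "mean": b.mean,
                "sd": b.sd,
                "cv_percent": b.cv_percent,
            }
            for b in report.blocks
        ],
        "global_cv_percent": None
        if np.isnan(report.global_cv_percent)
        else report.global_cv_percent,
        "n_frames": report.n_frames,
        "n_failed": report.n_failed,
        "failures": list(report.failures),
    }


def write_sequence_outputs(
    report: SequenceReport,
    results: list[FrameResult],
    outdir: str | Path,
) -> tuple[Path, Path, Path]:
    """Write results JSON, report JSON and the stats CSV table.

    JSON is serialized with sorted keys and repr-exact floats so identical
    runs produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results_path = outdir / "frame_results.json"
    report_path = outdir / "sequence_report.json"
    csv_path = outdir / "block_stats.csv"

    results_path.write_text(
        json.dumps([frame_result_to_dict(r) for r in results], indent=2, sort_keys=True)
        + "\n"
    )
    report_path.write_text(
        json.dumps(report_to_dict(report), indent=2, sort_keys=True) + "\n"
    )
    table = pd.DataFrame(
        [
            {
                "block_id": b.block_id,
                "n_frames": len(b.volumes),
                "mean": b.mean,
                "sd": b.sd,
                "cv_percent": b.cv_percent,
            }
            for b in report.blocks
        ],
        columns=["block_id", "n_frames", "mean", "sd", "cv_percent"],
    )
    table.to_csv(csv_path, index=False)
    return results_path, report_path, csv_path
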