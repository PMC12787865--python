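"""Pluggable perception stages: detection, prompt-based segmentation, depth.

The pipeline needs three perception capabilities — locate the tray and food
items in an RGB frame, turn bounding-box prompts into pixel masks, and
estimate a relative depth map for a cropped region of interest.  In
deployment those are served by trained models (an object detector, a
promptable segmenter, a monocular depth network); here they are defined as a
:class:`PerceptionBackend` protocol so any implementation can be plugged in.

The shipped :class:`MockBackend` serves all three stages from a synthetic
scene manifest (see :mod:`trayvol.scenes`): detections and masks come
straight from the manifest, and depth is the scene's raster pushed through
the same crop/resize chain a real depth model would see (resized to the
model's square input, then resampled back to the crop so masks align at
native resolution).  It is bit-deterministic given a manifest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .geometry import BinaryMask, DepthMap, Polarity

__all__ = [
    "Detection",
    "RoiTransform",
    "BackendError",
    "PerceptionBackend",
    "MockBackend",
    "select_tray",
    "map_roi_coordinates",
    "resample_bilinear",
]

#: Square input size of the depth model stage, pixels.
DEPTH_MODEL_SIZE = 512


class BackendError(RuntimeError):
    """A perception stage failed (missing raster, invalid prompt, ...)."""


@dataclass(frozen=True)
class Detection:
    """One detected object: half-open pixel box, class label, confidence."""

    bbox: tuple[int, int, int, int]  # (x0, y0, x1, y1), half-open
    label: str
    confidence: float = 1.0

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.bbox
        if not (x0 < x1 and y0 < y1):
            raise ValueError(f"invalid bbox {self.bbox}: need x0 < x1 and y0 < y1")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must be in [0, 1]")

    @property
    def area(self) -> int:
        x0, y0, x1, y1 = self.bbox
        return (x1 - x0) * (y1 - y0)


@dataclass(frozen=True)
class RoiTransform:
    """Affine map between frame, crop and model-input coordinates.

    A frame point ``p`` maps to crop coordinates ``p - crop_origin`` and to
    model coordinates ``(p - crop_origin) * scale`` with
    ``scale = model_size / crop_size`` componentwise.
    """

    crop_origin: tuple[float, float]  # (x0, y0) in frame pixels
    crop_size: tuple[float, float]  # (w, h)
    model_size: tuple[float, float] = (DEPTH_MODEL_SIZE, DEPTH_MODEL_SIZE)

    def __post_init__(self) -> None:
        if min(self.crop_size) <= 0 or min(self.model_size) <= 0:
            raise ValueError("crop_size and model_size must be positive")

    @property
    def scale(self) -> tuple[float, float]:
        return (
            self.model_size[0] / self.crop_size[0],
            self.model_size[1] / self.crop_size[1],
        )

    @classmethod
    def from_bbox(
        cls, bbox: tuple[int, int, int, int], model_size: int = DEPTH_MODEL_SIZE
    ) -> "RoiTransform":
        x0, y0, x1, y1 = bbox
        return cls(
            crop_origin=(x0, y0),
            crop_size=(x1 - x0, y1 - y0),
            model_size=(model_size, model_size),
        )


def map_roi_coordinates(
    point: tuple[float, float], transform: RoiTransform, direction: str = "frame_to_model"
) -> tuple[float, float]:
    """Map a point between frame and model coordinate systems.

    ``direction`` is ``"frame_to_model"`` or ``"model_to_frame"``; the two
    are exact inverses up to floating round-off.
    """
    x, y = point
    ox, oy = transform.crop_origin
    sx, sy = transform.scale
    if direction == "frame_to_model":
        return ((x - ox) * sx, (y - oy) * sy)
    if direction == "model_to_frame":
        return (x / sx + ox, y / sy + oy)
    raise ValueError(f"unknown direction {direction!r}")


def resample_bilinear(values: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Bilinear resampling with linear extrapolation at the borders.

    Pixel centers are aligned between grids (output center i maps to input
    coordinate ``(i + 0.5) * in/out - 0.5``).  Linear extrapolation outside
    the input pixel-center hull — instead of edge clamping — makes the
    operation exact on planar rasters, so a perfectly planar depth map
    survives any downsample/upsample chain unchanged (up to round-off).
    """
    in_h, in_w = values.shape
    out_h, out_w = out_shape
    if (in_h, in_w) == (out_h, out_w):
        return values.astype(np.float64, copy=True)
    interp = RegularGridInterpolator(
        (np.arange(in_h, dtype=np.float64), np.arange(in_w, dtype=np.float64)),
        values.astype(np.float64),
        method="linear",
        bounds_error=False,
        fill_value=None,  # linear extrapolation beyond the border pixel centers
    )
    rows = (np.arange(out_h) + 0.5) * (in_h / out_h) - 0.5
    cols = (np.arange(out_w) + 0.5) * (in_w / out_w) - 0.5
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return interp(np.stack([rr, cc], axis=-1))


def select_tray(detections: list[Detection]) -> Detection | None:
    """Pick the tray detection: highest confidence, ties broken by box area."""
    trays = [d for d in detections if d.label == "tray"]
    if not trays:
        return None
    return max(trays, key=lambda d: (d.confidence, d.area))


@runtime_checkable
class PerceptionBackend(Protocol):
    """Contract every perception backend (mock or real-model adapter) meets."""

    def detect(self, frame_ref: str) -> list[Detection]:
        """All tray/plate/food detections for a frame."""

    def segment(self, frame_ref: str, prompt: Detection) -> BinaryMask:
        """Frame-resolution binary mask for a bounding-box prompt."""

    def estimate_depth(self, frame_ref: str, roi: RoiTransform) -> DepthMap:
        """Relative depth for the ROI crop, resampled back to crop size."""


class MockBackend:
    """Deterministic backend serving synthetic-scene manifests.

    ``manifests`` maps frame ids to scene manifests as produced by
    :func:`trayvol.scenes.render_scene` (in-memory) or loaded from disk via
    :func:`trayvol.io.load_scene_manifest`.  No RNG is involved at inference:
    identical manifests give bit-identical outputs.
    """

    def __init__(self, manifests: dict[str, dict]):
        self._manifests = dict(manifests)

    @classmethod
    def from_scene(cls, scene) -> "MockBackend":
        manifest = scene.manifest
        return cls({manifest["frame_id"]: manifest})

    @classmethod
    def from_scenes(cls, frames: dict[str, "object"]) -> "MockBackend":
        return cls({fid: scene.manifest for fid, scene in frames.items()})

    def _manifest(self, frame_ref: str) -> dict:
        try:
            return self._manifests[frame_ref]
        except KeyError:
            raise BackendError(f"unknown frame {frame_ref!r}") from None

    def detect(self, frame_ref: str) -> list[Detection]:
        m = self._manifest(frame_ref)
        return [
            Detection(bbox=tuple(d["bbox"]), label=d["label"], confidence=d["confidence"])
            for d in m["detections"]
        ]

    def segment(self, frame_ref: str, prompt: Detection) -> BinaryMask:
        """Return the manifest mask of the item best matching the prompt box.

        The match is the manifest item whose bounding box overlaps the prompt
        box most, scored by intersection-over-union so a prompt that exactly
        frames an item beats a larger box that merely contains it; a prompt
        overlapping nothing, or lying outside the frame, is an error.
        """
        m = self._manifest(frame_ref)
        h, w = m["grid"]
        x0, y0, x1, y1 = prompt.bbox
        if x1 <= 0 or y1 <= 0 or x0 >= w or y0 >= h:
            raise BackendError("segmentation prompt lies outside the frame")

        best_label, best_overlap = None, 0.0
        prompt_area = (x1 - x0) * (y1 - y0)
        for d in m["detections"]:
            if d["label"] == "tray":
                continue
            bx0, by0, bx1, by1 = d["bbox"]
            ix = max(0, min(x1, bx1) - max(x0, bx0))
            iy = max(0, min(y1, by1) - max(y0, by0))
            inter = ix * iy
            union = prompt_area + (bx1 - bx0) * (by1 - by0) - inter
            overlap = inter / union if union else 0.0
            if overlap > best_overlap:
                best_label, best_overlap = d["label"], overlap
        if best_label is None:
            raise BackendError("prompt matches no item in the manifest")
        mask = m["masks"][best_label]
        return BinaryMask(mask.values, label=best_label, frame_id=m["frame_id"])

    def estimate_depth(self, frame_ref: str, roi: RoiTransform) -> DepthMap:
        """Scene raster cropped to the ROI and round-tripped through the
        model's square input size, so the mock shares the real adapters'
        resampling path."""
        m = self._manifest(frame_ref)
        depth: DepthMap = m.get("depth")
        if depth is None:
            raise BackendError("manifest has no depth raster")
        x0, y0 = (int(round(v)) for v in roi.crop_origin)
        w, h = (int(round(v)) for v in roi.crop_size)
        crop = depth.values[y0 : y0 + h, x0 : x0 + w]
        if crop.shape != (h, w):
            raise BackendError("ROI extends beyond the depth raster")
        model_h, model_w = int(roi.model_size[1]), int(roi.model_size[0])
        at_model = resample_bilinear(crop, (model_h, model_w))
        back = resample_bilinear(at_model, (h, w))
        return DepthMap(back, pixel_area=depth.pixel_area, polarity=depth.polarity)
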