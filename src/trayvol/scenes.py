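"""Synthetic overhead tray scenes with closed-form ground truth.

Real cafeteria captures come with no ground truth: the depth raster is a
relative map from a learned model and the true food volumes are unknown.
The scenes built here stand in for those captures with every quantity known
exactly:

* a global planar tilt ``a*x + b*y + c`` over the whole grid, emulating the
  perspective-induced slope monocular depth models impose on flat trays;
* a flat circular plate whose outer rim band is food-free and sampleable;
* food items as solids of known closed-form volume (spherical caps, cones,
  boxes), rasterized at pixel centers;
* optional i.i.d. Gaussian depth noise (seeded);
* rotation sequences of the same items, emulating repeated passes of one
  plate under the camera at different food orientations.

Depth units are tied to pixel units (1 depth unit = 1 pixel side length), so
analytic volumes are in pixel^3 — the same arbitrary units the integration
step reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .geometry import BinaryMask, DepthMap, PlaneModel, Polarity

__all__ = [
    "ShapeSpec",
    "SceneSpec",
    "SceneGroundTruth",
    "Scene",
    "ItemOverlapError",
    "analytic_volume",
    "render_scene",
    "rotation_sequence",
    "spec_from_dict",
]


class ItemOverlapError(ValueError):
    """Two item footprints overlap, making per-item ground truth ambiguous."""


@dataclass(frozen=True)
class ShapeSpec:
    """One food item: a solid with a closed-form volume.

    kind
        ``"spherical_cap"`` (params ``radius`` R, ``height`` h <= R),
        ``"cone"`` (params ``radius`` r, ``height`` h), or
        ``"box"`` (params ``width``, ``length``, ``height``).
        Lengths in pixels, heights in depth units (= pixels).
    position
        Footprint center ``(x, y)`` in pixel coordinates.
    rotation_deg
        In-plane rotation about the footprint center (only affects
        non-rotationally-symmetric shapes, i.e. boxes).
    """

    kind: str
    params: dict[str, float]
    position: tuple[float, float]
    label: str = "item"
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("spherical_cap", "cone", "box"):
            raise ValueError(f"unknown shape kind {self.kind!r}")
        for name, value in self.params.items():
            if value <= 0:
                raise ValueError(f"shape parameter {name} must be positive")
        if self.kind == "spherical_cap" and self.params["height"] > self.params["radius"] * (
            1 + 1e-12
        ):
            raise ValueError("cap height cannot exceed sphere radius")


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic tray scene."""

    grid: tuple[int, int] = (512, 512)  # (height, width) pixels
    plane: tuple[float, float, float] = (0.0, 0.0, 0.0)  # true tilt (a, b, c)
    plate_center: tuple[float, float] | None = None  # defaults to grid center
    plate_radius: float | None = None  # defaults to 0.45 * min(grid)
    rim_width: float = 10.0
    items: tuple[ShapeSpec, ...] = ()
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.grid
        if self.plate_center is None:
            object.__setattr__(self, "plate_center", ((w - 1) / 2.0, (h - 1) / 2.0))
        if self.plate_radius is None:
            object.__setattr__(self, "plate_radius", 0.45 * min(h, w))
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        cx, cy = self.plate_center
        r = self.plate_radius
        if cx - r < -0.5 or cy - r < -0.5 or cx + r > w - 0.5 or cy + r > h - 0.5:
            raise ValueError("plate does not fit within the grid")
        object.__setattr__(self, "items", tuple(self.items))


@dataclass(frozen=True)
class SceneGroundTruth:
    """Everything the generator knows exactly about a rendered scene."""

    true_plane: PlaneModel
    item_volumes: dict[str, float]
    masks: dict[str, BinaryMask]
    plate_mask: BinaryMask


@dataclass(frozen=True)
class Scene:
    """A rendered scene: depth raster, ground truth, and a backend manifest."""

    spec: SceneSpec
    depth: DepthMap
    truth: SceneGroundTruth
    manifest: dict


def analytic_volume(shape: ShapeSpec) -> float:
    """Closed-form volume of a shape, in pixel^3 (= arbitrary units).

    spherical cap: pi*h^2*(R - h/3); cone: (1/3)*pi*r^2*h; box: w*l*h.
    """
    p = shape.params
    if shape.kind == "spherical_cap":
        R, h = p["radius"], p["height"]
        return math.pi * h * h * (R - h / 3.0)
    if shape.kind == "cone":
        return math.pi * p["radius"] ** 2 * p["height"] / 3.0
    if shape.kind == "box":
        return p["width"] * p["length"] * p["height"]
    raise ValueError(f"unknown shape kind {shape.kind!r}")  # pragma: no cover


def _elevation_field(shape: ShapeSpec, grid: tuple[int, int]) -> np.ndarray:
    """Height of the shape above the base plane at every pixel center."""
    h_px, w_px = grid
    y, x = np.mgrid[0:h_px, 0:w_px].astype(np.float64)
    cx, cy = shape.position
    dx, dy = x - cx, y - cy
    p = shape.params

    if shape.kind == "spherical_cap":
        R, h = p["radius"], p["height"]
        base_r2 = R * R - (R - h) ** 2  # squared radius of the cap's base disk
        d2 = dx * dx + dy * dy
        inside = d2 <= base_r2
        z = np.zeros(grid)
        z[inside] = np.sqrt(R * R - d2[inside]) - (R - h)
        return z
    if shape.kind == "cone":
        r, h = p["radius"], p["height"]
        d = np.hypot(dx, dy)
        return np.maximum(h * (1.0 - d / r), 0.0) * (d <= r)
    # box: rotate pixel coordinates back into the box frame
    theta = math.radians(shape.rotation_deg)
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    inside = (np.abs(u) <= p["width"] / 2.0) & (np.abs(v) <= p["length"] / 2.0)
    return inside * p["height"]


def _footprint(shape: ShapeSpec, grid: tuple[int, int]) -> np.ndarray:
    return _elevation_field(shape, grid) > 0.0


def _item_within_plate(mask: np.ndarray, spec: SceneSpec) -> bool:
    h, w = spec.grid
    y, x = np.mgrid[0:h, 0:w].astype(np.float64)
    cx, cy = spec.plate_center
    inner_r = spec.plate_radius - spec.rim_width
    plate_interior = (x - cx) ** 2 + (y - cy) ** 2 <= inner_r * inner_r
    return bool(np.all(plate_interior[mask]))


def render_scene(spec: SceneSpec) -> Scene:
    """Rasterize a scene spec into a depth map with exact ground truth.

    The depth raster is the true plane evaluated on the grid plus each item's
    elevation field plus Gaussian noise from a generator seeded with
    ``spec.seed`` — bit-reproducible for a given spec.  Item masks are the
    exact rasterized footprints.  Items must stay inside the plate's
    food-free rim and may not overlap each other.
    """
    h, w = spec.grid
    true_plane = PlaneModel(*spec.plane)
    depth_values = true_plane.evaluate(spec.grid).astype(np.float64)

    masks: dict[str, BinaryMask] = {}
    volumes: dict[str, float] = {}
    occupied = np.zeros(spec.grid, dtype=bool)
    for item in spec.items:
        foot = _footprint(item, spec.grid)
        if (occupied & foot).any():
            raise ItemOverlapError("item overlap")
        if not _item_within_plate(foot, spec):
            raise ValueError(
                f"item {item.label!r} extends outside the plate's food-free region"
            )
        occupied |= foot
        depth_values += _elevation_field(item, spec.grid)
        masks[item.label] = BinaryMask(foot, label=item.label)
        volumes[item.label] = analytic_volume(item)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        depth_values = depth_values + rng.normal(0.0, spec.noise_sd, size=spec.grid)

    y, x = np.mgrid[0:h, 0:w].astype(np.float64)
    cx, cy = spec.plate_center
    plate = (x - cx) ** 2 + (y - cy) ** 2 <= spec.plate_radius**2
    plate_mask = BinaryMask(plate, label="plate")

    depth = DepthMap(depth_values, pixel_area=1.0, polarity=Polarity.HIGHER_IS_ELEVATED)
    truth = SceneGroundTruth(
        true_plane=true_plane, item_volumes=volumes, masks=masks, plate_mask=plate_mask
    )
    manifest = _build_manifest(spec, depth, truth)
    return Scene(spec=spec, depth=depth, truth=truth, manifest=manifest)


def _bbox_of(mask: np.ndarray) -> tuple[int, int, int, int]:
    """Half-open (x0, y0, x1, y1) bounding box of a boolean mask."""
    rows, cols = np.nonzero(mask)
    return int(cols.min()), int(rows.min()), int(cols.max()) + 1, int(rows.max()) + 1


def _build_manifest(spec: SceneSpec, depth: DepthMap, truth: SceneGroundTruth) -> dict:
    """In-memory manifest in the form the mock perception backend consumes."""
    h, w = spec.grid
    detections = [
        {"label": "tray", "bbox": [0, 0, w, h], "confidence": 1.0},
        {
            "label": "plate",
            "bbox": list(_bbox_of(truth.plate_mask.values)),
            "confidence": 1.0,
        },
    ]
    for label, mask in truth.masks.items():
        detections.append(
            {"label": label, "bbox": list(_bbox_of(mask.values)), "confidence": 1.0}
        )
    return {
        "schema_version": 1,
        "frame_id": f"scene-seed{spec.seed}",
        "grid": [h, w],
        "detections": detections,
        "depth": depth,
        "masks": {"plate": truth.plate_mask, **truth.masks},
        "ground_truth": {
            "plane": [spec.plane[0], spec.plane[1], spec.plane[2]],
            "item_volumes": dict(truth.item_volumes),
        },
    }


def spec_from_dict(data: dict) -> SceneSpec:
    """Build a SceneSpec from a plain mapping (parsed YAML/JSON spec file)."""
    items = tuple(
        ShapeSpec(
            kind=item["kind"],
            params={k: float(v) for k, v in item["params"].items()},
            position=tuple(item["position"]),
            label=item.get("label", f"item{i}"),
            rotation_deg=float(item.get("rotation_deg", 0.0)),
        )
        for i, item in enumerate(data.get("items", []))
    )
    return SceneSpec(
        grid=tuple(data.get("grid", (512, 512))),
        plane=tuple(data.get("plane", (0.0, 0.0, 0.0))),
        plate_center=tuple(data["plate_center"]) if "plate_center" in data else None,
        plate_radius=data.get("plate_radius"),
        rim_width=float(data.get("rim_width", 10.0)),
        items=items,
        noise_sd=float(data.get("noise_sd", 0.0)),
        seed=int(data.get("seed", 0)),
    )


def rotation_sequence(spec: SceneSpec, angles: list[float]) -> list[Scene]:
    """Render one scene per rotation angle of the same items.

    Each angle is added to every item's base in-plane rotation; everything
    else (plane, plate, noise seed) is unchanged, so ground-truth volumes are
    identical across the sequence.  Raises if a rotation pushes an item
    outside the plate's food-free region.
    """
    scenes = []
    for angle in angles:
        rotated_items = tuple(
            replace(item, rotation_deg=item.rotation_deg + angle) for item in spec.items
        )
        scenes.append(render_scene(replace(spec, items=rotated_items)))
    return scenes
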