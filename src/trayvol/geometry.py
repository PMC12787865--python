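"""Base-plane correction and volumetric integration for overhead depth maps.

Monocular depth models produce *relative* depth: a unitless raster, typically
normalized to [0, 1], whose values order surfaces by distance to the camera
but carry no metric scale.  Under an overhead camera the raster also carries a
spurious global tilt induced by perspective cues.  This module implements the
geometric core that turns such a raster plus per-item segmentation masks into
per-item volumes:

1. sample the annular rim band just inside the plate mask (assumed flat),
2. fit a least-squares base plane ``z = a*x + b*y + c`` to the rim samples,
3. subtract the plane from the depth map (``z_corrected = z_depth - (ax+by+c)``),
4. integrate the positive part of the corrected depth over each food mask,
   each pixel contributing ``z_corrected * s**2`` where ``s**2`` is the area
   per pixel.

Volumes are in arbitrary cubic units (depth unit x pixel area) until a
density calibration maps them to grams.

Coordinate convention: 0-based, ``x`` is the column index and ``y`` the row
index, origin at the top-left pixel.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "Polarity",
    "DepthMap",
    "BinaryMask",
    "PlaneModel",
    "CorrectedDepthMap",
    "VolumeEstimate",
    "RimUnavailableError",
    "DegeneratePlaneFitError",
    "sample_rim",
    "fit_plane",
    "fit_base_plane",
    "correct_depth",
    "integrate_volume",
    "normalize_polarity",
]

#: Rim bands larger than this are thinned by a deterministic uniform stride
#: before plane fitting; keeps the least-squares cost bounded without RNG.
MAX_RIM_POINTS = 5000

#: Singular-value ratio below which the plane-fit design matrix is treated as
#: rank deficient (collinear rim points).
RANK_TOL = 1e-10


class RimUnavailableError(ValueError):
    """No usable rim band: plate mask empty, or fully covered by food."""


class DegeneratePlaneFitError(ValueError):
    """Plane fit is under-determined (< 3 points or collinear support)."""


class Polarity(str, enum.Enum):
    """Whether larger relative-depth values mean higher elevation.

    Monocular relative-depth models usually emit larger values for surfaces
    nearer the camera; under an overhead camera that means food tops.  The
    convention is model-dependent, so it is carried explicitly and can be
    flipped with :func:`normalize_polarity`.
    """

    HIGHER_IS_ELEVATED = "higher_is_elevated"
    LOWER_IS_ELEVATED = "lower_is_elevated"


@dataclass(frozen=True)
class DepthMap:
    """A 2-D relative-depth raster with pixel-area metadata.

    Parameters
    ----------
    values : ndarray of float, shape (height, width)
        Relative depth, nominally in [0, 1] (operations may push values
        outside that range).  Stored as float64.
    pixel_area : float
        Area per pixel, ``s**2``, in arbitrary squared length units.
    polarity : Polarity
        Elevation convention of ``values``.
    """

    values: np.ndarray
    pixel_area: float = 1.0
    polarity: Polarity = Polarity.HIGHER_IS_ELEVATED

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError(f"depth values must be 2-D, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("depth values must all be finite")
        if not self.pixel_area > 0:
            raise ValueError("pixel_area must be > 0")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "polarity", Polarity(self.polarity))

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class BinaryMask:
    """A boolean per-item mask aligned to a depth map."""

    values: np.ndarray
    label: str = ""
    frame_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {v.shape}")
        object.__setattr__(self, "values", v.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_pixels(self) -> int:
        return int(self.values.sum())

    def is_empty(self) -> bool:
        return not self.values.any()


@dataclass(frozen=True)
class PlaneModel:
    """Fitted base plane ``z = a*x + b*y + c``.

    ``a`` and ``b`` are slopes per pixel along columns (x) and rows (y);
    ``c`` is the offset in depth units.  ``n_points`` and ``rms_residual``
    describe the least-squares fit (0 for analytically constructed planes).
    """

    a: float
    b: float
    c: float
    n_points: int = 0
    rms_residual: float = 0.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"plane coefficient {name} must be finite")

    def evaluate(self, shape: tuple[int, int]) -> np.ndarray:
        """Evaluate the plane on a pixel grid of the given (height, width)."""
        h, w = shape
        y, x = np.mgrid[0:h, 0:w]
        return self.a * x + self.b * y + self.c

    def at(self, x: np.ndarray | float, y: np.ndarray | float) -> np.ndarray | float:
        return self.a * np.asarray(x, dtype=np.float64) + self.b * np.asarray(
            y, dtype=np.float64
        ) + self.c


@dataclass(frozen=True)
class CorrectedDepthMap:
    """Depth after base-plane subtraction; may be negative unless clipped."""

    values: np.ndarray
    source_plane: PlaneModel
    pixel_area: float = 1.0
    clipped: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("corrected depth must be 2-D")
        if self.clipped and (v < 0).any():
            raise ValueError("clipped map contains negative values")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class VolumeEstimate:
    """Integrated per-item volume in arbitrary cubic units."""

    volume: float
    label: str = ""
    frame_id: str = ""
    n_pixels: int = 0

    def __post_init__(self) -> None:
        if self.volume < 0:
            raise ValueError("volume must be >= 0")
        if self.n_pixels < 0:
            raise ValueError("n_pixels must be >= 0")


def sample_rim(
    plate_mask: BinaryMask,
    band_width: int = 5,
    exclusion_masks: tuple[BinaryMask, ...] | list[BinaryMask] = (),
    max_points: int | None = MAX_RIM_POINTS,
) -> np.ndarray:
    """Sample the annular band just inside the plate-mask boundary.

    The band is the plate mask minus its morphological erosion by
    ``band_width`` iterations (4-connected structuring element): the outer
    ring of plate pixels, assumed to lie on the flat plate surface.  Pixels
    covered by any exclusion mask (food items) are dropped so food does not
    bias the base-plane fit.

    Returns
    -------
    ndarray of int, shape (n, 2)
        Rim pixel coordinates as ``(x, y)`` = (column, row) pairs in
        deterministic row-major order.  If the band exceeds ``max_points``
        it is thinned with a deterministic uniform stride.

    Raises
    ------
    RimUnavailableError
        If the plate mask is empty or the band is empty after exclusion.
    """
    if band_width < 1:
        raise ValueError("band_width must be >= 1")
    if plate_mask.is_empty():
        raise RimUnavailableError("rim unavailable")

    mask = plate_mask.values
    eroded = ndimage.binary_erosion(mask, iterations=band_width)
    band = mask & ~eroded
    for excl in exclusion_masks:
        if excl.shape != plate_mask.shape:
            raise ValueError("exclusion mask shape mismatch")
        band &= ~excl.values
    if not band.any():
        raise RimUnavailableError("rim unavailable")

    rows, cols = np.nonzero(band)  # np.nonzero is row-major
    points = np.column_stack([cols, rows])
    if max_points is not None and len(points) > max_points:
        stride = int(np.ceil(len(points) / max_points))
        points = points[::stride]
    return points


def fit_plane(points: np.ndarray) -> PlaneModel:
    """Least-squares plane ``z = a*x + b*y + c`` through (x, y, z) samples.

    Solved with an SVD-based orthogonal decomposition (``numpy.linalg.lstsq``)
    rather than normal equations, so rank deficiency is detected reliably: a
    singular-value ratio below 1e-10 (collinear support) raises
    :class:`DegeneratePlaneFitError`.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must have shape (n, 3) of (x, y, z)")
    n = len(pts)
    if n < 3:
        raise DegeneratePlaneFitError("degenerate plane fit")

    design = np.column_stack([pts[:, 0], pts[:, 1], np.ones(n)])
    sv = np.linalg.svd(design, compute_uv=False)
    if sv[0] == 0 or sv[-1] / sv[0] < RANK_TOL:
        raise DegeneratePlaneFitError("degenerate plane fit")

    coeffs, _, _, _ = np.linalg.lstsq(design, pts[:, 2], rcond=None)
    residuals = pts[:, 2] - design @ coeffs
    rms = float(np.sqrt(np.mean(residuals**2)))
    return PlaneModel(
        a=float(coeffs[0]), b=float(coeffs[1]), c=float(coeffs[2]),
        n_points=n, rms_residual=rms,
    )


def fit_base_plane(
    depth: DepthMap,
    plate_mask: BinaryMask,
    band_width: int = 5,
    exclusion_masks: tuple[BinaryMask, ...] | list[BinaryMask] = (),
    max_points: int | None = MAX_RIM_POINTS,
) -> PlaneModel:
    """Rim sampling + plane fit in one step: the base plane of a frame."""
    if plate_mask.shape != depth.shape:
        raise ValueError("plate mask shape does not match depth map")
    xy = sample_rim(plate_mask, band_width, exclusion_masks, max_points)
    z = depth.values[xy[:, 1], xy[:, 0]]
    return fit_plane(np.column_stack([xy, z]))


def correct_depth(depth: DepthMap, plane: PlaneModel, clip: bool = True) -> CorrectedDepthMap:
    """Subtract the base plane: ``z_corrected = z_depth - (a*x + b*y + c)``.

    With ``clip=True`` negative values (pixels below the estimated plate
    surface) are set to zero, matching positive-part volume integration.
    The depth map must already be in higher-is-elevated polarity
    (see :func:`normalize_polarity`).
    """
    if depth.polarity is not Polarity.HIGHER_IS_ELEVATED:
        raise ValueError(
            "depth polarity must be higher_is_elevated before plane correction; "
            "apply normalize_polarity first"
        )
    corrected = depth.values - plane.evaluate(depth.shape)
    if clip:
        corrected = np.maximum(corrected, 0.0)
    return CorrectedDepthMap(
        values=corrected, source_plane=plane, pixel_area=depth.pixel_area, clipped=clip
    )


def integrate_volume(corrected: CorrectedDepthMap, mask: BinaryMask) -> VolumeEstimate:
    """Positive-part volume of one item: ``V = sum z_corrected * s**2``.

    Each pixel in the mask with strictly positive corrected depth contributes
    a vertical prism of base area ``s**2`` (the pixel area) and height
    ``z_corrected``.  Non-positive pixels contribute nothing; an empty mask
    yields a zero-volume estimate with a warning rather than an error, so one
    bad mask does not abort a multi-item frame.  Accumulation is in float64.
    """
    if corrected.shape != mask.shape:
        raise ValueError("corrected depth and mask shapes differ")
    if mask.is_empty():
        warnings.warn(
            f"empty mask for item {mask.label!r}; reporting zero volume",
            stacklevel=2,
        )
        return VolumeEstimate(0.0, label=mask.label, frame_id=mask.frame_id, n_pixels=0)
    z = corrected.values[mask.values]
    positive = z > 0.0
    volume = float(np.sum(z[positive], dtype=np.float64) * corrected.pixel_area)
    return VolumeEstimate(
        volume=volume,
        label=mask.label,
        frame_id=mask.frame_id,
        n_pixels=int(positive.sum()),
    )


def normalize_polarity(depth: DepthMap, target: Polarity | str) -> DepthMap:
    """Flip the depth map so its polarity matches ``target``.

    Flipping maps each value ``v`` to ``max(values) - v``, preserving the
    relative ordering of elevations while reversing which extreme is "up".
    A map already in target polarity is returned unchanged.
    """
    target = Polarity(target)
    if depth.polarity is target:
        return depth
    flipped = depth.values.max() - depth.values
    return DepthMap(values=flipped, pixel_area=depth.pixel_area, polarity=target)
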