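"""File I/O: depth rasters, masks, scene manifests, configs, calibration CSV.

Depth rasters are accepted in three forms:

* ``.npy`` — raw float array (lossless, preferred for synthetic scenes),
* ``.tif``/``.tiff`` — 32-bit float single-channel TIFF,
* ``.png`` — 16-bit grayscale with a JSON sidecar ``<name>.json`` holding
  ``{"scale": s, "offset": o, "polarity": ...}`` so that
  ``depth = stored * scale + offset``.

Masks are 8-bit single-channel PNGs, nonzero = foreground, one file per item.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .calibration import CalibrationPair
from .geometry import BinaryMask, DepthMap, Polarity
from .scenes import Scene

__all__ = [
    "read_depth",
    "write_depth",
    "read_mask",
    "write_mask",
    "write_scene",
    "load_scene_manifest",
    "read_calibration_csv",
    "load_config_file",
]


def read_depth(path: str | Path, pixel_area: float = 1.0) -> DepthMap:
    """Read a depth raster; format chosen by extension."""
    path = Path(path)
    suffix = path.suffix.lower()
    polarity = Polarity.HIGHER_IS_ELEVATED
    if suffix == ".npy":
        values = np.load(path)
    elif suffix in (".tif", ".tiff"):
        values = tifffile.imread(path)
    elif suffix == ".png":
        stored = iio.imread(path).astype(np.float64)
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise FileNotFoundError(f"16-bit PNG depth needs a sidecar: {sidecar}")
        meta = json.loads(sidecar.read_text())
        values = stored * meta["scale"] + meta["offset"]
        polarity = Polarity(meta.get("polarity", polarity))
    else:
        raise ValueError(f"unsupported depth raster format: {path.name}")
    return DepthMap(np.asarray(values, dtype=np.float64), pixel_area=pixel_area,
                    polarity=polarity)


def write_depth(depth: DepthMap, path: str | Path) -> None:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".npy":
        np.save(path, depth.values)
    elif suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, depth.values.astype(np.float32))
    elif suffix == ".png":
        vmin, vmax = float(depth.values.min()), float(depth.values.max())
        span = vmax - vmin if vmax > vmin else 1.0
        stored = np.round((depth.values - vmin) / span * 65535).astype(np.uint16)
        iio.imwrite(path, stored)
        sidecar = {"scale": span / 65535, "offset": vmin, "polarity": depth.polarity.value}
        path.with_suffix(".json").write_text(json.dumps(sidecar, sort_keys=True) + "\n")
    else:
        raise ValueError(f"unsupported depth raster format: {path.name}")


def read_mask(path: str | Path, label: str = "", frame_id: str = "") -> BinaryMask:
    values = iio.imread(Path(path))
    if values.ndim == 3:  # tolerate RGB(A) masks: any nonzero channel counts
        values = values.any(axis=-1)
    return BinaryMask(values != 0, label=label, frame_id=frame_id)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    iio.imwrite(Path(path), (mask.values.astype(np.uint8) * 255))


def write_scene(scene: Scene, outdir: str | Path) -> Path:
    """Write a rendered scene's rasters and manifest JSON to a directory.

    Returns the manifest path.  The manifest references the raster files by
    name, so the directory is self-contained and relocatable.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame_id = scene.manifest["frame_id"]

    depth_name = "depth.npy"
    write_depth(scene.depth, outdir / depth_name)
    mask_names: dict[str, str] = {}
    for label, mask in scene.manifest["masks"].items():
        name = f"mask_{label}.png"
        write_mask(mask, outdir / name)
        mask_names[label] = name

    manifest = {
        "schema_version": scene.manifest["schema_version"],
        "frame_id": frame_id,
        "grid": scene.manifest["grid"],
        "detections": scene.manifest["detections"],
        "depth_file": depth_name,
        "mask_files": mask_names,
        "ground_truth": scene.manifest["ground_truth"],
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest_path


def load_scene_manifest(path: str | Path) -> dict:
    """Load a scene manifest from disk into the in-memory (array-backed) form
    that :class:`trayvol.backends.MockBackend` consumes."""
    path = Path(path)
    manifest = json.loads(path.read_text())
    base = path.parent
    frame_id = manifest["frame_id"]
    manifest["depth"] = read_depth(base / manifest.pop("depth_file"))
    manifest["masks"] = {
        label: read_mask(base / name, label=label, frame_id=frame_id)
        for label, name in manifest.pop("mask_files").items()
    }
    manifest["detections"] = [
        {**d, "bbox": list(d["bbox"])} for d in manifest["detections"]
    ]
    return manifest


def read_calibration_csv(path: str | Path) -> dict[str, list[CalibrationPair]]:
    """Read calibration pairs from a CSV with columns food_class,volume,weight."""
    df = pd.read_csv(path)
    required = {"food_class", "volume", "weight"}
    if not required.issubset(df.columns):
        raise ValueError(f"calibration CSV needs columns {sorted(required)}")
    pairs: dict[str, list[CalibrationPair]] = {}
    for row in df.itertuples(index=False):
        pairs.setdefault(str(row.food_class), []).append(
            CalibrationPair(volume=float(row.volume), weight=float(row.weight),
                            food_class=str(row.food_class))
        )
    return pairs


def load_config_file(path: str | Path) -> dict:
    """Load a pipeline config mapping from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    return data
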