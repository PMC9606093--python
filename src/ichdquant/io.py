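"""File formats: TIFF volumes/maps with JSON sidecars, catalogs, run configs.

Physical units never live in TIFF tags: every array on disk is paired with a
JSON sidecar (same stem, ``.json``) that records voxel/pixel size and
provenance.  Reading without a sidecar is an error — a voxel grid without a
physical scale cannot be quantified.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import tifffile
import yaml

from .phase import ProjectionImage, ThicknessMap
from .volume import IchdQuantError, VoxelVolume
from .xfm import CellMask, ElementalMap

__all__ = [
    "read_volume",
    "write_volume",
    "read_map",
    "write_map",
    "write_cell_mask",
    "read_cell_mask",
    "load_run_config",
    "config_hash",
]


class SidecarError(IchdQuantError):
    """Missing or inconsistent JSON sidecar."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _write_sidecar(path: Path, payload: dict[str, Any]) -> None:
    _sidecar_path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _read_sidecar(path: Path) -> dict[str, Any]:
    sc = _sidecar_path(path)
    if not sc.exists():
        raise SidecarError(
            f"no sidecar {sc.name} next to {path.name}: voxel/pixel size unknown"
        )
    return json.loads(sc.read_text())


def write_volume(volume: VoxelVolume, path: str | Path) -> None:
    """Write a volume as a multi-page TIFF (or raw ``.raw``) plus sidecar.

    float32 round-trips bit-identically; integer dtypes are preserved exactly.
    """
    path = Path(path)
    values = volume.values
    if values.dtype not in (np.uint8, np.uint16, np.float32):
        values = values.astype(np.float32)
    if path.suffix == ".raw":
        values.tofile(path)
    else:
        tifffile.imwrite(path, values, photometric="minisblack")
    _write_sidecar(path, {
        "voxel_size_um": volume.voxel_size,
        "shape": list(values.shape),
        "dtype": str(values.dtype),
        "meta": _jsonable(volume.meta),
    })


def read_volume(path: str | Path) -> VoxelVolume:
    path = Path(path)
    sc = _read_sidecar(path)
    shape = tuple(sc["shape"])
    dtype = np.dtype(sc["dtype"])
    if path.suffix == ".raw":
        data = np.fromfile(path, dtype=dtype)
        if data.size != int(np.prod(shape)):
            raise IchdQuantError(
                f"corrupt raw volume {path.name}: expected {int(np.prod(shape))} "
                f"values, found {data.size}"
            )
        values = data.reshape(shape)
    else:
        try:
            values = tifffile.imread(path)
        except Exception as exc:
            raise IchdQuantError(f"corrupt TIFF volume {path.name}: {exc}") from exc
        values = np.asarray(values)
        if values.ndim == 2:
            values = values[None]
        if values.shape != shape:
            raise IchdQuantError(
                f"volume {path.name}: data shape {values.shape} != sidecar {shape}"
            )
    return VoxelVolume(values, voxel_size=float(sc["voxel_size_um"]),
                       meta=sc.get("meta", {}))


def write_map(
    image: ElementalMap | ThicknessMap | ProjectionImage | np.ndarray,
    path: str | Path,
    **extra_meta: Any,
) -> None:
    """Write a 2-D image as single-page float32 TIFF + sidecar."""
    path = Path(path)
    payload: dict[str, Any] = dict(extra_meta)
    if isinstance(image, ElementalMap):
        arr, payload0 = image.values, {
            "pixel_size_um": image.pixel_size_um, "element": image.element,
            "units": "ng/mm2", "meta": _jsonable(image.meta),
        }
    elif isinstance(image, ThicknessMap):
        arr, payload0 = image.thickness, {
            "pixel_size_um": image.pixel_size_um, "units": "m",
            "meta": _jsonable(image.meta),
        }
    elif isinstance(image, ProjectionImage):
        arr, payload0 = image.intensity, {
            "pixel_size_um": image.pixel_size_um,
            "distance_m": image.distance_m,
            "I0": image.flat_intensity,
            "meta": _jsonable(image.meta),
        }
    else:
        arr, payload0 = np.asarray(image), {}
    payload0.update(payload)
    tifffile.imwrite(path, np.asarray(arr, dtype=np.float32))
    _write_sidecar(path, payload0)


def read_map(path: str | Path) -> tuple[np.ndarray, dict[str, Any]]:
    """Read a 2-D float image and its sidecar metadata."""
    path = Path(path)
    sc = _read_sidecar(path)
    arr = np.asarray(tifffile.imread(path))
    return arr, sc


def write_cell_mask(mask: CellMask, path: str | Path) -> None:
    """uint16 label TIFF + CSV class table (``<stem>_classes.csv``)."""
    path = Path(path)
    tifffile.imwrite(path, mask.labels.astype(np.uint16))
    _write_sidecar(path, {"n_labels": len(mask.label_ids)})
    rows = "\n".join(f"{lab},{cls}" for lab, cls in sorted(mask.classes.items()))
    path.with_name(path.stem + "_classes.csv").write_text("label,class\n" + rows + "\n")


def read_cell_mask(path: str | Path) -> CellMask:
    path = Path(path)
    labels = np.asarray(tifffile.imread(path))
    classes: dict[int, str] = {}
    table = path.with_name(path.stem + "_classes.csv")
    if not table.exists():
        raise SidecarError(f"no class table {table.name} next to {path.name}")
    for line in table.read_text().strip().splitlines()[1:]:
        lab, cls = line.split(",")
        classes[int(lab)] = cls
    return CellMask(labels=labels, classes=classes)  # type: ignore[arg-type]


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)


def load_run_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML/JSON run configuration into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    if not isinstance(cfg, dict):
        raise IchdQuantError(f"run config {path.name} must be a mapping")
    return cfg


def config_hash(config: dict[str, Any]) -> str:
    """Stable short hash of a config dict, for provenance stamping."""
    canon = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
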