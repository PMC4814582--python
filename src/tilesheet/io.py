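"""Readers and writers for the package's on-disk formats.

Stacks, PSFs and phantoms travel as ImageJ-compatible TIFF (axis order
z, y, x with voxel sizes in the metadata); binary phase maps as 8-bit
grayscale PNG/BMP (0 ↔ phase 0, 255 ↔ phase π) with a JSON sidecar holding
the grid geometry and design parameters; tiled acquisitions as one TIFF per
tile plus a JSON manifest; metrics and plans as JSON/CSV.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict
from pathlib import Path

import numpy as np
import tifffile

from .imaging_sim import CameraModel, TiledStack, TilingPlan
from .slm_patterns import PhaseMapBinary, SlmGrid

__all__ = [
    "write_stack",
    "read_stack",
    "write_phase_map",
    "read_phase_map",
    "write_tiled_stack",
    "read_tiled_stack",
    "write_json",
    "read_json",
]


def write_stack(path: str | Path, data: np.ndarray, voxel: tuple[float, float, float]) -> None:
    """Write a (z, y, x) stack as ImageJ TIFF with voxel sizes in um."""
    dz, dy, dx = voxel
    tifffile.imwrite(
        str(path),
        np.asarray(data, dtype=np.float32),
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um", "axes": "ZYX"},
    )


def read_stack(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read an ImageJ TIFF stack and its (dz, dy, dx) voxel sizes."""
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        meta = tif.imagej_metadata or {}
        dz = float(meta.get("spacing", 1.0))
        page = tif.pages[0]
        res = page.tags.get("XResolution")
        dx = 1.0
        if res is not None:
            num, den = res.value
            dx = den / num
        res_y = page.tags.get("YResolution")
        dy = dx
        if res_y is not None:
            num, den = res_y.value
            dy = den / num
    return np.asarray(data, dtype=float), (dz, dy, dx)


def write_phase_map(path: str | Path, phase_map: PhaseMapBinary, **design_params) -> None:
    """Export a binary map as an 8-bit image (0 → 0, π → 255) + JSON sidecar."""
    import imageio.v3 as iio

    img = np.where(phase_map.values > math.pi / 2, 255, 0).astype(np.uint8)
    path = Path(path)
    iio.imwrite(path, img)
    sidecar = {
        "grid": asdict(phase_map.grid),
        "phase_levels": [0.0, math.pi],
        "encoding": {"0": 0.0, "255": math.pi},
        "provenance": phase_map.provenance,
        "design_params": design_params,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_phase_map(path: str | Path) -> PhaseMapBinary:
    """Load a binary phase map exported by :func:`write_phase_map`."""
    import imageio.v3 as iio

    path = Path(path)
    img = np.asarray(iio.imread(path))
    if not np.all(np.isin(img, (0, 255))):
        raise ValueError("phase-map image must be strictly binary (0/255)")
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    grid = SlmGrid(**sidecar["grid"])
    values = np.where(img > 127, math.pi, 0.0)
    return PhaseMapBinary(values, grid, sidecar.get("provenance", ""))


def write_tiled_stack(directory: str | Path, stack: TiledStack, **extra_manifest) -> Path:
    """Write one TIFF per tile plus a JSON manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for i, tile in enumerate(stack.tiles):
        name = f"tile_{i:03d}.tif"
        write_stack(directory / name, tile, stack.voxel)
        names.append(name)
    manifest = {
        "tiles": names,
        "positions_um": list(stack.plan.positions),
        "spacing_um": stack.plan.spacing,
        "sheet_length_um": stack.plan.sheet_length,
        "voxel_um": list(stack.voxel),
        "camera": asdict(stack.camera),
        "exposures_per_plane": stack.exposures_per_plane,
        **extra_manifest,
    }
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_tiled_stack(manifest_path: str | Path) -> TiledStack:
    """Load a tiled acquisition from its manifest."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    directory = manifest_path.parent
    tiles = []
    voxel = None
    for name in manifest["tiles"]:
        data, vox = read_stack(directory / name)
        tiles.append(data)
        voxel = vox
    plan = TilingPlan(
        tuple(manifest["positions_um"]),
        manifest["spacing_um"],
        manifest["sheet_length_um"],
    )
    camera = CameraModel(**manifest["camera"])
    return TiledStack(
        tuple(tiles),
        plan,
        tuple(manifest.get("voxel_um", voxel)),
        camera,
        manifest.get("exposures_per_plane", plan.n_tiles),
    )


def write_json(path: str | Path, obj) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
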