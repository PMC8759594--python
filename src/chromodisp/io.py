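"""Reading and writing of images, truth sidecars and measurement tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .morphometry import FocusMeasurement, ProjectedImage, max_project

__all__ = [
    "read_projected_image",
    "write_scene",
    "write_measurements_csv",
    "read_measurements_csv",
]


def _to_uint16(image: np.ndarray) -> np.ndarray:
    image = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    return (image * np.iinfo(np.uint16).max).round().astype(np.uint16)


def read_projected_image(path: str | Path, pixel_size_um: float, channel_name: str = "") -> ProjectedImage:
    """Read a single- or multi-page TIFF; multi-page stacks are max-projected."""
    data = tifffile.imread(str(path))
    if data.ndim == 3:
        return max_project(data, pixel_size_um, channel_name)
    return ProjectedImage(np.asarray(data, dtype=float), pixel_size_um, channel_name)


def write_scene(scene, directory: str | Path, name: str) -> dict[str, Path]:
    """Write a synthetic scene: 16-bit TIFFs plus a JSON truth sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    main = directory / f"{name}.tif"
    tifffile.imwrite(str(main), _to_uint16(scene.image))
    paths["image"] = main
    for channel, data in scene.channels.items():
        p = directory / f"{name}_{channel}.tif"
        if data.dtype == bool:
            tifffile.imwrite(str(p), data.astype(np.uint8) * 255)
        else:
            tifffile.imwrite(str(p), _to_uint16(data))
        paths[channel] = p
    sidecar = directory / f"{name}_truth.json"
    payload = {
        "pixel_size_um": scene.pixel_size_um,
        "truth": scene.truth,
        "params": None if scene.params is None else vars(scene.params) | {},
    }
    sidecar.write_text(json.dumps(payload, default=lambda o: list(o) if isinstance(o, tuple) else o, indent=1))
    paths["truth"] = sidecar
    return paths


def write_measurements_csv(measurements: list[FocusMeasurement], path: str | Path) -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "focus_id": [m.focus_id for m in measurements],
            "nucleus_id": [m.nucleus_id for m in measurements],
            "skeleton_dot_length_um": [m.skeleton_dot_length_um for m in measurements],
            "n_branches": [m.n_branches for m in measurements],
            "centroid_row_px": [m.centroid_px[0] for m in measurements],
            "centroid_col_px": [m.centroid_px[1] for m in measurements],
            "component_area_px": [m.component_area_px for m in measurements],
            "border_touching": [m.border_touching for m in measurements],
            "category": [m.category for m in measurements],
        }
    )
    frame.to_csv(path, index=False)
    return frame


def read_measurements_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
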