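"""Raster and plain-text readers/writers for the pipeline.

Images go through imageio/Pillow; label maps are written as indexed PNG
with one palette entry per class; polygons travel as long-format CSV
(polygon_id, class, x, y — one vertex per row); class statistics as CSV.
"""

from __future__ import annotations

import csv

import imageio.v3 as iio
import numpy as np
from PIL import Image

from .classify import ClassStats
from .errors import CorruptInputError, InvalidImageError
from .validation import PolygonSample

__all__ = [
    "read_rgb",
    "write_rgb",
    "ROLE_COLOURS",
    "write_role_png",
    "read_role_png",
    "write_polygons_csv",
    "read_polygons_csv",
    "write_class_stats_csv",
]

#: Display colours for the survey roles, matching the conventional map
#: rendering: green for healthy oat, yellow for dried, red for the
#: intermediate state, blue for shady ground.
ROLE_COLOURS = {
    "GO": (0, 170, 0),
    "DO": (230, 220, 0),
    "HD": (220, 30, 30),
    "SG": (30, 60, 230),
}


def read_rgb(path) -> np.ndarray:
    """Read an 8/16-bit image as an (H, W, 3) RGB array."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3 or arr.shape[-1] < 3:
        raise InvalidImageError(f"{path}: expected an RGB raster, got shape {arr.shape}")
    return arr[..., :3]


def write_rgb(path, rgb: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(rgb, dtype=np.uint8))


def write_role_png(path, role_map: np.ndarray, classes) -> None:
    """Write a role-index map as an indexed PNG with one palette entry per class."""
    role_map = np.asarray(role_map)
    if role_map.min() < 0 or role_map.max() >= len(classes):
        raise CorruptInputError("role map contains indices outside the class list")
    img = Image.fromarray(role_map.astype(np.uint8), mode="P")
    palette = []
    for cls in classes:
        palette.extend(ROLE_COLOURS.get(cls, (128, 128, 128)))
    img.putpalette(palette)
    img.save(path)


def read_role_png(path) -> np.ndarray:
    img = Image.open(path)
    if img.mode != "P":
        raise InvalidImageError(f"{path}: expected an indexed (palette) PNG")
    return np.asarray(img, dtype=np.int64)


def write_polygons_csv(path, polygons) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["polygon_id", "class", "x", "y"])
        for poly in polygons:
            for x, y in poly.vertices:
                writer.writerow([poly.polygon_id, poly.label, f"{x:g}", f"{y:g}"])


def read_polygons_csv(path) -> list[PolygonSample]:
    groups: dict[str, tuple[str, list[tuple[float, float]]]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            pid = row["polygon_id"]
            label, verts = groups.setdefault(pid, (row["class"], []))
            if row["class"] != label:
                raise CorruptInputError(f"polygon {pid!r} has conflicting class labels")
            verts.append((float(row["x"]), float(row["y"])))
    return [
        PolygonSample(pid, label, verts) for pid, (label, verts) in groups.items()
    ]


def write_class_stats_csv(path, stats: list[ClassStats], roles: dict[int, str] | None = None) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "role", "n_pixels", "mean_L", "mean_a", "mean_b", "sigma"])
        for s in stats:
            role = roles.get(s.label, "") if roles else ""
            writer.writerow(
                [s.label, role, s.n]
                + [f"{v:.6f}" for v in s.mean]
                + [f"{s.sigma:.6f}"]
            )
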