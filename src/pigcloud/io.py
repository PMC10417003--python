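"""Readers and writers for the on-disk formats of the pipeline.

Formats: 8-bit RGB PNG, 16-bit single-channel depth PNG (millimetres),
8-bit flat-colour mask PNG (lossless, so exact colour matching holds),
ASCII PLY point clouds with x/y/z/red/green/blue properties, Labelme-style
polygon annotation JSON, and YAML/JSON intrinsics configs.

Every writer/reader pair round-trips at documented precision: PNGs
bit-exactly, PLY coordinates to 1e-6 m and colours exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml
from shapely import contains_xy
from shapely.geometry import Polygon

from .errors import FormatError
from .evaluation import GroundTruth
from .geometry import CameraIntrinsics, PointCloud

__all__ = [
    "read_depth_png",
    "write_depth_png",
    "read_rgb_png",
    "write_rgb_png",
    "read_ply",
    "write_ply",
    "read_intrinsics",
    "write_intrinsics",
    "read_labelme_json",
    "rasterise_polygon",
]


def write_depth_png(depth: np.ndarray, path: str | Path) -> None:
    """Write a depth grid as a lossless 16-bit single-channel PNG."""
    depth = np.asarray(depth)
    if depth.ndim != 2:
        raise FormatError("depth must be a single-channel 2D grid")
    if depth.dtype != np.uint16:
        if np.any(depth < 0) or np.any(depth > 65535):
            raise FormatError("depth counts out of 16-bit range")
        depth = depth.astype(np.uint16)
    iio.imwrite(Path(path), depth, extension=".png")


def read_depth_png(path: str | Path) -> np.ndarray:
    """Read a 16-bit single-channel depth PNG (bit-exact round-trip).

    Raises :class:`FormatError` for 8-bit or multi-channel input, with a
    hint: depth must be exported as 16-bit grayscale, not a rendered view.
    """
    arr = iio.imread(Path(path), extension=".png")
    if arr.ndim != 2:
        raise FormatError(
            f"{path}: expected single-channel depth, got shape {arr.shape}; "
            "export raw 16-bit grayscale depth, not an RGB rendering"
        )
    if arr.dtype != np.uint16:
        raise FormatError(
            f"{path}: expected 16-bit depth, got {arr.dtype}; "
            "8-bit PNGs cannot hold millimetre depth counts"
        )
    return arr


def write_rgb_png(img: np.ndarray, path: str | Path) -> None:
    img = np.asarray(img, dtype=np.uint8)
    if img.ndim != 3 or img.shape[2] != 3:
        raise FormatError("RGB image must be (H, W, 3)")
    iio.imwrite(Path(path), img, extension=".png")


def read_rgb_png(path: str | Path) -> np.ndarray:
    arr = iio.imread(Path(path), extension=".png")
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    if arr.ndim != 3 or arr.shape[2] != 3 or arr.dtype != np.uint8:
        raise FormatError(f"{path}: expected 8-bit 3-channel PNG, got {arr.dtype} {arr.shape}")
    return arr


def write_ply(cloud: PointCloud, path: str | Path) -> None:
    """Write an ASCII PLY with x,y,z (float) and red,green,blue (uchar).

    Clouds without colours are written white. NaN or infinite coordinates
    are refused with a count of offending points.
    """
    bad = int(np.sum(~np.all(np.isfinite(cloud.points), axis=1)))
    if bad:
        raise FormatError(f"refusing to write {bad} non-finite points")
    n = len(cloud)
    colors = (
        cloud.colors
        if cloud.colors is not None
        else np.full((n, 3), 255, dtype=np.uint8)
    )
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {n}",
        "property float x",
        "property float y",
        "property float z",
        "property uchar red",
        "property uchar green",
        "property uchar blue",
        "end_header",
    ]
    for p, c in zip(cloud.points, colors):
        lines.append(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {c[0]} {c[1]} {c[2]}")
    Path(path).write_text("\n".join(lines) + "\n")


_PLY_TYPE_PARSERS = {
    "float": float, "float32": float, "double": float, "float64": float,
    "uchar": int, "uint8": int, "char": int, "int8": int,
    "short": int, "ushort": int, "int": int, "uint": int,
    "int16": int, "uint16": int, "int32": int, "uint32": int,
}


def read_ply(path: str | Path) -> PointCloud:
    """Read an ASCII PLY; x/y/z and red/green/blue are used, extras ignored."""
    text = Path(path).read_text().splitlines()
    if not text or text[0].strip() != "ply":
        raise FormatError(f"{path}: not a PLY file")
    n_vertex = None
    properties: list[str] = []
    i = 1
    in_vertex_element = False
    while i < len(text):
        line = text[i].strip()
        i += 1
        if line == "end_header":
            break
        parts = line.split()
        if not parts or parts[0] == "comment":
            continue
        if parts[0] == "format":
            if parts[1] != "ascii":
                raise FormatError(f"{path}: only ASCII PLY is supported")
        elif parts[0] == "element":
            in_vertex_element = parts[1] == "vertex"
            if in_vertex_element:
                n_vertex = int(parts[2])
        elif parts[0] == "property" and in_vertex_element:
            if parts[1] == "list":
                raise FormatError(f"{path}: list properties not supported on vertices")
            if parts[1] not in _PLY_TYPE_PARSERS:
                raise FormatError(f"{path}: unknown property type {parts[1]}")
            properties.append(parts[2])
    else:
        raise FormatError(f"{path}: missing end_header")
    if n_vertex is None:
        raise FormatError(f"{path}: no vertex element")
    for axis in ("x", "y", "z"):
        if axis not in properties:
            raise FormatError(f"{path}: vertex property {axis} missing")
    rows = [text[i + k].split() for k in range(n_vertex)]
    if any(len(r) < len(properties) for r in rows):
        raise FormatError(f"{path}: truncated vertex data")
    cols = {name: j for j, name in enumerate(properties)}
    data = np.array(
        [[float(r[cols["x"]]), float(r[cols["y"]]), float(r[cols["z"]])] for r in rows],
        dtype=np.float64,
    ).reshape(-1, 3)
    colors = None
    if all(c in cols for c in ("red", "green", "blue")):
        colors = np.array(
            [[int(float(r[cols["red"]])), int(float(r[cols["green"]])), int(float(r[cols["blue"]]))] for r in rows],
            dtype=np.uint8,
        ).reshape(-1, 3)
    return PointCloud(points=data, colors=colors)


def write_intrinsics(intr: CameraIntrinsics, path: str | Path) -> None:
    p = Path(path)
    if p.suffix.lower() == ".json":
        p.write_text(json.dumps(intr.to_dict(), indent=2) + "\n")
    else:
        p.write_text(yaml.safe_dump(intr.to_dict(), sort_keys=False))


def read_intrinsics(path: str | Path) -> CameraIntrinsics:
    p = Path(path)
    text = p.read_text()
    data = json.loads(text) if p.suffix.lower() == ".json" else yaml.safe_load(text)
    try:
        return CameraIntrinsics.from_dict(data)
    except (KeyError, TypeError, ValueError) as e:
        raise FormatError(f"{path}: invalid intrinsics config: {e}") from e


def rasterise_polygon(
    points: list[tuple[float, float]], shape: tuple[int, int]
) -> np.ndarray:
    """Rasterise a polygon to a boolean mask by the pixel-centre rule.

    A pixel (u, v) is inside iff its centre point lies strictly within the
    polygon. Annotation pixel counts depend on this rule, so it is fixed
    and tested: the axis-aligned square (0,0)-(10,10) covers the 100 pixel
    centres 0.5..9.5 in each axis.
    """
    h, w = shape
    poly = Polygon(points)
    if not poly.is_valid:
        poly = poly.buffer(0)
    xs = np.arange(w) + 0.5
    ys = np.arange(h) + 0.5
    xx, yy = np.meshgrid(xs, ys)
    return contains_xy(poly, xx.ravel(), yy.ravel()).reshape(h, w)


def read_labelme_json(
    path: str | Path, shape: tuple[int, int] | None = None
) -> list[GroundTruth]:
    """Read Labelme-style polygon annotations into ground-truth instances.

    Each polygon shape becomes one instance (duplicate labels stay
    distinct). Malformed shapes are skipped with a warning; the file is an
    error only if it contains shapes but none are valid.
    """
    import logging

    log = logging.getLogger(__name__)
    data = json.loads(Path(path).read_text())
    shapes = data.get("shapes", [])
    if shape is None:
        h = int(data.get("imageHeight", 0))
        w = int(data.get("imageWidth", 0))
        if h <= 0 or w <= 0:
            raise FormatError(f"{path}: no image size in file; pass shape=")
        shape = (h, w)
    out: list[GroundTruth] = []
    skipped = 0
    for k, s in enumerate(shapes):
        pts = s.get("points")
        if not pts or len(pts) < 3:
            log.warning("%s: shape %d has <3 points, skipped", path, k)
            skipped += 1
            continue
        try:
            mask = rasterise_polygon([(float(x), float(y)) for x, y in pts], shape)
        except (TypeError, ValueError) as e:
            log.warning("%s: shape %d invalid (%s), skipped", path, k, e)
            skipped += 1
            continue
        if not mask.any():
            log.warning("%s: shape %d rasterises to zero pixels, skipped", path, k)
            skipped += 1
            continue
        vv, uu = np.nonzero(mask)
        box = (float(uu.min()), float(vv.min()), float(uu.max() + 1), float(vv.max() + 1))
        out.append(GroundTruth(box=box, image_id=str(data.get("imagePath", path)), mask=mask))
    if shapes and not out:
        raise FormatError(f"{path}: no valid shapes ({skipped} skipped)")
    return out
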