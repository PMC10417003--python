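"""Lifting 2D instance masks and depth into per-animal 3D point clouds.

The core procedure: a registered RGB + 16-bit depth frame from a fixed
overhead camera is back-projected through a pinhole model to a full-frame
cloud; a flat-colour instance mask image (one colour per animal, black
background) splits that cloud into per-instance object clouds. Instance
masks themselves can be built by intersecting detection boxes with a
semantic foreground mask.

Conventions (fixed, documented):

* pixels are 0-based with a pixel-centre convention: integer (u, v) is the
  centre of column u, row v;
* boxes are half-open: ``(x_min, y_min, x_max, y_max)`` covers integer
  pixels ``x_min <= u < x_max``;
* the camera frame is right-handed, +z along the optical axis away from the
  camera, so a floor 3 m below the sensor sits at z = 3.0;
* stored depth counts are converted to metres by ``depth_scale`` (0.001 for
  millimetre PNGs); the count 0 means "no return" and never produces a point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    AnnotationError,
    InvalidDepthError,
    RegistrationMismatchError,
)

__all__ = [
    "CameraIntrinsics",
    "PointCloud",
    "BoxMask",
    "InstanceMaskSet",
    "backproject_pixel",
    "project_point",
    "depth_to_cloud",
    "build_instance_masks",
    "extract_object_clouds",
]


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole camera parameters mapping pixel + depth to metric 3D.

    Parameters
    ----------
    fx, fy : float
        Focal lengths in pixels.
    cx, cy : float
        Principal point in pixels (pixel-centre convention).
    width, height : int
        Frame size in pixels.
    depth_scale : float
        Metres per stored depth count; 0.001 for millimetre-encoded 16-bit
        PNGs as produced by RealSense-class sensors.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    depth_scale: float = 0.001

    def __post_init__(self) -> None:
        if not (self.fx > 0 and self.fy > 0):
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the frame")
        if not self.depth_scale > 0:
            raise ValueError("depth_scale must be positive")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("frame size must be positive")

    def to_dict(self) -> dict:
        return {
            "fx": self.fx,
            "fy": self.fy,
            "cx": self.cx,
            "cy": self.cy,
            "width": self.width,
            "height": self.height,
            "depth_scale": self.depth_scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraIntrinsics":
        return cls(
            fx=float(d["fx"]),
            fy=float(d["fy"]),
            cx=float(d["cx"]),
            cy=float(d["cy"]),
            width=int(d["width"]),
            height=int(d["height"]),
            depth_scale=float(d.get("depth_scale", 0.001)),
        )


@dataclass
class PointCloud:
    """An ordered set of 3D points in metres, camera frame, with optional colours.

    ``points`` is an (N, 3) float64 array; ``colors`` is either None or an
    (N, 3) uint8 array parallel to ``points``.
    """

    points: np.ndarray
    colors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point coordinates must be finite")
        if self.colors is not None:
            self.colors = np.asarray(self.colors, dtype=np.uint8).reshape(-1, 3)
            if len(self.colors) != len(self.points):
                raise ValueError("colors must parallel points")

    def __len__(self) -> int:
        return len(self.points)

    @classmethod
    def empty(cls, with_colors: bool = True) -> "PointCloud":
        return cls(
            points=np.empty((0, 3), dtype=np.float64),
            colors=np.empty((0, 3), dtype=np.uint8) if with_colors else None,
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "PointCloud":
        """Return the cloud under the rigid motion ``p -> R p + t``."""
        pts = self.points @ np.asarray(rotation, dtype=np.float64).T + np.asarray(
            translation, dtype=np.float64
        )
        return PointCloud(points=pts, colors=None if self.colors is None else self.colors.copy())


@dataclass(frozen=True)
class BoxMask:
    """A scored detection box: half-open pixel rectangle plus confidence."""

    box: tuple[float, float, float, float]
    score: float = 1.0
    instance_id: str | int | None = None

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.box
        if not (x0 < x1 and y0 < y1):
            raise ValueError(f"degenerate box {self.box}")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")


@dataclass
class InstanceMaskSet:
    """Per-instance flat-colour masks plus the ordered mask colour list.

    ``mask_image`` is (H, W, 3) uint8 with black background; every non-black
    pixel must exactly equal one entry of ``colour_list``. Colour matching is
    exact — masks must be stored losslessly (PNG).
    """

    mask_image: np.ndarray
    colour_list: list[tuple[int, int, int]]
    instance_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mask_image = np.asarray(self.mask_image, dtype=np.uint8)
        if self.mask_image.ndim != 3 or self.mask_image.shape[2] != 3:
            raise ValueError("mask_image must be (H, W, 3)")
        self.colour_list = [tuple(int(c) for c in col) for col in self.colour_list]
        if len(set(self.colour_list)) != len(self.colour_list):
            raise AnnotationError("mask colours must be pairwise distinct")
        if (0, 0, 0) in self.colour_list:
            raise AnnotationError("black is reserved for background")
        if not self.instance_ids:
            self.instance_ids = list(range(len(self.colour_list)))
        if len(self.instance_ids) != len(self.colour_list):
            raise AnnotationError("instance_ids must parallel colour_list")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask_image.shape[:2]

    def instance_mask(self, index: int) -> np.ndarray:
        """Boolean (H, W) mask of the instance at ``index`` in the colour list."""
        colour = np.array(self.colour_list[index], dtype=np.uint8)
        return np.all(self.mask_image == colour, axis=2)

    def validate_against_colour_list(self) -> None:
        """Raise :class:`AnnotationError` if the mask contains unlisted colours."""
        flat = self.mask_image.reshape(-1, 3)
        nonblack = flat[np.any(flat != 0, axis=1)]
        if len(nonblack) == 0:
            return
        present = {tuple(int(c) for c in row) for row in np.unique(nonblack, axis=0)}
        unlisted = present - set(self.colour_list)
        if unlisted:
            raise AnnotationError(f"mask colours not in colour list: {sorted(unlisted)}")


def backproject_pixel(
    u: float, v: float, d_raw: int | float, intr: CameraIntrinsics
) -> tuple[float, float, float]:
    """Back-project one pixel with a raw depth count to a metric 3D point.

    z = d_raw * depth_scale, x = (u - cx) * z / fx, y = (v - cy) * z / fy.

    Raises
    ------
    InvalidDepthError
        If ``d_raw`` is 0 (no sensor return): callers must skip such pixels,
        never emit a point at the origin.
    """
    if d_raw == 0:
        raise InvalidDepthError(f"no depth return at pixel ({u}, {v})")
    if d_raw < 0:
        raise InvalidDepthError("negative depth count")
    if not (0 <= u < intr.width and 0 <= v < intr.height):
        raise ValueError(f"pixel ({u}, {v}) outside {intr.width}x{intr.height} frame")
    z = float(d_raw) * intr.depth_scale
    x = (u - intr.cx) * z / intr.fx
    y = (v - intr.cy) * z / intr.fy
    return (x, y, z)


def project_point(
    x: float, y: float, z: float, intr: CameraIntrinsics
) -> tuple[float, float]:
    """Forward pinhole projection; inverse of :func:`backproject_pixel` for z > 0."""
    if z <= 0:
        raise ValueError("cannot project a point at or behind the camera")
    return (x * intr.fx / z + intr.cx, y * intr.fy / z + intr.cy)


def _backproject_grid(
    depth: np.ndarray, intr: CameraIntrinsics, select: np.ndarray
) -> np.ndarray:
    """Vectorised back-projection of the selected (boolean mask) pixels.

    Pixels are emitted in row-major order. ``select`` must already exclude
    zero-depth pixels.
    """
    vv, uu = np.nonzero(select)
    z = depth[vv, uu].astype(np.float64) * intr.depth_scale
    x = (uu.astype(np.float64) - intr.cx) * z / intr.fx
    y = (vv.astype(np.float64) - intr.cy) * z / intr.fy
    return np.column_stack([x, y, z])


def _check_registered(rgb: np.ndarray, depth: np.ndarray, intr: CameraIntrinsics) -> None:
    if rgb.shape[:2] != depth.shape:
        raise RegistrationMismatchError(
            f"RGB {rgb.shape[:2]} and depth {depth.shape} are not co-registered"
        )
    if depth.shape != (intr.height, intr.width):
        raise RegistrationMismatchError(
            f"depth {depth.shape} does not match intrinsics "
            f"{(intr.height, intr.width)}"
        )
    if np.any(depth < 0):
        raise InvalidDepthError("depth counts must be non-negative")


def depth_to_cloud(
    rgb: np.ndarray, depth: np.ndarray, intr: CameraIntrinsics
) -> PointCloud:
    """Back-project every valid-depth pixel of a registered RGB-D frame.

    Returns the full-frame cloud: one point per pixel with a nonzero depth
    count, coloured from the RGB frame, in row-major pixel order.
    """
    rgb = np.asarray(rgb)
    depth = np.asarray(depth)
    _check_registered(rgb, depth, intr)
    valid = depth > 0
    points = _backproject_grid(depth, intr, valid)
    colors = rgb[valid].astype(np.uint8)
    return PointCloud(points=points, colors=colors)


def build_instance_masks(
    boxes: list[BoxMask],
    semantic_mask: np.ndarray,
    colour_list: list[tuple[int, int, int]],
) -> InstanceMaskSet:
    """Intersect detection boxes with a semantic foreground mask.

    A pixel belongs to instance i iff the semantic mask marks it foreground
    and it lies inside box i. A pixel inside several boxes goes to the box
    with the highest score; exact score ties go to the lower instance index.
    Each instance is painted with its colour from ``colour_list``.
    """
    semantic = np.asarray(semantic_mask).astype(bool)
    h, w = semantic.shape
    if len(colour_list) < len(boxes):
        raise AnnotationError(
            f"colour list has {len(colour_list)} entries for {len(boxes)} boxes"
        )
    mask_image = np.zeros((h, w, 3), dtype=np.uint8)
    # Paint in ascending priority so the highest-score box (ties: lowest
    # index) is painted last and owns contested pixels.
    order = sorted(range(len(boxes)), key=lambda i: (boxes[i].score, -i))
    for i in order:
        x0, y0, x1, y1 = boxes[i].box
        x0 = max(0, int(np.floor(x0)))
        y0 = max(0, int(np.floor(y0)))
        x1 = min(w, int(np.ceil(x1)))
        y1 = min(h, int(np.ceil(y1)))
        if x0 >= x1 or y0 >= y1:
            continue
        region = np.zeros((h, w), dtype=bool)
        region[y0:y1, x0:x1] = True
        region &= semantic
        mask_image[region] = np.array(colour_list[i], dtype=np.uint8)
    ids = [b.instance_id if b.instance_id is not None else i for i, b in enumerate(boxes)]
    return InstanceMaskSet(
        mask_image=mask_image,
        colour_list=list(colour_list[: len(boxes)]),
        instance_ids=ids,
    )


def extract_object_clouds(
    rgb: np.ndarray,
    depth: np.ndarray,
    masks: InstanceMaskSet,
    intr: CameraIntrinsics,
) -> list[PointCloud]:
    """Split a registered RGB-D frame into per-instance object clouds.

    For each colour in the mask colour list, in order, back-project exactly
    the pixels whose mask colour matches that entry exactly and whose depth
    count is nonzero. Points are coloured from the RGB frame (never from the
    mask).

    Raises
    ------
    AnnotationError
        If the mask image contains a non-black colour absent from the list.
    RegistrationMismatchError
        If RGB, depth and mask do not share one pixel grid.
    """
    rgb = np.asarray(rgb)
    depth = np.asarray(depth)
    _check_registered(rgb, depth, intr)
    if masks.shape != depth.shape:
        raise RegistrationMismatchError(
            f"mask {masks.shape} and depth {depth.shape} are not co-registered"
        )
    masks.validate_against_colour_list()
    valid_depth = depth > 0
    clouds: list[PointCloud] = []
    for index in range(len(masks.colour_list)):
        select = masks.instance_mask(index) & valid_depth
        points = _backproject_grid(depth, intr, select)
        colors = rgb[select].astype(np.uint8)
        clouds.append(PointCloud(points=points, colors=colors))
    return clouds
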