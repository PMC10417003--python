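"""Synthetic overhead RGB-D scenes with pixel-exact ground truth.

Emulates the acquisition geometry of a fixed top-view depth camera over a
pen: a flat floor ~3 m below the sensor, 848x480 frames, and several
animal-sized convex blobs (half-ellipsoids) resting on the floor. Each
scene carries everything the rest of the pipeline consumes — RGB, 16-bit
depth in millimetres, a flat-colour instance mask image with its colour
list, tight detection boxes — plus the exact per-instance ground-truth
clouds, so lifting, evaluation, registration and preprocessing are all
testable without any recorded data.

What this emulates and what it does not: the depth image has the correct
metric geometry (floor plane, animal-height elevations, optional Gaussian
millimetre noise with non-returning zero pixels), and illumination scales
the RGB channel only, mirroring day/night capture at the level where depth
is unaffected. It does not model animal shape detail, pose, motion blur or
sensor-specific depth artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import PlacementError
from .evaluation import Detection
from .geometry import BoxMask, CameraIntrinsics, InstanceMaskSet, PointCloud

__all__ = [
    "DEFAULT_PALETTE",
    "SceneConfig",
    "SceneFixture",
    "PerturbedDetections",
    "default_intrinsics",
    "generate_scene",
    "perturb_detections",
]

#: Distinct, non-black instance mask colours (enough for a crowded pen).
DEFAULT_PALETTE: tuple[tuple[int, int, int], ...] = (
    (230, 25, 75),
    (60, 180, 75),
    (255, 225, 25),
    (0, 130, 200),
    (245, 130, 48),
    (145, 30, 180),
    (70, 240, 240),
    (240, 50, 230),
    (210, 245, 60),
    (0, 128, 128),
    (220, 190, 255),
    (170, 110, 40),
)


def default_intrinsics() -> CameraIntrinsics:
    """848x480 overhead pinhole, D455-like focal length (~87 deg HFOV)."""
    return CameraIntrinsics(
        fx=425.0, fy=425.0, cx=423.5, cy=239.5, width=848, height=480, depth_scale=0.001
    )


@dataclass(frozen=True)
class SceneConfig:
    """Generation parameters for one synthetic pen scene.

    Defaults reflect the acquisition setting the pipeline targets: camera
    3 m above the floor, 848x480 frames, pig-scale footprints (ellipse
    semi-axes of 60-110 by 25-50 px at that range span roughly 0.85-1.55 m
    by 0.35-0.7 m on the floor) and back heights of 0.4-0.7 m.
    """

    n_animals: int = 4
    floor_depth_m: float = 3.0
    height_range_m: tuple[float, float] = (0.4, 0.7)
    semi_major_px: tuple[float, float] = (60.0, 110.0)
    semi_minor_px: tuple[float, float] = (25.0, 50.0)
    intrinsics: CameraIntrinsics = field(default_factory=default_intrinsics)
    illumination: float = 1.0
    noise_sigma_mm: float = 0.0
    allow_overlap: bool = False
    max_placement_retries: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 0:
            raise ValueError("n_animals must be non-negative")
        if self.noise_sigma_mm < 0:
            raise ValueError("depth noise must be non-negative")
        if self.illumination <= 0:
            raise ValueError("illumination factor must be positive")
        if self.n_animals > len(DEFAULT_PALETTE):
            raise ValueError(f"at most {len(DEFAULT_PALETTE)} instances supported")


@dataclass
class SceneFixture:
    """One generated scene plus its exact ground truth."""

    rgb: np.ndarray
    depth: np.ndarray
    masks: InstanceMaskSet
    boxes: list[BoxMask]
    gt_clouds: list[PointCloud]
    config: SceneConfig


def _ellipse_footprint(
    shape: tuple[int, int],
    centre: tuple[float, float],
    axes: tuple[float, float],
    angle: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean footprint of a rotated ellipse and its normalised radius^2 field."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dx = xx - centre[0]
    dy = yy - centre[1]
    ca, sa = np.cos(angle), np.sin(angle)
    xe = (dx * ca + dy * sa) / axes[0]
    ye = (-dx * sa + dy * ca) / axes[1]
    r2 = xe * xe + ye * ye
    return r2 <= 1.0, r2


def generate_scene(cfg: SceneConfig) -> SceneFixture:
    """Generate one deterministic scene from its config.

    Floor pixels sit at the floor depth (plus optional noise); animal pixels
    are elevated by a half-ellipsoid height profile, so every mask pixel is
    strictly nearer the camera than the floor. The illumination factor
    scales the RGB image only — depth, masks and hence all ground-truth
    clouds are independent of it.
    """
    rng = np.random.default_rng(cfg.seed)
    intr = cfg.intrinsics
    h, w = intr.height, intr.width
    floor_mm = cfg.floor_depth_m * 1000.0
    depth_f = np.full((h, w), floor_mm, dtype=np.float64)

    # Floor texture: muted concrete grey with deterministic speckle.
    base = np.array([120, 112, 104], dtype=np.float64)
    rgb_f = base + rng.normal(0.0, 6.0, size=(h, w, 3))

    occupied = np.zeros((h, w), dtype=bool)
    mask_image = np.zeros((h, w, 3), dtype=np.uint8)
    colour_list: list[tuple[int, int, int]] = []
    boxes: list[BoxMask] = []
    footprints: list[np.ndarray] = []

    for i in range(cfg.n_animals):
        placed = False
        for _ in range(cfg.max_placement_retries):
            a = rng.uniform(*cfg.semi_major_px)
            b = rng.uniform(*cfg.semi_minor_px)
            angle = rng.uniform(0.0, np.pi)
            ext_x = np.hypot(a * np.cos(angle), b * np.sin(angle))
            ext_y = np.hypot(a * np.sin(angle), b * np.cos(angle))
            if 2 * ext_x >= w - 2 or 2 * ext_y >= h - 2:
                continue
            cx = rng.uniform(ext_x + 1, w - 1 - ext_x - 1)
            cy = rng.uniform(ext_y + 1, h - 1 - ext_y - 1)
            footprint, r2 = _ellipse_footprint((h, w), (cx, cy), (a, b), angle)
            if footprint.sum() == 0:
                continue
            if not cfg.allow_overlap and np.any(footprint & occupied):
                continue
            height = rng.uniform(*cfg.height_range_m)
            elevation = height * np.sqrt(np.clip(1.0 - r2, 0.0, None))
            # Later animals overwrite earlier ones where overlap is allowed
            # (the nearer surface wins is not modelled; adhesion stress only).
            depth_f[footprint] = floor_mm - elevation[footprint] * 1000.0
            colour = DEFAULT_PALETTE[i]
            mask_image[footprint] = np.array(colour, dtype=np.uint8)
            body = np.array([226, 178, 166], dtype=np.float64)  # pale pink hide
            shade = 0.7 + 0.3 * (elevation[footprint] / height)
            rgb_f[footprint] = body * shade[:, None] + rng.normal(
                0.0, 4.0, size=(int(footprint.sum()), 3)
            )
            colour_list.append(colour)
            footprints.append(footprint)
            occupied |= footprint
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place animal {i} within {cfg.max_placement_retries} retries"
            )

    if cfg.noise_sigma_mm > 0:
        depth_f = depth_f + rng.normal(0.0, cfg.noise_sigma_mm, size=(h, w))
    depth = np.clip(np.rint(depth_f), 0, 65535).astype(np.uint16)

    rgb = np.clip(np.rint(rgb_f * cfg.illumination), 0, 255).astype(np.uint8)

    # Overlap may hide earlier instances; masks record the visible colour.
    masks = InstanceMaskSet(
        mask_image=mask_image,
        colour_list=colour_list,
        instance_ids=list(range(len(colour_list))),
    )

    gt_clouds: list[PointCloud] = []
    for i in range(len(colour_list)):
        visible = masks.instance_mask(i) & (depth > 0)
        vv, uu = np.nonzero(visible)
        z = depth[vv, uu].astype(np.float64) * intr.depth_scale
        pts = np.column_stack(
            [
                (uu - intr.cx) * z / intr.fx,
                (vv - intr.cy) * z / intr.fy,
                z,
            ]
        )
        gt_clouds.append(PointCloud(points=pts, colors=rgb[visible]))
        if visible.any():
            boxes.append(
                BoxMask(
                    box=(
                        float(uu.min()),
                        float(vv.min()),
                        float(uu.max() + 1),
                        float(vv.max() + 1),
                    ),
                    score=1.0,
                    instance_id=i,
                )
            )
        else:
            boxes.append(BoxMask(box=(0.0, 0.0, 1.0, 1.0), score=0.0, instance_id=i))

    return SceneFixture(
        rgb=rgb, depth=depth, masks=masks, boxes=boxes, gt_clouds=gt_clouds, config=cfg
    )


@dataclass
class PerturbedDetections:
    """Detections derived from ground truth with known correspondence.

    ``gt_index[k]`` names the ground-truth box detection k was derived from,
    or None for an injected false positive.
    """

    detections: list[Detection]
    gt_index: list[int | None]

    @property
    def n_true(self) -> int:
        return sum(1 for g in self.gt_index if g is not None)

    @property
    def n_false(self) -> int:
        return sum(1 for g in self.gt_index if g is None)


def perturb_detections(
    fixture: SceneFixture,
    drop_rate: float = 0.0,
    jitter_px: float = 0.0,
    fp_rate: float = 0.0,
    seed: int = 0,
) -> PerturbedDetections:
    """Turn a scene's ground-truth boxes into a detection set of known composition.

    Each ground-truth box is dropped with probability ``drop_rate``
    (drop_rate=1 drops all, 0 keeps all); survivors are jittered uniformly
    by up to ``jitter_px`` per coordinate and scored in [0.9, 1.0]. False
    positives are then injected, round(fp_rate * kept) of them, placed
    disjoint from every ground-truth box and scored in [0.3, 0.5] — so
    expected precision and AP follow from the counts analytically.
    """
    for name, rate in (("drop_rate", drop_rate), ("fp_rate", fp_rate)):
        if not 0.0 <= rate <= (1.0 if name == "drop_rate" else float("inf")):
            raise ValueError(f"{name} out of range")
    rng = np.random.default_rng(seed)
    intr = fixture.config.intrinsics
    dets: list[Detection] = []
    origin: list[int | None] = []
    for i, box in enumerate(fixture.boxes):
        if box.score == 0.0:  # fully occluded instance: nothing to detect
            continue
        if drop_rate >= 1.0 or (drop_rate > 0.0 and rng.random() < drop_rate):
            continue
        x0, y0, x1, y1 = box.box
        if jitter_px > 0:
            j = rng.uniform(-jitter_px, jitter_px, size=4)
            x0, y0, x1, y1 = x0 + j[0], y0 + j[1], x1 + j[2], y1 + j[3]
            x0, x1 = min(x0, x1 - 1), max(x1, x0 + 1)
            y0, y1 = min(y0, y1 - 1), max(y1, y0 + 1)
        dets.append(
            Detection(box=(x0, y0, x1, y1), score=float(rng.uniform(0.9, 1.0)), image_id=0)
        )
        origin.append(i)
    n_fp = int(round(fp_rate * len(dets)))
    gt_boxes = [b.box for b in fixture.boxes if b.score > 0]
    for _ in range(n_fp):
        for _attempt in range(500):
            bw = rng.uniform(30, 80)
            bh = rng.uniform(30, 80)
            fx0 = rng.uniform(0, intr.width - bw - 1)
            fy0 = rng.uniform(0, intr.height - bh - 1)
            cand = (fx0, fy0, fx0 + bw, fy0 + bh)
            if all(
                min(cand[2], g[2]) <= max(cand[0], g[0])
                or min(cand[3], g[3]) <= max(cand[1], g[1])
                for g in gt_boxes
            ):
                dets.append(
                    Detection(box=cand, score=float(rng.uniform(0.3, 0.5)), image_id=0)
                )
                origin.append(None)
                break
        else:
            raise PlacementError("could not place a disjoint false-positive box")
    return PerturbedDetections(detections=dets, gt_index=origin)


def rebrightened(fixture: SceneFixture, illumination: float) -> SceneFixture:
    """The same scene regenerated under a different illumination factor."""
    return generate_scene(replace(fixture.config, illumination=illumination))
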