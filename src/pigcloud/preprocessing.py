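"""Frame deduplication by double perceptual hashing, and mosaic augmentation.

Long overhead recordings of a pen produce many near-identical frames. Each
frame is summarised by two 64-bit perceptual hashes of its 8x8 grayscale
thumbnail:

* aHash (average hash): bit set where the thumbnail pixel exceeds the
  thumbnail mean;
* dHash (difference hash): bit set where a pixel is brighter than its right
  neighbour on a 9x8 thumbnail (invariant to uniform brightness scaling).

A frame is dropped iff BOTH its aHash and dHash Hamming distances to some
already-kept frame fall at or below their thresholds — requiring the two
hashes to agree reduces false drops. The first frame is always kept and
output order is preserved.

Mosaic augmentation stitches corner crops of four images around a jittered
centre point into one canvas, translating and clipping their annotations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from PIL import Image

__all__ = [
    "FrameHash",
    "MosaicSample",
    "frame_hashes",
    "hamming",
    "dedup_frames",
    "mosaic",
]

_GRAY_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class FrameHash:
    """aHash + dHash bit strings of one frame (64 bits each at hash_size=8)."""

    ahash_bits: str
    dhash_bits: str


@dataclass
class MosaicSample:
    """A stitched training image with its transformed annotations."""

    image: np.ndarray
    annotations: list[dict]
    dropped: list[dict]
    centre: tuple[int, int]
    seed: int


def _to_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim == 2:
        return img.astype(np.float64)
    return img[..., :3].astype(np.float64) @ _GRAY_WEIGHTS


def _thumbnail(gray: np.ndarray, width: int, height: int) -> np.ndarray:
    pil = Image.fromarray(gray.astype(np.float32), mode="F")
    return np.asarray(pil.resize((width, height), Image.Resampling.LANCZOS), dtype=np.float64)


def frame_hashes(img: np.ndarray, hash_size: int = 8) -> FrameHash:
    """Compute the aHash and dHash bit strings of an image.

    Deterministic for a given image. A constant image yields the documented
    degenerate all-zero hashes (no pixel exceeds the mean, no gradient).
    """
    if hash_size < 2:
        raise ValueError("hash_size must be >= 2")
    gray = _to_gray(img)
    a_thumb = _thumbnail(gray, hash_size, hash_size)
    a_bits = (a_thumb > a_thumb.mean()).ravel()
    d_thumb = _thumbnail(gray, hash_size + 1, hash_size)
    d_bits = (d_thumb[:, 1:] > d_thumb[:, :-1]).ravel()
    return FrameHash(
        ahash_bits="".join("1" if b else "0" for b in a_bits),
        dhash_bits="".join("1" if b else "0" for b in d_bits),
    )


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length bit strings."""
    if len(a) != len(b):
        raise ValueError("bit strings must have equal length")
    return sum(x != y for x, y in zip(a, b))


def dedup_frames(
    frames: Sequence[np.ndarray],
    threshold_a: int = 5,
    threshold_d: int = 5,
    hash_size: int = 8,
) -> list[int]:
    """Indices of frames to keep after double-hash deduplication.

    A frame is dropped iff both hash distances to some already-kept frame
    are at or below the thresholds; the first frame is always kept and order
    is preserved.
    """
    n_bits = hash_size * hash_size
    if not (0 <= threshold_a <= n_bits and 0 <= threshold_d <= n_bits):
        raise ValueError(f"thresholds must lie in [0, {n_bits}]")
    kept: list[int] = []
    kept_hashes: list[FrameHash] = []
    for i, frame in enumerate(frames):
        h = frame_hashes(frame, hash_size)
        duplicate = any(
            hamming(h.ahash_bits, k.ahash_bits) <= threshold_a
            and hamming(h.dhash_bits, k.dhash_bits) <= threshold_d
            for k in kept_hashes
        )
        if not duplicate:
            kept.append(i)
            kept_hashes.append(h)
    return kept


def _clip_box(
    box: tuple[float, float, float, float],
    region: tuple[float, float, float, float],
) -> tuple[float, float, float, float] | None:
    x0 = max(box[0], region[0])
    y0 = max(box[1], region[1])
    x1 = min(box[2], region[2])
    y1 = min(box[3], region[3])
    if x0 >= x1 or y0 >= y1:
        return None
    return (x0, y0, x1, y1)


def _box_area(box: tuple[float, float, float, float]) -> float:
    return (box[2] - box[0]) * (box[3] - box[1])


def mosaic(
    imgs: Sequence[np.ndarray],
    anns: Sequence[list[dict]],
    canvas: tuple[int, int] = (640, 640),
    seed: int = 0,
    centre: tuple[int, int] | None = None,
    min_area_fraction: float = 0.01,
) -> MosaicSample:
    """Stitch corner crops of four images around a jittered centre point.

    The centre is drawn uniformly from the central 50% of the canvas (or
    fixed via ``centre``). Quadrant q of the output is filled with the
    same-corner crop of input q (top-left quadrant from the top-left of
    image 0, and so on). Annotations are dicts with a ``bbox`` key holding
    a half-open ``(x0, y0, x1, y1)`` box; they are translated into canvas
    coordinates, clipped to their quadrant, and dropped when the surviving
    area falls below ``min_area_fraction`` of the original. Deterministic
    under a fixed seed.
    """
    if len(imgs) != 4 or len(anns) != 4:
        raise ValueError("mosaic takes exactly 4 images and 4 annotation sets")
    cw, ch = canvas
    rng = np.random.default_rng(seed)
    if centre is None:
        mcx = int(rng.integers(cw // 4, cw - cw // 4 + 1))
        mcy = int(rng.integers(ch // 4, ch - ch // 4 + 1))
    else:
        mcx, mcy = centre
    first = np.asarray(imgs[0])
    channels = first.shape[2] if first.ndim == 3 else 1
    out = np.zeros((ch, cw, channels) if channels > 1 else (ch, cw), dtype=first.dtype)
    # (canvas region, which input corner the crop is anchored to)
    quadrants = [
        ((0, 0, mcx, mcy), "tl"),
        ((mcx, 0, cw, mcy), "tr"),
        ((0, mcy, mcx, ch), "bl"),
        ((mcx, mcy, cw, ch), "br"),
    ]
    kept_annotations: list[dict] = []
    dropped: list[dict] = []
    for q, ((qx0, qy0, qx1, qy1), corner) in enumerate(quadrants):
        img = np.asarray(imgs[q])
        ih, iw = img.shape[:2]
        qw, qh = qx1 - qx0, qy1 - qy0
        if iw < qw or ih < qh:
            raise ValueError(f"input {q} ({iw}x{ih}) smaller than its quadrant ({qw}x{qh})")
        sx0 = 0 if corner in ("tl", "bl") else iw - qw
        sy0 = 0 if corner in ("tl", "tr") else ih - qh
        out[qy0:qy1, qx0:qx1] = img[sy0 : sy0 + qh, sx0 : sx0 + qw]
        # Source-image box -> canvas coordinates: shift by (qx0 - sx0, qy0 - sy0).
        dx, dy = qx0 - sx0, qy0 - sy0
        for ann in anns[q]:
            bx = ann["bbox"]
            moved = (bx[0] + dx, bx[1] + dy, bx[2] + dx, bx[3] + dy)
            clipped = _clip_box(moved, (qx0, qy0, qx1, qy1))
            record = dict(ann)
            record["source_index"] = q
            if clipped is None or _box_area(clipped) < min_area_fraction * _box_area(bx):
                record["bbox"] = clipped
                dropped.append(record)
            else:
                record["bbox"] = clipped
                kept_annotations.append(record)
    return MosaicSample(
        image=out,
        annotations=kept_annotations,
        dropped=dropped,
        centre=(mcx, mcy),
        seed=seed,
    )
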