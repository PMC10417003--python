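"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — nested loops, exhaustive scans —
and shares no code with the package internals it checks.
"""

from __future__ import annotations

import numpy as np


def backproject_loop(rgb, depth, intr, select=None):
    """Brute-force per-pixel back-projection in row-major order."""
    points, colors = [], []
    h, w = depth.shape
    for v in range(h):
        for u in range(w):
            if depth[v, u] == 0:
                continue
            if select is not None and not select[v, u]:
                continue
            z = float(depth[v, u]) * intr.depth_scale
            points.append(((u - intr.cx) * z / intr.fx, (v - intr.cy) * z / intr.fy, z))
            colors.append(tuple(int(c) for c in rgb[v, u]))
    return np.array(points, dtype=np.float64).reshape(-1, 3), np.array(
        colors, dtype=np.uint8
    ).reshape(-1, 3)


def box_iou_oracle(a, b) -> float:
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    union = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
    return inter / union


def ap_enumeration_oracle(dets, gts, iou_threshold: float) -> float:
    """AP by exhaustive PR enumeration with its own greedy matcher.

    Detections are processed in descending score (stable on ties); each
    claims its best still-free ground truth of the same image with IoU at
    or above the threshold. AP is then the exact area under the all-point
    interpolated PR curve, with the precision envelope recomputed for every
    recall level by a full O(n^2) scan.
    """
    n_gt = len(gts)
    if n_gt == 0 or len(dets) == 0:
        return 0.0
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].score, i))
    used = [False] * n_gt
    flags = []
    for i in order:
        best, best_v = -1, -1.0
        for j in range(n_gt):
            if used[j] or gts[j].image_id != dets[i].image_id:
                continue
            v = box_iou_oracle(dets[i].box, gts[j].box)
            if v >= iou_threshold and v > best_v:
                best, best_v = j, v
        if best >= 0:
            used[best] = True
            flags.append(True)
        else:
            flags.append(False)
    recalls, precisions = [], []
    tp = fp = 0
    for f in flags:
        tp, fp = tp + int(f), fp + int(not f)
        recalls.append(tp / n_gt)
        precisions.append(tp / (tp + fp))
    ap = 0.0
    prev_r = 0.0
    for r in sorted(set(recalls)):
        if r == prev_r:
            continue
        envelope = max(p for rr, p in zip(recalls, precisions) if rr >= r)
        ap += (r - prev_r) * envelope
        prev_r = r
    return ap


def conv3x3_loop(x: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    """Nested-loop 3x3 cross-correlation with zero padding."""
    c_out, c_in = kernels.shape[:2]
    _, h, w = x.shape
    out = np.zeros((c_out, h, w))
    for o in range(c_out):
        for i in range(c_in):
            for y in range(h):
                for xx in range(w):
                    acc = 0.0
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xc = y + dy, xx + dx
                            if 0 <= yy < h and 0 <= xc < w:
                                acc += x[i, yy, xc] * kernels[o, i, dy + 1, dx + 1]
                    out[o, y, xx] += acc
    return out


def res2net_loop(x: np.ndarray, spec) -> np.ndarray:
    """Hierarchy + projections computed with the nested-loop convolution."""
    c = spec.channels
    w = c // 4
    u = np.zeros_like(x)
    for o in range(c):
        for i in range(c):
            u[o] += spec.in_proj[o, i] * x[i]
    xs = [u[i * w : (i + 1) * w] for i in range(4)]
    y1 = xs[0] if spec.k1 is None else conv3x3_loop(xs[0], spec.k1)
    y2 = conv3x3_loop(xs[1], spec.k2)
    y3 = conv3x3_loop(xs[2] + y2, spec.k3)
    y4 = conv3x3_loop(xs[3] + y3, spec.k4)
    concat = np.concatenate([y1, y2, y3, y4], axis=0)
    out = np.zeros_like(x)
    for o in range(c):
        for i in range(c):
            out[o] += spec.out_proj[o, i] * concat[i]
    return out + x


def pairwise_dedup_oracle(hashes, ta: int, td: int) -> list[int]:
    """Keep-set by exhaustive pairwise Hamming distances, first-kept rule."""

    def ham(a, b):
        return sum(x != y for x, y in zip(a, b))

    kept = []
    for i, h in enumerate(hashes):
        if not any(
            ham(h.ahash_bits, hashes[k].ahash_bits) <= ta
            and ham(h.dhash_bits, hashes[k].dhash_bits) <= td
            for k in kept
        ):
            kept.append(i)
    return kept


def random_toy_detections(seed: int, max_boxes: int = 10):
    """One random toy scene: ground-truth boxes plus noisy/spurious detections."""
    from pigcloud.evaluation import Detection, GroundTruth

    rng = np.random.default_rng(seed)
    n_gt = int(rng.integers(1, max_boxes + 1))
    gts, dets = [], []
    for _ in range(n_gt):
        x0, y0 = rng.uniform(0, 200, 2)
        bw, bh = rng.uniform(10, 60, 2)
        gts.append(GroundTruth(box=(x0, y0, x0 + bw, y0 + bh)))
        if rng.random() < 0.85:  # noisy copy of the ground truth
            j = rng.uniform(-4, 4, 4)  # shrink bounded below box width
            dets.append(
                Detection(
                    box=(x0 + j[0], y0 + j[1], x0 + bw + j[2], y0 + bh + j[3]),
                    score=float(rng.uniform(0.2, 1.0)),
                )
            )
    for _ in range(int(rng.integers(0, 4))):  # spurious detections
        x0, y0 = rng.uniform(0, 220, 2)
        bw, bh = rng.uniform(10, 50, 2)
        dets.append(
            Detection(box=(x0, y0, x0 + bw, y0 + bh), score=float(rng.uniform(0.2, 1.0)))
        )
    return dets, gts
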