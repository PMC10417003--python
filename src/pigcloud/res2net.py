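"""Numeric reference forward pass of the Res2Net bottleneck.

The block splits its (1x1-projected) feature channels into four equal groups
X1..X4 and builds a hierarchy of 3x3 convolutions:

    Y1 = X1
    Y2 = K2(X2)
    Y3 = K3(X3 + Y2)
    Y4 = K4(X4 + Y3)

The groups are concatenated, projected back with a 1x1 convolution, and
added to the block input (residual connection). Each later group thereby
sees an increasingly large receptive field — the multiscale, fine-grained
feature mixing the block exists for.

This is a pure-numpy forward computation for studying and testing the
structure; there is no training, normalisation or backprop. An optional
elementwise activation hook can be applied after each group convolution.
Whether X1 passes through its own 3x3 convolution varies between published
variants; the pass-through form is the default and a K1 kernel may be
supplied to enable the convolved form.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.signal import correlate2d

__all__ = ["Res2NetBlockSpec", "res2net_forward"]


def _conv_same(x: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    """3x3 multi-channel cross-correlation with zero padding, stride 1.

    ``x`` is (C_in, H, W); ``kernels`` is (C_out, C_in, 3, 3).
    """
    c_out = kernels.shape[0]
    out = np.zeros((c_out, x.shape[1], x.shape[2]), dtype=np.float64)
    for o in range(c_out):
        for i in range(x.shape[0]):
            out[o] += correlate2d(x[i], kernels[o, i], mode="same", fillvalue=0.0)
    return out


@dataclass
class Res2NetBlockSpec:
    """Weights of one Res2Net bottleneck with a fixed scale of 4.

    ``channels`` must be divisible by 4; each group has width w = channels/4.
    ``k2, k3, k4`` are (w, w, 3, 3) convolution kernels for groups 2-4;
    ``k1`` is optional (pass-through group 1 when None). ``in_proj`` and
    ``out_proj`` are (channels, channels) 1x1-convolution weight matrices.
    """

    channels: int
    k2: np.ndarray
    k3: np.ndarray
    k4: np.ndarray
    in_proj: np.ndarray
    out_proj: np.ndarray
    k1: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.channels % 4 != 0 or self.channels <= 0:
            raise ValueError("channels must be a positive multiple of 4")
        w = self.width
        for name in ("k2", "k3", "k4"):
            k = np.asarray(getattr(self, name), dtype=np.float64)
            if k.shape != (w, w, 3, 3):
                raise ValueError(f"{name} must have shape {(w, w, 3, 3)}, got {k.shape}")
            setattr(self, name, k)
        if self.k1 is not None:
            self.k1 = np.asarray(self.k1, dtype=np.float64)
            if self.k1.shape != (w, w, 3, 3):
                raise ValueError(f"k1 must have shape {(w, w, 3, 3)}")
        for name in ("in_proj", "out_proj"):
            m = np.asarray(getattr(self, name), dtype=np.float64)
            if m.shape != (self.channels, self.channels):
                raise ValueError(f"{name} must be {self.channels}x{self.channels}")
            setattr(self, name, m)

    @property
    def width(self) -> int:
        return self.channels // 4

    @classmethod
    def zeros(cls, channels: int) -> "Res2NetBlockSpec":
        """The all-zero-weight spec: the forward pass is the identity (pure residual)."""
        w = channels // 4
        return cls(
            channels=channels,
            k2=np.zeros((w, w, 3, 3)),
            k3=np.zeros((w, w, 3, 3)),
            k4=np.zeros((w, w, 3, 3)),
            in_proj=np.zeros((channels, channels)),
            out_proj=np.zeros((channels, channels)),
        )

    @classmethod
    def identity_kernels(cls, channels: int) -> "Res2NetBlockSpec":
        """Identity projections and centre-1 (discrete delta) group kernels.

        With these weights the hierarchy is laid bare: Y2 = X2, Y3 = X3 + X2,
        Y4 = X4 + X3 + X2.
        """
        w = channels // 4
        delta = np.zeros((w, w, 3, 3))
        for i in range(w):
            delta[i, i, 1, 1] = 1.0
        return cls(
            channels=channels,
            k2=delta.copy(),
            k3=delta.copy(),
            k4=delta.copy(),
            in_proj=np.eye(channels),
            out_proj=np.eye(channels),
        )

    @classmethod
    def random(cls, channels: int, rng: np.random.Generator, scale: float = 0.1) -> "Res2NetBlockSpec":
        w = channels // 4
        return cls(
            channels=channels,
            k2=rng.normal(0, scale, (w, w, 3, 3)),
            k3=rng.normal(0, scale, (w, w, 3, 3)),
            k4=rng.normal(0, scale, (w, w, 3, 3)),
            in_proj=rng.normal(0, scale, (channels, channels)),
            out_proj=rng.normal(0, scale, (channels, channels)),
        )

    def to_manifest(self) -> dict:
        """Serialise to a plain JSON-compatible weight manifest."""
        d = {
            "channels": self.channels,
            "k2": self.k2.tolist(),
            "k3": self.k3.tolist(),
            "k4": self.k4.tolist(),
            "in_proj": self.in_proj.tolist(),
            "out_proj": self.out_proj.tolist(),
        }
        if self.k1 is not None:
            d["k1"] = self.k1.tolist()
        return d

    @classmethod
    def from_manifest(cls, d: dict) -> "Res2NetBlockSpec":
        return cls(
            channels=int(d["channels"]),
            k2=np.array(d["k2"]),
            k3=np.array(d["k3"]),
            k4=np.array(d["k4"]),
            in_proj=np.array(d["in_proj"]),
            out_proj=np.array(d["out_proj"]),
            k1=np.array(d["k1"]) if "k1" in d else None,
        )


def res2net_forward(
    x: np.ndarray,
    spec: Res2NetBlockSpec,
    activation: Callable[[np.ndarray], np.ndarray] | None = None,
    return_groups: bool = False,
):
    """Forward pass of the bottleneck on a (channels, H, W) feature map.

    Returns the output feature map (same shape), or ``(output, [Y1..Y4])``
    when ``return_groups`` is set. ``activation``, when given, is applied
    elementwise after each group convolution.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 3 or x.shape[0] != spec.channels:
        raise ValueError(
            f"input must be ({spec.channels}, H, W), got {x.shape}"
        )
    act = activation if activation is not None else (lambda a: a)
    w = spec.width
    u = np.tensordot(spec.in_proj, x, axes=([1], [0]))
    groups = [u[i * w : (i + 1) * w] for i in range(4)]
    if spec.k1 is None:
        y1 = groups[0]
    else:
        y1 = act(_conv_same(groups[0], spec.k1))
    y2 = act(_conv_same(groups[1], spec.k2))
    y3 = act(_conv_same(groups[2] + y2, spec.k3))
    y4 = act(_conv_same(groups[3] + y3, spec.k4))
    concat = np.concatenate([y1, y2, y3, y4], axis=0)
    out = np.tensordot(spec.out_proj, concat, axes=([1], [0])) + x
    if return_groups:
        return out, [y1, y2, y3, y4]
    return out
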