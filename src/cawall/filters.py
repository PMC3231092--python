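"""Directional feature filters and feature images for arterial wall detection.

The boundary evidence fed to the dual-curve optimizer is built from three
ingredients:

* the MacLeod oriented edge operator, evaluated at four orientations
  (0, pi/4, pi/2, 3*pi/4) and combined by the sum of absolute responses;
* a small signed enhancement kernel ``f_x`` tuned to the intima-media
  transition geometry (7 x 7, three +1 and three -1 entries), which keeps
  the echo-polarity information that the magnitude term discards;
* for the near wall, an intensity-context image H that measures how dark the
  ``r`` rows beneath each pixel are, evaluated only below the previously
  detected outer wall.

All kernels are applied by correlation (kernel laid onto the image without
flipping) with replicate (edge-clamp) padding; ``flip_fx`` switches the
enhancement kernel to convolution orientation.  Feature maps are min-max
normalized to [0, 1] over the region of interest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "Kernel",
    "FeatureMap",
    "DEFAULT_ORIENTATIONS",
    "build_macleod",
    "build_imt_kernel",
    "build_ld_kernel",
    "build_outer_kernel",
    "kernel_response",
    "compute_feature_F",
    "compute_feature_H",
    "combine_near_wall",
    "normalize_map",
]

#: The four production edge orientations, radians from horizontal.
DEFAULT_ORIENTATIONS: tuple[float, ...] = (0.0, math.pi / 4, math.pi / 2, 3 * math.pi / 4)


@dataclass(frozen=True)
class Kernel:
    """A 2-D correlation kernel with its center cell as anchor."""

    weights: np.ndarray
    label: str

    @property
    def anchor(self) -> tuple[int, int]:
        return (self.weights.shape[0] // 2, self.weights.shape[1] // 2)

    def to_text(self) -> str:
        """Plain-text matrix for inspection."""
        rows = [" ".join(f"{v: .6g}" for v in row) for row in self.weights]
        return f"# {self.label}\n" + "\n".join(rows) + "\n"


@dataclass(frozen=True)
class FeatureMap:
    """A per-ROI grid of boundary-evidence values in [0, 1].

    ``provenance`` records which construction produced it: ``"F"`` (edge
    feature), ``"H"`` (below-darkness context), ``"combined"`` (near-wall
    cost ``1 - F + cH``) or ``"outer"`` (signed outer-wall response).
    """

    values: np.ndarray
    provenance: str

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2:
            raise ValueError("FeatureMap values must be 2-D")
        if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
            raise ValueError("FeatureMap values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def normalize_map(raw: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1].

    Degenerate (flat) maps normalize to all zeros when the raw response is
    identically zero (no evidence anywhere), otherwise to the constant 0.5.
    """
    raw = np.asarray(raw, dtype=float)
    lo, hi = raw.min(), raw.max()
    if hi - lo <= 1e-12 * max(1.0, abs(lo), abs(hi)):
        if max(abs(lo), abs(hi)) <= 1e-9:
            return np.zeros_like(raw)
        return np.full_like(raw, 0.5)
    return (raw - lo) / (hi - lo)


def build_macleod(size: int = 7, d_c: float = 2.0, d_pk: float = 2.0,
                  theta: float = 0.0) -> Kernel:
    """Oriented MacLeod edge kernel.

    The weight at integer offset (x, y) from the anchor (y is the row offset,
    increasing downward) is

        exp(-(x^2 + y^2) / d_c^2) *
            [exp(-((d_xy + d_pk) / d_pk)^2) - exp(-((d_xy - d_pk) / d_pk)^2)]

    with ``d_xy = x sin(theta) - y cos(theta)``, the perpendicular distance of
    the point from the edge axis at orientation ``theta``.  ``d_c`` sets the
    radial decay, ``d_pk`` the distance from the axis to the positive and
    negative weight peaks.  The weights sum to zero exactly (the bracket is
    odd under point reflection of the grid).
    """
    if size % 2 == 0 or size < 3:
        raise ValueError("kernel size must be odd and >= 3")
    if d_c <= 0 or d_pk <= 0:
        raise ValueError("d_c and d_pk must be > 0")
    h = size // 2
    y, x = np.mgrid[-h : h + 1, -h : h + 1].astype(float)
    dxy = x * math.sin(theta) - y * math.cos(theta)
    radial = np.exp(-(x**2 + y**2) / d_c**2)
    lobes = np.exp(-(((dxy + d_pk) / d_pk) ** 2)) - np.exp(-(((dxy - d_pk) / d_pk) ** 2))
    return Kernel(weights=radial * lobes, label=f"macleod({theta:.4g})")


def _imt_far_weights() -> np.ndarray:
    w = np.zeros((7, 7))
    w[0:3, 3] = -1.0
    w[4:7, 4] = 1.0
    return w


def build_imt_kernel(wall: str) -> Kernel:
    """7 x 7 intima-media enhancement kernel for the requested wall.

    The far-wall kernel stacks three -1 entries above the anchor row and
    three +1 entries below (offset one column apart); under correlation it
    responds positively to dark-above / bright-below transitions, i.e. the
    far wall's leading edges.  The near-wall kernel is its 180° rotation.
    """
    if wall == "far":
        return Kernel(weights=_imt_far_weights(), label="imt_far")
    if wall == "near":
        return Kernel(weights=np.rot90(_imt_far_weights(), 2).copy(), label="imt_near")
    raise ValueError(f"wall must be 'near' or 'far', got {wall!r}")


def build_ld_kernel(wall: str) -> Kernel:
    """Lumen-diameter enhancement kernel (reconstruction).

    A 7 x 7 antisymmetric dark-to-bright transition detector analogous to the
    intima-media kernels, centered on a single column: -1 entries in rows 0-2,
    +1 in rows 4-6 of the middle column for the far wall, and its vertical
    mirror for the near wall.  This is a reconstruction of the cited
    enhancement filter, not the original matrix.
    """
    w = np.zeros((7, 7))
    w[0:3, 3] = -1.0
    w[4:7, 3] = 1.0
    if wall == "far":
        return Kernel(weights=w, label="ld_far")
    if wall == "near":
        return Kernel(weights=np.flipud(w).copy(), label="ld_near")
    raise ValueError(f"wall must be 'near' or 'far', got {wall!r}")


def build_outer_kernel() -> Kernel:
    """The 9 x 1 column vector (-1,-1,-1,-1,0,1,1,1,1) used for the outer wall."""
    w = np.array([-1, -1, -1, -1, 0, 1, 1, 1, 1], dtype=float).reshape(9, 1)
    return Kernel(weights=w, label="outer_wall_f1")


def _as_weights(kernel) -> np.ndarray:
    return np.asarray(getattr(kernel, "weights", kernel), dtype=float)


def _check_roi(image: np.ndarray, kshape: tuple[int, int]) -> None:
    if image.shape[0] < kshape[0] or image.shape[1] < kshape[1]:
        raise ValueError(
            f"kernel {kshape} larger than ROI {image.shape}"
        )


def kernel_response(roi_image, kernel, *, flip: bool = False) -> np.ndarray:
    """Raw (unnormalized) response of a kernel on an image.

    Correlation with replicate padding by default; ``flip=True`` applies the
    kernel in convolution orientation instead.
    """
    image = np.asarray(getattr(roi_image, "values", roi_image), dtype=float)
    w = _as_weights(kernel)
    _check_roi(image, w.shape)
    op = ndimage.convolve if flip else ndimage.correlate
    return op(image, w, mode="nearest")


def compute_feature_F(roi_image, f_x, orientations=DEFAULT_ORIENTATIONS, *,
                      macleod_size: int = 7, d_c: float = 2.0, d_pk: float = 2.0,
                      combine: str = "sum", flip_fx: bool = False) -> FeatureMap:
    """Edge feature image F = (combined |MacLeod responses|) + I . f_x.

    Parameters
    ----------
    roi_image : (M, N) array in [0, 1]
        Normalized ROI sub-image.
    f_x : Kernel, array, or None
        Signed enhancement kernel; ``None`` (or all zeros) leaves the pure
        MacLeod magnitude term.
    orientations : iterable of float
        MacLeod orientations in radians.
    combine : {"sum", "max"}
        How the absolute oriented responses are merged.
    flip_fx : bool
        Apply ``f_x`` in convolution rather than correlation orientation.

    Returns
    -------
    FeatureMap
        Min-max normalized to [0, 1]; high values mark boundary evidence.
    """
    image = np.asarray(getattr(roi_image, "values", roi_image), dtype=float)
    if image.ndim != 2:
        raise ValueError("roi_image must be 2-D")
    if image.size and (image.min() < -1e-9 or image.max() > 1 + 1e-9):
        raise ValueError("roi_image must be normalized to [0, 1]")
    if combine not in ("sum", "max"):
        raise ValueError(f"combine must be 'sum' or 'max', got {combine!r}")

    responses = [
        np.abs(kernel_response(image, build_macleod(macleod_size, d_c, d_pk, th)))
        for th in orientations
    ]
    mac = np.sum(responses, axis=0) if combine == "sum" else np.max(responses, axis=0)
    raw = mac
    if f_x is not None:
        raw = raw + kernel_response(image, f_x, flip=flip_fx)
    return FeatureMap(values=normalize_map(raw), provenance="F")


def compute_feature_H(roi_image, y_outer, r: int = 5) -> FeatureMap:
    """Below-darkness context image H for near-wall detection.

    ``H(y, x) = 1 - mean(I[y+1 : y+r+1, x])`` for rows strictly between the
    outer-wall row ``y_outer(x)`` and ``M - r``; all other rows keep the
    neutral value 1.  High values mark rows with dark tissue (lumen/media)
    beneath them.
    """
    image = np.asarray(getattr(roi_image, "values", roi_image), dtype=float)
    if image.ndim != 2:
        raise ValueError("roi_image must be 2-D")
    m, n = image.shape
    r = int(r)
    if not 1 <= r < m:
        raise ValueError(f"r must satisfy 1 <= r < M (r={r}, M={m})")
    y_outer = np.broadcast_to(np.asarray(y_outer, dtype=int), (n,))

    cs = np.vstack([np.zeros((1, n)), np.cumsum(image, axis=0)])
    rows = np.arange(m)
    mean_below = np.full((m, n), np.nan)
    valid = rows <= m - 1 - r
    # mean of rows y+1 .. y+r
    mean_below[valid] = (cs[rows[valid] + 1 + r] - cs[rows[valid] + 1]) / r

    band = (rows[:, None] > y_outer[None, :]) & (rows[:, None] < m - r)
    h = np.ones((m, n))
    h[band] = 1.0 - mean_below[band]
    return FeatureMap(values=h, provenance="H")


def combine_near_wall(F, H, c: float = 0.5) -> FeatureMap:
    """Near-wall cost map ``1 - F + c*H``, min-max normalized.

    Low values mark boundary evidence (cost orientation): strong edges where
    the tissue beneath is bright (the adventitia-media interface sits above
    media followed by the bright intima band) score lower than curves lying
    with pure dark lumen beneath, which is what separates the true
    (adventitia, intima) pair from a sub-intima noise layer.
    """
    fv = np.asarray(getattr(F, "values", F), dtype=float)
    hv = np.asarray(getattr(H, "values", H), dtype=float)
    if fv.shape != hv.shape:
        raise ValueError(f"shape mismatch: F {fv.shape} vs H {hv.shape}")
    return FeatureMap(values=normalize_map(1.0 - fv + c * hv), provenance="combined")
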