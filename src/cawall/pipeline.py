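"""The per-sequence wall-detection procedure.

For each frame of a B-mode sequence the rectangular ROI (supplied once, for
the first frame) is split into an upper (near-wall) and lower (far-wall)
half.  Each half is re-registered to the moving artery by NCC tracking
against its first-frame template and the two wall interfaces are extracted
jointly by dual dynamic programming:

* far wall: cost = 1 - F with F built from the MacLeod bank and the far
  intima-media enhancement kernel; the upper curve is the intima
  (lumen-intima interface), the lower the adventitia (media-adventitia
  interface);
* near wall: first the outer wall is found by a single DP on the signed
  response of the 9 x 1 transition kernel, then the cost 1 - F + cH combines
  the edge feature (enhancement kernel -f_IMT(far), i.e. trailing-edge
  polarity) with the below-darkness context H evaluated under the outer
  wall; the upper curve is the adventitia, the lower the intima.

Detected traces are smoothed along columns by a shrinking-window moving
average, and the lumen diameter series is the distance between the two
intima traces.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from . import filters
from .ddp import DdpConfig, run_ddp, run_single_dp
from .tracking import TrackState, track_frame

logger = logging.getLogger("cawall")

__all__ = [
    "RoiSpec",
    "PipelineParams",
    "WallResult",
    "LumenSeries",
    "PipelineResult",
    "split_roi",
    "detect_near_wall",
    "detect_far_wall",
    "smooth_traces",
    "lumen_series",
    "run_pipeline",
]


@dataclass(frozen=True)
class RoiSpec:
    """Rectangular region of interest: top-left corner plus size, pixels."""

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("ROI width and height must be >= 1")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError("ROI corner must be non-negative")

    def shifted(self, dy: int) -> "RoiSpec":
        return replace(self, y0=self.y0 + dy)

    def extract(self, frame: np.ndarray) -> np.ndarray:
        if self.y0 + self.height > frame.shape[0] or self.x0 + self.width > frame.shape[1]:
            raise ValueError(f"ROI {self} leaves the frame of shape {frame.shape}")
        return frame[self.y0 : self.y0 + self.height, self.x0 : self.x0 + self.width]

    @property
    def columns(self) -> np.ndarray:
        return np.arange(self.x0, self.x0 + self.width)


@dataclass(frozen=True)
class PipelineParams:
    """All tunable parameters of the detection procedure."""

    # feature construction
    d_c: float = 2.0
    d_pk: float = 2.0
    macleod_size: int = 7
    orientations: tuple[float, ...] = filters.DEFAULT_ORIENTATIONS
    combine: str = "sum"
    flip_fx: bool = False
    r: int = 5       # depth of the below-darkness window H, pixels
    c: float = 0.5   # weight of H in the near-wall cost
    # dual dynamic programming
    alpha: float = 0.25
    beta: float = 0.15
    k: int = 1
    d_min: int = 4
    d_max: int | None = None  # None -> 0.9 * M
    # tracking and smoothing
    delta_s: int = 10
    smooth_window: int = 5

    def ddp_config(self) -> DdpConfig:
        return DdpConfig(alpha=self.alpha, beta=self.beta, k=self.k,
                         d_min=self.d_min, d_max=self.d_max)


@dataclass
class WallResult:
    """Per-frame dual boundary traces of one wall, in full-frame coordinates.

    For the near wall the adventitia lies above the intima (smaller rows);
    for the far wall the intima lies above the adventitia.
    """

    wall: str
    intima: np.ndarray       # (L, N) rows
    adventitia: np.ndarray   # (L, N) rows
    columns: np.ndarray      # (N,) frame column indices
    rois: list[RoiSpec]      # ROI actually used per frame (post-tracking)
    shifts: np.ndarray       # (L,) cumulative tracking shift
    ncc: np.ndarray          # (L,) best NCC per frame (nan for the first)
    total_costs: np.ndarray  # (L,) DDP objective of the dual trace

    @property
    def n_frames(self) -> int:
        return self.intima.shape[0]


@dataclass
class LumenSeries:
    """Per-frame lumen diameter: far intima minus near intima, per column."""

    diameter_px: np.ndarray  # (L, N)
    mean_px: np.ndarray      # (L,)
    pixel_size_mm: float

    @property
    def diameter_mm(self) -> np.ndarray:
        return self.diameter_px * self.pixel_size_mm

    @property
    def mean_mm(self) -> np.ndarray:
        return self.mean_px * self.pixel_size_mm


@dataclass
class PipelineResult:
    near: WallResult
    far: WallResult
    lumen: LumenSeries


def split_roi(roi: RoiSpec) -> tuple[RoiSpec, RoiSpec]:
    """Split an ROI into the upper (near-wall) and lower (far-wall) halves.

    Odd heights give the extra row to the upper half.
    """
    if roi.height < 2:
        raise ValueError("ROI height must be >= 2 to split")
    upper_h = (roi.height + 1) // 2
    upper = replace(roi, height=upper_h)
    lower = replace(roi, y0=roi.y0 + upper_h, height=roi.height - upper_h)
    return upper, lower


def _normalize_image(image: np.ndarray) -> np.ndarray:
    lo, hi = image.min(), image.max()
    if hi == lo:
        return np.zeros_like(image, dtype=float)
    return (image - lo) / (hi - lo)


def _tracked_rois(sequence, roi: RoiSpec, params: PipelineParams):
    """Yield (frame_index, roi_used, shift, ncc_value) registering each frame."""
    frames = sequence.frames
    state = TrackState(
        template=roi.extract(frames[0]).copy(),
        x0=roi.x0, y0=roi.y0, delta_s=params.delta_s,
    )
    yield 0, roi, 0, math.nan
    for j in range(1, frames.shape[0]):
        track_frame(state, frames[j])
        yield j, roi.shifted(state.current_shift), state.current_shift, state.ncc_trace[-1]


def _detect_wall(sequence, roi: RoiSpec, params: PipelineParams, wall: str) -> WallResult:
    frames = sequence.frames
    n_frames = frames.shape[0]
    intima = np.empty((n_frames, roi.width))
    adventitia = np.empty((n_frames, roi.width))
    rois: list[RoiSpec] = []
    shifts = np.zeros(n_frames, dtype=int)
    nccs = np.full(n_frames, np.nan)
    costs = np.empty(n_frames)

    fx_far = filters.build_imt_kernel("far").weights
    f_outer = filters.build_outer_kernel()
    cfg = params.ddp_config()

    for j, roi_j, shift, ncc_v in _tracked_rois(sequence, roi, params):
        sub = _normalize_image(roi_j.extract(frames[j]))
        if wall == "near":
            f1 = filters.FeatureMap(
                values=filters.normalize_map(
                    filters.kernel_response(sub, f_outer, flip=params.flip_fx)
                ),
                provenance="outer",
            )
            y_outer = run_single_dp(f1, replace(cfg, orientation="maximize_feature"))
            fmap = filters.compute_feature_F(
                sub, -fx_far, params.orientations, macleod_size=params.macleod_size,
                d_c=params.d_c, d_pk=params.d_pk, combine=params.combine,
                flip_fx=params.flip_fx,
            )
            hmap = filters.compute_feature_H(sub, y_outer, r=params.r)
            cost = filters.combine_near_wall(fmap, hmap, c=params.c)
        else:
            fmap = filters.compute_feature_F(
                sub, fx_far, params.orientations, macleod_size=params.macleod_size,
                d_c=params.d_c, d_pk=params.d_pk, combine=params.combine,
                flip_fx=params.flip_fx,
            )
            cost = filters.FeatureMap(values=1.0 - fmap.values, provenance="combined")
        try:
            trace, _ = run_ddp(cost, cfg)
        except ValueError as err:
            raise ValueError(f"frame {j}: DDP failed on the {wall} wall: {err}") from err

        upper = roi_j.y0 + trace.y1
        lower = roi_j.y0 + trace.y2
        if wall == "near":
            adventitia[j], intima[j] = upper, lower
        else:
            intima[j], adventitia[j] = upper, lower
        rois.append(roi_j)
        shifts[j] = shift
        nccs[j] = ncc_v
        costs[j] = trace.total_cost
        logger.debug("frame %d %s wall: shift=%+d ncc=%.4f cost=%.4f",
                     j, wall, shift, ncc_v, trace.total_cost)

    return WallResult(wall=wall, intima=intima, adventitia=adventitia,
                      columns=roi.columns, rois=rois, shifts=shifts,
                      ncc=nccs, total_costs=costs)


def detect_near_wall(sequence, roi: RoiSpec, params: PipelineParams | None = None) -> WallResult:
    """Detect the near-wall adventitia and intima in every frame.

    ``roi`` is the upper half of the full ROI (it must contain the near wall
    in every frame once tracking is applied).
    """
    return _detect_wall(sequence, roi, params or PipelineParams(), "near")


def detect_far_wall(sequence, roi: RoiSpec, params: PipelineParams | None = None) -> WallResult:
    """Detect the far-wall intima and adventitia in every frame."""
    return _detect_wall(sequence, roi, params or PipelineParams(), "far")


def _smooth1d(trace: np.ndarray, window: int) -> np.ndarray:
    half = window // 2
    n = trace.size
    cs = np.concatenate([[0.0], np.cumsum(trace)])
    i = np.arange(n)
    lo = np.maximum(0, i - half)
    hi = np.minimum(n, i + half + 1)
    return (cs[hi] - cs[lo]) / (hi - lo)


def smooth_traces(result: WallResult, window: int = 5) -> WallResult:
    """Moving-average smoothing of the traces along columns.

    The window must be odd; near the edges it shrinks symmetrically.  The
    wall's layer ordering is re-checked after smoothing.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 1")
    if window == 1:
        return result
    intima = np.vstack([_smooth1d(row, window) for row in result.intima])
    adventitia = np.vstack([_smooth1d(row, window) for row in result.adventitia])
    if result.wall == "near":
        ok = np.all(adventitia <= intima)
    else:
        ok = np.all(intima <= adventitia)
    if not ok:
        raise ValueError("layer ordering violated after smoothing")
    return replace(result, intima=intima, adventitia=adventitia)


def lumen_series(near: WallResult, far: WallResult, pixel_size_mm: float) -> LumenSeries:
    """Lumen diameter per column and frame: far intima minus near intima."""
    if near.intima.shape != far.intima.shape or not np.array_equal(near.columns, far.columns):
        raise ValueError("near and far results must share frames and column span")
    diam = far.intima - near.intima
    if (diam <= 0).any():
        j, x = np.argwhere(diam <= 0)[0]
        raise ValueError(
            f"crossing walls: non-positive lumen diameter at frame {j}, column {near.columns[x]}"
        )
    return LumenSeries(diameter_px=diam, mean_px=diam.mean(axis=1),
                       pixel_size_mm=pixel_size_mm)


def run_pipeline(sequence, roi: RoiSpec, params: PipelineParams | None = None) -> PipelineResult:
    """Full procedure: split ROI, detect both walls, smooth, assemble the LD series."""
    params = params or PipelineParams()
    upper, lower = split_roi(roi)
    near = smooth_traces(detect_near_wall(sequence, upper, params), params.smooth_window)
    far = smooth_traces(detect_far_wall(sequence, lower, params), params.smooth_window)
    lumen = lumen_series(near, far, sequence.pixel_size_mm)
    return PipelineResult(near=near, far=far, lumen=lumen)
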