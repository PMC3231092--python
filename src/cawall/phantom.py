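"""Synthetic dynamic B-mode-like artery sequences with exact boundary truth.

The phantom renders a longitudinal view of a layered arterial wall —
dark lumen, bright intima band, dark media, bright adventitia band,
moderate-echo surrounding tissue — pulsating over the cardiac cycle and
drifting vertically as a whole, with multiplicative speckle.  Rows increase
downward; the near wall occupies smaller row indices than the far wall.

Boundary coordinates are defined by the standard reading conventions:

* near wall: adventitia = adventitia-media interface (bottom of the upper
  bright band), intima = intima-lumen interface (trailing edges);
* far wall: intima = lumen-intima interface, adventitia = media-adventitia
  interface (leading edges).

Layer transitions are rendered as hard steps convolved with a Gaussian of
``EDGE_SIGMA_PX`` so the sub-pixel truth is physically meaningful.  Speckle
is a multiplicative Rayleigh factor with mean one, blended by
``speckle_scale`` and clamped to [0, 255] — a first-order surrogate for
post-compression B-mode speckle.  Optional extras reproduce two clinically
relevant complications: a plaque bump (focal extra wall thickness bulging
into the lumen) and a patchy bright sub-intima noise layer in the lumen
during systolic frames, which mimics the echoes that blur the near-wall
intima-lumen interface when the wall moves fastest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.special import ndtr

from .io import FrameSequence
from .pipeline import RoiSpec

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "PlaqueSpec",
    "SubintimaNoiseSpec",
    "generate_sequence",
    "default_roi",
    "systolic_frames",
]

# Rendering constants (8-bit intensity levels and geometry, pixels).
LUMEN_LEVEL = 15.0
MEDIA_LEVEL = 45.0
INTIMA_LEVEL = 205.0
ADVENTITIA_LEVEL = 205.0
TISSUE_LEVEL = 75.0
INTIMA_BAND_PX = 3.2     # thickness of the bright intima echo band
ADVENTITIA_BAND_PX = 6.0  # thickness of the bright adventitia echo band
EDGE_SIGMA_PX = 0.7      # Gaussian blur of layer transitions
DRIFT_PHASE = math.pi / 4  # phase lag of bulk motion vs pulsation


@dataclass(frozen=True)
class PlaqueSpec:
    """Focal extra wall thickness (raised-cosine bump bulging into the lumen)."""

    wall: str  # "near" or "far"
    col_start: int
    col_stop: int
    extra_px: float

    def profile(self, width: int) -> np.ndarray:
        if self.wall not in ("near", "far"):
            raise ValueError(f"plaque wall must be 'near' or 'far', got {self.wall!r}")
        if not 0 <= self.col_start < self.col_stop <= width:
            raise ValueError("plaque column range outside the image")
        x = np.arange(width, dtype=float)
        p = np.zeros(width)
        span = self.col_stop - self.col_start
        inside = (x >= self.col_start) & (x < self.col_stop)
        p[inside] = self.extra_px * 0.5 * (
            1 - np.cos(2 * math.pi * (x[inside] - self.col_start) / span)
        )
        return p


@dataclass(frozen=True)
class SubintimaNoiseSpec:
    """Patchy bright echo band in the lumen below the near-wall intima.

    Active only during the configured frame ranges (systole); the band's
    column profile is a smoothed seeded random field, so the echoes form
    elongated blobs rather than a coherent full-width layer.
    """

    intensity: float = INTIMA_LEVEL
    thickness_px: float = 3.0
    frames: tuple[tuple[int, int], ...] = ()
    gap_px: float = 2.0
    smooth_cols: float = 15.0

    def active(self, frame: int) -> bool:
        return any(a <= frame < b for a, b in self.frames)


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions of a synthetic sequence.

    Geometry is in pixels; the lumen diameter follows
    ``baseline + amplitude * sin(2*pi*t / frames_per_cycle)`` and the whole
    wall complex translates by
    ``wall_drift_amplitude * sin(2*pi*t / frames_per_cycle + pi/4)``.
    """

    width: int = 200
    height: int = 160
    n_frames: int = 80
    pixel_size_mm: float = 0.106
    lumen_center_row: float = 80.0
    baseline_lumen_diameter: float = 40.0
    pulsation_amplitude: float = 4.0
    frames_per_cycle: int = 40
    imt_near: float = 6.5
    imt_far: float = 6.5
    wall_drift_amplitude: float = 1.0
    speckle_scale: float = 0.5
    plaque: PlaqueSpec | None = None
    subintima_noise: SubintimaNoiseSpec | None = None
    seed: int = 0


@dataclass
class PhantomTruth:
    """Analytic sub-pixel boundary rows per frame and column."""

    near_intima: np.ndarray      # (L, W)
    near_adventitia: np.ndarray  # (L, W)
    far_intima: np.ndarray       # (L, W)
    far_adventitia: np.ndarray   # (L, W)
    bulk_shift: np.ndarray       # (L,)
    config: PhantomConfig = field(repr=False, default=None)

    @property
    def lumen_diameter(self) -> np.ndarray:
        """Per frame and column: far intima row minus near intima row."""
        return self.far_intima - self.near_intima

    @property
    def n_frames(self) -> int:
        return self.near_intima.shape[0]


def systolic_frames(config: PhantomConfig, fraction: float = 0.25) -> tuple[tuple[int, int], ...]:
    """Frame ranges of rapid lumen expansion (one per cardiac cycle)."""
    span = max(1, int(round(fraction * config.frames_per_cycle)))
    ranges = []
    for start in range(0, config.n_frames, config.frames_per_cycle):
        ranges.append((start, min(start + span, config.n_frames)))
    return tuple(ranges)


def _truth_for(config: PhantomConfig) -> PhantomTruth:
    L, W = config.n_frames, config.width
    t = np.arange(L, dtype=float)
    ld = config.baseline_lumen_diameter + config.pulsation_amplitude * np.sin(
        2 * math.pi * t / config.frames_per_cycle
    )
    shift = config.wall_drift_amplitude * np.sin(
        2 * math.pi * t / config.frames_per_cycle + DRIFT_PHASE
    )
    center = config.lumen_center_row + shift

    p_near = np.zeros(W)
    p_far = np.zeros(W)
    if config.plaque is not None:
        if config.plaque.wall == "near":
            p_near = config.plaque.profile(W)
        else:
            p_far = config.plaque.profile(W)

    near_base = center[:, None] - ld[:, None] / 2.0  # (L, W) broadcast
    far_base = center[:, None] + ld[:, None] / 2.0
    ones = np.ones(W)
    near_intima = near_base * ones + p_near
    near_adv = near_base * ones - config.imt_near
    far_intima = far_base * ones - p_far
    far_adv = far_base * ones + config.imt_far
    return PhantomTruth(
        near_intima=near_intima,
        near_adventitia=near_adv,
        far_intima=far_intima,
        far_adventitia=far_adv,
        bulk_shift=shift,
        config=config,
    )


def _validate(config: PhantomConfig, truth: PhantomTruth) -> None:
    if config.baseline_lumen_diameter - config.pulsation_amplitude <= 0:
        raise ValueError("baseline_lumen_diameter - pulsation_amplitude must be > 0")
    if config.imt_near <= INTIMA_BAND_PX or config.imt_far <= INTIMA_BAND_PX:
        raise ValueError(f"IMT must exceed the intima band ({INTIMA_BAND_PX} px)")
    margin = 3 * EDGE_SIGMA_PX
    top = truth.near_adventitia - ADVENTITIA_BAND_PX - margin
    bottom = truth.far_adventitia + ADVENTITIA_BAND_PX + margin
    ld = truth.lumen_diameter
    for j in range(truth.n_frames):
        if top[j].min() < 0 or bottom[j].max() > config.height - 1:
            raise ValueError(
                f"frame {j}: wall geometry escapes the {config.height}-row image "
                f"(rows {top[j].min():.1f}..{bottom[j].max():.1f})"
            )
        if ld[j].min() <= 0:
            raise ValueError(f"frame {j}: non-positive lumen diameter")
        if config.subintima_noise is not None and config.subintima_noise.active(j):
            depth = config.subintima_noise.gap_px + config.subintima_noise.thickness_px
            if (truth.near_intima[j] + depth >= truth.far_intima[j] - 1).any():
                raise ValueError(f"frame {j}: sub-intima noise layer escapes the lumen")


def _render_clean(truth: PhantomTruth, j: int) -> np.ndarray:
    cfg = truth.config
    y = np.arange(cfg.height, dtype=float)[:, None]  # (H, 1)
    sigma = EDGE_SIGMA_PX

    def edge(position_rows: np.ndarray) -> np.ndarray:
        return ndtr((y - position_rows[None, :]) / sigma)

    ni, na = truth.near_intima[j], truth.near_adventitia[j]
    fi, fa = truth.far_intima[j], truth.far_adventitia[j]
    img = np.full((cfg.height, cfg.width), TISSUE_LEVEL)
    img += (ADVENTITIA_LEVEL - TISSUE_LEVEL) * edge(na - ADVENTITIA_BAND_PX)
    img += (MEDIA_LEVEL - ADVENTITIA_LEVEL) * edge(na)
    img += (INTIMA_LEVEL - MEDIA_LEVEL) * edge(ni - INTIMA_BAND_PX)
    img += (LUMEN_LEVEL - INTIMA_LEVEL) * edge(ni)
    img += (INTIMA_LEVEL - LUMEN_LEVEL) * edge(fi)
    img += (MEDIA_LEVEL - INTIMA_LEVEL) * edge(fi + INTIMA_BAND_PX)
    img += (ADVENTITIA_LEVEL - MEDIA_LEVEL) * edge(fa)
    img += (TISSUE_LEVEL - ADVENTITIA_LEVEL) * edge(fa + ADVENTITIA_BAND_PX)
    return img


def _noise_profile(rng: np.random.Generator, width: int, smooth_cols: float) -> np.ndarray:
    g = gaussian_filter1d(rng.normal(size=width), smooth_cols, mode="wrap")
    sd = g.std()
    if sd == 0:
        return np.zeros(width)
    g = g / sd
    prof = np.clip(g, 0.0, None)
    peak = prof.max()
    return prof / peak if peak > 0 else prof


def generate_sequence(config: PhantomConfig) -> tuple[FrameSequence, PhantomTruth]:
    """Render a seeded phantom sequence and its exact boundary truth.

    Returns 8-bit grayscale frames (as a :class:`FrameSequence`, values
    divided by 255) and the noise-free analytic truth.  Identical config and
    seed give a bit-identical sequence.
    """
    truth = _truth_for(config)
    _validate(config, truth)
    rng = np.random.default_rng(config.seed)
    rayleigh_scale = math.sqrt(2.0 / math.pi)  # mean-1 Rayleigh factor

    frames = np.empty((config.n_frames, config.height, config.width), dtype=np.uint8)
    y = np.arange(config.height, dtype=float)[:, None]
    for j in range(config.n_frames):
        img = _render_clean(truth, j)
        noise = config.subintima_noise
        if noise is not None and noise.active(j):
            amp = _noise_profile(rng, config.width, noise.smooth_cols)
            top = truth.near_intima[j] + noise.gap_px
            bot = top + noise.thickness_px
            band = ndtr((y - top[None, :]) / EDGE_SIGMA_PX) - ndtr(
                (y - bot[None, :]) / EDGE_SIGMA_PX
            )
            img += (noise.intensity - LUMEN_LEVEL) * amp[None, :] * band
        if config.speckle_scale > 0:
            factor = 1.0 + config.speckle_scale * (
                rng.rayleigh(scale=rayleigh_scale, size=img.shape) - 1.0
            )
            img = img * factor
        frames[j] = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    seq = FrameSequence(frames=frames.astype(float) / 255.0,
                        pixel_size_mm=config.pixel_size_mm)
    return seq, truth


def default_roi(truth: PhantomTruth, purpose: str, margin: float = 6.0,
                col_margin: int = 4) -> RoiSpec:
    """Rectangle covering the relevant wall(s) in every frame with a margin.

    ``purpose`` selects the wall(s): ``"imt_near"``, ``"imt_far"`` or
    ``"lumen"`` (both walls; vertically centered on the mean lumen center so
    an equal split puts one wall in each half).
    """
    if truth is None or truth.n_frames == 0:
        raise ValueError("empty truth: cannot derive an ROI")
    cfg = truth.config
    band = ADVENTITIA_BAND_PX
    if purpose == "imt_near":
        top = truth.near_adventitia.min() - band - margin
        bottom = truth.near_intima.max() + margin
    elif purpose == "imt_far":
        top = truth.far_intima.min() - margin
        bottom = truth.far_adventitia.max() + band + margin
    elif purpose == "lumen":
        center = (truth.near_intima.mean() + truth.far_intima.mean()) / 2.0
        need_top = truth.near_adventitia.min() - band - margin
        need_bottom = truth.far_adventitia.max() + band + margin
        half = max(center - need_top, need_bottom - center)
        top, bottom = center - half, center + half
    else:
        raise ValueError(f"purpose must be imt_near, imt_far or lumen, got {purpose!r}")
    y0 = max(0, int(math.floor(top)))
    y1 = min(cfg.height, int(math.ceil(bottom)) + 1)
    return RoiSpec(
        x0=col_margin, y0=y0,
        width=cfg.width - 2 * col_margin, height=y1 - y0,
    )
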