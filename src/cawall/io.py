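"""Frame-sequence and result readers/writers plus run configuration.

Frames are exchanged as directories of numbered 8-bit grayscale PNG/BMP
files; traces and lumen series as CSV with documented stable schemas:

* traces:  ``frame, wall, layer, column, row_px, row_mm``
* lumen:   ``frame, mean_ld_px, mean_ld_mm``
* truth:   ``frame, wall, column, intima_row, adventitia_row``

Pixel values are normalized to [0, 1] on load; rows increase downward.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("cawall")

__all__ = [
    "FrameSequence",
    "RunConfig",
    "read_sequence",
    "write_frames",
    "write_traces",
    "read_traces",
    "write_lumen_csv",
    "write_truth_csv",
    "read_truth_csv",
    "write_overlays",
    "load_run_config",
    "write_resolved_config",
]

_IMAGE_EXTENSIONS = {".png", ".bmp", ".tif", ".tiff"}


@dataclass
class FrameSequence:
    """Ordered grayscale frames with pixel-size calibration.

    ``frames`` has shape (L, H, W) with values in [0, 1] (8-bit data divided
    by 255, so writing and re-reading round-trips exactly).
    """

    frames: np.ndarray
    pixel_size_mm: float = 0.106
    paths: list[str] | None = None

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


def _natural_key(name: str) -> tuple:
    """Sort key treating digit runs numerically, so frame2 < frame10."""
    return tuple(int(tok) if tok.isdigit() else tok
                 for tok in re.split(r"(\d+)", name))


def _to_gray(arr: np.ndarray, path) -> np.ndarray:
    if arr.ndim == 3:
        warnings.warn(f"{path}: color image converted to grayscale by luminance")
        arr = arr[..., :3] @ np.array([0.299, 0.587, 0.114])
    return arr.astype(float)


def read_sequence(directory, pixel_size_mm: float = 0.106) -> FrameSequence:
    """Load all frames of a directory in natural filename order.

    Values are normalized to [0, 1].  Raises ``ValueError`` on an empty
    directory or on mixed frame shapes (offenders listed).
    """
    directory = Path(directory)
    paths = sorted(
        (p for p in directory.iterdir() if p.suffix.lower() in _IMAGE_EXTENSIONS),
        key=lambda p: _natural_key(p.name),
    )
    if not paths:
        raise ValueError(f"no decodable image files in {directory}")
    arrays = []
    for p in paths:
        raw = iio.imread(p)
        scale = 65535.0 if raw.dtype == np.uint16 else 255.0
        arrays.append(_to_gray(np.asarray(raw), p) / scale)
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        common = max(shapes, key=lambda s: sum(a.shape == s for a in arrays))
        bad = [str(p) for p, a in zip(paths, arrays) if a.shape != common]
        raise ValueError(f"mixed frame shapes {sorted(shapes)}; offenders: {bad}")
    logger.info("read %d frames of shape %s from %s", len(arrays), arrays[0].shape, directory)
    return FrameSequence(
        frames=np.stack(arrays), pixel_size_mm=pixel_size_mm,
        paths=[str(p) for p in paths],
    )


def write_frames(sequence, directory, prefix: str = "frame", fmt: str = "png") -> list[str]:
    """Write frames as numbered 8-bit grayscale images; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frames = getattr(sequence, "frames", sequence)
    out = []
    for i, f in enumerate(frames):
        data = np.clip(np.rint(np.asarray(f, dtype=float) * 255.0), 0, 255).astype(np.uint8)
        path = directory / f"{prefix}{i:04d}.{fmt}"
        iio.imwrite(path, data)
        out.append(str(path))
    return out


def write_traces(results, out_dir, pixel_size_mm: float, name: str = "traces.csv") -> str:
    """Write per-frame, per-wall boundary traces to CSV.

    ``results`` is an iterable of WallResult; rows are in full-frame
    coordinates.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for res in results:
        for j in range(res.intima.shape[0]):
            for layer, rows in (("intima", res.intima[j]), ("adventitia", res.adventitia[j])):
                records.extend(
                    {
                        "frame": j,
                        "wall": res.wall,
                        "layer": layer,
                        "column": int(col),
                        "row_px": float(row),
                        "row_mm": float(row) * pixel_size_mm,
                    }
                    for col, row in zip(res.columns, rows)
                )
    path = out_dir / name
    pd.DataFrame.from_records(
        records, columns=["frame", "wall", "layer", "column", "row_px", "row_mm"]
    ).to_csv(path, index=False)
    return str(path)


def read_traces(path) -> pd.DataFrame:
    """Read a traces CSV back into a DataFrame (schema as written)."""
    return pd.read_csv(path)


def write_lumen_csv(lumen, path) -> str:
    """Write the per-frame mean lumen diameter series."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "frame": np.arange(len(lumen.mean_px)),
            "mean_ld_px": lumen.mean_px,
            "mean_ld_mm": lumen.mean_mm,
        }
    ).to_csv(path, index=False)
    return str(path)


def write_truth_csv(truth, path) -> str:
    """Write analytic phantom boundary truth in long format."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = np.arange(truth.near_intima.shape[0])
    cols = np.arange(truth.near_intima.shape[1])
    parts = []
    for wall, intima, adv in (
        ("near", truth.near_intima, truth.near_adventitia),
        ("far", truth.far_intima, truth.far_adventitia),
    ):
        fgrid, cgrid = np.meshgrid(frames, cols, indexing="ij")
        parts.append(
            pd.DataFrame(
                {
                    "frame": fgrid.ravel(),
                    "wall": wall,
                    "column": cgrid.ravel(),
                    "intima_row": intima.ravel(),
                    "adventitia_row": adv.ravel(),
                }
            )
        )
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)
    return str(path)


def read_truth_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_overlays(sequence, results, out_dir, prefix: str = "overlay") -> list[str]:
    """Write one RGB PNG per frame with the detected lines drawn (solid)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = sequence.frames
    colors = {"near": (255, 80, 80), "far": (80, 255, 80)}
    paths = []
    for j in range(frames.shape[0]):
        rgb = np.repeat(
            np.clip(np.rint(frames[j] * 255), 0, 255).astype(np.uint8)[..., None], 3, axis=2
        )
        for res in results:
            color = colors.get(res.wall, (255, 255, 0))
            for rows in (res.intima[j], res.adventitia[j]):
                rr = np.clip(np.rint(rows).astype(int), 0, rgb.shape[0] - 1)
                cc = np.asarray(res.columns, dtype=int)
                rgb[rr, cc] = color
        path = out_dir / f"{prefix}{j:04d}.png"
        iio.imwrite(path, rgb)
        paths.append(str(path))
    return paths


@dataclass
class RunConfig:
    """Fully-resolved configuration of a pipeline run."""

    frames_dir: str = ""
    out_dir: str = "out"
    pixel_size_mm: float = 0.106
    roi: dict = field(default_factory=dict)  # x0, y0, width, height
    # filter parameters
    d_c: float = 2.0
    d_pk: float = 2.0
    macleod_size: int = 7
    combine: str = "sum"
    flip_fx: bool = False
    r: int = 5
    c: float = 0.5
    # DDP parameters
    alpha: float = 0.25
    beta: float = 0.15
    k: int = 1
    d_min: int = 4
    d_max: int | None = None
    # tracking / smoothing / output
    delta_s: int = 10
    smooth_window: int = 5
    overlays: bool = False
    log_level: str = "INFO"


def load_run_config(path) -> RunConfig:
    """Load a YAML run configuration; missing keys take package defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def write_resolved_config(config: RunConfig, out_dir, name: str = "config_resolved.yaml") -> str:
    """Echo the fully-resolved configuration beside the outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / name
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
    return str(path)
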