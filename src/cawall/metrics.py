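"""Boundary-accuracy metrics, aggregation and derived hemodynamic indices.

Errors are row differences between a detected trace and a reference
(manual tracing or phantom truth) sampled at common columns:

* per-frame unsigned error  e_j = mean_i |y_det(i) - y_ref(i)|
* per-frame signed error    ê_j = mean_i (y_det(i) - y_ref(i))
* per-sequence summaries    E = mean_j e_j  (likewise for the signed form)

Sparse references (a handful of manually placed points per frame) are
completed by linear interpolation between points before comparison.
Pixel values convert to millimetres by the pixel-size calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ErrorSummary",
    "frame_error",
    "sequence_error",
    "px_to_mm",
    "interpolate_reference",
    "wall_error_summary",
    "distensibility",
    "distensibility_from_ld",
]


@dataclass
class ErrorSummary:
    """Per-frame and per-sequence boundary errors, pixels and millimetres."""

    per_frame_unsigned: np.ndarray
    per_frame_signed: np.ndarray
    pixel_size_mm: float

    @property
    def mean_unsigned_px(self) -> float:
        return float(np.mean(self.per_frame_unsigned))

    @property
    def mean_signed_px(self) -> float:
        return float(np.mean(self.per_frame_signed))

    @property
    def mean_unsigned_mm(self) -> float:
        return px_to_mm(self.mean_unsigned_px, self.pixel_size_mm)

    @property
    def mean_signed_mm(self) -> float:
        return px_to_mm(self.mean_signed_px, self.pixel_size_mm)

    def report(self) -> dict:
        """Rounded summary (2 decimals in pixels, 4 in millimetres)."""
        return {
            "mean_unsigned_px": round(self.mean_unsigned_px, 2),
            "mean_signed_px": round(self.mean_signed_px, 2),
            "mean_unsigned_mm": round(self.mean_unsigned_mm, 4),
            "mean_signed_mm": round(self.mean_signed_mm, 4),
            "n_frames": int(len(self.per_frame_unsigned)),
        }


def frame_error(reference, detected, signed: bool = False) -> float:
    """Mean (absolute) row difference of one frame's trace pair.

    ``signed=False`` gives the unsigned error mean|y_det - y_ref|;
    ``signed=True`` the raw mean difference (detected minus reference).
    """
    ref = np.asarray(reference, dtype=float)
    det = np.asarray(detected, dtype=float)
    if ref.shape != det.shape:
        raise ValueError(f"length mismatch: {ref.shape} vs {det.shape}")
    if ref.size == 0:
        raise ValueError("empty traces")
    diff = det - ref
    return float(diff.mean() if signed else np.abs(diff).mean())


def sequence_error(per_frame) -> float:
    """Arithmetic mean of per-frame errors over a sequence."""
    vals = np.asarray(list(per_frame), dtype=float)
    if vals.size == 0:
        raise ValueError("empty per-frame error list")
    return float(vals.mean())


def px_to_mm(value_px: float, pixel_size_mm: float = 0.106) -> float:
    """Convert a pixel quantity to millimetres."""
    if pixel_size_mm <= 0:
        raise ValueError("pixel_size_mm must be > 0")
    return float(value_px) * pixel_size_mm


def interpolate_reference(ref_columns, ref_rows, columns) -> np.ndarray:
    """Linearly interpolate a sparse reference trace onto a column grid.

    Columns outside the reference support take the nearest end value.
    """
    ref_columns = np.asarray(ref_columns, dtype=float)
    ref_rows = np.asarray(ref_rows, dtype=float)
    if ref_columns.size < 2:
        raise ValueError("need at least 2 reference points to interpolate")
    order = np.argsort(ref_columns)
    return np.interp(np.asarray(columns, dtype=float),
                     ref_columns[order], ref_rows[order])


def _pool_columns(detected: np.ndarray, truth: np.ndarray, columns) -> np.ndarray:
    cols = np.asarray(columns, dtype=int)
    return truth[:, cols] if truth.shape[1] != detected.shape[1] else truth


def wall_error_summary(result, truth_intima: np.ndarray, truth_adventitia: np.ndarray,
                       pixel_size_mm: float) -> ErrorSummary:
    """Pooled intima + adventitia errors of a WallResult against truth arrays.

    Truth arrays are full-width (frames x image columns); they are sampled at
    the result's column span.  Each frame's error pools the absolute (or raw)
    row differences of both layers.
    """
    ti = _pool_columns(result.intima, np.asarray(truth_intima, dtype=float), result.columns)
    ta = _pool_columns(result.adventitia, np.asarray(truth_adventitia, dtype=float),
                       result.columns)
    diffs = np.concatenate([result.intima - ti, result.adventitia - ta], axis=1)
    return ErrorSummary(
        per_frame_unsigned=np.abs(diffs).mean(axis=1),
        per_frame_signed=diffs.mean(axis=1),
        pixel_size_mm=pixel_size_mm,
    )


def distensibility(area_diastole: float, delta_area: float,
                   delta_pressure: float) -> tuple[float, float]:
    """Carotid distensibility and stiffness.

    CDist = dA / (A * dP) with A the diastolic lumen area, dA the maximal
    systolic-diastolic area change and dP the pulse pressure;
    CS = CDist^(-1/2).
    """
    if area_diastole <= 0 or delta_area <= 0 or delta_pressure <= 0:
        raise ValueError("all distensibility inputs must be > 0")
    cdist = delta_area / (area_diastole * delta_pressure)
    return cdist, cdist ** -0.5


def distensibility_from_ld(lumen, delta_pressure: float) -> tuple[float, float]:
    """Distensibility from a LumenSeries under a circular-lumen assumption.

    The lumen cross-section is approximated as a circle of the mean diameter
    (A = pi (LD/2)^2); diastole and systole are taken as the minimum and
    maximum of the per-frame mean diameter.  This is a documented
    approximation: the method measures diameters, not areas.
    """
    ld_mm = np.asarray(lumen.mean_mm, dtype=float)
    ld_dia, ld_sys = float(ld_mm.min()), float(ld_mm.max())
    area = np.pi * (ld_dia / 2.0) ** 2
    delta_area = np.pi * (ld_sys / 2.0) ** 2 - area
    return distensibility(area, delta_area, delta_pressure)
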