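"""Artery movement tracking by normalized cross-correlation (NCC).

The artery translates mostly vertically over the heart cycle, so the region
of interest must be re-registered on every frame before boundary detection.
A template is cut from the first frame and, for each subsequent frame, the
vertical shift ``s`` in ``[-delta_s, +delta_s]`` (relative to the previous
frame's position) maximizing the Pearson correlation between the template and
the shifted patch is taken: ``y_i = y_{i-1} + s*``.  The template is fixed:
every frame is compared against the first-frame patch, never frame-to-frame,
so tracking errors do not accumulate template drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TrackState", "ncc", "track_frame"]


@dataclass
class TrackState:
    """Mutable state of the vertical template tracker.

    ``current_shift`` is the cumulative integer shift of the ROI relative to
    its first-frame position; ``ncc_trace`` holds the best correlation value
    per tracked frame (for quality control).
    """

    template: np.ndarray
    x0: int
    y0: int
    delta_s: int = 10
    current_shift: int = 0
    ncc_trace: list[float] = field(default_factory=list)
    frame_index: int = 0  # index of the last frame consumed (0 = template frame)


def ncc(template, candidate) -> float:
    """Pearson correlation of two equally-shaped pixel patches, in [-1, 1].

    Raises ``ValueError`` for degenerate (constant) patches, whose
    correlation is undefined.
    """
    a = np.asarray(template, dtype=float)
    b = np.asarray(candidate, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("patches must contain at least 2 pixels")
    sa = a.std()
    sb = b.std()
    if sa == 0 or sb == 0:
        raise ValueError("degenerate (constant) patch: zero variance")
    r = float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))
    return min(1.0, max(-1.0, r))


def track_frame(state: TrackState, frame) -> TrackState:
    """Register the next frame and update the cumulative vertical shift.

    Evaluates the NCC of the fixed template against the frame patch at every
    integer shift ``s`` in ``[-delta_s, +delta_s]`` relative to the previous
    frame's position.  Ties are broken toward the smallest ``|s|``, then the
    negative ``s``.  The state is updated in place and returned.

    Raises ``ValueError`` (naming the frame index) if the search window does
    not fit inside the frame — the moving-target failure mode.
    """
    img = np.asarray(frame, dtype=float)
    h, w = state.template.shape
    base = state.y0 + state.current_shift
    idx = state.frame_index + 1
    if (
        base - state.delta_s < 0
        or base + state.delta_s + h > img.shape[0]
        or state.x0 < 0
        or state.x0 + w > img.shape[1]
    ):
        raise ValueError(
            f"frame {idx}: NCC search window [{base - state.delta_s}, "
            f"{base + state.delta_s + h}) leaves the frame of {img.shape[0]} rows"
        )

    best_s: int | None = None
    best_v = -np.inf
    for s in sorted(range(-state.delta_s, state.delta_s + 1), key=lambda s: (abs(s), s)):
        patch = img[base + s : base + s + h, state.x0 : state.x0 + w]
        try:
            v = ncc(state.template, patch)
        except ValueError:
            continue  # constant patch at this shift; cannot score it
        if v > best_v:
            best_v = v
            best_s = s
    if best_s is None:
        raise ValueError(f"frame {idx}: all candidate patches are degenerate")

    state.current_shift += best_s
    state.ncc_trace.append(best_v)
    state.frame_index = idx
    return state
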