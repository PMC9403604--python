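"""Recursive filtered-image motion representation of an eye video.

A filtered image at time t is the absolute difference between the raw
frame I_t and an intermediate image M_t that blends earlier frames
through an exponentially-weighted recursion:

    F_t = |I_t − M_t|,    M_t = (1 − β)·M_{t−1} + β·I_{t−1},

with M seeded by the first frame. The weight β in (0, 1] controls how
quickly M forgets the past: β = 1 collapses to plain frame differencing
(M_t = I_{t−1}); β → 0⁺ approaches comparison against the first frame.
Emission starts at t = 2, so a T-frame clip yields T − 1 images (600
frames → 599), the only reading consistent with the recursion's seed.

The sliding-window variant bounds the temporal context to the duration
of a nystagmus beat: for each window end position t = w..T the same
recursion is restarted on frames t−w+1..t and only the final filtered
image of that run is emitted, giving T − w + 1 images whose content
depends on nothing outside the window.

Video time is indexed 1..T, matching the clip convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .videoio import VideoClip

__all__ = ["FilterParams", "FilteredImageStack", "filtered_stack", "beta_sweep"]

# β values screened in the filtered-image optimisation experiment.
BETA_GRID = (0.001, 0.005, 0.01, 0.05, 0.1, 0.25, 0.5)

# Sliding-window lengths in frames at 60 Hz (150 ms, 333 ms, 500 ms, 1 s).
WINDOW_GRID = (10, 20, 30, 60)


@dataclass(frozen=True)
class FilterParams:
    """Recursion weight and optional sliding-window length.

    beta
        Recursion weight in (0, 1]. β = 0 is disallowed: it degenerates
        to a constant comparison with the first frame and is no longer a
        recursive filter.
    window
        Window length in frames (≥ 2); ``None`` selects the non-sliding
        variant that integrates the whole clip history.
    stride
        Step between consecutive window end positions (sliding only).
    """

    beta: float
    window: Optional[int] = None
    stride: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.beta <= 1.0:
            raise ValueError(f"beta must lie in (0, 1], got {self.beta}")
        if self.window is not None and self.window < 2:
            raise ValueError("window must be ≥ 2 frames")
        if self.stride < 1:
            raise ValueError("stride must be ≥ 1")


@dataclass
class FilteredImageStack:
    """Ordered motion images derived from one clip.

    ``t_index[i]`` is the source-frame time (1-based) that image ``i``
    corresponds to: 2..T non-sliding, w..T sliding.
    ``source_meta`` carries the clip's label/patient/condition/rate so a
    stack remains a self-contained training/evaluation unit.
    """

    images: np.ndarray
    params: FilterParams
    t_index: np.ndarray
    source_meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.images.shape[0]

    @property
    def label(self) -> Optional[int]:
        return self.source_meta.get("label")

    def quantized(self) -> np.ndarray:
        """8-bit view of the stack (for image-file export)."""
        return np.clip(np.rint(self.images), 0, 255).astype(np.uint8)


def filtered_stack(clip: VideoClip, params: FilterParams) -> FilteredImageStack:
    """Convert a clip into its stack of recursive-filtered motion images.

    Non-sliding: T − 1 images, t = 2..T. Sliding with window w: one
    image per window end position t = w..T (at the configured stride).
    Arithmetic is carried in float64; values stay within [0, 255] by
    construction since M is a convex combination of frames.
    """
    frames = clip.frames.astype(np.float64)
    T = frames.shape[0]
    beta = params.beta

    if params.window is None:
        if T < 2:
            raise ValueError("need at least 2 frames for filtering")
        images = _recursive_filter(frames, beta)
        t_index = np.arange(2, T + 1)
    else:
        w = params.window
        if T < w:
            raise ValueError(f"clip of {T} frames is shorter than window {w}")
        images, t_index = _sliding_filter(frames, beta, w, params.stride)

    meta = {
        "label": clip.label,
        "patient_id": clip.patient_id,
        "condition": clip.condition,
        "rate": clip.rate,
        "source": clip.source,
    }
    return FilteredImageStack(images=images, params=params, t_index=t_index, source_meta=meta)


def _recursive_filter(frames: np.ndarray, beta: float) -> np.ndarray:
    """Run the recursion over a full frame sequence; emit F_2..F_T."""
    T = frames.shape[0]
    out = np.empty((T - 1,) + frames.shape[1:], dtype=np.float64)
    M = frames[0].copy()
    for t in range(1, T):  # array index t ↔ time t+1
        M *= 1.0 - beta
        M += beta * frames[t - 1]
        np.abs(frames[t] - M, out=out[t - 1])
    return out


def _sliding_filter(
    frames: np.ndarray, beta: float, w: int, stride: int
) -> tuple[np.ndarray, np.ndarray]:
    """Final filtered image of the restarted recursion for each window.

    The restarted recursion over frames s..s+w−1 (seed M = I_s) leaves

        M_final = (1−β)^{w−1}·I_s + Σ_{j=0}^{w−2} β(1−β)^{w−2−j}·I_{s+j},

    a fixed FIR kernel over the first w−1 frames of the window, so all
    windows are evaluated as one tensor contraction.
    """
    T = frames.shape[0]
    kernel = beta * (1.0 - beta) ** np.arange(w - 2, -1, -1)
    kernel[0] += (1.0 - beta) ** (w - 1)  # seed weight folds into I_s

    ends = np.arange(w, T + 1, stride)  # 1-based window end times
    windows = np.lib.stride_tricks.sliding_window_view(frames, w - 1, axis=0)
    # windows[s] spans frames s..s+w−2 (0-based); window ending at time t
    # starts at 0-based index t − w.
    starts = ends - w
    M_final = np.tensordot(kernel, np.moveaxis(windows[starts], -1, 1), axes=(0, 1))
    images = np.abs(frames[ends - 1] - M_final)
    return images, ends


def beta_sweep(
    clip: VideoClip,
    betas: Iterable[float] = BETA_GRID,
    params_base: Optional[FilterParams] = None,
) -> dict[float, FilteredImageStack]:
    """One filtered stack per β, sharing window/stride from ``params_base``."""
    window = params_base.window if params_base is not None else None
    stride = params_base.stride if params_base is not None else 1
    return {
        float(b): filtered_stack(clip, FilterParams(beta=float(b), window=window, stride=stride))
        for b in betas
    }
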