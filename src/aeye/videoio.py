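"""Reading, normalising, trimming, degrading and writing eye-video clips.

A clip is an ordered stack of grayscale frames with a sampling rate and
optional label / patient / gaze-condition metadata. Video time is indexed
1..T throughout the package (frame ``i`` of the underlying array is time
``t = i + 1``).

Supported on-disk forms:

* packed frame-stack archive (``.npz``) with keys ``frames``/``rate`` and
  optional ``label``/``patient_id``/``condition`` — lossless, round-trips
  bitwise;
* a directory of PNG frames in lexicographic order, with an optional
  ``meta.json`` sidecar;
* standard containers (AVI/MP4/MOV) through imageio, when an imageio
  plugin for the container is available.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "VideoClip",
    "DegradationSpec",
    "load_clip",
    "save_clip",
    "trim_clip",
    "resample_rate",
    "downscale",
    "degrade_grid",
    "reverse_clip",
]


@dataclass
class VideoClip:
    """Ordered grayscale frame stack; the unit of classification.

    Parameters
    ----------
    frames
        Array of shape ``(T, H, W)`` with intensities in ``[0, 255]``.
    rate
        Sampling rate in Hz (> 0).
    label
        Optional binary class: 1 = nystagmus, 0 = no nystagmus.
    patient_id
        Opaque identifier used for patient-stratified splitting.
    condition
        Gaze/positional tag, e.g. ``"primary"`` or ``"eccentric"``.
    source
        Provenance string.
    """

    frames: np.ndarray
    rate: float
    label: Optional[int] = None
    patient_id: Optional[str] = None
    condition: Optional[str] = None
    source: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a (T, H, W) stack, got shape {self.frames.shape}"
            )
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        lo, hi = float(self.frames.min(initial=0)), float(self.frames.max(initial=0))
        if lo < 0 or hi > 255:
            raise ValueError(f"intensities must lie in [0, 255], got [{lo}, {hi}]")
        if self.label is not None:
            self.label = int(self.label)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def resolution(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration(self) -> float:
        """Clip duration in seconds."""
        return self.n_frames / self.rate

    def with_frames(self, frames: np.ndarray, **meta) -> "VideoClip":
        """Copy of this clip with new frames, metadata preserved."""
        out = replace(self, frames=frames)
        for k, v in meta.items():
            setattr(out, k, v)
        return out


@dataclass(frozen=True)
class DegradationSpec:
    """One cell of the rate × resolution degradation grid."""

    target_rate: float
    target_resolution: tuple[int, int]

    def validate(self, clip: VideoClip) -> None:
        if self.target_rate <= 0:
            raise ValueError("target_rate must be positive")
        ratio = clip.rate / self.target_rate
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"target rate {self.target_rate} must divide source rate {clip.rate}"
            )
        th, tw = self.target_resolution
        sh, sw = clip.resolution
        if th > sh or tw > sw:
            raise ValueError(
                f"target resolution {self.target_resolution} exceeds source {clip.resolution}"
            )


# ---------------------------------------------------------------------------
# I/O


_META_KEYS = ("label", "patient_id", "condition", "source")


def save_clip(clip: VideoClip, path: str | Path, fmt: Optional[str] = None) -> None:
    """Write a clip to disk.

    ``fmt`` is inferred from the path when omitted: ``.npz`` archive
    (lossless, bitwise round-trip), a directory of PNG frames plus a
    ``meta.json`` sidecar, or a standard container by extension (requires
    an imageio plugin; 8-bit, shape/rate round-trip only).
    """
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "npz":
        payload = {"frames": clip.frames, "rate": np.asarray(clip.rate)}
        for key in _META_KEYS:
            value = getattr(clip, key)
            if value is not None and value != "":
                payload[key] = np.asarray(value)
        np.savez(path, **payload)
    elif fmt == "frames":
        import imageio.v3 as iio

        path.mkdir(parents=True, exist_ok=True)
        width = max(6, len(str(clip.n_frames)))
        frames8 = np.clip(np.rint(clip.frames), 0, 255).astype(np.uint8)
        for i, frame in enumerate(frames8, start=1):
            iio.imwrite(path / f"frame_{i:0{width}d}.png", frame)
        meta = {"rate": clip.rate}
        meta.update({k: getattr(clip, k) for k in _META_KEYS})
        (path / "meta.json").write_text(json.dumps(meta, indent=1))
    elif fmt == "container":
        import imageio.v3 as iio

        frames8 = np.clip(np.rint(clip.frames), 0, 255).astype(np.uint8)
        try:
            iio.imwrite(path, frames8, fps=clip.rate)
        except Exception as exc:  # plugin availability depends on the install
            raise IOError(
                f"no imageio plugin could write container {path.suffix!r}; "
                "use the lossless .npz archive or a PNG frame directory"
            ) from exc
    else:
        raise ValueError(f"unknown format {fmt!r}")


def load_clip(
    path: str | Path,
    as_grayscale: bool = True,
    rate: Optional[float] = None,
) -> VideoClip:
    """Read a clip from an archive, frame directory or video container.

    ``rate`` overrides (or supplies, for frame directories without a
    sidecar) the sampling rate. RGB input is reduced to a single channel
    by the standard luma weighting.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path)
    if fmt == "npz":
        with np.load(path, allow_pickle=False) as data:
            frames = data["frames"]
            meta = {}
            for key in _META_KEYS:
                if key in data:
                    raw = data[key][()]
                    meta[key] = int(raw) if key == "label" else str(raw)
            file_rate = float(data["rate"][()])
        return VideoClip(frames=frames, rate=rate or file_rate, **meta)
    if fmt == "frames":
        import imageio.v3 as iio

        frame_files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff"}
        )
        if not frame_files:
            raise IOError(f"no frame images found in {path}")
        frames = np.stack([_to_gray(iio.imread(p), as_grayscale) for p in frame_files])
        meta: dict = {}
        file_rate = None
        sidecar = path / "meta.json"
        if sidecar.exists():
            raw = json.loads(sidecar.read_text())
            file_rate = raw.get("rate")
            meta = {k: raw[k] for k in _META_KEYS if raw.get(k) is not None}
        if rate is None and file_rate is None:
            raise ValueError("frame directory has no rate metadata; pass rate=")
        return VideoClip(frames=frames, rate=rate or float(file_rate), **meta)
    # container
    import imageio.v3 as iio

    try:
        raw = iio.imread(path)
        props = iio.improps(path)
    except Exception as exc:
        raise IOError(
            f"no imageio plugin could read container {path.suffix!r}"
        ) from exc
    if raw.ndim == 3 and raw.shape[-1] in (3, 4):  # single RGB image
        raw = raw[None]
    frames = np.stack([_to_gray(f, as_grayscale) for f in raw])
    if frames.shape[0] == 0:
        raise IOError(f"{path} contains zero frames")
    file_rate = getattr(props, "fps", None)
    if rate is None and not file_rate:
        raise ValueError("container carries no frame rate; pass rate=")
    return VideoClip(frames=frames, rate=rate or float(file_rate), source=str(path))


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".npz":
        return "npz"
    if suffix in {".avi", ".mp4", ".mov", ".mkv", ".webm", ".gif"}:
        return "container"
    if suffix == "":
        return "frames"
    raise ValueError(f"cannot infer clip format from {path.name!r}")


def _to_gray(frame: np.ndarray, as_grayscale: bool) -> np.ndarray:
    if frame.ndim == 2 or not as_grayscale:
        if frame.ndim != 2:
            raise ValueError("multi-channel frame with as_grayscale=False")
        return frame
    if frame.ndim == 3 and frame.shape[-1] in (3, 4):
        rgb = frame[..., :3].astype(np.float64)
        return rgb @ np.array([0.299, 0.587, 0.114])
    raise ValueError(f"unsupported frame shape {frame.shape}")


# ---------------------------------------------------------------------------
# Transforms


def trim_clip(clip: VideoClip, seconds: float) -> VideoClip:
    """Keep the first ``floor(seconds × rate)`` frames.

    Mirrors the study protocol of using only the first 10 s (600 frames
    at 60 Hz) of each recording.
    """
    n_keep = math.floor(seconds * clip.rate)
    if n_keep > clip.n_frames:
        raise ValueError(
            f"clip has {clip.duration:.3f}s, cannot trim to {seconds}s"
        )
    return clip.with_frames(clip.frames[:n_keep])


def resample_rate(clip: VideoClip, target_rate: float) -> VideoClip:
    """Decimate to ``target_rate`` by keeping every (rate/target)-th frame.

    Pure decimation starting from the first frame — no temporal
    interpolation — so lower rates are exact subsamples of the 60 Hz
    master, as in a simulated lower-rate recording.
    """
    ratio = clip.rate / target_rate
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"source rate {clip.rate} not an integer multiple of {target_rate}"
        )
    step = int(round(ratio))
    return clip.with_frames(clip.frames[::step], rate=float(target_rate))


def downscale(clip: VideoClip, target_resolution: tuple[int, int]) -> VideoClip:
    """Resize every frame to ``target_resolution`` by area averaging.

    When source dims are integer multiples of the target, exact block
    means are used; otherwise an anti-aliased area-style resize.
    Intensities remain in [0, 255].
    """
    th, tw = target_resolution
    sh, sw = clip.resolution
    if th > sh or tw > sw:
        raise ValueError(f"target {target_resolution} exceeds source {clip.resolution}")
    if (th, tw) == (sh, sw):
        return clip.with_frames(clip.frames.copy())
    frames = clip.frames.astype(np.float64)
    if sh % th == 0 and sw % tw == 0:
        fh, fw = sh // th, sw // tw
        out = frames.reshape(clip.n_frames, th, fh, tw, fw).mean(axis=(2, 4))
    else:
        from skimage.transform import resize

        out = np.stack(
            [
                resize(f, (th, tw), order=1, anti_aliasing=True, preserve_range=True)
                for f in frames
            ]
        )
    return clip.with_frames(np.clip(out, 0.0, 255.0))


def degrade_grid(
    clip: VideoClip,
    rates: Sequence[float],
    resolutions: Sequence[tuple[int, int]],
) -> list[VideoClip]:
    """One degraded clip per (rate, resolution) cell of the grid.

    The cell equal to the source spec is the unmodified original, so the
    3×3 grid {60,30,15} Hz × {(240,320),(60,80),(15,20)} yields the
    original plus 8 variants.
    """
    out = []
    for rate in rates:
        for resolution in resolutions:
            DegradationSpec(rate, tuple(resolution)).validate(clip)
            cell = resample_rate(clip, rate)
            cell = downscale(cell, tuple(resolution))
            out.append(cell)
    return out


def reverse_clip(clip: VideoClip) -> VideoClip:
    """Reverse frame order; all other metadata preserved."""
    return clip.with_frames(clip.frames[::-1].copy())
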