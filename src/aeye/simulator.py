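"""Synthetic video-oculography: waveforms, distractors, rendering, datasets.

Emulates monocular infrared-style eye videos with known ground truth so
the whole detection pipeline is trainable and testable without clinical
recordings. A clip is produced in two stages:

1. ``gen_trace`` realises a parametric eye-position time series (the
   gaze trace) from a waveform description — jerk nystagmus with linear,
   velocity-decreasing or velocity-increasing slow phases, or pendular
   nystagmus — plus non-nystagmus distractors (blinks, lid closure,
   square-wave jerks, slow drift, tremor noise). Every beat (slow-phase
   + fast-phase cycle) is annotated exactly.
2. ``render_clip`` draws sclera / iris / pupil at the trace position in
   every frame, applies an illumination gradient, occluding eyelid bands
   for blinks, and sensor noise, and labels the clip by the operational
   rule: nystagmus iff the trace contains ≥ 2 consecutive beats.

Slow-phase durations default to the physiological 150–350 ms range; fast
phases are rendered as 1–2 sample transitions, since saccadic velocities
exceed what 60 Hz sampling can resolve, so jerk waveforms appear as
sampled sawtooths. Amplitude is specified in degrees and converted to
pixels by a gain proportional to frame height, so the same waveform spec
degrades realistically when rendered at lower resolutions (possibly to
sub-pixel motion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .videoio import VideoClip

__all__ = [
    "WaveformSpec",
    "DistractorSpec",
    "EyeAppearance",
    "GazeTrace",
    "gen_trace",
    "render_clip",
    "synth_clip",
    "make_dataset",
]

WAVEFORM_KINDS = (
    "none",
    "jerk_linear",
    "jerk_velocity_decreasing",
    "jerk_velocity_increasing",
    "pendular",
)

#: pixels per degree of eye rotation at the reference 240-row resolution
PX_PER_DEG_AT_240 = 3.0


@dataclass(frozen=True)
class WaveformSpec:
    """Parametric description of a nystagmus (or quiescent) waveform.

    kind
        ``none`` (fixation), one of the three jerk morphologies, or
        ``pendular`` (sinusoid, no fast phase).
    slow_phase_duration
        Slow-phase duration in ms; nominal range 150–350.
    amplitude
        Beat amplitude in degrees.
    direction
        Unit 2-D direction of the slow phase in image (x, y) coordinates.
    n_beats
        Number of consecutive beats; ≥ 2 ⇒ the clip is nystagmus. For
        pendular waveforms this counts full oscillation cycles.
    onset
        Time of the first beat, seconds.
    pendular_frequency
        Oscillation frequency in Hz (pendular only).
    decay_constant
        Per-second exponential rate of the slow-phase velocity envelope
        (velocity-decreasing / -increasing only).
    """

    kind: str = "jerk_linear"
    slow_phase_duration: float = 250.0
    amplitude: float = 2.0
    direction: tuple[float, float] = (1.0, 0.0)
    n_beats: int = 0
    onset: float = 0.5
    pendular_frequency: float = 3.0
    decay_constant: float = 8.0

    def __post_init__(self) -> None:
        if self.kind not in WAVEFORM_KINDS:
            raise ValueError(f"unknown waveform kind {self.kind!r}")
        if self.slow_phase_duration <= 0:
            raise ValueError("slow_phase_duration must be positive")
        if self.n_beats < 0:
            raise ValueError("n_beats must be ≥ 0")
        if self.kind == "pendular" and self.pendular_frequency <= 0:
            raise ValueError("pendular_frequency must be positive")
        norm = math.hypot(*self.direction)
        if norm == 0:
            raise ValueError("direction must be a nonzero vector")


@dataclass(frozen=True)
class DistractorSpec:
    """Non-nystagmus eye-motion and occlusion events.

    Distractors alone never satisfy the ≥2-beat rule, so a clip whose
    waveform has fewer than two beats is always labeled no-nystagmus no
    matter how busy its distractors are.
    """

    blink_times: tuple[float, ...] = ()
    blink_duration: float = 150.0  # ms
    lid_closure_intervals: tuple[tuple[float, float], ...] = ()
    square_wave_jerks: tuple[tuple[float, float, float], ...] = ()  # (t, amp deg, latency s)
    drift_velocity: float = 0.0  # deg/s along +x
    tremor_noise_sd: float = 0.0  # deg


@dataclass(frozen=True)
class EyeAppearance:
    """Rendering parameters for the synthetic eye."""

    pupil_radius: float = 14.0
    iris_radius: float = 38.0
    sclera_intensity: float = 170.0
    iris_intensity: float = 90.0
    pupil_intensity: float = 15.0
    illumination_gradient: float = 0.0  # peak-to-peak fractional shading
    sensor_noise_sd: float = 2.0  # intensity units
    gaze_offset: tuple[float, float] = (0.0, 0.0)  # px; eccentric positioning

    def __post_init__(self) -> None:
        if self.pupil_radius >= self.iris_radius:
            raise ValueError("pupil_radius must be smaller than iris_radius")
        if not (
            self.pupil_intensity < self.iris_intensity
            and self.pupil_intensity < self.sclera_intensity
        ):
            raise ValueError("pupil must be the darkest structure")

    def scaled(self, factor: float) -> "EyeAppearance":
        """Appearance with all pixel-valued fields scaled by ``factor``."""
        return replace(
            self,
            pupil_radius=self.pupil_radius * factor,
            iris_radius=self.iris_radius * factor,
            gaze_offset=(self.gaze_offset[0] * factor, self.gaze_offset[1] * factor),
        )


@dataclass
class GazeTrace:
    """Realised eye-position time series with exact beat annotations.

    positions
        (T, 2) array of (x, y) displacements in pixels about the eye's
        rest position, at the reference 240-row scale.
    beat_annotations
        One ``((slow_start, slow_end), (fast_start, fast_end))`` pair of
        sample-index intervals per beat, ordered and non-overlapping.
    occlusion
        (T,) array in [0, 1]: fraction of the eye covered by the lid.
    """

    positions: np.ndarray
    rate: float
    beat_annotations: list = field(default_factory=list)
    occlusion: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("trace positions must be finite")
        if self.occlusion is None:
            self.occlusion = np.zeros(len(self.positions))

    @property
    def n_beats(self) -> int:
        return len(self.beat_annotations)

    @property
    def is_nystagmus(self) -> bool:
        """The operational label rule: ≥ 2 consecutive beats."""
        return self.n_beats >= 2


# ---------------------------------------------------------------------------
# Waveform realisation


def gen_trace(
    spec: WaveformSpec,
    distractors: Optional[DistractorSpec] = None,
    rate: float = 60.0,
    duration: float = 10.0,
    seed: int = 0,
) -> GazeTrace:
    """Realise a gaze trace from a waveform spec plus distractors.

    Fast phases are corrective saccades of the beat amplitude in the
    opposite direction, completed within 1–2 samples. The trace is in
    pixels at the reference 240-row scale; tremor noise is seeded
    Gaussian jitter on position.
    """
    distractors = distractors or DistractorSpec()
    n = int(round(duration * rate))
    if n < 2:
        raise ValueError("duration × rate must be ≥ 2 samples")
    rng = np.random.default_rng(seed)
    px_gain = PX_PER_DEG_AT_240

    direction = np.asarray(spec.direction, dtype=np.float64)
    direction = direction / np.linalg.norm(direction)
    amp_px = spec.amplitude * px_gain

    along = np.zeros(n)
    beats: list = []

    if spec.kind == "pendular":
        if spec.n_beats > 0:
            period = 1.0 / spec.pendular_frequency
            t = np.arange(n) / rate
            active = (t >= spec.onset) & (t < spec.onset + spec.n_beats * period)
            phase = 2 * np.pi * spec.pendular_frequency * (t - spec.onset)
            along[active] = 0.5 * amp_px * np.sin(phase[active])
            for b in range(spec.n_beats):
                s0 = int(round((spec.onset + b * period) * rate))
                half = int(round((spec.onset + (b + 0.5) * period) * rate))
                s1 = int(round((spec.onset + (b + 1) * period) * rate))
                if s1 > n:
                    break
                beats.append(((s0, half), (half, s1)))
    elif spec.kind != "none" and spec.n_beats > 0:
        slow_len = max(2, int(round(spec.slow_phase_duration / 1000.0 * rate)))
        fast_len = 1 if rate <= 30 else 2
        pos = int(round(spec.onset * rate))
        lam = spec.decay_constant
        tau = np.arange(slow_len) / rate
        if spec.kind == "jerk_linear":
            ramp = tau / (slow_len / rate)
        elif spec.kind == "jerk_velocity_decreasing":
            ramp = (1.0 - np.exp(-lam * tau)) / (1.0 - math.exp(-lam * slow_len / rate))
        else:  # velocity increasing
            ramp = (np.exp(lam * tau) - 1.0) / (math.exp(lam * slow_len / rate) - 1.0)
        for _ in range(spec.n_beats):
            end_slow = pos + slow_len
            end_fast = end_slow + fast_len
            if end_fast > n:
                break
            along[pos:end_slow] = amp_px * ramp
            if fast_len == 2:
                along[end_slow] = 0.5 * amp_px
            beats.append(((pos, end_slow), (end_slow, end_fast)))
            pos = end_fast
    positions = np.outer(along, direction)

    # --- distractors -------------------------------------------------------
    t = np.arange(n) / rate
    positions[:, 0] += distractors.drift_velocity * px_gain * t
    for jerk_t, jerk_amp, latency in distractors.square_wave_jerks:
        i0 = int(round(jerk_t * rate))
        i1 = int(round((jerk_t + latency) * rate))
        positions[i0 : max(i1, i0 + 1), 0] += jerk_amp * px_gain
    if distractors.tremor_noise_sd > 0:
        positions += rng.normal(
            0.0, distractors.tremor_noise_sd * px_gain, size=positions.shape
        )

    occlusion = np.zeros(n)
    blink_half = distractors.blink_duration / 1000.0 / 2.0
    for bt in distractors.blink_times:
        lo = int(math.floor((bt - blink_half) * rate))
        hi = int(math.ceil((bt + blink_half) * rate))
        for i in range(max(lo, 0), min(hi + 1, n)):
            # triangular profile: fully closed at blink centre
            frac = 1.0 - abs(i / rate - bt) / max(blink_half, 1e-9)
            occlusion[i] = max(occlusion[i], min(max(frac, 0.0), 1.0))
    for start, end in distractors.lid_closure_intervals:
        i0, i1 = int(round(start * rate)), int(round(end * rate))
        occlusion[max(i0, 0) : min(i1, n)] = 1.0

    return GazeTrace(positions=positions, rate=rate, beat_annotations=beats, occlusion=occlusion)


# ---------------------------------------------------------------------------
# Rendering


def render_clip(
    trace: GazeTrace,
    appearance: Optional[EyeAppearance] = None,
    resolution: tuple[int, int] = (240, 320),
    seed: int = 0,
    patient_id: Optional[str] = None,
    condition: Optional[str] = None,
) -> VideoClip:
    """Draw the eye at each trace position; label from the ≥2-beat rule.

    Deterministic given (trace, appearance, resolution, seed). Raises if
    the eye's excursions leave the frame.
    """
    appearance = appearance or EyeAppearance()
    H, W = resolution
    scale = H / 240.0
    app = appearance.scaled(scale) if scale != 1.0 else appearance
    rng = np.random.default_rng(seed)

    centre = np.array([W / 2.0, H / 2.0])
    offsets = trace.positions * scale + np.asarray(app.gaze_offset)
    xy = centre + offsets
    r_iris = app.iris_radius
    if (
        (xy[:, 0] - r_iris).min() < 0
        or (xy[:, 0] + r_iris).max() > W
        or (xy[:, 1] - r_iris).min() < 0
        or (xy[:, 1] + r_iris).max() > H
    ):
        raise ValueError("eye excursion leaves the frame; reduce amplitude or offset")

    shade = None
    if app.illumination_gradient:
        col = np.arange(W, dtype=np.float64)
        shade = 1.0 + app.illumination_gradient * (col / max(W - 1, 1) - 0.5)

    T = len(trace.positions)
    frames = np.empty((T, H, W), dtype=np.float64)
    pad = int(math.ceil(r_iris)) + 1
    for i in range(T):
        cx, cy = xy[i]
        frame = frames[i]
        frame.fill(app.sclera_intensity)
        # disks drawn only inside the eye's bounding box
        x0, x1 = int(cx) - pad, int(cx) + pad + 1
        y0, y1 = int(cy) - pad, int(cy) + pad + 1
        yy, xx = np.mgrid[y0:y1, x0:x1]
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2
        box = frame[y0:y1, x0:x1]
        box[r2 <= app.iris_radius**2] = app.iris_intensity
        box[r2 <= app.pupil_radius**2] = app.pupil_intensity
        occ = trace.occlusion[i]
        if occ > 0:
            lid_rows = int(round(occ * (cy + r_iris)))
            frame[:lid_rows, :] = app.sclera_intensity * 0.85
        if shade is not None:
            frame *= shade
    if app.sensor_noise_sd > 0:
        noise = rng.standard_normal(size=frames.shape)
        noise *= app.sensor_noise_sd
        frames += noise
    np.clip(frames, 0.0, 255.0, out=frames)
    # quantize to the 8-bit depth a real sensor delivers
    frames = np.rint(frames).astype(np.uint8)

    return VideoClip(
        frames=frames,
        rate=trace.rate,
        label=int(trace.is_nystagmus),
        patient_id=patient_id,
        condition=condition,
        source="synthetic",
    )


def synth_clip(
    spec: WaveformSpec,
    distractors: Optional[DistractorSpec] = None,
    appearance: Optional[EyeAppearance] = None,
    rate: float = 60.0,
    duration: float = 10.0,
    resolution: tuple[int, int] = (240, 320),
    seed: int = 0,
    **render_kw,
) -> VideoClip:
    """Convenience: gen_trace → render_clip with a shared seed."""
    trace = gen_trace(spec, distractors, rate=rate, duration=duration, seed=seed)
    return render_clip(trace, appearance, resolution=resolution, seed=seed + 1, **render_kw)


# ---------------------------------------------------------------------------
# Dataset generation


def make_dataset(
    n_videos: int = 40,
    class_ratio: float = 0.5,
    rate: float = 60.0,
    duration: float = 10.0,
    resolution: tuple[int, int] = (240, 320),
    eccentric_fraction: float = 0.443,
    patients: int = 30,
    seed: int = 0,
    jerk_decreasing_fraction: float = 0.05,
) -> list[VideoClip]:
    """Generate a labeled synthetic dataset mirroring the study design.

    Classes are balanced to ``class_ratio`` exactly (rounded); every
    simulated patient contributes clips of both classes; a rounded
    ``eccentric_fraction`` of clips carry a nonzero gaze offset and the
    ``"eccentric"`` condition tag. Among nystagmus clips 95% are linear
    jerk and 5% velocity-decreasing jerk by default, matching the
    clinical waveform composition. Fully deterministic given ``seed``.
    """
    if not 0.0 < class_ratio < 1.0:
        raise ValueError("class_ratio must lie in (0, 1)")
    if patients < 1:
        raise ValueError("need at least one patient")
    n_pos = int(round(n_videos * class_ratio))
    n_neg = n_videos - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("class_ratio leaves one class empty")
    if n_pos < patients or n_neg < patients:
        raise ValueError(
            f"{patients} patients cannot each contribute both classes "
            f"with class counts ({n_pos}, {n_neg})"
        )
    rng = np.random.default_rng(seed)

    n_ecc = int(round(n_videos * eccentric_fraction))
    eccentric_flags = np.zeros(n_videos, dtype=bool)
    eccentric_flags[:n_ecc] = True
    rng.shuffle(eccentric_flags)

    labels = np.array([1] * n_pos + [0] * n_neg)
    # round-robin patient assignment within each class ⇒ every patient
    # appears in both classes
    patient_of = np.empty(n_videos, dtype=object)
    patient_of[:n_pos] = [f"P{(i % patients):03d}" for i in range(n_pos)]
    patient_of[n_pos:] = [f"P{(i % patients):03d}" for i in range(n_neg)]
    order = rng.permutation(n_videos)

    duration_beats_max = int((duration - 1.0) / 0.17)  # leave room after onset
    clips: list[VideoClip] = []
    for idx in order:
        label = int(labels[idx])
        clip_seed = int(rng.integers(0, 2**31 - 1))
        crng = np.random.default_rng(clip_seed)
        if label == 1:
            kind = (
                "jerk_velocity_decreasing"
                if crng.random() < jerk_decreasing_fraction
                else "jerk_linear"
            )
            # enough beats to fill most of the clip, as in sustained nystagmus
            n_beats = int(crng.integers(max(4, duration_beats_max // 2), max(5, duration_beats_max)))
            spec = WaveformSpec(
                kind=kind,
                slow_phase_duration=float(crng.uniform(150.0, 350.0)),
                amplitude=float(crng.uniform(1.0, 3.0)),
                direction=(1.0, 0.0) if crng.random() < 0.8 else (0.0, 1.0),
                n_beats=n_beats,
                onset=float(crng.uniform(0.2, 0.8)),
            )
        else:
            # quiescent, or a single beat: below the ≥2-beat threshold
            spec = WaveformSpec(
                kind="none" if crng.random() < 0.7 else "jerk_linear",
                slow_phase_duration=float(crng.uniform(150.0, 350.0)),
                amplitude=float(crng.uniform(1.0, 3.0)),
                n_beats=1,
                onset=float(crng.uniform(0.2, duration / 2)),
            )
        distract = DistractorSpec(
            blink_times=tuple(
                float(t)
                for t in crng.uniform(0.3, duration - 0.3, size=crng.integers(0, 3))
            ),
            square_wave_jerks=(
                ((float(crng.uniform(0.3, duration - 0.6)), float(crng.uniform(0.5, 1.5)), 0.25),)
                if crng.random() < 0.4
                else ()
            ),
            drift_velocity=float(crng.uniform(-0.3, 0.3)),
            tremor_noise_sd=float(crng.uniform(0.0, 0.05)),
        )
        eccentric = bool(eccentric_flags[idx])
        offset_mag = 40.0 if eccentric else 0.0
        appearance = EyeAppearance(
            illumination_gradient=float(crng.uniform(-0.2, 0.2)),
            sensor_noise_sd=float(crng.uniform(1.0, 4.0)),
            gaze_offset=(
                float(crng.choice([-offset_mag, offset_mag])) if eccentric else 0.0,
                0.0,
            ),
        )
        trace = gen_trace(spec, distract, rate=rate, duration=duration, seed=clip_seed)
        clip = render_clip(
            trace,
            appearance,
            resolution=resolution,
            seed=clip_seed + 1,
            patient_id=str(patient_of[idx]),
            condition="eccentric" if eccentric else "primary",
        )
        assert clip.label == label, "waveform spec violated the label rule"
        clips.append(clip)
    return clips
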