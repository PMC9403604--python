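"""Aggregate per-filtered-image probabilities into video-level decisions.

Every filtered image of a video receives a nystagmus probability from
the classifier; a voting rule turns that vector into one video-level
score and label:

* soft voting — score is the mean probability;
* hard (majority) voting — each image is binarized at a per-image
  threshold and the score is the fraction of positive images;
* temporal voting — positive iff a sufficiently long run of consecutive
  positive images exists, reflecting the requirement that nystagmus
  beats are contiguous in time; the score is longest-run / stack length;
* ensemble — average of two models' video-level scores (canonically a
  soft-vote model and a hard-vote model).

Conventions (documented and tested): images at exactly the per-image
threshold binarize positive (≥), and video labels use score ≥
video_threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "VotingSpec",
    "PerImageScores",
    "VideoDecision",
    "soft_vote",
    "hard_vote",
    "temporal_vote",
    "ensemble_vote",
    "longest_positive_run",
]

#: run lengths (frames) screened in the temporal-voting experiments
RUN_LENGTH_GRID = (50, 100, 150, 350)


@dataclass
class PerImageScores:
    """Per-filtered-image nystagmus probabilities for one video."""

    probs: np.ndarray
    t_index: Optional[np.ndarray] = None
    video_id: str = ""

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 1:
            raise ValueError("probs must be a 1-D vector")
        if self.probs.size and (self.probs.min() < 0 or self.probs.max() > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.t_index is not None:
            self.t_index = np.asarray(self.t_index)
            if self.t_index.shape != self.probs.shape:
                raise ValueError("t_index must align with probs")

    def __len__(self) -> int:
        return self.probs.size


@dataclass(frozen=True)
class VotingSpec:
    """Voting method plus its thresholds."""

    method: str = "soft"
    prob_threshold: float = 0.5
    video_threshold: float = 0.5
    run_length: int = 50

    def __post_init__(self) -> None:
        if self.method not in {"soft", "hard", "temporal"}:
            raise ValueError(f"unknown voting method {self.method!r}")
        if not 0.0 < self.prob_threshold < 1.0:
            raise ValueError("prob_threshold must lie in (0, 1)")
        if not 0.0 < self.video_threshold < 1.0:
            raise ValueError("video_threshold must lie in (0, 1)")
        if self.run_length < 1:
            raise ValueError("run_length must be ≥ 1")


@dataclass
class VideoDecision:
    """Video-level score and class from one voting rule."""

    video_id: str
    score: float
    label: int
    method: str


def _require_nonempty(scores: PerImageScores) -> None:
    if len(scores) == 0:
        raise ValueError("cannot vote on an empty score vector")


def soft_vote(scores: PerImageScores, spec: Optional[VotingSpec] = None) -> VideoDecision:
    """Video score = mean per-image probability."""
    spec = spec or VotingSpec(method="soft")
    _require_nonempty(scores)
    score = float(scores.probs.mean())
    return VideoDecision(
        video_id=scores.video_id,
        score=score,
        label=int(score >= spec.video_threshold),
        method="soft",
    )


def hard_vote(scores: PerImageScores, spec: Optional[VotingSpec] = None) -> VideoDecision:
    """Video score = fraction of images voting positive after binarization."""
    spec = spec or VotingSpec(method="hard")
    _require_nonempty(scores)
    votes = scores.probs >= spec.prob_threshold
    score = float(votes.mean())
    return VideoDecision(
        video_id=scores.video_id,
        score=score,
        label=int(score >= spec.video_threshold),
        method="hard",
    )


def longest_positive_run(votes: np.ndarray) -> int:
    """Length of the longest run of consecutive True values."""
    best = run = 0
    for v in votes:
        run = run + 1 if v else 0
        best = max(best, run)
    return best


def temporal_vote(scores: PerImageScores, spec: Optional[VotingSpec] = None) -> VideoDecision:
    """Positive iff ≥ run_length consecutive images vote positive.

    Encodes the temporal criterion that nystagmus beats are contiguous:
    isolated positive images scattered through the clip do not qualify.
    """
    spec = spec or VotingSpec(method="temporal")
    _require_nonempty(scores)
    votes = scores.probs >= spec.prob_threshold
    run = longest_positive_run(votes)
    return VideoDecision(
        video_id=scores.video_id,
        score=run / len(scores),
        label=int(run >= spec.run_length),
        method=f"temporal(run≥{spec.run_length})",
    )


def ensemble_vote(decision_a: VideoDecision, decision_b: VideoDecision) -> VideoDecision:
    """Average two models' video scores; label at 0.5.

    Canonically combines a soft-vote decision from one backbone with a
    hard-vote decision from another.
    """
    if decision_a.video_id != decision_b.video_id:
        raise ValueError(
            f"decisions refer to different videos: "
            f"{decision_a.video_id!r} vs {decision_b.video_id!r}"
        )
    score = (decision_a.score + decision_b.score) / 2.0
    return VideoDecision(
        video_id=decision_a.video_id,
        score=score,
        label=int(score >= 0.5),
        method=f"ensemble({decision_a.method}+{decision_b.method})",
    )
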