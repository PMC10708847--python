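"""Shared containers and errors for the single-channel EEG pipeline.

The platform records one prefrontal (Fp1) channel per subject at 512 Hz in
vendor integer units; everything downstream works on 2-s epochs of 1024
samples.  The types here are deliberately thin: raw traces, epochs and the
session annotation that marks which time segments count toward the
attention summary.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RawTrace",
    "Epoch",
    "EpochStatus",
    "Segment",
    "SessionAnnotation",
    "BetawatchError",
    "ClippingError",
    "EmptyCohortError",
    "DuplicatePacketError",
    "ConfigError",
    "EpochLengthError",
    "DegenerateEpochError",
    "EmptyBandError",
    "NormalizationError",
    "ConstantInputError",
    "InsufficientDataError",
    "EmptyGroupError",
    "SingleClassError",
]


class BetawatchError(Exception):
    """Base class for pipeline errors."""


class ClippingError(BetawatchError):
    """A synthetic component is so large that >1% of samples would clip."""


class EmptyCohortError(BetawatchError):
    """A cohort of zero subjects was requested."""


class DuplicatePacketError(BetawatchError):
    """Two packets with the same sequence number were received."""


class ConfigError(BetawatchError):
    """A processing configuration value is inconsistent."""


class EpochLengthError(BetawatchError):
    """An epoch does not have the configured number of samples."""


class DegenerateEpochError(BetawatchError):
    """An epoch has zero variance and cannot be z-scored."""


class EmptyBandError(BetawatchError):
    """A frequency band contains no spectrum bins."""


class NormalizationError(BetawatchError):
    """Cohort min-max normalization is undefined (all totals equal)."""


class ConstantInputError(BetawatchError):
    """A correlation input vector is constant."""


class InsufficientDataError(BetawatchError):
    """Too few observations for the requested robust procedure."""


class EmptyGroupError(BetawatchError):
    """A performance group became empty after the exclusion rules."""


class SingleClassError(BetawatchError):
    """Classification requires both pass and fail labels to be present."""


@dataclass
class RawTrace:
    """A per-subject stream of vendor integer units at a fixed sample rate.

    Parameters
    ----------
    subject_id : str
        Identifier of the recorded subject.
    fs : float
        Sampling frequency in Hz.
    samples : numpy.ndarray
        Signed integer vendor units, one per sample.
    seed : int or None
        Seed used to generate the trace, if synthetic.
    n_clipped : int
        Number of samples clipped to the vendor range at generation time.
    meta : dict
        Free-form metadata echoed to the JSON sidecar.
    """

    subject_id: str
    fs: float
    samples: np.ndarray
    seed: int | None = None
    n_clipped: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


class EpochStatus(enum.Enum):
    """Fate of an epoch in the per-subject summary."""

    ACCEPTED = "accepted"
    REJECTED_ARTIFACT = "rejected_artifact"
    REJECTED_DEGENERATE = "rejected_degenerate"
    EXCLUDED_BY_MASK = "excluded_by_mask"


@dataclass
class Epoch:
    """A contiguous analysis window of raw vendor-unit samples.

    ``index`` counts epochs from the start of the recording; ``start_s`` is
    the absolute start time so annotation masking can decide whether the
    window lies inside a video segment.
    """

    subject_id: str
    index: int
    start_s: float
    raw: np.ndarray

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw)

    def __len__(self) -> int:
        return len(self.raw)

    def end_s(self, fs: float) -> float:
        return self.start_s + len(self.raw) / fs


VALID_SEGMENT_LABELS = frozenset({"video", "survey", "quiz", "briefing", "closing"})


@dataclass(frozen=True)
class Segment:
    """A labelled time interval of the session, in seconds."""

    label: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.label not in VALID_SEGMENT_LABELS:
            raise ValueError(f"unknown segment label {self.label!r}")
        if not self.end_s > self.start_s:
            raise ValueError("segment must have positive duration")


@dataclass
class SessionAnnotation:
    """Ordered, non-overlapping labelled segments covering the session.

    Only epochs that lie fully inside ``video`` segments contribute to the
    attention summary; survey/quiz blocks between videos are masked out.
    """

    segments: list[Segment]

    def __post_init__(self) -> None:
        segs = [s if isinstance(s, Segment) else Segment(*s) for s in self.segments]
        for a, b in zip(segs, segs[1:]):
            if b.start_s < a.end_s:
                raise ValueError("segments must be non-overlapping and ascending")
        self.segments = segs

    @property
    def video_segments(self) -> list[Segment]:
        return [s for s in self.segments if s.label == "video"]

    @property
    def end_s(self) -> float:
        return self.segments[-1].end_s if self.segments else 0.0

    def contains_epoch(self, start_s: float, end_s: float) -> bool:
        """True iff [start_s, end_s) lies fully inside one video segment."""
        for seg in self.video_segments:
            if start_s >= seg.start_s and end_s <= seg.end_s:
                return True
        return False

    @classmethod
    def standard_session(
        cls,
        n_video_segments: int = 4,
        video_s: float = 240.0,
        survey_s: float = 90.0,
        quiz_s: float = 90.0,
    ) -> "SessionAnnotation":
        """The study timeline: alternating video and question blocks.

        The default is four 4-min video segments, each followed by a
        90-s mental-state survey and a 90-s content quiz (28 min total);
        only the 16 min of video count toward the summary.
        """
        segs: list[Segment] = []
        t = 0.0
        for _ in range(n_video_segments):
            segs.append(Segment("video", t, t + video_s))
            t += video_s
            segs.append(Segment("survey", t, t + survey_s))
            t += survey_s
            segs.append(Segment("quiz", t, t + quiz_s))
            t += quiz_s
        return cls(segs)
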