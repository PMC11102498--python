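"""10-ms pitch frame sequences: speech classification and segmentation.

Interview responses arrive as fixed-rate frame tables, one row per 10-ms
analysis frame carrying the fundamental frequency (F0, Hz; 0 for unvoiced
frames) and optionally intensity (dB).  A frame is *speech* when its F0
falls strictly inside a band (default 75–250 Hz, the male-voice band that
also excludes high-frequency noise).  A maximal run of at least 50
consecutive speech frames (500 ms) is an *utterance*; a maximal run of
non-speech frames is a *gap*; speech runs shorter than the utterance
minimum form a third class of *sub-threshold runs* so that utterances,
gaps and sub-threshold runs partition the response exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

FRAME_MS = 10.0
"""Fixed frame hop in milliseconds."""

DEFAULT_F0_LOW_HZ = 75.0
DEFAULT_F0_HIGH_HZ = 250.0
MIN_UTTERANCE_FRAMES = 50


class EmptySequenceError(ValueError):
    """Raised when an operation receives a frame sequence with no frames."""


class MaskNotSetError(RuntimeError):
    """Raised when segmentation is requested before speech classification."""


@dataclass(frozen=True)
class Frame:
    """A single 10-ms analysis frame.

    Parameters
    ----------
    index : int
        Frame ordinal within the response (0-based; one frame per 10 ms).
    f0 : float
        Fundamental frequency in Hz; 0 encodes an unvoiced frame.
    intensity : float, optional
        Intensity in dB, if the source provided it.
    """

    index: int
    f0: float
    intensity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError(f"frame index must be non-negative, got {self.index}")
        if self.f0 < 0:
            raise ValueError(f"f0 must be non-negative, got {self.f0}")


@dataclass
class FrameSequence:
    """An ordered, contiguous sequence of 10-ms frames for one response.

    F0 and intensity are held as arrays (frame ``i`` is the i-th entry);
    ``speech_mask`` is ``None`` until :func:`classify_speech_frames` sets it.
    """

    response_id: str
    participant_id: str
    f0: np.ndarray
    intensity: Optional[np.ndarray] = None
    speech_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.f0 = np.asarray(self.f0, dtype=float)
        if self.f0.ndim != 1:
            raise ValueError("f0 must be one-dimensional")
        if np.any(self.f0 < 0):
            raise ValueError("f0 values must be non-negative")
        if self.intensity is not None:
            self.intensity = np.asarray(self.intensity, dtype=float)
            if self.intensity.shape != self.f0.shape:
                raise ValueError("intensity must align with f0")
        if self.speech_mask is not None:
            self.speech_mask = np.asarray(self.speech_mask, dtype=bool)
            if self.speech_mask.shape != self.f0.shape:
                raise ValueError("speech_mask must have one entry per frame")

    @classmethod
    def from_frames(
        cls, response_id: str, participant_id: str, frames: Sequence[Frame]
    ) -> "FrameSequence":
        """Build a sequence from :class:`Frame` records (must be contiguous)."""
        indices = [f.index for f in frames]
        if indices != list(range(len(frames))):
            raise ValueError("frames must be contiguous, ordered and start at 0")
        intensity = None
        if frames and all(f.intensity is not None for f in frames):
            intensity = np.array([f.intensity for f in frames], dtype=float)
        return cls(
            response_id=response_id,
            participant_id=participant_id,
            f0=np.array([f.f0 for f in frames], dtype=float),
            intensity=intensity,
        )

    @property
    def n_frames(self) -> int:
        return int(self.f0.shape[0])

    @property
    def total_duration_ms(self) -> float:
        return FRAME_MS * self.n_frames

    @property
    def frames(self) -> list[Frame]:
        """Materialize :class:`Frame` records (convenience accessor)."""
        if self.intensity is None:
            return [Frame(i, float(v)) for i, v in enumerate(self.f0)]
        return [
            Frame(i, float(v), float(w))
            for i, (v, w) in enumerate(zip(self.f0, self.intensity))
        ]

    def speech_f0(self) -> np.ndarray:
        """Pitch values of speech frames, in frame order (mask required)."""
        if self.speech_mask is None:
            raise MaskNotSetError(
                f"speech mask not set for response {self.response_id!r}; "
                "run classify_speech_frames first"
            )
        return self.f0[self.speech_mask]


@dataclass(frozen=True)
class SegmentationResult:
    """Partition of a response into utterances, gaps and sub-threshold runs.

    All ranges are half-open ``(start, end)`` frame-index pairs.  The three
    range lists are pairwise disjoint and jointly cover ``[0, total)``.
    """

    utterances: tuple[tuple[int, int], ...]
    gaps: tuple[tuple[int, int], ...]
    subthreshold_runs: tuple[tuple[int, int], ...]
    speech_frame_count: int
    total_frame_count: int

    @property
    def utterance_frame_count(self) -> int:
        return sum(e - s for s, e in self.utterances)

    def utterance_durations_s(self) -> np.ndarray:
        return np.array([(e - s) * FRAME_MS / 1000.0 for s, e in self.utterances])

    def gap_durations_s(self) -> np.ndarray:
        return np.array([(e - s) * FRAME_MS / 1000.0 for s, e in self.gaps])


def classify_speech_frames(
    seq: FrameSequence,
    low: float = DEFAULT_F0_LOW_HZ,
    high: float = DEFAULT_F0_HIGH_HZ,
) -> FrameSequence:
    """Mark frames whose F0 lies strictly inside ``(low, high)`` as speech.

    Both bounds are strict: a frame at exactly 75 Hz or 250 Hz is
    non-speech, and unvoiced frames (f0 = 0) are always non-speech.
    Returns a copy of ``seq`` with ``speech_mask`` set.
    """
    if low >= high:
        raise ValueError(f"band bounds must satisfy low < high, got {low} >= {high}")
    if seq.n_frames == 0:
        raise EmptySequenceError(
            f"response {seq.response_id!r} has no frames to classify"
        )
    mask = (seq.f0 > low) & (seq.f0 < high)
    return replace(seq, speech_mask=mask)


def _runs(mask: np.ndarray):
    """Yield (value, start, end) for maximal constant runs of a boolean array."""
    start = 0
    for value, group in itertools.groupby(mask):
        length = sum(1 for _ in group)
        yield bool(value), start, start + length
        start += length


def segment(
    seq: FrameSequence, min_utterance_frames: int = MIN_UTTERANCE_FRAMES
) -> SegmentationResult:
    """Partition a classified sequence into utterances, gaps and short runs.

    Maximal speech runs of at least ``min_utterance_frames`` frames become
    utterances; shorter speech runs are sub-threshold; maximal non-speech
    runs are gaps (including leading/trailing ones).
    """
    if seq.speech_mask is None:
        raise MaskNotSetError(
            f"response {seq.response_id!r} must be classified before segmentation"
        )
    if min_utterance_frames < 1:
        raise ValueError("min_utterance_frames must be positive")
    utterances: list[tuple[int, int]] = []
    gaps: list[tuple[int, int]] = []
    short: list[tuple[int, int]] = []
    for is_speech, start, end in _runs(seq.speech_mask):
        if not is_speech:
            gaps.append((start, end))
        elif end - start >= min_utterance_frames:
            utterances.append((start, end))
        else:
            short.append((start, end))
    return SegmentationResult(
        utterances=tuple(utterances),
        gaps=tuple(gaps),
        subthreshold_runs=tuple(short),
        speech_frame_count=int(seq.speech_mask.sum()),
        total_frame_count=seq.n_frames,
    )


def speech_seconds(seg: SegmentationResult) -> float:
    """Seconds of speech in a response: speech-frame count x 10 ms.

    Counts every speech-classified frame, including frames in sub-threshold
    runs — this is the quantity the 10-second response filter consumes.
    """
    return seg.speech_frame_count * FRAME_MS / 1000.0


# ---------------------------------------------------------------------------
# Frame-table I/O
# ---------------------------------------------------------------------------

FRAME_TABLE_SUFFIX = ".frames.csv"


def read_frame_table(path: str | Path) -> FrameSequence:
    """Read a delimited frame table (columns time_s, f0_hz[, intensity_db]).

    Participant and response identifiers are taken from the file name,
    expected as ``<participant>_<response>.frames.csv``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"time_s", "f0_hz"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if len(df) == 0:
        raise EmptySequenceError(f"{path}: empty frame table")
    participant_id, response_id = _ids_from_name(path)
    intensity = df["intensity_db"].to_numpy() if "intensity_db" in df.columns else None
    return FrameSequence(
        response_id=response_id,
        participant_id=participant_id,
        f0=df["f0_hz"].to_numpy(),
        intensity=intensity,
    )


def write_frame_table(seq: FrameSequence, directory: str | Path) -> Path:
    """Write ``seq`` as ``<participant>_<response>.frames.csv`` under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{seq.participant_id}_{seq.response_id}{FRAME_TABLE_SUFFIX}"
    data = {
        "time_s": np.arange(seq.n_frames) * FRAME_MS / 1000.0,
        "f0_hz": seq.f0,
    }
    if seq.intensity is not None:
        data["intensity_db"] = seq.intensity
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6g")
    return path


def _ids_from_name(path: Path) -> tuple[str, str]:
    stem = path.name
    for suffix in (FRAME_TABLE_SUFFIX, ".csv", ".txt"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    if "_" not in stem:
        raise ValueError(
            f"{path.name}: cannot split into <participant>_<response>"
        )
    participant_id, response_id = stem.split("_", 1)
    return participant_id, response_id


def read_praat_pitch(path: str | Path) -> FrameSequence:
    """Read a Praat Pitch object saved as a *short text file*.

    The short-text layout is: two header lines (``File type`` /
    ``Object class``), a blank line, then the bare numbers xmin, xmax, nx,
    dx, x1, ceiling, maxnCandidates, followed per frame by intensity,
    nCandidates and then (frequency, strength) for each candidate.  The
    first candidate is Praat's winning pitch path; frequency 0 (or at/above
    the ceiling) encodes an unvoiced frame.  The 10-ms frame convention is
    enforced via dx.
    """
    path = Path(path)
    values: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("File type", "Object class", '"')):
                continue
            values.append(line)
    if len(values) < 7:
        raise ValueError(f"{path}: not a Praat Pitch short text file")
    it = iter(values)
    float(next(it))  # xmin
    float(next(it))  # xmax
    nx = int(float(next(it)))
    dx = float(next(it))
    float(next(it))  # x1
    ceiling = float(next(it))
    int(float(next(it)))  # maxnCandidates
    if abs(dx - FRAME_MS / 1000.0) > 1e-9:
        raise ValueError(f"{path}: frame step {dx}s, expected 0.01s")
    f0 = np.zeros(nx)
    intensity = np.zeros(nx)
    for i in range(nx):
        intensity[i] = float(next(it))
        n_cand = int(float(next(it)))
        for j in range(n_cand):
            freq = float(next(it))
            float(next(it))  # strength
            if j == 0:
                f0[i] = freq if 0.0 < freq < ceiling else 0.0
    participant_id, response_id = _ids_from_name(path)
    return FrameSequence(
        response_id=response_id,
        participant_id=participant_id,
        f0=f0,
        intensity=intensity,
    )
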