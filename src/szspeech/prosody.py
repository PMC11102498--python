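"""The nine acoustic prosodic features of a segmented response.

Duration features (MUD, MGD, MSR, MSRS) summarize speech pacing; pitch
features (MP, PR, PS, FPC, J) summarize intonation dynamics over the
speech-classified frames.  Features that a response cannot define (e.g.
MUD with zero utterances) are reported as NaN — an explicit undefined
marker, never fabricated as 0 — and imputed or dropped downstream.

Pitch-indexed features (FPC, J) operate by default on the concatenated
sequence of speech frames: the v-th speech frame, regardless of the gaps
between them, so pairs and windows may bridge a silence.  A
gap-respecting alternative is available via ``bridge_gaps=False``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Optional

import numpy as np

from .frames import FrameSequence, MaskNotSetError, SegmentationResult, segment

UNDEFINED = float("nan")

#: Canonical order of the nine classification features.
ACOUSTIC_FEATURES = ("MUD", "MGD", "MSR", "MSRS", "MP", "PR", "PS", "FPC", "J")


class ZeroWindowSumError(ZeroDivisionError):
    """A jitter window summed to zero, leaving the statistic undefined."""


@dataclass(frozen=True)
class JitterParams:
    """Locality parameter for the jitter statistic.

    K is the odd width (in speech frames) of the local window; the default
    of 5 means each frame's pitch is compared against its 2 neighbours on
    each side.
    """

    K: int = 5
    denominator: str = "sum"  # "sum" (as defined) or "mean" (sensitivity variant)

    def __post_init__(self) -> None:
        if self.K < 3 or self.K % 2 == 0:
            raise ValueError(f"K must be an odd integer >= 3, got {self.K}")
        if self.denominator not in ("sum", "mean"):
            raise ValueError("denominator must be 'sum' or 'mean'")


@dataclass
class ProsodicFeatureVector:
    """The nine acoustic features of one response, plus the PR variant.

    Units: MUD/MGD seconds, MSR/MSRS ratios in [0, 1], MP/PS Hz,
    PR/PR_min/J dimensionless, FPC a correlation in [-1, 1].
    Undefined features are NaN.
    """

    MUD: float = UNDEFINED
    MGD: float = UNDEFINED
    MSR: float = UNDEFINED
    MSRS: float = UNDEFINED
    MP: float = UNDEFINED
    PR: float = UNDEFINED
    PR_min: float = UNDEFINED
    PS: float = UNDEFINED
    FPC: float = UNDEFINED
    J: float = UNDEFINED

    def as_dict(self, include_variant: bool = False) -> dict[str, float]:
        out = {name: getattr(self, name) for name in ACOUSTIC_FEATURES}
        if include_variant:
            out["PR_min"] = self.PR_min
        return out


def mud(seg: SegmentationResult) -> float:
    """Mean utterance duration in seconds; NaN when there are no utterances."""
    durations = seg.utterance_durations_s()
    if durations.size == 0:
        return UNDEFINED
    return float(durations.mean())


def mgd(seg: SegmentationResult) -> float:
    """Mean gap duration in seconds; NaN when there are no gaps."""
    durations = seg.gap_durations_s()
    if durations.size == 0:
        return UNDEFINED
    return float(durations.mean())


def msr(seg: SegmentationResult) -> float:
    """Utterance time over total response time (0 when no utterances)."""
    if seg.total_frame_count == 0:
        raise ValueError("MSR undefined for an empty response")
    return seg.utterance_frame_count / seg.total_frame_count


def msrs(seg: SegmentationResult) -> float:
    """Speech frames over total frames (an upper bound on MSR)."""
    if seg.total_frame_count == 0:
        raise ValueError("MSRS undefined for an empty response")
    return seg.speech_frame_count / seg.total_frame_count


def mp(seq: FrameSequence) -> float:
    """Mean pitch (Hz) over speech frames; NaN without speech frames."""
    p = seq.speech_f0()
    if p.size == 0:
        return UNDEFINED
    return float(p.mean())


def ps(seq: FrameSequence) -> float:
    """Sample standard deviation of speech-frame pitch (Hz); needs >= 2 frames."""
    p = seq.speech_f0()
    if p.size < 2:
        return UNDEFINED
    return float(p.std(ddof=1))


def pitch_range(seq: FrameSequence, mode: str = "mean") -> float:
    """Normalized pitch range of speech frames.

    ``mode='mean'``: (max - min) / mean pitch.  ``mode='min'``: the
    alternative normalization (max - min) / min pitch.
    """
    if mode not in ("mean", "min"):
        raise ValueError("mode must be 'mean' or 'min'")
    p = seq.speech_f0()
    if p.size == 0:
        return UNDEFINED
    spread = float(p.max() - p.min())
    denom = float(p.mean()) if mode == "mean" else float(p.min())
    if denom == 0.0:
        return UNDEFINED
    return spread / denom


def _lag1_pairs(seq: FrameSequence, bridge_gaps: bool) -> tuple[np.ndarray, np.ndarray]:
    if bridge_gaps:
        p = seq.speech_f0()
        return p[:-1], p[1:]
    # gap-respecting variant: only pairs of temporally adjacent speech frames
    mask = seq.speech_mask
    if mask is None:
        raise MaskNotSetError("speech mask not set")
    keep = mask[:-1] & mask[1:]
    return seq.f0[:-1][keep], seq.f0[1:][keep]


def fpc(seq: FrameSequence, bridge_gaps: bool = True) -> float:
    """Frame pitch correlation: lag-1 Pearson autocorrelation of speech pitch.

    The Pearson correlation between the speech-frame pitch sequence and
    its one-step-shifted copy.  High values mean the speaker sustains
    pitch from frame to frame.  NaN when fewer than 3 speech frames or
    when either paired sequence is constant.
    """
    x, y = _lag1_pairs(seq, bridge_gaps)
    if x.size < 2 or seq.speech_f0().size < 3:
        return UNDEFINED
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return UNDEFINED
    return float(np.corrcoef(x, y)[0, 1])


def jitter(
    seq: FrameSequence,
    params: JitterParams = JitterParams(),
    bridge_gaps: bool = True,
) -> float:
    """Local deviation of pitch from stationarity.

    With R speech frames of pitch p(0..R-1), half-window h = (K-1)/2 and
    local window sum S(v) = sum_{k=-h..h} p(v+k),

        J = 1/(R-K) * sum_{v=h}^{R-h-1} (p(v) - S(v)/K) / S(v)

    i.e. each interior frame's signed deviation from its local K-frame
    mean, normalized by the local window sum and averaged.  The
    ``denominator='mean'`` variant divides by S(v)/K instead, scaling the
    statistic by K.  NaN when R <= K; a zero window sum raises, since no
    finite value exists (impossible for speech frames, whose pitch is
    positive).
    """
    K = params.K
    if bridge_gaps:
        segments = [seq.speech_f0()]
    else:
        # gap-respecting variant: windows never straddle a silence
        segments = _speech_run_pitches(seq)
    term_sum = 0.0
    normalizer = 0
    any_speech = sum(p.size for p in segments)
    if any_speech <= K:
        return UNDEFINED
    for p in segments:
        R = p.size
        if R <= K:
            continue
        h = (K - 1) // 2
        window_sums = np.convolve(p, np.ones(K), mode="valid")  # S(v), v=h..R-h-1
        if np.any(window_sums == 0):
            raise ZeroWindowSumError("a local pitch window sums to zero")
        numerator = p[h : R - h] - window_sums / K
        denom = window_sums if params.denominator == "sum" else window_sums / K
        term_sum += float(np.sum(numerator / denom))
        normalizer += R - K
    if normalizer == 0:
        return UNDEFINED
    return term_sum / normalizer


def _speech_run_pitches(seq: FrameSequence) -> list[np.ndarray]:
    from .frames import _runs

    if seq.speech_mask is None:
        raise MaskNotSetError("speech mask not set")
    return [
        seq.f0[start:end]
        for is_speech, start, end in _runs(seq.speech_mask)
        if is_speech
    ]


def extract_all(
    seq: FrameSequence,
    jitter_params: JitterParams = JitterParams(),
    min_utterance_frames: int = 50,
    bridge_gaps: bool = True,
) -> ProsodicFeatureVector:
    """Compute all prosodic features of a classified frame sequence.

    The sequence must already carry a speech mask; segmentation is
    performed here.  Undefined features propagate as NaN.
    """
    if seq.speech_mask is None:
        raise MaskNotSetError(
            f"response {seq.response_id!r} must be classified before extraction"
        )
    seg = segment(seq, min_utterance_frames=min_utterance_frames)
    return ProsodicFeatureVector(
        MUD=mud(seg),
        MGD=mgd(seg),
        MSR=msr(seg),
        MSRS=msrs(seg),
        MP=mp(seq),
        PR=pitch_range(seq, mode="mean"),
        PR_min=pitch_range(seq, mode="min"),
        PS=ps(seq),
        FPC=fpc(seq, bridge_gaps=bridge_gaps),
        J=jitter(seq, jitter_params, bridge_gaps=bridge_gaps),
    )
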