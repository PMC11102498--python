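"""Synthetic cohort generation for end-to-end pipeline testing.

Generates everything the pipeline consumes — 10-ms frame sequences,
annotated transcripts, a word-embedding table, a reference-corpus
adjective profile, and participant metadata — with controllable group
effects, so every stage runs without any external data.

Acoustic model per response: speech and silence alternate; silence
durations are lognormal; speech runs are a mixture of sub-threshold
bursts (shorter than the 500 ms utterance minimum) and utterance runs of
500 ms plus an exponential excess.  Speech-frame pitch follows an AR(1)
process around the group mean, truncated to the interior of the 75-250 Hz
band so that generated speech classifies as speech.  The default group
parameters are calibrated analytically so cohort means of MUD, MGD, MSR
and MSRS land near the published group profile for controls
(0.558 s, 0.236 s, 0.446, 0.563) and patients (~0.52 s, 0.928 s, 0.220,
0.311), and the AR(1) coefficients near the published lag-1 pitch
correlations (0.58 vs 0.48).  The patient utterance-duration target sits
just above the 500 ms floor: a mean below it is unattainable under the
utterance definition.

Text model: content words embed as unit vectors clustered into topics;
a response is a topic-respecting random walk that switches topics with a
group-specific probability (driving derailment down as switching rises),
and noun tokens occasionally take an adjectival modifier drawn from the
noun's own topic or — at the group's atypicality rate — from a foreign
topic (driving incoherence down).  A matching reference corpus of
typical noun-adjective pairs is emitted and digested into the profile.
Tokens are abstract lowercase strings; no natural language is emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.signal import lfilter

from .clinstats import ParticipantRecord, write_metadata
from .frames import FrameSequence, write_frame_table
from .textfeat import (
    AdjectiveProfile,
    AnnotatedResponse,
    AnnotatedToken,
    EmbeddingTable,
    build_adjective_profile,
    write_conllu,
)


@dataclass(frozen=True)
class GroupAcousticSpec:
    """Per-group parameters of the frame-sequence generator.

    Each response first draws its own latent parameters (gap mean,
    utterance excess, sub-run probability, pitch mean/SD/AR coefficient)
    from between-response distributions, then generates frames from
    them.  The between-response SDs reproduce the response-level spread
    of the duration and pitch features; within a response, gap durations
    are lognormal around the response's gap mean and utterance excesses
    exponential around its excess mean.
    """

    gap_mean_s: float
    gap_between_sd_s: float  # SD of the response-level mean gap
    subrun_prob: float  # fraction of speech runs below the utterance minimum
    subrun_prob_sd: float
    subrun_min_s: float
    subrun_max_s: float
    utterance_excess_mean_s: float  # mean excess over the 500 ms floor
    utterance_excess_between_sd_s: float
    pitch_mean_hz: float
    pitch_between_sd_hz: float  # SD of the response-level mean pitch
    pitch_sd_hz: float  # mean within-response pitch SD
    pitch_sd_between_sd_hz: float
    pitch_ar1: float
    pitch_ar1_sd: float
    jitter_noise_hz: float  # extra white pitch noise per speech frame
    target_speech_mean_s: float
    target_speech_sd_s: float
    gap_within_cv: float = 0.6  # CV of individual gap durations in a response

    def __post_init__(self) -> None:
        if not -1.0 < self.pitch_ar1 < 1.0:
            raise ValueError("pitch AR(1) coefficient must lie in (-1, 1)")
        for name in ("gap_mean_s", "subrun_min_s", "target_speech_mean_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.subrun_prob <= 1.0:
            raise ValueError("subrun_prob must be a probability")


@dataclass(frozen=True)
class GroupTextSpec:
    """Per-group parameters of the transcript generator."""

    content_words_per_response: int
    topic_switch_prob: float
    atypical_adj_prob: float
    adj_pair_prob: float = 0.35  # chance a noun token takes an amod adjective
    function_word_prob: float = 0.30

    def __post_init__(self) -> None:
        for name in ("topic_switch_prob", "atypical_adj_prob", "adj_pair_prob",
                     "function_word_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")


CONTROL_ACOUSTIC = GroupAcousticSpec(
    gap_mean_s=0.236,
    gap_between_sd_s=0.083,
    subrun_prob=0.568,
    subrun_prob_sd=0.10,
    subrun_min_s=0.02,
    subrun_max_s=0.20,
    utterance_excess_mean_s=0.058,
    utterance_excess_between_sd_s=0.110,
    pitch_mean_hz=129.2,
    pitch_between_sd_hz=22.1,
    pitch_sd_hz=21.6,
    pitch_sd_between_sd_hz=5.5,
    pitch_ar1=0.581,
    pitch_ar1_sd=0.096,
    jitter_noise_hz=0.0,
    target_speech_mean_s=30.0,
    target_speech_sd_s=12.0,
)

PATIENT_ACOUSTIC = GroupAcousticSpec(
    gap_mean_s=0.928,
    gap_between_sd_s=1.10,
    subrun_prob=0.676,
    subrun_prob_sd=0.08,
    subrun_min_s=0.02,
    subrun_max_s=0.183,
    utterance_excess_mean_s=0.008,
    utterance_excess_between_sd_s=0.016,
    pitch_mean_hz=125.4,
    pitch_between_sd_hz=21.3,
    pitch_sd_hz=19.4,
    pitch_sd_between_sd_hz=7.4,
    pitch_ar1=0.483,
    pitch_ar1_sd=0.147,
    jitter_noise_hz=0.0,
    target_speech_mean_s=22.0,
    target_speech_sd_s=8.0,
)

CONTROL_TEXT = GroupTextSpec(
    content_words_per_response=60,
    topic_switch_prob=0.05,
    atypical_adj_prob=0.05,
)

PATIENT_TEXT = GroupTextSpec(
    content_words_per_response=60,
    topic_switch_prob=0.12,
    atypical_adj_prob=0.25,
)


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort.

    Defaults mirror the study conditions: 25 controls and 23 patients,
    18 responses each (14 picture descriptions + 4 open questions).
    """

    n_control: int = 25
    n_patient: int = 23
    responses_per_participant: int = 18
    control_acoustic: GroupAcousticSpec = CONTROL_ACOUSTIC
    patient_acoustic: GroupAcousticSpec = PATIENT_ACOUSTIC
    control_text: GroupTextSpec = CONTROL_TEXT
    patient_text: GroupTextSpec = PATIENT_TEXT
    vocab_nouns_per_topic: int = 12
    vocab_verbs_per_topic: int = 10
    vocab_adjs_per_topic: int = 8
    vocab_advs_per_topic: int = 6
    n_topics: int = 8
    embedding_dim: int = 50
    embedding_common: float = 0.5  # shared anisotropy component (baseline cosine)
    embedding_topic: float = 0.8  # topic-cluster component
    embedding_noise: float = 1.55  # word-specific component
    n_corpus_documents: int = 40
    panss_mean: float = 17.5
    panss_sd: float = 5.5
    control_age: tuple[float, float] = (33.2, 10.0)
    patient_age: tuple[float, float] = (25.5, 6.4)
    control_education: tuple[float, float] = (11.96, 0.20)
    patient_education: tuple[float, float] = (11.21, 1.12)

    def acoustic(self, group: str) -> GroupAcousticSpec:
        return self.control_acoustic if group == "control" else self.patient_acoustic

    def text(self, group: str) -> GroupTextSpec:
        return self.control_text if group == "control" else self.patient_text

    @classmethod
    def null(cls, **overrides) -> "CohortSpec":
        """A cohort with identical group parameters (no true effect)."""
        base = cls(**overrides)
        return replace(
            base,
            patient_acoustic=base.control_acoustic,
            patient_text=base.control_text,
            patient_age=base.control_age,
            patient_education=base.control_education,
        )


# ---------------------------------------------------------------------------
# Acoustic generation
# ---------------------------------------------------------------------------


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and SD."""
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def gen_frames(
    spec: CohortSpec,
    group: str,
    participant_id: str,
    response_id: str,
    rng: np.random.Generator,
    f0_low: float = 75.0,
    f0_high: float = 250.0,
) -> FrameSequence:
    """Generate one response's frame sequence under the group's parameters."""
    a = spec.acoustic(group)

    # response-level latent parameters (between-response heterogeneity)
    gap_mean_r = _lognormal_draw(rng, a.gap_mean_s, a.gap_between_sd_s)
    excess_r = _lognormal_draw(
        rng, a.utterance_excess_mean_s, a.utterance_excess_between_sd_s
    )
    subrun_prob_r = float(
        np.clip(rng.normal(a.subrun_prob, a.subrun_prob_sd), 0.0, 1.0)
    )
    pitch_mean_r = float(
        np.clip(rng.normal(a.pitch_mean_hz, a.pitch_between_sd_hz), f0_low + 10, f0_high - 30)
    )
    pitch_sd_r = max(float(rng.normal(a.pitch_sd_hz, a.pitch_sd_between_sd_hz)), 0.0)
    if a.pitch_sd_hz == 0.0 and a.pitch_sd_between_sd_hz == 0.0:
        pitch_sd_r = 0.0
    ar1_r = float(np.clip(rng.normal(a.pitch_ar1, a.pitch_ar1_sd), 0.0, 0.98))

    tgt_mu, tgt_sigma = _lognormal_params(
        a.target_speech_mean_s, max(a.target_speech_sd_s, 1e-6)
    )
    target_frames = max(int(round(np.exp(rng.normal(tgt_mu, tgt_sigma)) * 100)), 50)
    gap_mu, gap_sigma = _lognormal_params(
        gap_mean_r, max(a.gap_within_cv * gap_mean_r, 1e-6)
    )

    run_lengths: list[tuple[bool, int]] = []  # (is_speech, n_frames)
    speech_frames = 0
    if rng.random() < 0.5:  # leading gap
        run_lengths.append((False, _gap_frames(rng, gap_mu, gap_sigma)))
    while speech_frames < target_frames:
        if rng.random() < subrun_prob_r:
            dur = rng.uniform(a.subrun_min_s, a.subrun_max_s)
            n = min(max(int(round(dur * 100)), 1), 49)
        else:
            n = 50 + int(rng.exponential(excess_r * 100))
        run_lengths.append((True, n))
        speech_frames += n
        run_lengths.append((False, _gap_frames(rng, gap_mu, gap_sigma)))

    total = sum(n for _, n in run_lengths)
    f0 = np.zeros(total)
    pitch = _ar1_pitch(
        pitch_mean_r, pitch_sd_r, ar1_r, a.jitter_noise_hz, speech_frames, rng
    )
    pitch = np.clip(pitch, f0_low + 1.0, f0_high - 1.0)
    pos = 0
    consumed = 0
    for is_speech, n in run_lengths:
        if is_speech:
            f0[pos : pos + n] = pitch[consumed : consumed + n]
            consumed += n
        pos += n
    return FrameSequence(
        response_id=response_id, participant_id=participant_id, f0=f0
    )


def _lognormal_draw(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd <= 0:
        return mean
    mu, sigma = _lognormal_params(mean, sd)
    return float(np.exp(rng.normal(mu, sigma)))


def _gap_frames(rng: np.random.Generator, mu: float, sigma: float) -> int:
    return max(int(round(np.exp(rng.normal(mu, sigma)) * 100)), 1)


def _ar1_pitch(
    mean_hz: float,
    sd_hz: float,
    phi: float,
    noise_hz: float,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    if n == 0:
        return np.zeros(0)
    if sd_hz == 0.0 and noise_hz == 0.0:
        return np.full(n, mean_hz)
    innov_sd = sd_hz * np.sqrt(max(1.0 - phi**2, 0.0))
    eps = rng.normal(0.0, innov_sd, size=n)
    eps[0] = rng.normal(0.0, sd_hz)  # stationary start
    deviations = lfilter([1.0], [1.0, -phi], eps)
    pitch = mean_hz + deviations
    if noise_hz > 0.0:
        pitch = pitch + rng.normal(0.0, noise_hz, size=n)
    return pitch


# ---------------------------------------------------------------------------
# Text generation
# ---------------------------------------------------------------------------


@dataclass
class TextWorld:
    """Shared text-side assets of a cohort: vocabulary, embeddings, profile."""

    embeddings: EmbeddingTable
    nouns: list[list[str]]  # per topic
    verbs: list[list[str]]
    adjs: list[list[str]]
    advs: list[list[str]]
    corpus: list[AnnotatedResponse]
    profile: AdjectiveProfile

    @property
    def n_topics(self) -> int:
        return len(self.nouns)


_FUNCTION_WORDS = (
    ("det0", "DET"),
    ("det1", "DET"),
    ("adp0", "ADP"),
    ("adp1", "ADP"),
    ("pron0", "PRON"),
    ("cconj0", "CCONJ"),
)


def gen_text_world(spec: CohortSpec, rng: np.random.Generator) -> TextWorld:
    """Build the topic-clustered vocabulary, embeddings and reference profile."""
    kinds = {
        "n": spec.vocab_nouns_per_topic,
        "v": spec.vocab_verbs_per_topic,
        "adj": spec.vocab_adjs_per_topic,
        "adv": spec.vocab_advs_per_topic,
    }
    def unit(v: np.ndarray) -> np.ndarray:
        return v / np.linalg.norm(v)

    centers = np.stack(
        [unit(rng.normal(size=spec.embedding_dim)) for _ in range(spec.n_topics)]
    )
    common = unit(rng.normal(size=spec.embedding_dim)) * spec.embedding_common
    vectors: dict[str, np.ndarray] = {}
    by_kind: dict[str, list[list[str]]] = {k: [] for k in kinds}
    for t in range(spec.n_topics):
        for kind, count in kinds.items():
            words = []
            for i in range(count):
                word = f"t{t}{kind}{i}"
                vec = (
                    common
                    + spec.embedding_topic * centers[t]
                    + spec.embedding_noise * unit(rng.normal(size=spec.embedding_dim))
                )
                vectors[word] = unit(vec)
                words.append(word)
            by_kind[kind].append(words)
    embeddings = EmbeddingTable(vectors)

    corpus = []
    for d in range(spec.n_corpus_documents):
        tokens: list[AnnotatedToken] = []
        topic = int(rng.integers(spec.n_topics))
        for _ in range(6):  # six typical noun-adjective pairs per document
            noun = by_kind["n"][topic][int(rng.integers(kinds["n"]))]
            adj = by_kind["adj"][topic][int(rng.integers(kinds["adj"]))]
            adj_idx = len(tokens)
            tokens.append(
                AnnotatedToken(adj, adj, "ADJ", head=adj_idx + 1, deprel="amod")
            )
            tokens.append(AnnotatedToken(noun, noun, "NOUN", head=None, deprel="root"))
            if rng.random() < 0.5:
                topic = int(rng.integers(spec.n_topics))
        corpus.append(
            AnnotatedResponse(
                response_id=f"doc{d:03d}", participant_id="corpus", tokens=tokens
            )
        )
    profile = build_adjective_profile(corpus)
    return TextWorld(
        embeddings=embeddings,
        nouns=by_kind["n"],
        verbs=by_kind["v"],
        adjs=by_kind["adj"],
        advs=by_kind["adv"],
        corpus=corpus,
        profile=profile,
    )


def gen_transcript(
    spec: CohortSpec,
    world: TextWorld,
    group: str,
    participant_id: str,
    response_id: str,
    rng: np.random.Generator,
) -> AnnotatedResponse:
    """Generate one annotated response as a topic-respecting token walk."""
    t = spec.text(group)
    tokens: list[AnnotatedToken] = []
    topic = int(rng.integers(world.n_topics))
    content_emitted = 0
    while content_emitted < t.content_words_per_response:
        if rng.random() < t.function_word_prob:
            surface, pos = _FUNCTION_WORDS[int(rng.integers(len(_FUNCTION_WORDS)))]
            tokens.append(AnnotatedToken(surface, surface, pos, None, "dep"))
            continue
        if rng.random() < t.topic_switch_prob:
            topic = int(rng.integers(world.n_topics))
        kind = rng.choice(["n", "v", "adj", "adv"], p=[0.35, 0.30, 0.20, 0.15])
        if kind == "n":
            pair = rng.random() < t.adj_pair_prob
            if pair:
                adj_topic = topic
                if rng.random() < t.atypical_adj_prob:
                    others = [x for x in range(world.n_topics) if x != topic]
                    adj_topic = others[int(rng.integers(len(others)))]
                adj = world.adjs[adj_topic][int(rng.integers(len(world.adjs[0])))]
                adj_idx = len(tokens)
                tokens.append(
                    AnnotatedToken(adj, adj, "ADJ", head=adj_idx + 1, deprel="amod")
                )
                content_emitted += 1
            noun = world.nouns[topic][int(rng.integers(len(world.nouns[0])))]
            tokens.append(AnnotatedToken(noun, noun, "NOUN", None, "root"))
            content_emitted += 1
        else:
            pool = {"v": world.verbs, "adj": world.adjs, "adv": world.advs}[kind]
            pos = {"v": "VERB", "adj": "ADJ", "adv": "ADV"}[kind]
            word = pool[topic][int(rng.integers(len(pool[0])))]
            tokens.append(AnnotatedToken(word, word, pos, None, "dep"))
            content_emitted += 1
    return AnnotatedResponse(
        response_id=response_id, participant_id=participant_id, tokens=tokens
    )


# ---------------------------------------------------------------------------
# Metadata and full-cohort assembly
# ---------------------------------------------------------------------------


def gen_metadata(
    spec: CohortSpec, rng: np.random.Generator
) -> list[ParticipantRecord]:
    """Draw demographics and PANSS-6 totals for every participant."""
    records = []
    for i in range(spec.n_control):
        records.append(
            ParticipantRecord(
                participant_id=f"c{i + 1:02d}",
                group="control",
                age=_clipped_normal(rng, *spec.control_age, 18.0, 60.0),
                education_years=_clipped_normal(rng, *spec.control_education, 6.0, 20.0),
            )
        )
    for i in range(spec.n_patient):
        panss = int(round(_clipped_normal(rng, spec.panss_mean, spec.panss_sd, 0.0, 36.0)))
        records.append(
            ParticipantRecord(
                participant_id=f"p{i + 1:02d}",
                group="patient",
                age=_clipped_normal(rng, *spec.patient_age, 18.0, 60.0),
                education_years=_clipped_normal(rng, *spec.patient_education, 6.0, 20.0),
                panss_total=panss,
            )
        )
    return records


def _clipped_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    return float(np.clip(rng.normal(mean, sd), lo, hi))


@dataclass
class SyntheticCohort:
    """A complete generated cohort, in memory."""

    spec: CohortSpec
    seed: int
    metadata: list[ParticipantRecord]
    frame_sequences: list[FrameSequence]
    responses: list[AnnotatedResponse]
    world: TextWorld

    @property
    def embeddings(self) -> EmbeddingTable:
        return self.world.embeddings

    @property
    def profile(self) -> AdjectiveProfile:
        return self.world.profile

    def group_of(self, participant_id: str) -> str:
        for r in self.metadata:
            if r.participant_id == participant_id:
                return r.group
        raise KeyError(participant_id)


def generate_cohort(spec: CohortSpec, seed: int) -> SyntheticCohort:
    """Generate a full cohort deterministically from one seed."""
    root = np.random.SeedSequence(seed)
    ss_meta, ss_world, ss_frames, ss_text = root.spawn(4)
    meta_rng = np.random.default_rng(ss_meta)
    world_rng = np.random.default_rng(ss_world)
    metadata = gen_metadata(spec, meta_rng)
    world = gen_text_world(spec, world_rng)

    frame_rng = np.random.default_rng(ss_frames)
    text_rng = np.random.default_rng(ss_text)
    frame_sequences = []
    responses = []
    for record in metadata:
        for j in range(spec.responses_per_participant):
            response_id = f"r{j + 1:02d}"
            frame_sequences.append(
                gen_frames(spec, record.group, record.participant_id, response_id, frame_rng)
            )
            responses.append(
                gen_transcript(
                    spec, world, record.group, record.participant_id, response_id, text_rng
                )
            )
    return SyntheticCohort(
        spec=spec,
        seed=seed,
        metadata=metadata,
        frame_sequences=frame_sequences,
        responses=responses,
        world=world,
    )


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write a cohort to disk in the formats the pipeline readers consume."""
    directory = Path(directory)
    frames_dir = directory / "frames"
    transcripts_dir = directory / "transcripts"
    for seq in cohort.frame_sequences:
        write_frame_table(seq, frames_dir)
    for resp in cohort.responses:
        write_conllu(
            resp, transcripts_dir / f"{resp.participant_id}_{resp.response_id}.conllu"
        )
    emb_path = cohort.embeddings.write_word2vec(directory / "embeddings.vec")
    profile_path = cohort.profile.write(directory / "adjective_profile.tsv")
    meta_path = write_metadata(cohort.metadata, directory / "metadata.csv")
    return {
        "frames": frames_dir,
        "transcripts": transcripts_dir,
        "embeddings": emb_path,
        "profile": profile_path,
        "metadata": meta_path,
    }
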