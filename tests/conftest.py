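"""Shared fixtures: small synthetic cohorts and toy inputs."""

import numpy as np
import pytest

from szspeech.frames import FrameSequence, classify_speech_frames
from szspeech.synthdata import (
    CohortSpec,
    GroupTextSpec,
    generate_cohort,
    CONTROL_TEXT,
    PATIENT_TEXT,
)
from szspeech.textfeat import AnnotatedResponse, AnnotatedToken, EmbeddingTable


def make_sequence(f0, rid="r1", pid="p1", classify=True):
    seq = FrameSequence(response_id=rid, participant_id=pid, f0=np.asarray(f0, float))
    return classify_speech_frames(seq) if classify else seq


@pytest.fixture(scope="session")
def small_spec():
    """A fast cohort: 6+6 participants, 4 short responses each."""
    import dataclasses

    control_a = dataclasses.replace(
        CohortSpec().control_acoustic, target_speech_mean_s=14.0, target_speech_sd_s=2.0
    )
    patient_a = dataclasses.replace(
        CohortSpec().patient_acoustic, target_speech_mean_s=13.0, target_speech_sd_s=2.0
    )
    return CohortSpec(
        n_control=6,
        n_patient=6,
        responses_per_participant=4,
        control_acoustic=control_a,
        patient_acoustic=patient_a,
        control_text=GroupTextSpec(
            content_words_per_response=40,
            topic_switch_prob=CONTROL_TEXT.topic_switch_prob,
            atypical_adj_prob=CONTROL_TEXT.atypical_adj_prob,
        ),
        patient_text=GroupTextSpec(
            content_words_per_response=40,
            topic_switch_prob=PATIENT_TEXT.topic_switch_prob,
            atypical_adj_prob=PATIENT_TEXT.atypical_adj_prob,
        ),
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec, seed=7)


@pytest.fixture(scope="session")
def toy_embeddings():
    """Hand-set 2-D embeddings used by the text-feature oracles."""
    return EmbeddingTable(
        {
            "sun": np.array([1.0, 0.0]),
            "moon": np.array([0.0, 1.0]),
            "star": np.array([1.0, 1.0]),
            "bright": np.array([1.0, 0.0]),
            "dark": np.array([0.0, 1.0]),
            "warm": np.array([3.0, 4.0]),
        }
    )


def token(lemma, pos, head=None, deprel="dep"):
    return AnnotatedToken(surface=lemma, lemma=lemma, pos=pos, head=head, deprel=deprel)


def response(lemmas_pos, rid="r1", pid="p1"):
    toks = [token(l, p) for l, p in lemmas_pos]
    return AnnotatedResponse(response_id=rid, participant_id=pid, tokens=toks)
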