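"""Semantic text features: derailment and incoherence.

Derailment (topical drift) is the mean cosine similarity between each
content word's embedding and the embeddings of its k following content
words, averaged over the response; lower values mean faster topic
mutation.  Incoherence (atypical adjective use) compares each
noun-modifying adjective in a response against the idf-weighted mean
embedding of the adjectives that modify the same noun in a reference
corpus.  Both operate at the lemma level, on annotated transcripts
(token, lemma, UPOS, dependency head/relation) supplied as CoNLL-U.

The package does not run a tagger or parser: annotations are input.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

log = logging.getLogger(__name__)

UNDEFINED = float("nan")

CONTENT_POS = frozenset({"NOUN", "VERB", "ADJ", "ADV"})
DERAILMENT_KS = (1, 2, 3, 4, 5, 6)

#: Canonical order of the seven textual classification features.
TEXT_FEATURES = tuple(f"derailment_k{k}" for k in DERAILMENT_KS) + ("incoherence",)


class EmptyCorpusError(ValueError):
    """Raised when an adjective profile is requested from an empty corpus."""


# ---------------------------------------------------------------------------
# Annotated transcripts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnotatedToken:
    """One token of an annotated transcript.

    ``head`` is the index of the syntactic head *within the response's
    token list*, or None for a root; ``deprel`` is the Universal
    Dependencies relation label (adjectival modifiers carry ``amod``).
    """

    surface: str
    lemma: str
    pos: str
    head: Optional[int] = None
    deprel: str = "dep"


@dataclass
class AnnotatedResponse:
    """An annotated transcript of one interview response, in surface order."""

    response_id: str
    participant_id: str
    tokens: list[AnnotatedToken] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tokens)

    def content_tokens(self) -> list[AnnotatedToken]:
        return [t for t in self.tokens if t.pos in CONTENT_POS]

    def amod_pairs(self) -> list[tuple[str, str]]:
        """(noun lemma, adjective lemma) pairs linked by the amod relation."""
        pairs = []
        for tok in self.tokens:
            if tok.deprel != "amod" or tok.pos != "ADJ" or tok.head is None:
                continue
            head = self.tokens[tok.head]
            if head.pos == "NOUN":
                pairs.append((head.lemma.lower(), tok.lemma.lower()))
        return pairs


# ---------------------------------------------------------------------------
# Embeddings (word2vec text format)
# ---------------------------------------------------------------------------


class EmbeddingTable:
    """A static word-embedding lookup with case-normalized keys."""

    def __init__(self, vectors: dict[str, np.ndarray]):
        if not vectors:
            raise ValueError("embedding table must not be empty")
        dims = {np.asarray(v).shape for v in vectors.values()}
        if len(dims) != 1 or len(next(iter(dims))) != 1:
            raise ValueError("all embedding vectors must share one 1-D shape")
        self._vectors = {
            k.lower(): np.asarray(v, dtype=float) for k, v in vectors.items()
        }
        self.dimension = int(next(iter(dims))[0])

    def __contains__(self, word: str) -> bool:
        return word.lower() in self._vectors

    def __len__(self) -> int:
        return len(self._vectors)

    def get(self, word: str) -> Optional[np.ndarray]:
        return self._vectors.get(word.lower())

    def __getitem__(self, word: str) -> np.ndarray:
        vec = self.get(word)
        if vec is None:
            raise KeyError(word)
        return vec

    @property
    def words(self) -> list[str]:
        return list(self._vectors)

    @classmethod
    def read_word2vec(cls, path: str | Path) -> "EmbeddingTable":
        """Read the word2vec text format (header line ``<count> <dim>``)."""
        path = Path(path)
        vectors: dict[str, np.ndarray] = {}
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().split()
            if len(header) != 2:
                raise ValueError(f"{path}: malformed word2vec header")
            _, dim = int(header[0]), int(header[1])
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                if len(parts) != dim + 1:
                    raise ValueError(f"{path}: bad vector row for {parts[0]!r}")
                vectors[parts[0]] = np.array(parts[1:], dtype=float)
        return cls(vectors)

    def write_word2vec(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self._vectors)} {self.dimension}\n")
            for word, vec in self._vectors.items():
                fh.write(word + " " + " ".join(f"{x:.6g}" for x in vec) + "\n")
        return path


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity; 0 when either vector is zero."""
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


# ---------------------------------------------------------------------------
# Derailment
# ---------------------------------------------------------------------------


def content_filter(
    resp: AnnotatedResponse, emb: Optional[EmbeddingTable] = None
) -> list[tuple[str, Optional[np.ndarray]]]:
    """Content-word lemmas (nouns, verbs, adjectives, adverbs) in order.

    With an embedding table given, lemmas lacking a vector are dropped
    (logged) and each kept lemma is paired with its vector; without one,
    vectors are None.
    """
    out: list[tuple[str, Optional[np.ndarray]]] = []
    dropped = 0
    for tok in resp.content_tokens():
        lemma = tok.lemma.lower()
        if emb is None:
            out.append((lemma, None))
            continue
        vec = emb.get(lemma)
        if vec is None:
            dropped += 1
            continue
        out.append((lemma, vec))
    if dropped:
        log.debug(
            "response %s: dropped %d content tokens with no embedding",
            resp.response_id,
            dropped,
        )
    return out


def derailment(resp: AnnotatedResponse, emb: EmbeddingTable, k: int) -> float:
    """Mean forward cosine similarity over a k-word window of content words.

    For each content word i, the mean cosine similarity between its vector
    and the vectors of the up-to-k following content words; the response
    score is the mean over all words with at least one follower.  NaN when
    fewer than two content words carry vectors.
    """
    if not 1 <= k <= 6:
        raise ValueError(f"k must be in 1..6, got {k}")
    vecs = [v for _, v in content_filter(resp, emb)]
    n = len(vecs)
    if n < 2:
        return UNDEFINED
    word_scores = []
    for i in range(n - 1):  # the final word has no followers
        followers = vecs[i + 1 : i + 1 + k]
        sims = [cosine(vecs[i], w) for w in followers]
        word_scores.append(sum(sims) / len(sims))
    return float(np.mean(word_scores))


# ---------------------------------------------------------------------------
# Incoherence
# ---------------------------------------------------------------------------


@dataclass
class AdjectiveProfile:
    """Reference-corpus digest: per noun, adjective document frequencies.

    ``pairs[noun_lemma][adjective_lemma]`` is the number of corpus
    documents in which the adjective modifies that noun (via amod);
    ``corpus_document_count`` is the total number of corpus documents.
    """

    pairs: dict[str, dict[str, int]]
    corpus_document_count: int

    def __post_init__(self) -> None:
        if self.corpus_document_count < 1:
            raise ValueError("corpus_document_count must be positive")
        for noun, adjs in self.pairs.items():
            for adj, df in adjs.items():
                if not 1 <= df <= self.corpus_document_count:
                    raise ValueError(
                        f"df({noun}, {adj}) = {df} outside "
                        f"[1, {self.corpus_document_count}]"
                    )

    def idf(self, noun: str, adjective: str) -> float:
        """ln(N / df) of an adjective for a given noun."""
        df = self.pairs[noun][adjective]
        return math.log(self.corpus_document_count / df)

    def write(self, path: str | Path) -> Path:
        """Serialize as TSV with a corpus-size header line."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"#corpus_document_count={self.corpus_document_count}\n")
            fh.write("noun_lemma\tadjective_lemma\tdocument_frequency\n")
            for noun in sorted(self.pairs):
                for adj in sorted(self.pairs[noun]):
                    fh.write(f"{noun}\t{adj}\t{self.pairs[noun][adj]}\n")
        return path

    @classmethod
    def read(cls, path: str | Path) -> "AdjectiveProfile":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            first = fh.readline().strip()
            if not first.startswith("#corpus_document_count="):
                raise ValueError(f"{path}: missing corpus_document_count header")
            n_docs = int(first.split("=", 1)[1])
            header = fh.readline().strip().split("\t")
            if header[:3] != ["noun_lemma", "adjective_lemma", "document_frequency"]:
                raise ValueError(f"{path}: unexpected column header")
            pairs: dict[str, dict[str, int]] = {}
            for line in fh:
                if not line.strip():
                    continue
                noun, adj, df = line.rstrip("\n").split("\t")
                pairs.setdefault(noun, {})[adj] = int(df)
        return cls(pairs=pairs, corpus_document_count=n_docs)


def build_adjective_profile(
    corpus: Sequence[AnnotatedResponse],
) -> AdjectiveProfile:
    """Digest a reference corpus into per-noun adjective document frequencies.

    Each document contributes each distinct (noun, adjective) amod pair at
    most once (document frequency, not raw count).
    """
    if len(corpus) == 0:
        raise EmptyCorpusError("cannot build an adjective profile from no documents")
    pairs: dict[str, dict[str, int]] = {}
    for doc in corpus:
        for noun, adj in set(doc.amod_pairs()):
            pairs.setdefault(noun, {})
            pairs[noun][adj] = pairs[noun].get(adj, 0) + 1
    return AdjectiveProfile(pairs=pairs, corpus_document_count=len(corpus))


def incoherence(
    resp: AnnotatedResponse,
    emb: EmbeddingTable,
    profile: AdjectiveProfile,
) -> float:
    """Atypicality of a response's noun-modifying adjectives.

    For each amod (noun, adjective) pair whose noun appears in the
    reference profile and whose adjective has an embedding: the profile's
    adjectives for that noun are aggregated into a single vector — an
    idf-weighted element-wise mean with weights ln(N/df), renormalized to
    sum to 1 — and the pair scores the cosine similarity between the
    response adjective's vector and that aggregate.  The response score is
    the mean pair score; NaN when no pair is scoreable.  Lower scores mean
    more atypical adjective use.

    When every profile adjective for a noun has df = N (idf mass zero),
    weights fall back to uniform so the aggregate remains defined.
    """
    pairs = resp.amod_pairs()
    scores = []
    skipped_nouns = 0
    for noun, adj in pairs:
        if noun not in profile.pairs:
            skipped_nouns += 1
            continue
        adj_vec = emb.get(adj)
        if adj_vec is None:
            continue
        aggregate = _aggregate_profile_vector(noun, profile, emb)
        if aggregate is None:
            continue
        scores.append(cosine(adj_vec, aggregate))
    if skipped_nouns:
        log.debug(
            "response %s: %d amod pairs skipped (noun absent from profile)",
            resp.response_id,
            skipped_nouns,
        )
    if not scores:
        return UNDEFINED
    return float(np.mean(scores))


def _aggregate_profile_vector(
    noun: str, profile: AdjectiveProfile, emb: EmbeddingTable
) -> Optional[np.ndarray]:
    entries = [
        (emb.get(adj), profile.idf(noun, adj))
        for adj in profile.pairs[noun]
        if adj in emb
    ]
    if not entries:
        return None
    vectors = np.stack([v for v, _ in entries])
    weights = np.array([w for _, w in entries], dtype=float)
    total = weights.sum()
    if total <= 0.0:
        weights = np.full(len(entries), 1.0 / len(entries))
    else:
        weights = weights / total
    return vectors.T @ weights


@dataclass
class TextFeatureVector:
    """The seven textual features of one response (NaN where undefined)."""

    derailment_k1: float = UNDEFINED
    derailment_k2: float = UNDEFINED
    derailment_k3: float = UNDEFINED
    derailment_k4: float = UNDEFINED
    derailment_k5: float = UNDEFINED
    derailment_k6: float = UNDEFINED
    incoherence: float = UNDEFINED

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in TEXT_FEATURES}


def extract_all_text(
    resp: AnnotatedResponse,
    emb: EmbeddingTable,
    profile: AdjectiveProfile,
) -> TextFeatureVector:
    """All seven textual features of one annotated response."""
    values = {f"derailment_k{k}": derailment(resp, emb, k) for k in DERAILMENT_KS}
    values["incoherence"] = incoherence(resp, emb, profile)
    return TextFeatureVector(**values)


# ---------------------------------------------------------------------------
# CoNLL-U I/O
# ---------------------------------------------------------------------------


def read_conllu(path: str | Path) -> AnnotatedResponse:
    """Read one response from a CoNLL-U file.

    Sentences are concatenated in order; within-sentence head indices are
    rebased onto the response-wide token list (root becomes None).
    Multiword-token ranges and empty nodes are skipped.  Participant and
    response ids are taken from ``# participant_id = ...`` /
    ``# response_id = ...`` comments when present, else from the file name
    (``<participant>_<response>.conllu``).
    """
    path = Path(path)
    participant_id = response_id = None
    tokens: list[AnnotatedToken] = []
    sentence_rows: list[tuple[int, str, str, str, int, str]] = []

    def flush() -> None:
        nonlocal sentence_rows
        offset = len(tokens)
        ids = {tid: offset + i for i, (tid, *_rest) in enumerate(sentence_rows)}
        for tid, form, lemma, upos, head, deprel in sentence_rows:
            abs_head = None if head == 0 else ids.get(head)
            tokens.append(
                AnnotatedToken(
                    surface=form, lemma=lemma, pos=upos, head=abs_head, deprel=deprel
                )
            )
        sentence_rows = []

    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                flush()
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, value = line[1:].partition("=")
                    key = key.strip()
                    if key == "participant_id":
                        participant_id = value.strip()
                    elif key == "response_id":
                        response_id = value.strip()
                continue
            cols = line.split("\t")
            if len(cols) != 10:
                raise ValueError(f"{path}: malformed CoNLL-U row: {line!r}")
            tid = cols[0]
            if "-" in tid or "." in tid:
                continue  # multiword-token range / empty node
            sentence_rows.append(
                (int(tid), cols[1], cols[2], cols[3], int(cols[6]), cols[7])
            )
    flush()
    if participant_id is None or response_id is None:
        stem = path.name.removesuffix(".conllu")
        if "_" in stem:
            p, _, r = stem.partition("_")
            participant_id = participant_id or p
            response_id = response_id or r
        else:
            participant_id = participant_id or "unknown"
            response_id = response_id or stem
    return AnnotatedResponse(
        response_id=response_id, participant_id=participant_id, tokens=tokens
    )


def write_conllu(resp: AnnotatedResponse, path: str | Path) -> Path:
    """Write a response as a single-sentence CoNLL-U file with id comments."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# participant_id = {resp.participant_id}\n")
        fh.write(f"# response_id = {resp.response_id}\n")
        for i, tok in enumerate(resp.tokens):
            head = 0 if tok.head is None else tok.head + 1
            fh.write(
                "\t".join(
                    [
                        str(i + 1),
                        tok.surface,
                        tok.lemma,
                        tok.pos,
                        "_",
                        "_",
                        str(head),
                        tok.deprel,
                        "_",
                        "_",
                    ]
                )
                + "\n"
            )
        fh.write("\n")
    return path
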