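"""End-to-end orchestration: configuration, extraction, assembly, outputs.

``run_pipeline`` drives the stages in method order — frame
classification/segmentation, prosodic extraction, textual extraction,
cohort assembly and filtering, group statistics, cross-validated
classification, and the clinical analyses — reading the on-disk formats
the other modules define and writing delimited tables plus a JSON run
manifest stamped with a configuration hash.  Stages whose inputs are
missing are skipped with an explicit notice, never silently.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import clinstats as _clinstats
from . import cohort as _cohort
from .cohort import COMBINED_FEATURES, FeatureTable
from .frames import (
    FrameSequence,
    classify_speech_frames,
    read_frame_table,
    segment,
    speech_seconds,
)
from .prosody import ACOUSTIC_FEATURES, JitterParams, extract_all
from .textfeat import (
    AdjectiveProfile,
    AnnotatedResponse,
    EmbeddingTable,
    TEXT_FEATURES,
    extract_all_text,
    derailment,
    incoherence,
    read_conllu,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline knobs and input locations; round-trips through YAML."""

    frames_dir: Optional[str] = None
    transcripts_dir: Optional[str] = None
    embeddings_path: Optional[str] = None
    profile_path: Optional[str] = None
    metadata_path: Optional[str] = None
    output_dir: str = "szspeech_out"
    f0_low_hz: float = 75.0
    f0_high_hz: float = 250.0
    min_utterance_frames: int = 50
    jitter_k: int = 5
    min_speech_seconds: float = 10.0
    min_participant_words: int = 500
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    n_folds: int = 5
    feature_sets: tuple[str, ...] = ("acoustic", "textual", "combined")
    classifiers: tuple[str, ...] = ("xgb", "rf", "svm")
    group_folds: bool = False
    cluster_ks: tuple[int, ...] = (2, 3, 8)
    cluster_runs: int = 50

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_plain_dict(), fh, sort_keys=True)
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("seeds", "feature_sets", "classifiers", "cluster_ks"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def as_plain_dict(self) -> dict:
        d = asdict(self)
        for key, value in d.items():
            if isinstance(value, tuple):
                d[key] = list(value)
        return d

    def config_hash(self) -> str:
        canonical = json.dumps(self.as_plain_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Feature extraction over collections
# ---------------------------------------------------------------------------


def extract_prosodic_features(
    sequences: Sequence[FrameSequence], config: RunConfig | None = None
) -> tuple[pd.DataFrame, dict[tuple[str, str], float]]:
    """Prosodic feature rows plus speech seconds per (participant, response)."""
    config = config or RunConfig()
    params = JitterParams(K=config.jitter_k)
    rows = []
    seconds: dict[tuple[str, str], float] = {}
    for seq in sequences:
        classified = classify_speech_frames(seq, config.f0_low_hz, config.f0_high_hz)
        seg = segment(classified, config.min_utterance_frames)
        vec = extract_all(classified, params, config.min_utterance_frames)
        key = (seq.participant_id, seq.response_id)
        seconds[key] = speech_seconds(seg)
        rows.append(
            {
                "participant_id": seq.participant_id,
                "response_id": seq.response_id,
                **vec.as_dict(include_variant=True),
            }
        )
    return pd.DataFrame(rows), seconds


def extract_text_features(
    responses: Sequence[AnnotatedResponse],
    embeddings: EmbeddingTable,
    profile: AdjectiveProfile,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Textual feature rows plus total word counts per participant.

    Word counts include every surface token (content and function words),
    matching the interview-length exclusion criterion.
    """
    rows = []
    word_counts: dict[str, int] = {}
    for resp in responses:
        word_counts[resp.participant_id] = word_counts.get(resp.participant_id, 0) + len(
            resp
        )
        vec = _fast_text_features(resp, embeddings, profile)
        rows.append(
            {
                "participant_id": resp.participant_id,
                "response_id": resp.response_id,
                **vec,
            }
        )
    return pd.DataFrame(rows), word_counts


def _fast_text_features(resp, embeddings, profile) -> dict[str, float]:
    """All derailment windows from one cosine matrix, plus incoherence."""
    from .textfeat import DERAILMENT_KS, content_filter

    vecs = [v for _, v in content_filter(resp, embeddings)]
    out: dict[str, float] = {}
    n = len(vecs)
    if n < 2:
        for k in DERAILMENT_KS:
            out[f"derailment_k{k}"] = float("nan")
    else:
        V = np.stack(vecs)
        norms = np.linalg.norm(V, axis=1)
        norms[norms == 0] = 1.0
        sims = (V / norms[:, None]) @ (V / norms[:, None]).T
        for k in DERAILMENT_KS:
            word_scores = [
                float(np.mean(sims[i, i + 1 : i + 1 + k])) for i in range(n - 1)
            ]
            out[f"derailment_k{k}"] = float(np.mean(word_scores))
    out["incoherence"] = incoherence(resp, embeddings, profile)
    return out


def assemble_feature_table(
    prosodic: pd.DataFrame,
    textual: Optional[pd.DataFrame],
    group_by_participant: Mapping[str, str],
) -> FeatureTable:
    """Join modality frames on (participant, response) and attach labels."""
    df = prosodic.copy()
    if textual is not None:
        df = df.merge(textual, on=["participant_id", "response_id"], how="outer")
    df["group"] = df["participant_id"].map(dict(group_by_participant))
    if df["group"].isna().any():
        unknown = sorted(df.loc[df["group"].isna(), "participant_id"].unique())
        raise ValueError(f"participants with no group label: {unknown}")
    return FeatureTable(df)


# ---------------------------------------------------------------------------
# Supplementary-style feature-table reader
# ---------------------------------------------------------------------------

_HEADER_ALIASES = {
    "participant": "participant_id",
    "subject": "participant_id",
    "subject_id": "participant_id",
    "id": "participant_id",
    "question": "response_id",
    "question_id": "response_id",
    "response": "response_id",
    "label": "group",
    "diagnosis": "group",
    "jitter": "J",
    "pitch_range": "PR",
    "pitch range": "PR",
    "mean pitch": "MP",
    "pitch sd": "PS",
    "sp": "PS",
    **{f"derailment {k}": f"derailment_k{k}" for k in range(1, 7)},
    **{f"der. {k}": f"derailment_k{k}" for k in range(1, 7)},
    **{f"derailment_{k}": f"derailment_k{k}" for k in range(1, 7)},
    "inco.": "incoherence",
}
_GROUP_ALIASES = {
    "control": "control",
    "controls": "control",
    "healthy": "control",
    "hc": "control",
    "patient": "patient",
    "patients": "patient",
    "schizophrenia": "patient",
    "sz": "patient",
}


def read_supplementary_features(path: str | Path) -> FeatureTable:
    """Read a per-response feature table in a tolerant column layout.

    Canonical feature names (the 16 features), common aliases
    ("Derailment 1", "Jitter", ...) and id/group synonyms are mapped;
    unknown columns are dropped with a warning; group labels are
    normalized to control/patient.  Missing participant or group columns
    are an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    canonical = {c: c for c in ("participant_id", "response_id", "group") + COMBINED_FEATURES}
    rename: dict[str, str] = {}
    drop: list[str] = []
    for col in df.columns:
        key = col.strip()
        target = canonical.get(key) or _HEADER_ALIASES.get(key.lower())
        if target is None and key.upper() in canonical:
            target = key.upper()
        if target is None and key.lower() in canonical:
            target = key.lower()
        if target is None:
            drop.append(col)
        else:
            rename[col] = target
    if drop:
        warnings.warn(f"{path.name}: ignoring unknown columns {drop}", UserWarning)
        df = df.drop(columns=drop)
    df = df.rename(columns=rename)
    for required in ("participant_id", "group"):
        if required not in df.columns:
            raise ValueError(f"{path}: no column maps to {required!r}")
    if "response_id" not in df.columns:
        df["response_id"] = [str(i) for i in range(len(df))]
    df["participant_id"] = df["participant_id"].astype(str)
    df["response_id"] = df["response_id"].astype(str)
    df["group"] = (
        df["group"].astype(str).str.strip().str.lower().map(_GROUP_ALIASES)
    )
    if df["group"].isna().any():
        raise ValueError(f"{path}: unrecognized group labels")
    return FeatureTable(df)


# ---------------------------------------------------------------------------
# The pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages the configured inputs allow; return the manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.as_plain_dict(),
        "config_hash": config.config_hash(),
        "stages": {},
        "outputs": {},
        "notices": [],
    }

    prosodic = seconds = None
    if config.frames_dir and Path(config.frames_dir).is_dir():
        sequences = [
            read_frame_table(p)
            for p in sorted(Path(config.frames_dir).glob("*.frames.csv"))
        ]
        prosodic, seconds = extract_prosodic_features(sequences, config)
        manifest["stages"]["prosody"] = {"n_responses": len(prosodic)}
    else:
        manifest["notices"].append("frames input missing: prosodic stages skipped")

    textual = word_counts = None
    text_inputs = (
        config.transcripts_dir
        and Path(config.transcripts_dir).is_dir()
        and config.embeddings_path
        and Path(config.embeddings_path).is_file()
        and config.profile_path
        and Path(config.profile_path).is_file()
    )
    if text_inputs:
        responses = [
            read_conllu(p)
            for p in sorted(Path(config.transcripts_dir).glob("*.conllu"))
        ]
        embeddings = EmbeddingTable.read_word2vec(config.embeddings_path)
        profile = AdjectiveProfile.read(config.profile_path)
        textual, word_counts = extract_text_features(responses, embeddings, profile)
        manifest["stages"]["textfeat"] = {"n_responses": len(textual)}
    else:
        manifest["notices"].append("text inputs missing: textual stages skipped")

    records = None
    if config.metadata_path and Path(config.metadata_path).is_file():
        records = _clinstats.read_metadata(config.metadata_path)
        group_map = {r.participant_id: r.group for r in records}
    else:
        manifest["notices"].append("metadata missing: downstream stages limited")
        group_map = {}

    if prosodic is None and textual is None:
        manifest["notices"].append("no modality inputs: nothing to assemble")
        _write_manifest(manifest, out)
        return manifest
    if not group_map:
        _write_manifest(manifest, out)
        return manifest

    base = prosodic if prosodic is not None else textual
    other = textual if prosodic is not None else None
    table = assemble_feature_table(base, other, group_map)

    # inclusion filters
    if word_counts is not None:
        kept = _cohort.filter_participants(word_counts, config.min_participant_words)
        table = _cohort.apply_participant_filter(table, kept)
    if seconds is not None:
        table = _cohort.filter_responses(table, seconds, config.min_speech_seconds)
    manifest["stages"]["cohort"] = {"retained": table.group_counts()}
    table_path = table.write(out / "feature_table.csv")
    manifest["outputs"]["feature_table"] = str(table_path)

    if min(table.group_counts().values()) < 2:
        manifest["notices"].append(
            "fewer than 2 retained responses in a group: downstream "
            "statistics and classification skipped"
        )
        _write_manifest(manifest, out)
        return manifest

    feature_sets = [
        fs
        for fs in config.feature_sets
        if (fs != "textual" or textual is not None)
        and (fs != "acoustic" or prosodic is not None)
        and (fs != "combined" or (textual is not None and prosodic is not None))
    ]

    # group statistics and correlations
    stats_set = feature_sets[-1] if feature_sets else None
    if stats_set:
        comparison = _cohort.group_ttests(table, stats_set, level="response")
        comparison.table.to_csv(out / "group_ttests_response.csv")
        _cohort.group_ttests(table, stats_set, level="participant").table.to_csv(
            out / "group_ttests_participant.csv"
        )
        corr = _cohort.correlation_matrix(table, stats_set)
        corr.to_csv(out / "feature_correlations.csv")
        _cohort.normality_report(table, stats_set).to_csv(
            out / "normality_report.csv", index=False
        )
        manifest["stages"]["stats"] = {"feature_set": stats_set}

    # classification
    cv_rows = []
    for fs in feature_sets:
        for clf in config.classifiers:
            protocol = _classify.EvaluationProtocol(
                seeds=tuple(config.seeds),
                n_folds=config.n_folds,
                classifier=clf,
                feature_set=fs,
                group_folds=config.group_folds,
            )
            result = _classify.run_cv(table, protocol)
            row = {"feature_set": fs, "classifier": clf}
            for m in _classify.METRIC_NAMES:
                row[f"{m}_mean"] = result.mean(m)
                row[f"{m}_sd"] = result.sd(m)
            cv_rows.append(row)
    if cv_rows:
        cv_df = pd.DataFrame(cv_rows)
        cv_df.to_csv(out / "classification_results.csv", index=False)
        manifest["stages"]["classify"] = {"n_runs": len(cv_rows)}
        manifest["outputs"]["classification"] = str(out / "classification_results.csv")

    # clinical statistics (participant level)
    if records is not None and prosodic is not None and "combined" in feature_sets:
        frame = _clinstats.participant_frame(records, table)
        manifest["stages"]["clinstats"] = {}
        reg_rows = []
        for feat in ACOUSTIC_FEATURES:
            try:
                res = _clinstats.feature_regression(frame, feat)
            except ValueError as exc:
                manifest["notices"].append(f"regression {feat}: {exc}")
                continue
            for predictor in res.standardized.index:
                reg_rows.append(
                    {
                        "feature": feat,
                        "predictor": predictor,
                        "beta": res.standardized.loc[predictor, "beta"],
                        "t": res.standardized.loc[predictor, "t"],
                        "r_squared": res.r_squared,
                        "f": res.f_statistic,
                    }
                )
        if reg_rows:
            pd.DataFrame(reg_rows).to_csv(out / "regressions.csv", index=False)
        mi_rows = []
        n_patients = int((frame["group"] == "patient").sum())
        for fs in ("acoustic", "textual"):
            if fs not in feature_sets:
                continue
            for k in config.cluster_ks:
                if k >= n_patients:
                    manifest["notices"].append(f"cluster-mi skipped: k={k} >= n")
                    continue
                mi = _clinstats.cluster_mi(
                    frame, fs, k, runs=config.cluster_runs, seed=config.seeds[0]
                )
                mi_rows.append(
                    {
                        "feature_set": fs,
                        "k": k,
                        "mi_mean": mi.mi_mean,
                        "mi_sd": mi.mi_sd,
                    }
                )
        if mi_rows:
            pd.DataFrame(mi_rows).to_csv(out / "cluster_mi.csv", index=False)

    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    log.info(
        "pipeline complete: stages %s", ", ".join(manifest["stages"]) or "(none)"
    )
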