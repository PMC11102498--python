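"""Cohort assembly: inclusion filters, the feature table, group statistics.

The classification substrate is a response-level table — one row per
retained response with a participant id, a group label (control or
patient), the nine acoustic features and the seven textual features.
Inclusion filters: responses with less than 10 s of speech are dropped
(too little signal for stable prosodic estimates), and participants who
produced fewer than 500 words across their whole interview are excluded
with all their responses.

Group comparisons use Welch's unequal-variance two-sample t-test, at the
response level or after aggregating to one mean vector per participant.
A Shapiro-Wilk normality report is provided as an advisory diagnostic;
it gates nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .prosody import ACOUSTIC_FEATURES
from .textfeat import TEXT_FEATURES

log = logging.getLogger(__name__)

GROUPS = ("control", "patient")
COMBINED_FEATURES = tuple(ACOUSTIC_FEATURES) + tuple(TEXT_FEATURES)
ID_COLUMNS = ("participant_id", "response_id", "group")

MIN_SPEECH_SECONDS = 10.0
MIN_PARTICIPANT_WORDS = 500


def feature_columns(feature_set: str) -> tuple[str, ...]:
    """Column names for a feature-set selector (acoustic|textual|combined)."""
    if feature_set == "acoustic":
        return tuple(ACOUSTIC_FEATURES)
    if feature_set == "textual":
        return tuple(TEXT_FEATURES)
    if feature_set == "combined":
        return COMBINED_FEATURES
    raise ValueError(f"unknown feature set {feature_set!r}")


@dataclass
class FeatureTable:
    """Response-by-feature matrix with identifiers and group labels.

    Wraps a DataFrame whose columns are ``participant_id``,
    ``response_id``, ``group`` and the 16 feature columns (missing
    feature columns are permitted; views select 9, 7 or 16 of them).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ID_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"feature table missing columns {missing}")
        bad = set(self.df["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def features(self, feature_set: str = "combined") -> pd.DataFrame:
        cols = [c for c in feature_columns(feature_set) if c in self.df.columns]
        want = feature_columns(feature_set)
        if tuple(cols) != want:
            raise ValueError(
                f"feature set {feature_set!r} needs columns {want}, "
                f"table has {tuple(self.df.columns)}"
            )
        return self.df[list(cols)]

    @property
    def labels(self) -> pd.Series:
        return self.df["group"]

    def group_counts(self) -> dict[str, int]:
        counts = self.df["group"].value_counts()
        return {g: int(counts.get(g, 0)) for g in GROUPS}

    def participant_level(self, feature_set: str = "combined") -> pd.DataFrame:
        """Aggregate to one row per participant: the unweighted mean of
        that participant's responses per feature (NaN-aware)."""
        cols = list(feature_columns(feature_set))
        grouped = self.df.groupby(["participant_id", "group"], sort=True)[cols]
        return grouped.mean().reset_index()

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        cols = [c for c in ID_COLUMNS + COMBINED_FEATURES if c in self.df.columns]
        self.df[cols].to_csv(path, index=False, float_format="%.8g")
        return path

    @classmethod
    def read(cls, path: str | Path) -> "FeatureTable":
        return cls(pd.read_csv(path, dtype={"participant_id": str, "response_id": str}))


def filter_responses(
    table: FeatureTable,
    speech_seconds_by_response: Mapping[tuple[str, str], float],
    min_seconds: float = MIN_SPEECH_SECONDS,
) -> FeatureTable:
    """Drop responses carrying less than ``min_seconds`` of speech.

    The boundary is inclusive: a response with exactly 10.0 s is kept.
    ``speech_seconds_by_response`` maps (participant_id, response_id) to
    seconds of speech; rows absent from the mapping are dropped.
    Retained counts per group are logged.
    """
    keys = list(zip(table.df["participant_id"], table.df["response_id"]))
    seconds = np.array(
        [speech_seconds_by_response.get(key, float("-inf")) for key in keys]
    )
    kept = FeatureTable(table.df[seconds >= min_seconds])
    log.info(
        "response filter (>= %.1f s speech): retained %s of %d responses",
        min_seconds,
        kept.group_counts(),
        len(table),
    )
    return kept


def filter_participants(
    word_counts: Mapping[str, int], min_words: int = MIN_PARTICIPANT_WORDS
) -> set[str]:
    """Participants with at least ``min_words`` surface tokens in total."""
    kept = {p for p, n in word_counts.items() if n >= min_words}
    excluded = set(word_counts) - kept
    if excluded:
        log.info(
            "participant filter (< %d words): excluded %s", min_words, sorted(excluded)
        )
    return kept


def apply_participant_filter(table: FeatureTable, kept: set[str]) -> FeatureTable:
    """Drop every response of participants outside ``kept``."""
    return FeatureTable(table.df[table.df["participant_id"].isin(kept)])


@dataclass
class GroupComparison:
    """Welch t-test results per feature, with group summary statistics."""

    table: pd.DataFrame  # index: feature; columns below
    level: str

    COLUMNS = (
        "control_mean",
        "control_sd",
        "patient_mean",
        "patient_sd",
        "n_control",
        "n_patient",
        "t",
        "p",
    )


def group_ttests(
    table: FeatureTable,
    feature_set: str = "combined",
    level: str = "response",
) -> GroupComparison:
    """Welch two-sample t-tests (control minus patient) per feature.

    ``level='response'`` tests response-level values; ``level='participant'``
    first averages each participant's responses (unweighted).  NaN cells
    are dropped pairwise per feature.  Features with fewer than two
    defined values in either group are marked untestable (all-NaN row).
    """
    if level not in ("response", "participant"):
        raise ValueError("level must be 'response' or 'participant'")
    if level == "participant":
        df = table.participant_level(feature_set)
    else:
        df = table.df
    rows = {}
    for feat in feature_columns(feature_set):
        a = df.loc[df["group"] == "control", feat].dropna().to_numpy()
        b = df.loc[df["group"] == "patient", feat].dropna().to_numpy()
        if a.size < 2 or b.size < 2:
            rows[feat] = dict.fromkeys(GroupComparison.COLUMNS, float("nan"))
            log.warning("feature %s untestable at level=%s", feat, level)
            continue
        t, p = stats.ttest_ind(a, b, equal_var=False)
        rows[feat] = {
            "control_mean": a.mean(),
            "control_sd": a.std(ddof=1),
            "patient_mean": b.mean(),
            "patient_sd": b.std(ddof=1),
            "n_control": a.size,
            "n_patient": b.size,
            "t": float(t),
            "p": float(p),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")[list(GroupComparison.COLUMNS)]
    return GroupComparison(table=out, level=level)


def normality_report(
    table: FeatureTable, feature_set: str = "combined"
) -> pd.DataFrame:
    """Advisory Shapiro-Wilk W and p per feature and group (gates nothing)."""
    rows = []
    for feat in feature_columns(feature_set):
        for group in GROUPS:
            x = table.df.loc[table.df["group"] == group, feat].dropna().to_numpy()
            if x.size < 3 or np.ptp(x) == 0:
                w = p = float("nan")
            else:
                w, p = stats.shapiro(x)
            rows.append({"feature": feat, "group": group, "W": w, "p": p})
    return pd.DataFrame(rows)


def correlation_matrix(
    table: FeatureTable, feature_set: str = "combined", min_periods: int = 3
) -> pd.DataFrame:
    """Pairwise Pearson correlations between features (pairwise deletion).

    Symmetric with unit diagonal; entries with fewer than ``min_periods``
    complete pairs, or involving a constant feature, are NaN.
    """
    feats = table.features(feature_set)
    corr = feats.corr(method="pearson", min_periods=min_periods)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def plot_correlation_heatmap(corr: pd.DataFrame, path: str | Path) -> Path:
    """Render the feature-correlation matrix as a heat map image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(0.6 * len(corr) + 2, 0.6 * len(corr) + 1.5))
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr)), corr.columns, rotation=90)
    ax.set_yticks(range(len(corr)), corr.index)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
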