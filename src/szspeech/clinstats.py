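"""Participant-level clinical statistics.

Two analyses link the speech features to clinical variables:

* Multiple regressions of each (participant-aggregated, standardized)
  prosodic feature on standardized age, standardized years of education,
  and a group indicator — quantifying whether group membership explains
  a feature beyond the demographic covariates.
* k-means clustering of the patients in feature space, followed by the
  plug-in mutual information (natural log) between the cluster
  assignment and the PANSS-6 total score treated as a discrete variable.
  Centroids are randomly initialized with no restarts within a run;
  repeating the analysis (50 runs by default) yields the reported
  mean (SD).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.cluster import KMeans
from sklearn.metrics import mutual_info_score

from .cohort import FeatureTable, feature_columns

log = logging.getLogger(__name__)

PANSS_MAX = 36


class CollinearPredictorsError(ValueError):
    """Raised when the regression design matrix is rank-deficient."""


@dataclass
class ParticipantRecord:
    """One participant: demographics, clinical score, aggregated features."""

    participant_id: str
    group: str
    age: float
    education_years: float
    panss_total: Optional[int] = None
    features: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.group not in ("control", "patient"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.age <= 0:
            raise ValueError("age must be positive")
        if (self.panss_total is not None) != (self.group == "patient"):
            raise ValueError("panss_total must be present iff group == 'patient'")
        if self.panss_total is not None and not 0 <= self.panss_total <= PANSS_MAX:
            raise ValueError(f"panss_total outside [0, {PANSS_MAX}]")


def read_metadata(path: str | Path) -> list[ParticipantRecord]:
    """Read participant metadata from delimited text.

    Columns: participant_id, group, age, education_years, panss_total
    (empty for controls).
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    records = []
    for row in df.itertuples(index=False):
        panss = getattr(row, "panss_total", None)
        panss = None if panss is None or pd.isna(panss) else int(panss)
        records.append(
            ParticipantRecord(
                participant_id=row.participant_id,
                group=row.group,
                age=float(row.age),
                education_years=float(row.education_years),
                panss_total=panss,
            )
        )
    return records


def write_metadata(records: Sequence[ParticipantRecord], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "group": r.group,
                "age": r.age,
                "education_years": r.education_years,
                "panss_total": r.panss_total,
            }
            for r in records
        ]
    ).to_csv(path, index=False)
    return path


def participant_frame(
    records: Sequence[ParticipantRecord], table: FeatureTable
) -> pd.DataFrame:
    """Join metadata with participant-aggregated features (mean per feature)."""
    meta = pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "group": r.group,
                "age": r.age,
                "education_years": r.education_years,
                "panss_total": r.panss_total,
            }
            for r in records
        ]
    )
    agg = table.participant_level("combined").drop(columns=["group"])
    return meta.merge(agg, on="participant_id", how="inner")


@dataclass
class RegressionResult:
    """Standardized multiple-regression summary for one feature.

    ``standardized`` / ``raw``: per-predictor (age, education, group)
    coefficient and t statistic; the t's are identical across the two
    scalings.  R², F and degrees of freedom describe the overall model.
    """

    feature: str
    standardized: pd.DataFrame  # index: predictor; columns beta, t, p
    raw: pd.DataFrame
    r_squared: float
    f_statistic: float
    df_model: int
    df_resid: int
    n: int


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise CollinearPredictorsError("a predictor or outcome is constant")
    return (x - x.mean()) / sd


def feature_regression(frame: pd.DataFrame, feature: str) -> RegressionResult:
    """OLS of a standardized feature on age, education and group.

    ``frame`` is a participant-level table (see :func:`participant_frame`).
    All variables, including the patient indicator, are z-scored for the
    standardized coefficients; raw-scale coefficients are reported
    alongside.  Requires >= 10 complete records and a full-rank design.
    """
    cols = ["age", "education_years", "group", feature]
    data = frame[cols].dropna()
    n = len(data)
    if n < 10:
        raise ValueError(f"need >= 10 complete records, have {n}")
    y_raw = data[feature].to_numpy(dtype=float)
    predictors_raw = np.column_stack(
        [
            data["age"].to_numpy(dtype=float),
            data["education_years"].to_numpy(dtype=float),
            (data["group"] == "patient").to_numpy(dtype=float),
        ]
    )
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), predictors_raw])) < 4:
        raise CollinearPredictorsError("design matrix is rank-deficient")
    names = ["age", "education", "group"]

    def fit(y, X):
        model = sm.OLS(y, sm.add_constant(X)).fit()
        return pd.DataFrame(
            {
                "beta": model.params[1:],
                "t": model.tvalues[1:],
                "p": model.pvalues[1:],
            },
            index=names,
        ), model

    try:
        z_predictors = np.column_stack([_zscore(c) for c in predictors_raw.T])
        y_z = _zscore(y_raw)
    except CollinearPredictorsError:
        raise
    std_table, std_model = fit(y_z, z_predictors)
    raw_table, _ = fit(y_raw, predictors_raw)
    return RegressionResult(
        feature=feature,
        standardized=std_table,
        raw=raw_table,
        r_squared=float(std_model.rsquared),
        f_statistic=float(std_model.fvalue),
        df_model=int(std_model.df_model),
        df_resid=int(std_model.df_resid),
        n=n,
    )


@dataclass
class ClusterMIResult:
    """Mutual information (nats) between cluster labels and PANSS totals."""

    feature_set: str
    k: int
    runs: int
    mi_mean: float
    mi_sd: float
    mi_values: np.ndarray


def plugin_mutual_information(labels_a, labels_b) -> float:
    """Plug-in (maximum-likelihood) MI of two discrete variables, in nats."""
    return float(mutual_info_score(labels_a, labels_b))


def cluster_mi(
    frame: pd.DataFrame,
    feature_set: str = "acoustic",
    k: int = 2,
    runs: int = 50,
    seed: int = 0,
) -> ClusterMIResult:
    """k-means over standardized patient features vs PANSS-6 totals.

    Patients only.  Per run, k-means starts from fresh random centroids
    (drawn from the data, one initialization per run) and runs to
    convergence; the MI between the resulting cluster assignment and the
    discrete PANSS-total variable is recorded.  Reports mean (SD) over
    ``runs`` runs.
    """
    patients = frame[frame["group"] == "patient"].dropna(subset=["panss_total"])
    cols = [c for c in feature_columns(feature_set)]
    X = patients[cols].to_numpy(dtype=float)
    # impute rare undefined cells with the column mean before standardizing
    col_means = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), col_means, X)
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k = {k} must be smaller than the number of patients ({n})")
    if k < 1:
        raise ValueError("k must be >= 1")
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Xz = (X - X.mean(axis=0)) / sd
    panss = patients["panss_total"].to_numpy(dtype=int)
    rng = np.random.default_rng(seed)
    mi_values = np.empty(runs)
    for r in range(runs):
        run_seed = int(rng.integers(0, 2**31 - 1))
        km = KMeans(n_clusters=k, init="random", n_init=1, random_state=run_seed)
        labels = km.fit_predict(Xz)
        mi_values[r] = plugin_mutual_information(labels, panss)
    return ClusterMIResult(
        feature_set=feature_set,
        k=k,
        runs=runs,
        mi_mean=float(mi_values.mean()),
        mi_sd=float(mi_values.std(ddof=1)) if runs > 1 else 0.0,
        mi_values=mi_values,
    )
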