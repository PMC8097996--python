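"""Survival dataset container shared by the tree, forest and evaluation layers.

A dataset is a fixed-length numeric feature matrix (after ``-1`` padding of
missing values), a follow-up time in days, and a binary event indicator per
patient. Times are right-censored: ``event == 0`` means follow-up ended
(study end or dropout) before the outcome occurred.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SurvivalData", "make_survival_data"]


@dataclass
class SurvivalData:
    """Right-censored survival records with a shared feature space.

    Parameters
    ----------
    time : array of shape (n,)
        Follow-up duration in days, ``>= 0``.
    event : array of shape (n,)
        1 if the outcome was observed at ``time``, 0 if censored.
    X : array of shape (n, p)
        Numeric covariates; missing values are expected to be padded
        (conventionally to ``-1``) before model fitting.
    feature_names : list of str
        Column names for ``X``.
    patient_ids : array-like, optional
        Identifier per row; defaults to ``0..n-1``.
    """

    time: np.ndarray
    event: np.ndarray
    X: np.ndarray
    feature_names: list[str]
    patient_ids: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        n = len(self.time)
        if len(self.event) != n or self.X.shape[0] != n:
            raise ValueError("time, event and X must have matching lengths")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match X columns")
        if np.any(self.time < 0):
            raise ValueError("time must be non-negative")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event must be 0/1")
        self.event = self.event.astype(int)
        if not np.isfinite(self.X).all():
            raise ValueError("X must be finite (pad missing values first)")
        if self.patient_ids is None:
            self.patient_ids = np.arange(n)
        else:
            self.patient_ids = np.asarray(self.patient_ids)
            if len(self.patient_ids) != n:
                raise ValueError("patient_ids length must match time")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset(self, idx) -> "SurvivalData":
        """Rows selected by integer or boolean index (copy)."""
        idx = np.asarray(idx)
        return SurvivalData(
            time=self.time[idx],
            event=self.event[idx],
            X=self.X[idx],
            feature_names=list(self.feature_names),
            patient_ids=self.patient_ids[idx],
        )


def make_survival_data(features: pd.DataFrame, outcomes: pd.DataFrame) -> SurvivalData:
    """Align a padded feature table with an outcomes table on ``patient_id``.

    ``features`` is indexed by patient id (as written by the feature
    engineering stage); ``outcomes`` has columns ``patient_id``,
    ``time_days`` and ``event``.
    """
    out = outcomes.set_index("patient_id") if "patient_id" in outcomes.columns else outcomes
    common = features.index.intersection(out.index)
    if len(common) == 0:
        raise ValueError("no shared patient ids between features and outcomes")
    feats = features.loc[common]
    out = out.loc[common]
    return SurvivalData(
        time=out["time_days"].to_numpy(dtype=float),
        event=out["event"].to_numpy(),
        X=feats.to_numpy(dtype=float),
        feature_names=list(feats.columns),
        patient_ids=common.to_numpy(),
    )
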