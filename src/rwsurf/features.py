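"""Per-patient covariates from longitudinal labs and a baseline table.

Visit-to-visit variability of serial HbA1c and lipid measurements is
summarized per patient as the temporal standard deviation (sample SD,
n-1 denominator) and coefficient of variation, CV = 100 * SD / mean. A
patient contributes variability statistics for an analyte only with three
or more in-window measurements; with fewer, mean/SD/CV are recorded as
missing while the baseline (earliest in-window) value is kept.

Clinical flags follow standard definitions: a hypoglycemia episode is a
blood glucose strictly below 3.9 mmol/L; anemia is hemoglobin < 13 g/dL
(male) or < 12 g/dL (female); iron deficiency is ferritin < 67.4 pmol/L;
NLR is the baseline neutrophil count divided by the lymphocyte count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ANALYTES",
    "VARIABILITY_ANALYTES",
    "LabSeries",
    "VariabilitySummary",
    "FeatureMatrix",
    "summarize_variability",
    "count_hypoglycemia",
    "compute_nlr",
    "flag_anemia",
    "flag_iron_deficiency",
    "build_feature_matrix",
    "pad_missing",
]

#: Closed analyte vocabulary with their units.
ANALYTES = {
    "hba1c": "%",
    "total_cholesterol": "mmol/L",
    "hdl_c": "mmol/L",
    "ldl_c": "mmol/L",
    "triglyceride": "mmol/L",
    "glucose": "mmol/L",
    "hemoglobin": "g/dL",
    "ferritin": "pmol/L",
    "neutrophil": "x10^9/L",
    "lymphocyte": "x10^9/L",
}

#: Analytes whose serial variability enters the model.
VARIABILITY_ANALYTES = ("hba1c", "total_cholesterol", "hdl_c", "ldl_c", "triglyceride")

HYPOGLYCEMIA_THRESHOLD = 3.9  # mmol/L, strict
ANEMIA_THRESHOLDS = {"male": 13.0, "female": 12.0}  # g/dL, strict
IRON_DEFICIENCY_THRESHOLD = 67.4  # pmol/L, strict

MIN_MEASUREMENTS = 3


@dataclass
class LabSeries:
    """One patient's time-stamped measurements of one analyte."""

    patient_id: object
    analyte: str
    dates: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.analyte not in ANALYTES:
            raise ValueError(f"unknown analyte {self.analyte!r}")
        self.dates = pd.to_datetime(np.asarray(self.dates)).to_numpy()
        self.values = np.asarray(self.values, dtype=float)
        if len(self.dates) != len(self.values):
            raise ValueError("dates and values must have equal length")
        if not np.isfinite(self.values).all():
            raise ValueError("values must be finite")
        order = np.argsort(self.dates, kind="stable")
        self.dates = self.dates[order]
        self.values = self.values[order]


@dataclass
class VariabilitySummary:
    """Temporal summary of one analyte for one patient.

    ``eligible`` is True iff the patient has at least three in-window
    measurements; otherwise mean/sd/cv are NaN. ``baseline`` is the
    earliest in-window value (NaN when the window is empty).
    """

    baseline: float
    mean: float
    sd: float
    cv: float
    n_measurements: int
    eligible: bool


def summarize_variability(series: LabSeries, window) -> VariabilitySummary:
    """SD/CV summary of the observations of ``series`` inside ``window``.

    ``window`` is an inclusive (start, end) pair of dates. The SD uses the
    n-1 denominator; CV = 100 * sd / mean, set missing when the mean is 0.
    """
    start, end = (pd.Timestamp(window[0]), pd.Timestamp(window[1]))
    if end < start:
        raise ValueError("window end precedes window start")
    mask = (series.dates >= start.to_datetime64()) & (series.dates <= end.to_datetime64())
    vals = series.values[mask]
    n = len(vals)
    if n == 0:
        return VariabilitySummary(math.nan, math.nan, math.nan, math.nan, 0, False)
    baseline = float(vals[0])  # dates are sorted on construction
    if n < MIN_MEASUREMENTS:
        return VariabilitySummary(baseline, math.nan, math.nan, math.nan, n, False)
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    cv = 100.0 * sd / mean if mean != 0 else math.nan
    return VariabilitySummary(baseline, mean, sd, cv, n, True)


def count_hypoglycemia(series: LabSeries) -> int:
    """Number of glucose readings strictly below 3.9 mmol/L."""
    if series.analyte != "glucose":
        raise ValueError("hypoglycemia counting requires a glucose series")
    return int((series.values < HYPOGLYCEMIA_THRESHOLD).sum())


def compute_nlr(neutrophil: float, lymphocyte: float) -> float:
    """Neutrophil-to-lymphocyte ratio; NaN when the denominator is zero."""
    if neutrophil < 0 or lymphocyte < 0:
        raise ValueError("cell counts must be non-negative")
    if lymphocyte == 0:
        return math.nan
    return neutrophil / lymphocyte


def flag_anemia(hemoglobin: float, sex: str) -> bool:
    """Anemia flag: hb < 13 g/dL for males, < 12 g/dL for females (strict)."""
    if hemoglobin < 0:
        raise ValueError("hemoglobin must be non-negative")
    if sex not in ANEMIA_THRESHOLDS:
        raise ValueError(f"unknown sex {sex!r}")
    return hemoglobin < ANEMIA_THRESHOLDS[sex]


def flag_iron_deficiency(ferritin: float) -> bool:
    """Iron-deficiency flag: ferritin < 67.4 pmol/L (strict)."""
    if ferritin < 0:
        raise ValueError("ferritin must be non-negative")
    return ferritin < IRON_DEFICIENCY_THRESHOLD


@dataclass
class FeatureMatrix:
    """Per-patient covariates with an explicit missingness mask.

    ``frame`` is indexed by patient id; ``mask`` is True where the value
    is missing. After :func:`pad_missing` the values are numeric with -1
    in place of missing cells while the mask is retained for diagnostics.
    """

    frame: pd.DataFrame
    mask: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.frame.columns) != list(self.mask.columns) or not self.frame.index.equals(self.mask.index):
            raise ValueError("frame and mask must be aligned")

    def to_csv(self, path, mask_path=None) -> None:
        self.frame.to_csv(path, index_label="patient_id")
        if mask_path is not None:
            self.mask.to_csv(mask_path, index_label="patient_id")

    @classmethod
    def read_csv(cls, path, mask_path) -> "FeatureMatrix":
        frame = pd.read_csv(path, index_col="patient_id")
        mask = pd.read_csv(mask_path, index_col="patient_id").astype(bool)
        return cls(frame=frame, mask=mask)


def feature_columns(drug_flags=()) -> list[str]:
    """Documented, stable column order of the engineered feature matrix."""
    cols = []
    for a in VARIABILITY_ANALYTES:
        cols += [f"{a}_baseline", f"{a}_mean", f"{a}_sd", f"{a}_cv"]
    cols += ["hypoglycemia_count", "nlr", "anemia", "iron_deficiency", "age", "sex"]
    cols += list(drug_flags)
    return cols


def build_feature_matrix(labs: pd.DataFrame, baseline: pd.DataFrame, window,
                         hypoglycemia_mode: str = "window") -> FeatureMatrix:
    """Engineer the per-patient covariate table.

    Parameters
    ----------
    labs : DataFrame
        Long format with columns ``patient_id``, ``analyte``, ``date``,
        ``value``.
    baseline : DataFrame
        One row per patient: ``patient_id``, ``age``, ``sex`` plus any
        boolean drug-flag columns, which are carried through.
    window : (start, end)
        Inclusive lookback window for variability and baseline values.
    hypoglycemia_mode : {"window", "followup"}
        Whether hypoglycemia episodes are counted inside the lookback
        window only (default, avoids using post-baseline information in a
        predictor) or over every available glucose reading.

    A variability analyte with fewer than three in-window measurements
    yields missing mean/sd/cv but keeps its baseline value; a missing
    input (e.g. no ferritin measurement) yields a missing flag, never a
    False one.
    """
    required = {"patient_id", "analyte", "date", "value"}
    if not required.issubset(labs.columns):
        raise ValueError(f"labs table must have columns {sorted(required)}")
    if hypoglycemia_mode not in ("window", "followup"):
        raise ValueError("hypoglycemia_mode must be 'window' or 'followup'")
    unknown = set(labs["analyte"]) - set(ANALYTES)
    if unknown:
        row = labs.index[labs["analyte"].isin(unknown)][0]
        raise ValueError(f"unknown analyte {labs.loc[row, 'analyte']!r} in labs row {row}")
    if baseline["patient_id"].duplicated().any():
        dup = baseline.loc[baseline["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ValueError(f"duplicate patient id {dup!r} in baseline table")

    drug_flags = [c for c in baseline.columns if c not in ("patient_id", "age", "sex")]
    cols = feature_columns(drug_flags)
    base = baseline.set_index("patient_id")
    labs = labs.assign(date=pd.to_datetime(labs["date"]))
    rows = {}
    grouped = {k: g for k, g in labs.groupby(["patient_id", "analyte"], sort=False)}
    for pid in base.index:
        row: dict[str, float] = {}

        def series_for(analyte):
            g = grouped.get((pid, analyte))
            if g is None:
                return None
            return LabSeries(pid, analyte, g["date"].to_numpy(), g["value"].to_numpy())

        for a in VARIABILITY_ANALYTES:
            s = series_for(a)
            if s is None:
                summ = VariabilitySummary(math.nan, math.nan, math.nan, math.nan, 0, False)
            else:
                summ = summarize_variability(s, window)
            row[f"{a}_baseline"] = summ.baseline
            row[f"{a}_mean"] = summ.mean
            row[f"{a}_sd"] = summ.sd
            row[f"{a}_cv"] = summ.cv

        glu = series_for("glucose")
        if glu is None:
            row["hypoglycemia_count"] = math.nan
        elif hypoglycemia_mode == "followup":
            row["hypoglycemia_count"] = count_hypoglycemia(glu)
        else:
            start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
            m = (glu.dates >= start.to_datetime64()) & (glu.dates <= end.to_datetime64())
            row["hypoglycemia_count"] = int((glu.values[m] < HYPOGLYCEMIA_THRESHOLD).sum())

        def baseline_value(analyte):
            s = series_for(analyte)
            if s is None:
                return math.nan
            summ = summarize_variability(s, window)
            return summ.baseline

        neut, lymph = baseline_value("neutrophil"), baseline_value("lymphocyte")
        row["nlr"] = compute_nlr(neut, lymph) if not (math.isnan(neut) or math.isnan(lymph)) else math.nan

        sex = base.at[pid, "sex"] if "sex" in base.columns else None
        hb = baseline_value("hemoglobin")
        if math.isnan(hb) or sex not in ANEMIA_THRESHOLDS:
            row["anemia"] = math.nan
        else:
            row["anemia"] = float(flag_anemia(hb, sex))
        ferr = baseline_value("ferritin")
        row["iron_deficiency"] = math.nan if math.isnan(ferr) else float(flag_iron_deficiency(ferr))

        age = base.at[pid, "age"] if "age" in base.columns else math.nan
        row["age"] = float(age) if pd.notna(age) else math.nan
        row["sex"] = {"male": 1.0, "female": 0.0}.get(sex, math.nan)
        for flag in drug_flags:
            v = base.at[pid, flag]
            row[flag] = float(v) if pd.notna(v) else math.nan
        rows[pid] = row

    frame = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    frame.index.name = "patient_id"
    return FeatureMatrix(frame=frame, mask=frame.isna())


def pad_missing(matrix: FeatureMatrix) -> FeatureMatrix:
    """Replace every missing cell by -1, keeping the missingness mask."""
    padded = matrix.frame.astype(float).fillna(-1.0)
    return FeatureMatrix(frame=padded, mask=matrix.mask.copy())
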