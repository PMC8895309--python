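"""Cohort and tract-metric tables: validation, I/O, and streamline aggregation.

The behavioral table holds one row per child (age, sex, three CVLT-c recall
scores, optional memory-discrimination score); the tract-metric table holds
one row per (subject, tract, hemisphere) with the tract-averaged diffusion
parameters FA, RD, and AD.  Diffusivities are accepted in any consistent
unit (mm^2/s or 1e-3 mm^2/s); downstream standardization makes every
analysis scale-invariant, so no conversion is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRACTS = (
    "uncinate_fasciculus",
    "dorsal_cingulum",
    "ventral_cingulum",
    "fornix",
)
HEMISPHERES = ("left", "right")
METRICS = ("fa", "rd", "ad")
EM_SCORES = ("sdfr", "ldfr", "ldcr")

#: CVLT-c list length; recall counts cannot exceed it.
CVLT_MAX = 15

COHORT_COLUMNS = ["subject_id", "age", "sex", "sdfr", "ldfr", "ldcr"]
METRIC_COLUMNS = ["subject_id", "tract", "hemisphere", "fa", "rd", "ad"]


class CohortFormatError(ValueError):
    """Malformed input file (missing columns, unparsable fields)."""


class CohortIntegrityError(ValueError):
    """Structurally valid input violating a table invariant."""


class InsufficientDataError(ValueError):
    """Too few complete subjects for the requested analysis."""


@dataclass
class Cohort:
    """Validated behavioral table, one row per subject.

    ``data`` is indexed by position with columns
    ``subject_id, age, sex, sdfr, ldfr, ldcr[, discrimination]``.
    """

    data: pd.DataFrame
    rejected: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        validate_cohort_frame(self.data)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.data["subject_id"])

    @property
    def has_discrimination(self) -> bool:
        return "discrimination" in self.data.columns

    def em_scores(self) -> pd.DataFrame:
        """The three recall scores indexed by subject_id."""
        return self.data.set_index("subject_id")[list(EM_SCORES)]

    def ages(self) -> pd.Series:
        return self.data.set_index("subject_id")["age"]


@dataclass
class TractMetricTable:
    """Tract-averaged diffusion metrics, one row per (subject, tract, hemisphere).

    Missing rows are allowed: a failed tract reconstruction simply has no
    entry, and listwise deletion happens per tract when matrices are built.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        validate_metric_frame(self.data)

    def subjects_with_tract(self, tract: str) -> set[str]:
        """Subjects having both hemispheres of ``tract``."""
        sub = self.data[self.data["tract"] == tract]
        counts = sub.groupby("subject_id")["hemisphere"].nunique()
        return set(counts[counts == 2].index)


def validate_cohort_frame(df: pd.DataFrame) -> None:
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"cohort table missing columns: {missing}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise CohortIntegrityError(
            f"duplicate subject_id: {sorted(set(dup.astype(str)))}"
        )
    if (df["age"] <= 0).any():
        bad = df.loc[df["age"] <= 0, "subject_id"].tolist()
        raise CohortIntegrityError(f"non-positive age for subjects: {bad}")
    bad_sex = set(df["sex"]) - {"F", "M"}
    if bad_sex:
        raise CohortIntegrityError(f"sex must be F or M, got: {sorted(bad_sex)}")
    for col in EM_SCORES:
        out = df[(df[col] < 0) | (df[col] > CVLT_MAX)]
        if len(out):
            raise CohortIntegrityError(
                f"{col} outside [0, {CVLT_MAX}] for subjects: "
                f"{out['subject_id'].tolist()}"
            )


def validate_metric_frame(df: pd.DataFrame) -> None:
    missing = [c for c in METRIC_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"metric table missing columns: {missing}")
    bad_tract = set(df["tract"]) - set(TRACTS)
    if bad_tract:
        raise CohortIntegrityError(f"unknown tract(s): {sorted(bad_tract)}")
    bad_hemi = set(df["hemisphere"]) - set(HEMISPHERES)
    if bad_hemi:
        raise CohortIntegrityError(f"unknown hemisphere(s): {sorted(bad_hemi)}")
    key = df[["subject_id", "tract", "hemisphere"]]
    if key.duplicated().any():
        dups = key[key.duplicated()].to_records(index=False).tolist()
        raise CohortIntegrityError(f"duplicate (subject, tract, hemisphere): {dups}")
    if ((df["fa"] < 0) | (df["fa"] > 1)).any():
        raise CohortIntegrityError("fa outside [0, 1]")
    if (df["rd"] <= 0).any() or (df["ad"] <= 0).any():
        raise CohortIntegrityError("rd and ad must be positive")


def _read_delim(path, tab: bool) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t" if tab else ",", encoding="utf-8")


def load_cohort(path, *, tab: bool = False) -> Cohort:
    """Read and validate a cohort table.

    Rows with unparsable or out-of-range ages/scores are rejected
    individually and reported (1-based data line numbers in
    ``Cohort.rejected``); structural problems (missing columns, duplicate
    ids among the retained rows) raise instead.
    """
    df = _read_delim(path, tab)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing columns {missing}")

    rejected: list[str] = []
    keep = np.ones(len(df), dtype=bool)
    num_cols = ["age", *EM_SCORES] + (
        ["discrimination"] if "discrimination" in df.columns else []
    )
    for col in num_cols:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        problems = []
        if not np.isfinite(row["age"]) or row["age"] <= 0:
            problems.append("age")
        for col in EM_SCORES:
            v = row[col]
            if not np.isfinite(v) or v < 0 or v > CVLT_MAX:
                problems.append(col)
        if problems:
            keep[i] = False
            rejected.append(f"line {line} ({row['subject_id']}): bad {problems}")
    df = df[keep].reset_index(drop=True)
    df["subject_id"] = df["subject_id"].astype(str)
    return Cohort(data=df, rejected=rejected)


def load_metrics(path, *, tab: bool = False) -> TractMetricTable:
    """Read and validate a tract-metric table."""
    df = _read_delim(path, tab)
    missing = [c for c in METRIC_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing columns {missing}")
    df["subject_id"] = df["subject_id"].astype(str)
    for col in METRICS:
        df[col] = pd.to_numeric(df[col], errors="raise")
    return TractMetricTable(data=df.reset_index(drop=True))


def write_cohort(cohort: Cohort, path, *, tab: bool = False) -> None:
    cohort.data.to_csv(path, sep="\t" if tab else ",", index=False)


def write_metrics(metrics: TractMetricTable, path, *, tab: bool = False) -> None:
    metrics.data.to_csv(path, sep="\t" if tab else ",", index=False)


# ---------------------------------------------------------------------------
# Streamline-to-tract aggregation

def aggregate_streamline_metrics(samples: dict[int, np.ndarray] | pd.DataFrame) -> float:
    """Two-stage tract average of a diffusion metric.

    Each streamline is first averaged along its length, then the
    per-streamline means are averaged.  This is NOT the pooled mean over all
    samples: streamlines with more sample points do not weigh more.

    ``samples`` is either a mapping streamline_id -> 1-D array of values, or
    a DataFrame with columns ``streamline_id`` and ``value`` (the on-disk
    layout, one row per sampled point).
    """
    if isinstance(samples, pd.DataFrame):
        if not {"streamline_id", "value"} <= set(samples.columns):
            raise CohortFormatError(
                "streamline table needs streamline_id and value columns"
            )
        groups = {k: g["value"].to_numpy() for k, g in samples.groupby("streamline_id")}
    else:
        groups = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    if not groups:
        raise ValueError("no streamlines to aggregate")
    means = []
    for sid, vals in groups.items():
        if vals.size == 0:
            raise ValueError(f"streamline {sid} has no samples")
        means.append(float(np.mean(vals)))
    return float(np.mean(means))


# ---------------------------------------------------------------------------
# Analysis matrices

@dataclass
class AnalysisMatrix:
    """Listwise-complete paired blocks for one tract.

    X columns follow the fixed order left FA, left RD, left AD, right FA,
    right RD, right AD so salience vectors are comparable across runs; rows
    are sorted by subject_id.
    """

    subject_ids: list[str]
    X: np.ndarray
    x_names: list[str]
    Y: np.ndarray
    y_names: list[str]
    dropped: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.X.shape[0]


def x_column_names(tract: str) -> list[str]:
    return [f"{tract}_{h}_{m}" for h in HEMISPHERES for m in METRICS]


def build_analysis_matrix(
    cohort: Cohort,
    metrics: TractMetricTable,
    tract: str,
    y_spec: str = "em_scores",
) -> AnalysisMatrix:
    """Assemble the X (diffusion) and Y (behavior or age) blocks for a tract.

    Subjects missing either hemisphere of the tract, or any Y variable, are
    dropped listwise and reported.  ``y_spec`` is ``"em_scores"`` (three
    recall scores), ``"age"``, or ``"discrimination"``.
    """
    if tract not in TRACTS:
        raise ValueError(f"unknown tract {tract!r}")
    sub = metrics.data[metrics.data["tract"] == tract]
    if sub.empty:
        raise ValueError(f"tract {tract!r} absent from metric table")

    wide = sub.pivot(index="subject_id", columns="hemisphere", values=list(METRICS))
    x_cols = [(m, h) for h in HEMISPHERES for m in METRICS]
    have_all = wide.index[wide[x_cols].notna().all(axis=1)] if not wide.empty else []

    beh = cohort.data.set_index("subject_id")
    if y_spec == "em_scores":
        y_names = list(EM_SCORES)
    elif y_spec == "age":
        y_names = ["age"]
    elif y_spec == "discrimination":
        if not cohort.has_discrimination:
            raise CohortFormatError("cohort has no discrimination column")
        y_names = ["discrimination"]
    else:
        raise ValueError(f"unknown y_spec {y_spec!r}")

    ok_beh = beh.index[beh[y_names].notna().all(axis=1)]
    keep = sorted(set(have_all) & set(ok_beh) & set(beh.index))
    dropped = sorted(set(beh.index) - set(keep))

    X = np.column_stack([wide.loc[keep, c].to_numpy(float) for c in x_cols])
    Y = beh.loc[keep, y_names].to_numpy(float)
    p = X.shape[1]
    if len(keep) < p + 2:
        raise InsufficientDataError(
            f"{tract}: only {len(keep)} complete subjects for p={p} predictors"
        )
    return AnalysisMatrix(
        subject_ids=list(keep),
        X=X,
        x_names=x_column_names(tract),
        Y=Y,
        y_names=y_names,
        dropped=dropped,
    )
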