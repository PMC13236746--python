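"""Containers and I/O for experiment-based calibration data.

A calibration experiment manipulates a latent variable to known
condition-level *standard scores* and records, for each measurement
method, the *measured scores* it produces.  This module holds the two
levels at which such data circulate:

* raw, long-format observations (one row per subject x condition x
  method) wrapped in :class:`StudyData`;
* study-level summaries (within-subject Cohen's d, sample size,
  acquisition date, one row per study x method) as :class:`StudySummary`
  rows — the form in which retrodictive validity is typically published.

Both kinds coexist inside a :class:`CalibrationCorpus`, ordered by
acquisition date.  Method missingness (a method not measured in a study)
is first-class: it is recorded, never imputed, and downstream evidence
synthesis accounts for it explicitly.

The bundled fear-conditioning summary table (nine datasets, four
psychophysiological measures: SCR, PSR, RAR, HPR) is exposed through
:func:`table1_fixture`.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, fields as dc_fields, is_dataclass, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .errors import EmptyCorpusError, FormatError, ValidationError

logger = logging.getLogger(__name__)

#: A measurement method is identified by a short, non-empty string label.
MethodId = str

_DATE_RE = re.compile(r"^(\d{4})-(\d{2})$")

LONG_COLUMNS = (
    "study_id",
    "date",
    "subject",
    "condition",
    "standard_score",
    "method",
    "measured_score",
)

SUMMARY_COLUMNS = ("study_id", "date", "method", "cohen_d", "n_subjects")


def date_key(date: str) -> tuple[int, int]:
    """Sortable (year, month) key for a ``YYYY-MM`` date string."""
    m = _DATE_RE.match(str(date))
    if not m:
        raise ValidationError(f"date {date!r} is not in YYYY-MM format")
    year, month = int(m.group(1)), int(m.group(2))
    if not 1 <= month <= 12:
        raise ValidationError(f"date {date!r} has month outside 1..12")
    return year, month


@dataclass(frozen=True)
class StudySummary:
    """Published per-study, per-method summary: within-subject Cohen's d
    (the d_z of the condition difference) and the sample size."""

    study_id: str
    date: str
    method: MethodId
    cohen_d: float
    n_subjects: int

    def __post_init__(self) -> None:
        if not self.study_id:
            raise ValidationError("study_id must be non-empty")
        if not self.method:
            raise ValidationError("method label must be non-empty")
        date_key(self.date)
        if not np.isfinite(self.cohen_d):
            raise ValidationError(
                f"{self.study_id}/{self.method}: cohen_d must be finite"
            )
        if int(self.n_subjects) < 2:
            raise ValidationError(
                f"{self.study_id}/{self.method}: n_subjects must be >= 2"
            )


class StudyData:
    """Raw long-format calibration observations for one study.

    Parameters
    ----------
    study_id : str
        Unique study label.
    date : str
        Acquisition date, ``YYYY-MM``.
    data : pandas.DataFrame
        Columns ``subject, condition, standard_score, method,
        measured_score``; one row per observation.  The standard score
        must be constant within a condition.

    Notes
    -----
    A balanced within-subject design (every subject observed under every
    condition, per method) is the expected shape; imbalance is flagged on
    :attr:`unbalanced_methods` and logged, not rejected.
    """

    def __init__(self, study_id: str, date: str, data: pd.DataFrame) -> None:
        if not study_id:
            raise ValidationError("study_id must be non-empty")
        date_key(date)
        required = {"subject", "condition", "standard_score", "method", "measured_score"}
        missing = required - set(data.columns)
        if missing:
            raise FormatError(
                f"study {study_id}: missing observation column(s) {sorted(missing)}"
            )
        data = data.copy()
        data["measured_score"] = pd.to_numeric(data["measured_score"], errors="raise")
        data["standard_score"] = pd.to_numeric(data["standard_score"], errors="raise")
        if not np.isfinite(data["measured_score"]).all():
            raise ValidationError(f"study {study_id}: non-finite measured_score")
        # the standard score is a property of the condition, not the row
        per_cond = data.groupby("condition")["standard_score"].nunique()
        bad = per_cond[per_cond > 1]
        if len(bad):
            raise ValidationError(
                f"study {study_id}: standard_score varies within condition(s) "
                f"{list(bad.index)}"
            )
        if data["condition"].nunique() < 2:
            raise ValidationError(f"study {study_id}: needs >= 2 distinct conditions")
        if data.empty:
            raise ValidationError(f"study {study_id}: no observations")

        self.study_id = str(study_id)
        self.date = str(date)
        self.data = data.reset_index(drop=True)
        self.unbalanced_methods: set[MethodId] = set()
        n_cond = data["condition"].nunique()
        for method, sub in data.groupby("method"):
            counts = sub.groupby("subject")["condition"].nunique()
            if (counts < n_cond).any():
                self.unbalanced_methods.add(str(method))
        if self.unbalanced_methods:
            logger.warning(
                "study %s: unbalanced design for method(s) %s",
                study_id,
                sorted(self.unbalanced_methods),
            )

    @property
    def methods_available(self) -> frozenset[MethodId]:
        return frozenset(str(m) for m in self.data["method"].unique())

    @property
    def conditions(self) -> list:
        return sorted(self.data["condition"].unique())

    def n_subjects(self, method: MethodId) -> int:
        sub = self.data[self.data["method"] == method]
        return int(sub["subject"].nunique())

    def observations(self, method: MethodId) -> pd.DataFrame:
        sub = self.data[self.data["method"] == method]
        if sub.empty:
            from .errors import AvailabilityError

            raise AvailabilityError(
                f"method {method!r} not measured in study {self.study_id}"
            )
        return sub

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"StudyData({self.study_id!r}, {self.date!r}, "
            f"{len(self.data)} obs, methods={sorted(self.methods_available)})"
        )


class _SummaryGroup:
    """All summary rows of one study, grouped for corpus-level iteration."""

    def __init__(self, rows: Sequence[StudySummary]) -> None:
        ids = {r.study_id for r in rows}
        dates = {r.date for r in rows}
        if len(ids) != 1 or len(dates) != 1:
            raise ValidationError("summary group must share study_id and date")
        methods = [r.method for r in rows]
        if len(methods) != len(set(methods)):
            raise ValidationError(
                f"study {rows[0].study_id}: duplicate summary rows for a method"
            )
        self.study_id = rows[0].study_id
        self.date = rows[0].date
        self.rows = {r.method: r for r in rows}

    @property
    def methods_available(self) -> frozenset[MethodId]:
        return frozenset(self.rows)

    def n_subjects(self, method: MethodId) -> int:
        return int(self.rows[method].n_subjects)

    def cohen_d(self, method: MethodId) -> float:
        return float(self.rows[method].cohen_d)


StudyEntry = Union[StudyData, _SummaryGroup]


class CalibrationCorpus:
    """An ordered collection of calibration studies.

    Studies may be raw (:class:`StudyData`) or summary-level
    (:class:`StudySummary` rows); both sort together by acquisition date,
    ties broken by ``study_id`` so the ordering is stable and total.
    """

    def __init__(self, studies: Iterable[Union[StudyData, StudySummary, _SummaryGroup]]):
        entries: list[StudyEntry] = []
        summary_rows: dict[str, list[StudySummary]] = {}
        for s in studies:
            if isinstance(s, StudySummary):
                summary_rows.setdefault(s.study_id, []).append(s)
            elif isinstance(s, (StudyData, _SummaryGroup)):
                entries.append(s)
            else:
                raise TypeError(f"unsupported study entry {type(s).__name__}")
        entries.extend(_SummaryGroup(rows) for rows in summary_rows.values())
        ids = [e.study_id for e in entries]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate study_id(s): {dupes}")
        self.studies: list[StudyEntry] = sorted(
            entries, key=lambda e: (date_key(e.date), e.study_id)
        )
        #: bookkeeping from readers (e.g. rows dropped for NaN scores)
        self.dropped_rows: int = 0

    def __len__(self) -> int:
        return len(self.studies)

    def __iter__(self):
        return iter(self.studies)

    def __getitem__(self, study_id: str) -> StudyEntry:
        for e in self.studies:
            if e.study_id == study_id:
                return e
        raise KeyError(study_id)

    @property
    def study_ids(self) -> list[str]:
        return [e.study_id for e in self.studies]

    @property
    def methods(self) -> list[MethodId]:
        out: set[MethodId] = set()
        for e in self.studies:
            out |= set(e.methods_available)
        return sorted(out)

    def availability(self) -> pd.DataFrame:
        """Boolean studies x methods matrix of method presence.

        Missing method x study combinations are holes in the calibration
        record; they are reported here and never imputed.
        """
        methods = self.methods
        mat = pd.DataFrame(
            False, index=self.study_ids, columns=methods, dtype=bool
        )
        for e in self.studies:
            for m in e.methods_available:
                mat.loc[e.study_id, m] = True
        return mat

    def studies_with(self, method: MethodId) -> list[StudyEntry]:
        return [e for e in self.studies if method in e.methods_available]

    def subset(self, study_ids: Sequence[str]) -> "CalibrationCorpus":
        keep = set(study_ids)
        return CalibrationCorpus([e for e in self.studies if e.study_id in keep])

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"CalibrationCorpus({len(self)} studies, "
            f"methods={self.methods})"
        )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_long_format(
    path: Union[str, Path],
    column_map: Mapping[str, str] | None = None,
) -> CalibrationCorpus:
    """Read raw long-format calibration data from CSV.

    The canonical columns are ``study_id, date, subject, condition,
    standard_score, method, measured_score``; ``column_map`` renames
    actual file columns onto these (``{"canonical": "actual"}``).

    Rows with a missing (NaN) measured score are rejected with a logged
    warning; the count is available as ``corpus.dropped_rows``.
    """
    df = pd.read_csv(path)
    if column_map:
        rename = {actual: canonical for canonical, actual in column_map.items()}
        df = df.rename(columns=rename)
    for col in LONG_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"long-format file is missing required column {col!r}")
    df["measured_score"] = pd.to_numeric(df["measured_score"], errors="coerce")
    bad = df["measured_score"].isna()
    n_dropped = int(bad.sum())
    if n_dropped:
        logger.warning(
            "dropping %d row(s) with missing/non-numeric measured_score", n_dropped
        )
        df = df[~bad]
    if df.empty:
        raise EmptyCorpusError("no usable observations in long-format file")
    studies = [
        StudyData(str(sid), str(sub["date"].iloc[0]), sub.drop(columns=["study_id", "date"]))
        for sid, sub in df.groupby("study_id", sort=False)
    ]
    corpus = CalibrationCorpus(studies)
    corpus.dropped_rows = n_dropped
    return corpus


def read_summary(
    path: Union[str, Path],
    column_map: Mapping[str, str] | None = None,
) -> CalibrationCorpus:
    """Read a study-level summary table (CSV) into a corpus.

    Two layouts are accepted:

    * long — columns ``study_id, date, method, cohen_d, n_subjects``;
    * wide — columns ``study_id, date, n_subjects`` plus one column per
      method holding Cohen's d, with ``.`` (or an empty cell) marking a
      method not measured in that study, as in printed summary tables.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if column_map:
        rename = {actual: canonical for canonical, actual in column_map.items()}
        df = df.rename(columns=rename)
    if "method" in df.columns:
        for col in SUMMARY_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"summary file is missing required column {col!r}")
        rows = [
            StudySummary(
                study_id=str(r["study_id"]),
                date=str(r["date"]),
                method=str(r["method"]),
                cohen_d=float(r["cohen_d"]),
                n_subjects=int(r["n_subjects"]),
            )
            for r in df.to_dict("records")
        ]
        return CalibrationCorpus(rows)
    for col in ("study_id", "date", "n_subjects"):
        if col not in df.columns:
            raise FormatError(f"summary file is missing required column {col!r}")
    method_cols = [c for c in df.columns if c not in ("study_id", "date", "n_subjects")]
    if not method_cols:
        raise FormatError("wide summary file has no method columns")
    rows = []
    for r in df.to_dict("records"):
        for m in method_cols:
            cell = str(r[m]).strip()
            if cell in (".", "", "nan", "NA"):
                continue  # a dot marks a missing measurement
            rows.append(
                StudySummary(
                    study_id=str(r["study_id"]),
                    date=str(r["date"]),
                    method=m,
                    cohen_d=float(cell),
                    n_subjects=int(r["n_subjects"]),
                )
            )
    if not rows:
        raise EmptyCorpusError("no summary rows in file")
    return CalibrationCorpus(rows)


def table1_fixture() -> CalibrationCorpus:
    """The bundled fear-conditioning summary corpus.

    Nine datasets acquired 2017-2021, each reporting within-subject
    Cohen's d for a subset of four psychophysiological measures of fear
    conditioning: skin conductance (SCR), pupil size (PSR), respiration
    amplitude (RAR) and heart period (HPR) responses, with per-study
    sample sizes and acquisition dates.  Methods not measured in a study
    are missing cells, not zeros.
    """
    ref = resources.files("retrocal").joinpath("data/fear_conditioning_summary.csv")
    with resources.as_file(ref) as p:
        return read_summary(p)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def results_to_frame(results: Sequence, columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Flatten a sequence of result dataclasses into a DataFrame."""
    if not results:
        return pd.DataFrame(columns=list(columns) if columns else [])
    recs = []
    for r in results:
        if is_dataclass(r):
            rec = asdict(r)
        elif isinstance(r, Mapping):
            rec = dict(r)
        else:
            raise TypeError(f"cannot serialise {type(r).__name__}")
        # collections serialise as ;-joined strings so the CSV round-trips
        for k, v in rec.items():
            if isinstance(v, (set, frozenset)):
                v = sorted(v)
            if isinstance(v, (list, tuple)):
                rec[k] = ";".join(str(x) for x in v)
        recs.append(rec)
    return pd.DataFrame(recs)


def write_table(results: Sequence, path: Union[str, Path], columns: Sequence[str] | None = None) -> None:
    """Write result rows to CSV.  An empty result set yields a header-only
    file (``columns`` supplies the header in that case)."""
    frame = results_to_frame(results, columns=columns)
    frame.to_csv(path, index=False)


def write_json_report(report, path: Union[str, Path]) -> None:
    """Write a dataclass or mapping as pretty-printed JSON."""
    obj = asdict(report) if is_dataclass(report) else report

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not JSON-serialisable: {type(o).__name__}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")


def write_long_format(corpus: CalibrationCorpus, path: Union[str, Path]) -> None:
    """Write the raw studies of a corpus back to canonical long CSV."""
    frames = []
    for e in corpus:
        if not isinstance(e, StudyData):
            continue
        df = e.data.copy()
        df.insert(0, "study_id", e.study_id)
        df.insert(1, "date", e.date)
        frames.append(df[list(LONG_COLUMNS)])
    if not frames:
        pd.DataFrame(columns=list(LONG_COLUMNS)).to_csv(path, index=False)
        return
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_summary(corpus: CalibrationCorpus, path: Union[str, Path]) -> None:
    """Write summary-level studies to long summary CSV."""
    rows = []
    for e in corpus:
        if isinstance(e, _SummaryGroup):
            for m in sorted(e.rows):
                r = e.rows[m]
                rows.append(
                    dict(
                        study_id=r.study_id,
                        date=r.date,
                        method=r.method,
                        cohen_d=r.cohen_d,
                        n_subjects=r.n_subjects,
                    )
                )
    pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS)).to_csv(path, index=False)
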