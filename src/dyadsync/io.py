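"""Delimited-text readers/writers for the pipeline's tabular formats.

File dialects are declared, never sniffed. All formats are documented in the
README: IBI tables (beat_time_s and/or ibi_ms), tall coded streams
(second, code), a dyad manifest linking files, and a covariate/outcome table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import ALPHABETS, UNCODABLE, CodedStream, DyadRecord, IBISeries

logger = logging.getLogger(__name__)

COVARIATE_COLUMNS = ("child_medication", "pubertal_status", "pandemic_cohort")
OUTCOME_COLUMNS = ("parent_dep_T", "child_dep_T", "child_internalizing_T", "child_total_T")

MANIFEST_FILE_COLUMNS = (
    "parent_ibi", "child_ibi", "parent_affect", "child_affect", "parent_ersb",
)


@dataclass
class TableDialect:
    """Column names and delimiter for the delimited-text inputs."""

    delimiter: str = ","
    time_col: str = "beat_time_s"
    interval_col: str = "ibi_ms"
    second_col: str = "second"
    code_col: str = "code"


def read_ibi(path, dialect: TableDialect = TableDialect(), person_id: Optional[str] = None) -> IBISeries:
    """Read an IBI table with an interval column (ms), a beat-time column (s),
    or both.

    Rows with non-positive intervals are rejected with a logged line number;
    non-monotone beat times are a hard error naming the first offending index.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=dialect.delimiter)
    pid = person_id if person_id is not None else path.stem

    has_time = dialect.time_col in df.columns
    has_interval = dialect.interval_col in df.columns
    if not has_time and not has_interval:
        raise ValueError(
            f"{path}: need column {dialect.time_col!r} or {dialect.interval_col!r}"
        )

    if has_interval:
        intervals = df[dialect.interval_col].to_numpy(dtype=float)
        bad = ~(intervals > 0)
        if np.any(bad):
            for i in np.flatnonzero(bad):
                # +2: header line plus 1-based numbering
                logger.warning(
                    "%s: rejecting beat at line %d (non-positive interval %g)",
                    path, i + 2, intervals[i],
                )
            df = df.loc[~bad].reset_index(drop=True)
            intervals = intervals[~bad]
    else:
        intervals = None

    if has_time:
        times = df[dialect.time_col].to_numpy(dtype=float)
        dt = np.diff(times)
        if np.any(dt <= 0):
            idx = int(np.argmax(dt <= 0)) + 1
            raise ValueError(f"{path}: beat times not strictly increasing at index {idx}")
        if intervals is None:
            intervals = np.empty_like(times)
            intervals[0] = times[0] * 1000.0
            intervals[1:] = dt * 1000.0
            if np.any(intervals <= 0):
                idx = int(np.argmax(intervals <= 0))
                raise ValueError(f"{path}: derived non-positive interval at index {idx}")
    else:
        times = np.cumsum(intervals) / 1000.0

    series = IBISeries(person_id=pid, beat_times=times, intervals=intervals)
    if has_time and has_interval:
        series.validate()
    return series


def write_ibi(series: IBISeries, path, dialect: TableDialect = TableDialect()) -> None:
    df = pd.DataFrame({
        dialect.time_col: series.beat_times,
        dialect.interval_col: series.intervals,
    })
    df.to_csv(path, sep=dialect.delimiter, index=False, float_format="%.6f")


def read_coded_stream(
    path,
    stream_kind: str,
    role: str,
    dialect: TableDialect = TableDialect(),
    task_length_s: Optional[int] = None,
    person_id: Optional[str] = None,
) -> CodedStream:
    """Read a tall (second, code) table into a CodedStream.

    Seconds are 0-based; gaps are filled with ``uncodable``. Unknown code
    tokens and duplicate second indices are hard errors.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=dialect.delimiter)
    pid = person_id if person_id is not None else path.stem

    seconds = df[dialect.second_col].to_numpy(dtype=int)
    codes = df[dialect.code_col].astype(str).to_numpy(dtype=object)

    dup = pd.Series(seconds).duplicated()
    if dup.any():
        raise ValueError(f"{path}: duplicate second index {seconds[dup.idxmax()]}")
    if len(seconds) and seconds.min() < 0:
        raise ValueError(f"{path}: negative second index {seconds.min()}")

    alphabet = ALPHABETS[stream_kind]
    unknown = sorted({c for c in codes if c not in alphabet})
    if unknown:
        raise ValueError(f"{path}: unknown {stream_kind} codes: {unknown}")

    n = task_length_s if task_length_s is not None else (int(seconds.max()) + 1 if len(seconds) else 0)
    filled = np.full(n, UNCODABLE, dtype=object)
    in_range = seconds < n
    filled[seconds[in_range]] = codes[in_range]

    stream = CodedStream(person_id=pid, role=role, stream_kind=stream_kind, codes=filled)
    stream.validate()
    return stream


def write_coded_stream(stream: CodedStream, path, dialect: TableDialect = TableDialect()) -> None:
    df = pd.DataFrame({
        dialect.second_col: np.arange(stream.task_length_s, dtype=int),
        dialect.code_col: stream.codes,
    })
    df.to_csv(path, sep=dialect.delimiter, index=False)


def read_outcome_table(path, dialect: TableDialect = TableDialect()) -> pd.DataFrame:
    df = pd.read_csv(path, sep=dialect.delimiter, dtype={"dyad_id": str})
    if df["dyad_id"].duplicated().any():
        dupes = df.loc[df["dyad_id"].duplicated(), "dyad_id"].tolist()
        raise ValueError(f"{path}: duplicate dyad_id(s): {dupes}")
    return df


def _get(row, col):
    if col not in row or pd.isna(row[col]):
        return None
    return row[col]


def assemble_dyads(
    manifest_path,
    outcome_path,
    base_dir=None,
    dialect: TableDialect = TableDialect(),
    task_length_s: Optional[int] = None,
) -> list[DyadRecord]:
    """Assemble DyadRecords from a manifest of file paths plus a
    covariate/outcome table keyed by dyad_id.

    Missing files (empty manifest cells) yield missing components; dyad_id
    collisions are a hard error.
    """
    manifest_path = Path(manifest_path)
    base = Path(base_dir) if base_dir is not None else manifest_path.parent
    manifest = pd.read_csv(manifest_path, sep=dialect.delimiter, dtype=str)
    if manifest["dyad_id"].duplicated().any():
        dupes = manifest.loc[manifest["dyad_id"].duplicated(), "dyad_id"].tolist()
        raise ValueError(f"{manifest_path}: dyad_id collision: {dupes}")
    outcomes = read_outcome_table(outcome_path, dialect).set_index("dyad_id")

    records: list[DyadRecord] = []
    for _, row in manifest.iterrows():
        dyad_id = row["dyad_id"]
        rec = DyadRecord(dyad_id=dyad_id)

        def _path(col):
            p = _get(row, col)
            return base / p if p else None

        for attr, col, reader_args in (
            ("parent_ibi", "parent_ibi", None),
            ("child_ibi", "child_ibi", None),
            ("parent_affect", "parent_affect", ("affect", "parent")),
            ("child_affect", "child_affect", ("affect", "child")),
            ("parent_ersb", "parent_ersb", ("ersb", "parent")),
        ):
            p = _path(col)
            if p is None:
                continue
            if reader_args is None:
                setattr(rec, attr, read_ibi(p, dialect, person_id=f"{dyad_id}_{col}"))
            else:
                kind, role = reader_args
                setattr(rec, attr, read_coded_stream(
                    p, kind, role, dialect,
                    task_length_s=task_length_s, person_id=f"{dyad_id}_{col}",
                ))

        if dyad_id in outcomes.index:
            orow = outcomes.loc[dyad_id]
            rec.covariates = {
                c: (None if pd.isna(orow.get(c)) else int(orow[c]))
                for c in COVARIATE_COLUMNS if c in outcomes.columns
            }
            for c in OUTCOME_COLUMNS:
                if c in outcomes.columns and not pd.isna(orow.get(c)):
                    setattr(rec, c, float(orow[c]))
        rec.validate()
        records.append(rec)
    return records


def missingness_report(records: Sequence[DyadRecord]) -> dict:
    """Counts of missing components per field, for the run log."""
    fields = ("parent_ibi", "child_ibi", "parent_affect", "child_affect",
              "parent_ersb", "parent_dep_T", "child_dep_T")
    report = {f: sum(1 for r in records if getattr(r, f) is None) for f in fields}
    report["n_dyads"] = len(records)
    return report
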