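"""Reading and writing study tables and analysis reports.

Annotation tables are delimited text with a header row (CSV, or TSV when
the extension is ``.tsv``) and columns ``reader_id, case_id, session,
label, entry_time_s`` — diff-able, spreadsheet-compatible, and round-trip
exact.  Sessions are stored as the strings "unaugmented"/"augmented", never
0/1, so a truth column can't silently stand in for a session column.
Missing reader-case cells are an error, never imputed.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import CompletenessError, IntegrityError, SchemaError
from .records import (
    Annotation,
    AnnotationMatrix,
    CaseRecord,
    ReaderProfile,
    Session,
    Specialty,
)

ANNOTATION_COLUMNS = ("reader_id", "case_id", "session", "label", "entry_time_s")
TRUTH_COLUMNS = ("case_id", "truth")
READER_COLUMNS = ("reader_id", "specialty", "group", "years_experience")


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() == ".tsv" else ","


def read_annotations(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> list[Annotation]:
    """Parse an annotation table into validated records.

    ``schema`` maps canonical column names to the file's column names when
    they differ.  Duplicate (reader, case, session) keys and non-binary
    labels are rejected with the offending key/row named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    rename = {v: k for k, v in (schema or {}).items()}
    df = df.rename(columns=rename)
    required = ["reader_id", "case_id", "session", "label"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    has_times = "entry_time_s" in df.columns

    keys = list(zip(df["reader_id"], df["case_id"], df["session"]))
    seen: set[tuple[str, str, str]] = set()
    dupes: list[tuple[str, str, str]] = []
    for key in keys:
        if key in seen:
            dupes.append(key)
        seen.add(key)
    if dupes:
        raise IntegrityError(
            f"{path}: duplicate (reader, case, session) key(s): {dupes[:5]}"
        )

    annotations: list[Annotation] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        raw_label = getattr(row, "label")
        try:
            label = float(raw_label)
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}: row {idx}: label {raw_label!r} is not numeric"
            ) from None
        if label not in (0.0, 1.0):
            raise ValueError(f"{path}: row {idx}: label {raw_label!r} not in {{0, 1}}")
        entry: float | None = None
        if has_times:
            raw_t = getattr(row, "entry_time_s")
            if raw_t is not None and not (isinstance(raw_t, float) and np.isnan(raw_t)):
                if str(raw_t).strip() != "":
                    entry = float(raw_t)
        try:
            annotations.append(
                Annotation(
                    reader_id=str(getattr(row, "reader_id")),
                    case_id=str(getattr(row, "case_id")),
                    session=Session.coerce(getattr(row, "session")),
                    label=int(label),
                    entry_time_s=entry,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {idx}: {exc}") from None
    return annotations


def write_annotations(annotations: Iterable[Annotation], path: str | Path) -> None:
    path = Path(path)
    rows = [
        {
            "reader_id": a.reader_id,
            "case_id": a.case_id,
            "session": a.session.value,
            "label": a.label,
            "entry_time_s": "" if a.entry_time_s is None else repr(a.entry_time_s),
        }
        for a in annotations
    ]
    df = pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS))
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_truth(path: str | Path) -> list[CaseRecord]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    missing = [c for c in TRUTH_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if df["case_id"].duplicated().any():
        dupes = df.loc[df["case_id"].duplicated(), "case_id"].tolist()
        raise IntegrityError(f"{path}: duplicate case_id(s): {dupes[:5]}")
    records = []
    for _, row in df.iterrows():
        n_lesions = row.get("n_lesions")
        diameter = row.get("max_diameter_mm")
        records.append(
            CaseRecord(
                case_id=str(row["case_id"]),
                truth=int(row["truth"]),
                n_lesions=None if pd.isna(n_lesions) else int(n_lesions),
                max_diameter_mm=None if pd.isna(diameter) else float(diameter),
            )
        )
    return records


def write_truth(cases: Iterable[CaseRecord], path: str | Path) -> None:
    rows = [
        {
            "case_id": c.case_id,
            "truth": c.truth,
            "n_lesions": "" if c.n_lesions is None else c.n_lesions,
            "max_diameter_mm": "" if c.max_diameter_mm is None else repr(c.max_diameter_mm),
        }
        for c in cases
    ]
    path = Path(path)
    pd.DataFrame(rows, columns=["case_id", "truth", "n_lesions", "max_diameter_mm"]).to_csv(
        path, sep=_sep_for(path), index=False
    )


def read_readers(path: str | Path) -> list[ReaderProfile]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in ("reader_id", "specialty") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    readers = []
    for _, row in df.iterrows():
        group = row.get("group")
        years = row.get("years_experience", 0.0)
        readers.append(
            ReaderProfile(
                reader_id=str(row["reader_id"]),
                specialty=Specialty(str(row["specialty"])),
                group=None if pd.isna(group) else int(group),
                years_experience=0.0 if pd.isna(years) else float(years),
            )
        )
    return readers


def write_readers(readers: Iterable[ReaderProfile], path: str | Path) -> None:
    rows = [
        {
            "reader_id": r.reader_id,
            "specialty": r.specialty.value,
            "group": "" if r.group is None else r.group,
            "years_experience": r.years_experience,
        }
        for r in readers
    ]
    path = Path(path)
    pd.DataFrame(rows, columns=list(READER_COLUMNS)).to_csv(
        path, sep=_sep_for(path), index=False
    )


def build_matrix(
    annotations: Iterable[Annotation],
    session: Session | str,
    readers: Sequence[ReaderProfile] | Sequence[str],
    cases: Sequence[CaseRecord] | Sequence[str],
) -> AnnotationMatrix:
    """Assemble the cases x readers binary grid for one session.

    Row order follows ``cases``, column order follows ``readers``; every
    (reader, case) pair must be present exactly once for the session.
    """
    session = Session.coerce(session)
    reader_ids = tuple(
        r.reader_id if isinstance(r, ReaderProfile) else str(r) for r in readers
    )
    case_ids = tuple(c.case_id if isinstance(c, CaseRecord) else str(c) for c in cases)
    if not reader_ids or not case_ids:
        raise SchemaError("build_matrix requires non-empty readers and cases")
    row = {cid: i for i, cid in enumerate(case_ids)}
    col = {rid: j for j, rid in enumerate(reader_ids)}
    labels = np.full((len(case_ids), len(reader_ids)), -1, dtype=np.int8)
    for ann in annotations:
        if ann.session is not session:
            continue
        i = row.get(ann.case_id)
        j = col.get(ann.reader_id)
        if i is None or j is None:
            continue  # annotation outside the requested roster/case list
        if labels[i, j] != -1:
            raise IntegrityError(
                f"duplicate annotation for reader {ann.reader_id}, case "
                f"{ann.case_id}, session {session.value}"
            )
        labels[i, j] = ann.label
    if (labels == -1).any():
        ii, jj = np.argwhere(labels == -1)[0]
        raise CompletenessError(
            f"missing annotation for reader {reader_ids[jj]}, case "
            f"{case_ids[ii]}, session {session.value}"
        )
    return AnnotationMatrix(labels, case_ids, reader_ids, session)


def write_matrix(matrix: AnnotationMatrix, path: str | Path) -> None:
    """Matrix CSV: case_id index column, one column per reader."""
    df = pd.DataFrame(
        matrix.labels, index=list(matrix.case_ids), columns=list(matrix.reader_ids)
    )
    df.index.name = "case_id"
    df.to_csv(Path(path), sep=_sep_for(Path(path)))


def read_matrix(path: str | Path, session: Session | str) -> AnnotationMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col="case_id")
    return AnnotationMatrix(
        df.to_numpy(dtype=np.int8),
        tuple(str(c) for c in df.index),
        tuple(str(r) for r in df.columns),
        Session.coerce(session),
    )


def format_p(p: float) -> str:
    """Journal-style p-value: '<.001' floor, 3 decimals below .01, else 2."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value outside [0, 1]: {p}")
    if p < 0.001:
        return "<.001"
    if p < 0.0095:
        return f"{p:.3f}".lstrip("0")
    if p > 0.99:
        return ">.99"
    return f"{p:.2f}".lstrip("0")


def write_report(results, outdir: str | Path) -> dict[str, Path]:
    """Write the machine-readable tables and human summary for a run.

    ``results`` is a :class:`readerstudy.pipeline.StudyResults`.  Output is
    deterministic for a fixed config + seed: full precision in the CSVs,
    3-decimal proportions and journal-style p-values in the Markdown
    summary.
    """
    from .pipeline import StudyResults  # local import to avoid a cycle

    if not isinstance(results, StudyResults):
        raise TypeError("write_report expects a StudyResults bundle")
    if not results.comparisons:
        raise ValueError("refusing to write a report for an empty results bundle")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    paths: dict[str, Path] = {}

    metrics_df = results.metrics_frame()
    paths["metrics"] = outdir / "metrics.csv"
    metrics_df.to_csv(paths["metrics"], index=False)

    paths["per_reader"] = outdir / "per_reader.csv"
    results.per_reader.to_csv(paths["per_reader"], index=False)

    paths["kappa"] = outdir / "kappa.csv"
    results.kappa_frame().to_csv(paths["kappa"], index=False)

    paths["timing"] = outdir / "timing.csv"
    results.timing_frame().to_csv(paths["timing"], index=False)

    paths["hypotheses"] = outdir / "hypotheses.csv"
    results.hypotheses_frame().to_csv(paths["hypotheses"], index=False)

    paths["summary"] = outdir / "summary.md"
    paths["summary"].write_text(results.summary_markdown())
    return paths
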