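"""Core domain records for a multi-reader multi-case (MRMC) crossover study.

The study structure these types describe: every reader labels every case
twice — once per session (with and without AI augmentation) — and each
(reader, case, session) triple yields exactly one binary annotation with a
logged entry time.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .exceptions import SchemaError

#: Clinical significance threshold: an aneurysm counts toward case truth
#: only if its diameter exceeds this (mm).
SIGNIFICANT_DIAMETER_MM = 3.0


class Session(str, enum.Enum):
    """Reading condition: plain images or images with model ROI overlays."""

    UNAUGMENTED = "unaugmented"
    AUGMENTED = "augmented"

    @classmethod
    def coerce(cls, value: "Session | str") -> "Session":
        if isinstance(value, Session):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise ValueError(
                f"session must be one of {[s.value for s in cls]}, got {value!r}"
            ) from None


class Specialty(str, enum.Enum):
    RADIOLOGIST = "radiologist"
    NEUROSURGEON = "neurosurgeon"
    RESIDENT = "resident"


def _check_binary(label: object, context: str) -> int:
    try:
        value = float(label)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        raise ValueError(f"{context}: label {label!r} is not binary") from None
    if value not in (0.0, 1.0):
        raise ValueError(f"{context}: label {label!r} is not in {{0, 1}}")
    return int(value)


@dataclass(frozen=True)
class CaseRecord:
    """Ground truth for one examination.

    truth=1 means the case contains at least one clinically significant
    aneurysm (diameter > 3 mm).  ``n_lesions`` and ``max_diameter_mm`` are
    known for simulated cases and may be None for external truth tables.
    """

    case_id: str
    truth: int
    n_lesions: int | None = None
    max_diameter_mm: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "truth", _check_binary(self.truth, f"case {self.case_id}"))
        if self.n_lesions is not None:
            if self.n_lesions < 0:
                raise ValueError(f"case {self.case_id}: n_lesions must be >= 0")
            if (self.truth == 1) != (self.n_lesions >= 1):
                raise ValueError(
                    f"case {self.case_id}: truth={self.truth} inconsistent with "
                    f"n_lesions={self.n_lesions}"
                )
        if self.truth == 1 and self.max_diameter_mm is not None:
            if not self.max_diameter_mm > SIGNIFICANT_DIAMETER_MM:
                raise ValueError(
                    f"case {self.case_id}: significant aneurysm requires diameter "
                    f"> {SIGNIFICANT_DIAMETER_MM} mm, got {self.max_diameter_mm}"
                )


@dataclass(frozen=True)
class Annotation:
    """One reader's binary call on one case in one session."""

    reader_id: str
    case_id: str
    session: Session
    label: int
    entry_time_s: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "session", Session.coerce(self.session))
        ctx = f"annotation ({self.reader_id}, {self.case_id}, {self.session.value})"
        object.__setattr__(self, "label", _check_binary(self.label, ctx))
        if self.entry_time_s is not None:
            if not np.isfinite(self.entry_time_s) or self.entry_time_s < 0:
                raise ValueError(f"{ctx}: entry_time_s must be finite and >= 0")


@dataclass(frozen=True)
class ReaderProfile:
    """A study reader: specialty, crossover group and reading order."""

    reader_id: str
    specialty: Specialty = Specialty.RADIOLOGIST
    group: int | None = None
    years_experience: float = 0.0
    case_order: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "specialty", Specialty(self.specialty))
        if self.group is not None and self.group not in (1, 2):
            raise ValueError(f"reader {self.reader_id}: group must be 1 or 2")

    @property
    def is_radiologist(self) -> bool:
        return self.specialty is Specialty.RADIOLOGIST

    def with_assignment(
        self, group: int, case_order: Sequence[str]
    ) -> "ReaderProfile":
        return replace(self, group=group, case_order=tuple(case_order))


def radiologists(readers: Iterable[ReaderProfile]) -> list[ReaderProfile]:
    """The board-certified radiologist subset used in the sensitivity analysis."""
    return [r for r in readers if r.is_radiologist]


@dataclass(frozen=True)
class AnnotationMatrix:
    """Complete cases x readers binary label grid for one session.

    Rows follow ``case_ids``, columns follow ``reader_ids``.
    """

    labels: np.ndarray
    case_ids: tuple[str, ...]
    reader_ids: tuple[str, ...]
    session: Session

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int8)
        if labels.ndim != 2:
            raise SchemaError("annotation matrix must be 2-D (cases x readers)")
        if labels.shape != (len(self.case_ids), len(self.reader_ids)):
            raise SchemaError(
                f"matrix shape {labels.shape} does not match "
                f"{len(self.case_ids)} cases x {len(self.reader_ids)} readers"
            )
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("annotation matrix entries must be binary")
        labels.setflags(write=False)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "case_ids", tuple(self.case_ids))
        object.__setattr__(self, "reader_ids", tuple(self.reader_ids))
        object.__setattr__(self, "session", Session.coerce(self.session))

    @property
    def n_cases(self) -> int:
        return self.labels.shape[0]

    @property
    def n_readers(self) -> int:
        return self.labels.shape[1]

    def subset_readers(self, reader_ids: Sequence[str]) -> "AnnotationMatrix":
        """Column subset (e.g. radiologists only), preserving case order."""
        missing = [r for r in reader_ids if r not in self.reader_ids]
        if missing:
            raise SchemaError(f"readers not in matrix: {missing}")
        idx = [self.reader_ids.index(r) for r in reader_ids]
        return AnnotationMatrix(
            self.labels[:, idx], self.case_ids, tuple(reader_ids), self.session
        )
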