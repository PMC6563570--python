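"""Study configuration: design parameters, calibration targets, analysis knobs.

Defaults reproduce the structure of the study the package models: 115 test
cases at 50% aneurysm prevalence, 8 readers (6 radiologists, 1 neurosurgeon,
1 resident) split into 2 crossover groups with a 14-day washout, 10 000
permutations for the agreement test, and an 8-hypothesis Benjamini-Hochberg
family.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .exceptions import SchemaError

#: The registered hypothesis family of a full run: the three accuracy metrics
#: for all clinicians and for the radiologist subset, plus reading time and
#: interrater agreement.  Order is the registration order, not significance.
DEFAULT_HYPOTHESIS_FAMILY: tuple[str, ...] = (
    "sensitivity.all",
    "specificity.all",
    "accuracy.all",
    "sensitivity.radiologists",
    "specificity.radiologists",
    "accuracy.radiologists",
    "time.all",
    "kappa.all",
)


@dataclass
class StudyConfig:
    """Parameters driving both simulation and analysis of one study."""

    # ---- design ----
    n_cases: int = 115
    prevalence: float = 0.5
    n_readers: int = 8
    n_radiologists: int = 6
    washout_days: int = 14

    # ---- generative calibration targets (session marginals) ----
    sens_unaugmented: float = 0.831
    sens_augmented: float = 0.890
    spec_unaugmented: float = 0.960
    spec_augmented: float = 0.975
    #: shared case-difficulty coupling tau (probit scale); drives inter-reader
    #: correlation and hence the agreement level
    case_coupling: float = 1.75
    #: half-range of the symmetric per-reader operating-point offsets
    reader_spread: float = 0.25

    # ---- reading-time model ----
    time_median_s: float = 50.0
    time_mean_s: float = 57.0
    p_interruption: float = 0.02
    interruption_min_s: float = 300.0
    interruption_max_s: float = 1200.0

    # ---- analysis ----
    n_permutations: int = 10_000
    seed: int = 0
    alpha: float = 0.05
    kappa_variant: str = "conger"
    permutation_unit: str = "case"
    trim_k: int = 5
    hypothesis_family: tuple[str, ...] = DEFAULT_HYPOTHESIS_FAMILY

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie strictly between 0 and 1")
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if self.n_readers % 2 != 0:
            raise ValueError(
                "n_readers must be even for the balanced 2-group crossover"
            )
        if not 0 <= self.n_radiologists <= self.n_readers:
            raise ValueError("n_radiologists must be between 0 and n_readers")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0.0 <= self.p_interruption <= 1.0:
            raise ValueError("p_interruption must lie in [0, 1]")
        if self.case_coupling < 0:
            raise ValueError("case_coupling must be >= 0")
        for name in ("sens_unaugmented", "sens_augmented",
                     "spec_unaugmented", "spec_augmented"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie strictly between 0 and 1")
        if self.kappa_variant not in ("conger", "fleiss"):
            raise ValueError("kappa_variant must be 'conger' or 'fleiss'")
        if self.permutation_unit not in ("case", "cell"):
            raise ValueError("permutation_unit must be 'case' or 'cell'")
        self.hypothesis_family = tuple(self.hypothesis_family)

    # ---- serialisation ----

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["hypothesis_family"] = list(self.hypothesis_family)
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "StudyConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        """Load a flat YAML or JSON config (format chosen by extension)."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise SchemaError(f"config {path} did not parse to a mapping")
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def canonical_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()
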