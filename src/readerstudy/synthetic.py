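"""Synthetic MRMC crossover cohort with the statistical structure the
analysis assumes.

Generative model (probit latent-threshold):

* Each case carries a latent difficulty shared by all readers and both
  sessions.  For a positive case with difficulty d ~ N(0,1), reader r in
  session s calls it positive with probability
  Phi(a_r + delta_sens*[s=augmented] - tau*d); for a negative case with
  latent e ~ N(0,1) the false-positive probability is
  Phi(b_r + delta_spec*[s=augmented] + tau*e) with delta_spec <= 0.
  Conditional on the latents, reader draws are independent.
* tau >= 0 couples readers through case difficulty and therefore sets the
  interrater agreement level; tau = 0 decouples them.
* A single per-reader operating-point offset (symmetric, mean-zero across
  the roster) shifts a_r and b_r together, mimicking liberal/conservative
  criterion placement.
* Reading durations are lognormal (median ~50 s, mean ~57 s by default)
  with a small probability of a long uniform "interruption" added, giving
  the 5-longest/5-shortest trimming rule something to remove; entry times
  are the cumulative sums along each reader's case order.

All randomness flows from one seed; each stage draws from an independent
substream derived by a fixed offset, so any stage is reproducible alone.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .config import StudyConfig
from .exceptions import SchemaError
from .records import (
    Annotation,
    AnnotationMatrix,
    CaseRecord,
    ReaderProfile,
    Session,
    Specialty,
)

# Aneurysm size strata (mm) and their frequencies in the source cohort
# (3-7, 7-12, 12-24, >=24 mm).
_DIAMETER_STRATA: tuple[tuple[float, float], ...] = (
    (3.0, 7.0),
    (7.0, 12.0),
    (12.0, 24.0),
    (24.0, 40.0),
)
_DIAMETER_WEIGHTS = np.array([148, 108, 61, 11], dtype=float)
#: fraction of positive cases carrying 2+ lesions (20 of 328)
_MULTI_LESION_RATE = 20 / 328

# fixed substream offsets off the global seed
_STREAM_TRUTH = 1
_STREAM_CROSSOVER = 2
_STREAM_LABELS = 3
_STREAM_TIMES = 4
_STREAM_SEGMENTATION = 5


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclass(frozen=True)
class GenerativeParams:
    """Reader propensities and effect sizes on the probit scale."""

    hit_propensity: np.ndarray  # a_r, one per reader
    false_alarm_propensity: np.ndarray  # b_r, one per reader
    delta_sens: float
    delta_spec: float  # <= 0: augmentation lowers false positives
    case_coupling: float  # tau >= 0
    time_log_median: float = math.log(50.0)
    time_log_sd: float = math.sqrt(2.0 * math.log(57.0 / 50.0))
    p_interruption: float = 0.02
    interruption_range: tuple[float, float] = (300.0, 1200.0)

    def __post_init__(self) -> None:
        a = np.asarray(self.hit_propensity, dtype=float)
        b = np.asarray(self.false_alarm_propensity, dtype=float)
        if a.ndim != 1 or a.shape != b.shape:
            raise ValueError("propensity arrays must be 1-D and of equal length")
        object.__setattr__(self, "hit_propensity", a)
        object.__setattr__(self, "false_alarm_propensity", b)
        if self.case_coupling < 0:
            raise ValueError("case_coupling must be >= 0")
        if not 0.0 <= self.p_interruption <= 1.0:
            raise ValueError("p_interruption must lie in [0, 1]")
        if self.delta_spec > 0:
            raise ValueError("delta_spec must be <= 0 (augmentation reduces FPs)")
        lo, hi = self.interruption_range
        if not 0 <= lo <= hi:
            raise ValueError("interruption_range must be ordered and non-negative")

    @property
    def n_readers(self) -> int:
        return self.hit_propensity.size

    @classmethod
    def from_targets(
        cls,
        n_readers: int,
        sens_unaugmented: float,
        sens_augmented: float,
        spec_unaugmented: float,
        spec_augmented: float,
        case_coupling: float,
        reader_spread: float = 0.25,
        time_median_s: float = 50.0,
        time_mean_s: float = 57.0,
        p_interruption: float = 0.02,
        interruption_range: tuple[float, float] = (300.0, 1200.0),
    ) -> "GenerativeParams":
        """Calibrate propensities so session marginals hit the targets.

        Integrating the case latent out of Phi(a - tau*d) gives the marginal
        Phi(a / sqrt(1 + tau^2)), so a = Phi^-1(target) * sqrt(1 + tau^2),
        and likewise for the false-alarm side with target 1 - specificity.
        Per-reader offsets are a symmetric mean-zero grid of half-range
        ``reader_spread`` applied to both propensities, so the roster-average
        marginals stay at the targets to second order.
        """
        scale = math.sqrt(1.0 + case_coupling**2)
        a = norm.ppf(sens_unaugmented) * scale
        b = norm.ppf(1.0 - spec_unaugmented) * scale
        d_sens = (norm.ppf(sens_augmented) - norm.ppf(sens_unaugmented)) * scale
        d_spec = (norm.ppf(1.0 - spec_augmented) - norm.ppf(1.0 - spec_unaugmented)) * scale
        offsets = (
            np.linspace(-1.0, 1.0, n_readers) * reader_spread
            if n_readers > 1
            else np.zeros(1)
        )
        if time_mean_s <= time_median_s:
            raise ValueError("lognormal durations require mean > median")
        return cls(
            hit_propensity=a + offsets,
            false_alarm_propensity=b + offsets,
            delta_sens=d_sens,
            delta_spec=d_spec,
            case_coupling=case_coupling,
            time_log_median=math.log(time_median_s),
            time_log_sd=math.sqrt(2.0 * math.log(time_mean_s / time_median_s)),
            p_interruption=p_interruption,
            interruption_range=interruption_range,
        )

    @classmethod
    def from_config(cls, config: StudyConfig) -> "GenerativeParams":
        return cls.from_targets(
            n_readers=config.n_readers,
            sens_unaugmented=config.sens_unaugmented,
            sens_augmented=config.sens_augmented,
            spec_unaugmented=config.spec_unaugmented,
            spec_augmented=config.spec_augmented,
            case_coupling=config.case_coupling,
            reader_spread=config.reader_spread,
            time_median_s=config.time_median_s,
            time_mean_s=config.time_mean_s,
            p_interruption=config.p_interruption,
            interruption_range=(config.interruption_min_s, config.interruption_max_s),
        )


def simulate_truth(n_cases: int, prevalence: float, seed: int = 0) -> list[CaseRecord]:
    """Stratified truth table: a deterministic positive count, shuffled order.

    The positive count is round-half-up(n_cases * prevalence) — mirroring a
    stratified 50/50 test-set construction, not Bernoulli sampling — so 115
    cases at prevalence 0.5 yield exactly 58 positives.  Positive cases get
    a max diameter drawn from the size strata and a lesion count of 1 or 2.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie strictly between 0 and 1")
    rng = _rng(seed, _STREAM_TRUTH)
    n_pos = int(math.floor(n_cases * prevalence + 0.5))
    truths = np.zeros(n_cases, dtype=int)
    truths[:n_pos] = 1
    rng.shuffle(truths)
    width = max(3, len(str(n_cases)))
    probs = _DIAMETER_WEIGHTS / _DIAMETER_WEIGHTS.sum()
    records: list[CaseRecord] = []
    for i, truth in enumerate(truths):
        case_id = f"case{i + 1:0{width}d}"
        if truth:
            stratum = rng.choice(len(_DIAMETER_STRATA), p=probs)
            lo, hi = _DIAMETER_STRATA[stratum]
            diameter = float(max(rng.uniform(lo, hi), np.nextafter(lo, hi)))
            n_lesions = 2 if rng.random() < _MULTI_LESION_RATE else 1
            records.append(CaseRecord(case_id, 1, n_lesions, diameter))
        else:
            records.append(CaseRecord(case_id, 0, 0, None))
    return records


def default_roster(config: StudyConfig) -> list[ReaderProfile]:
    """Roster matching the study composition: radiologists first, then a
    neurosurgeon and a resident filling the remaining slots."""
    readers: list[ReaderProfile] = []
    n_rad = config.n_radiologists
    exp = np.linspace(3.0, 12.0, n_rad) if n_rad > 1 else np.array([7.0])[:n_rad]
    for i in range(n_rad):
        readers.append(
            ReaderProfile(f"R{i + 1}", Specialty.RADIOLOGIST,
                          years_experience=float(exp[i]))
        )
    extras = [(Specialty.NEUROSURGEON, 2.0), (Specialty.RESIDENT, 1.5)]
    for j in range(config.n_readers - n_rad):
        spec, years = extras[j % len(extras)]
        readers.append(ReaderProfile(f"R{n_rad + j + 1}", spec, years_experience=years))
    return readers


def assign_crossover(
    readers: Sequence[ReaderProfile],
    cases: Sequence[CaseRecord],
    seed: int = 0,
) -> list[ReaderProfile]:
    """Assign crossover groups and per-reader reading orders.

    Readers split randomly and equally into groups 1 and 2 (group 1 reads
    unaugmented first).  Within each group, half receive a fixed random case
    order and the other half its exact reversal.
    """
    readers = list(readers)
    if len(readers) < 2:
        raise SchemaError("crossover assignment requires at least 2 readers")
    if len(readers) % 2 != 0:
        raise SchemaError("crossover design is balanced: reader count must be even")
    rng = _rng(seed, _STREAM_CROSSOVER)
    case_ids = [c.case_id for c in cases]
    perm = rng.permutation(len(readers))
    half = len(readers) // 2
    assigned: dict[int, ReaderProfile] = {}
    for group, member_idx in ((1, perm[:half]), (2, perm[half:])):
        order = list(rng.permutation(case_ids))
        for j, idx in enumerate(member_idx):
            reader_order = order if j < (len(member_idx) + 1) // 2 else order[::-1]
            assigned[idx] = readers[idx].with_assignment(group, reader_order)
    return [assigned[i] for i in range(len(readers))]


def simulate_annotation_matrices(
    cases: Sequence[CaseRecord],
    readers: Sequence[ReaderProfile],
    params: GenerativeParams,
    seed: int = 0,
) -> dict[Session, AnnotationMatrix]:
    """Draw both sessions' label grids from the probit latent model.

    Case latents are drawn once and shared across readers and sessions, so
    the same hard cases are missed in both arms; reader draws are
    independent given the latents.
    """
    if len(readers) == 0:
        raise SchemaError("empty reader roster")
    if len(cases) == 0:
        raise SchemaError("empty case list")
    if params.n_readers != len(readers):
        raise SchemaError(
            f"params calibrated for {params.n_readers} readers, roster has {len(readers)}"
        )
    rng = _rng(seed, _STREAM_LABELS)
    truth = np.array([c.truth for c in cases])
    latent = rng.standard_normal(len(cases))
    tau = params.case_coupling
    out: dict[Session, AnnotationMatrix] = {}
    case_ids = tuple(c.case_id for c in cases)
    reader_ids = tuple(r.reader_id for r in readers)
    for session in Session:
        augmented = session is Session.AUGMENTED
        a = params.hit_propensity + (params.delta_sens if augmented else 0.0)
        b = params.false_alarm_propensity + (params.delta_spec if augmented else 0.0)
        # positives: difficulty lowers detection; negatives: latent raises FPs
        eta_pos = a[None, :] - tau * latent[:, None]
        eta_neg = b[None, :] + tau * latent[:, None]
        p = norm.cdf(np.where(truth[:, None] == 1, eta_pos, eta_neg))
        labels = (rng.random(p.shape) < p).astype(np.int8)
        out[session] = AnnotationMatrix(labels, case_ids, reader_ids, session)
    return out


def simulate_annotations(
    cases: Sequence[CaseRecord],
    readers: Sequence[ReaderProfile],
    params: GenerativeParams,
    seed: int = 0,
) -> list[Annotation]:
    """Annotation records for both sessions (entry times not yet filled)."""
    matrices = simulate_annotation_matrices(cases, readers, params, seed)
    annotations: list[Annotation] = []
    for session, matrix in matrices.items():
        for i, case_id in enumerate(matrix.case_ids):
            for j, reader_id in enumerate(matrix.reader_ids):
                annotations.append(
                    Annotation(reader_id, case_id, session, int(matrix.labels[i, j]))
                )
    return annotations


def simulate_times(
    annotations: Sequence[Annotation],
    readers: Sequence[ReaderProfile],
    params: GenerativeParams,
    seed: int = 0,
) -> list[Annotation]:
    """Fill entry times: lognormal durations with rare long interruptions,
    accumulated along each reader's case order (same order in both sessions)."""
    rng = _rng(seed, _STREAM_TIMES)
    by_reader = {r.reader_id: r for r in readers}
    for r in readers:
        if r.case_order is None:
            raise SchemaError(f"reader {r.reader_id} has no reading order assigned")
    index: dict[tuple[str, str, Session], Annotation] = {}
    for ann in annotations:
        index[(ann.reader_id, ann.case_id, ann.session)] = ann
    lo, hi = params.interruption_range
    out: list[Annotation] = []
    for reader in readers:
        order = reader.case_order or ()
        for session in Session:
            n = len(order)
            durations = rng.lognormal(params.time_log_median, params.time_log_sd, n)
            if params.p_interruption > 0 and hi > lo:
                hit = rng.random(n) < params.p_interruption
                durations = durations + hit * rng.uniform(lo, hi, n)
            entry = np.cumsum(durations)
            for case_id, t in zip(order, entry):
                key = (reader.reader_id, case_id, session)
                if key not in index:
                    raise SchemaError(f"no annotation for {key}")
                ann = index.pop(key)
                out.append(
                    Annotation(ann.reader_id, ann.case_id, ann.session,
                               ann.label, float(t))
                )
    if index:
        raise SchemaError(
            f"{len(index)} annotations not covered by any reading order"
        )
    return out


def simulate_segmentation(
    case: CaseRecord,
    shape: tuple[int, int, int] = (16, 32, 32),
    seed: int = 0,
    background_max: float = 0.45,
    peak_range: tuple[float, float] = (0.7, 0.95),
    voxel_mm: float = 1.0,
) -> np.ndarray:
    """Toy voxel-probability volume standing in for a segmentation model.

    Negative cases get low-probability noise everywhere (< 0.5); positive
    cases additionally get one contiguous Gaussian blob whose peak exceeds
    0.5 and whose width scales with the lesion diameter, so the at-least-one-
    voxel binarisation rule recovers the truth by construction.
    """
    if len(shape) != 3 or any(s < 1 for s in shape):
        raise ValueError("shape must be three positive integers")
    rng = _rng(seed, _STREAM_SEGMENTATION)
    volume = rng.uniform(0.0, background_max, size=shape)
    if case.truth == 1:
        diameter = case.max_diameter_mm or 5.0
        radius_vox = float(np.clip(diameter / (2.0 * voxel_mm), 1.0, min(shape) / 3.0))
        center = np.array(
            [rng.integers(low=int(radius_vox), high=max(int(radius_vox) + 1, s - int(radius_vox)))
             for s in shape]
        )
        grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
        dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
        sigma = radius_vox / 2.0
        peak = rng.uniform(*peak_range)
        blob = peak * np.exp(-dist2 / (2.0 * sigma**2))
        volume = np.maximum(volume, blob)
    return np.clip(volume, 0.0, 1.0)


def simulate_study(
    config: StudyConfig, seed: int | None = None
) -> tuple[list[CaseRecord], list[ReaderProfile], list[Annotation]]:
    """End-to-end draw of one synthetic study from a configuration."""
    seed = config.seed if seed is None else seed
    cases = simulate_truth(config.n_cases, config.prevalence, seed)
    readers = assign_crossover(default_roster(config), cases, seed)
    params = GenerativeParams.from_config(config)
    annotations = simulate_annotations(cases, readers, params, seed)
    annotations = simulate_times(annotations, readers, params, seed)
    return cases, readers, annotations
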