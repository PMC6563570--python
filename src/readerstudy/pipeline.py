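"""End-to-end study analysis: simulate (optionally), analyze, report.

``analyze_study`` consumes annotations + truth + roster and produces the
full statistical read-out: per-reader and microaveraged accuracy metrics
with Wilson intervals, paired one-tailed t tests for all clinicians and for
the radiologist subset, trimmed time-to-diagnosis summaries, exact Fleiss
kappa per session with the case-swap permutation test, and
Benjamini-Hochberg adjusted p-values over the registered hypothesis family.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__ as _version
from .agreement import KappaResult, PermutationResult, kappa_difference_permutation, fleiss_exact_kappa
from .config import StudyConfig
from .exceptions import ReaderStudyError, SchemaError
from .inference import (
    HypothesisRecord,
    PairedTestResult,
    TimingSummary,
    bh_adjust,
    diagnosis_durations,
    mean_time_ci,
    paired_one_tailed_t,
    trim_durations,
)
from .io import format_p, write_annotations, write_readers, write_report, write_truth
from .metrics import (
    METRICS,
    ConfusionCounts,
    ProportionCI,
    confusion,
    metric,
    metric_with_ci,
    microaverage,
)
from .records import Annotation, AnnotationMatrix, CaseRecord, ReaderProfile, Session, radiologists
from .io import build_matrix
from .synthetic import simulate_study


@dataclass(frozen=True)
class MetricComparison:
    """One Table-row: a metric, a population, both sessions, and the test."""

    metric: str
    population: str  # "all" or "radiologists"
    micro_unaugmented: ProportionCI
    micro_augmented: ProportionCI
    test: PairedTestResult


@dataclass
class StudyResults:
    """Complete analysis bundle for one study run."""

    config: StudyConfig
    seed: int
    per_reader: pd.DataFrame
    comparisons: list[MetricComparison]
    kappa: dict[tuple[str, str], KappaResult]  # (population, session) -> result
    kappa_permutation: dict[str, PermutationResult]
    timing: list[TimingSummary]
    timing_pooled: dict[str, TimingSummary]  # session -> pooled summary
    timing_test: PairedTestResult | None
    hypotheses: list[HypothesisRecord] = field(default_factory=list)

    # ---- tabular views ----

    def metrics_frame(self) -> pd.DataFrame:
        padj = {h.id: h.p_adjusted for h in self.hypotheses}
        rows = []
        for comp in self.comparisons:
            hyp_id = f"{comp.metric}.{comp.population}"
            rows.append(
                {
                    "metric": comp.metric,
                    "population": comp.population,
                    "micro_unaugmented": comp.micro_unaugmented.estimate,
                    "unaug_ci_lower": comp.micro_unaugmented.lower,
                    "unaug_ci_upper": comp.micro_unaugmented.upper,
                    "micro_augmented": comp.micro_augmented.estimate,
                    "aug_ci_lower": comp.micro_augmented.lower,
                    "aug_ci_upper": comp.micro_augmented.upper,
                    "mean_increase": comp.test.mean_diff,
                    "increase_ci_lower": comp.test.ci_lower,
                    "increase_ci_upper": comp.test.ci_upper,
                    "t_stat": comp.test.t_stat,
                    "df": comp.test.df,
                    "p_unadjusted": comp.test.p_one_tailed,
                    "p_adjusted": padj.get(hyp_id),
                }
            )
        return pd.DataFrame(rows)

    def kappa_frame(self) -> pd.DataFrame:
        rows = []
        for (population, session), res in sorted(self.kappa.items()):
            perm = self.kappa_permutation.get(population)
            rows.append(
                {
                    "population": population,
                    "session": session,
                    "kappa": res.kappa,
                    "observed_agreement": res.observed_agreement,
                    "expected_agreement": res.expected_agreement,
                    "n_cases": res.n_cases,
                    "n_raters": res.n_raters,
                    "variant": res.variant,
                    "perm_diff": perm.observed_diff if perm else None,
                    "perm_p": perm.p_value if perm else None,
                    "perm_B": perm.n_permutations if perm else None,
                }
            )
        return pd.DataFrame(rows)

    def timing_frame(self) -> pd.DataFrame:
        rows = [
            {
                "reader_id": t.reader_id,
                "session": t.session.value,
                "n_raw": t.n_raw,
                "n_used": t.n_used,
                "mean_s": t.mean_s,
                "ci_lower_s": t.ci_lower_s,
                "ci_upper_s": t.ci_upper_s,
            }
            for t in self.timing + list(self.timing_pooled.values())
        ]
        return pd.DataFrame(rows)

    def hypotheses_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id": h.id,
                    "p_unadjusted": h.p_unadjusted,
                    "p_adjusted": h.p_adjusted,
                    "family_size": h.family_size,
                }
                for h in self.hypotheses
            ]
        )

    def summary_markdown(self) -> str:
        """Human-readable summary mirroring the machine-readable tables."""
        lines = [
            "# Reader study analysis",
            "",
            f"- readers: {self.config.n_readers} ({self.config.n_radiologists} radiologists)",
            f"- cases: {self.config.n_cases} at prevalence {self.config.prevalence}",
            f"- seed: {self.seed}; permutations B: {self.config.n_permutations}",
            f"- hypothesis family (m={len(self.hypotheses)}): "
            + ", ".join(h.id for h in self.hypotheses),
            "",
            "## Performance metrics (microaverage, 95% Wilson CI)",
            "",
            "| Metric | Population | Without augmentation | With augmentation | "
            "Mean increase (95% CI) | P | Adjusted P |",
            "|---|---|---|---|---|---|---|",
        ]
        padj = {h.id: h.p_adjusted for h in self.hypotheses}
        for comp in self.comparisons:
            u, a, t = comp.micro_unaugmented, comp.micro_augmented, comp.test
            pa = padj.get(f"{comp.metric}.{comp.population}")
            lines.append(
                f"| {comp.metric} | {comp.population} "
                f"| {u.estimate:.3f} ({u.lower:.3f} to {u.upper:.3f}) "
                f"| {a.estimate:.3f} ({a.lower:.3f} to {a.upper:.3f}) "
                f"| {t.mean_diff:.3f} ({t.ci_lower:.3f} to {t.ci_upper:.3f}) "
                f"| {format_p(t.p_one_tailed)} "
                f"| {format_p(pa) if pa is not None else 'n/a'} |"
            )
        lines += ["", "## Interrater agreement (exact Fleiss kappa)", ""]
        for (population, session), res in sorted(self.kappa.items()):
            lines.append(f"- {population}, {session}: kappa = {res.kappa:.3f}")
        for population, perm in self.kappa_permutation.items():
            adj = padj.get(f"kappa.{population}")
            lines.append(
                f"- {population}: difference {perm.observed_diff:.3f}, "
                f"permutation P = {format_p(perm.p_value)}"
                + (f", adjusted P = {format_p(adj)}" if adj is not None else "")
                + f" (B = {perm.n_permutations})"
            )
        if self.timing_pooled:
            lines += ["", "## Time to diagnosis (trimmed, pooled across readers)", ""]
            for session, t in sorted(self.timing_pooled.items()):
                lines.append(
                    f"- {session}: mean {t.mean_s:.2f} s "
                    f"(95% CI, {t.ci_lower_s:.2f}-{t.ci_upper_s:.2f}; n = {t.n_used})"
                )
            if self.timing_test is not None:
                tt = self.timing_test
                adj = padj.get("time.all")
                lines.append(
                    f"- mean decrease with augmentation: {-tt.mean_diff:.2f} s "
                    f"(95% CI, {-tt.ci_upper:.2f} to {-tt.ci_lower:.2f}), "
                    f"P = {format_p(tt.p_one_tailed)}"
                    + (f", adjusted P = {format_p(adj)}" if adj is not None else "")
                )
        return "\n".join(lines) + "\n"

    def results_hash(self) -> str:
        h = hashlib.sha256()
        for frame in (
            self.metrics_frame(),
            self.kappa_frame(),
            self.timing_frame(),
            self.hypotheses_frame(),
            self.per_reader,
        ):
            h.update(frame.to_csv(index=False).encode())
        return h.hexdigest()


def _per_reader_counts(
    annotations: Sequence[Annotation],
    cases: Sequence[CaseRecord],
    readers: Sequence[ReaderProfile],
) -> dict[tuple[str, Session], ConfusionCounts]:
    by_key: dict[tuple[str, Session], dict[str, int]] = {}
    for ann in annotations:
        by_key.setdefault((ann.reader_id, ann.session), {})[ann.case_id] = ann.label
    counts = {}
    for reader in readers:
        for session in Session:
            labels = by_key.get((reader.reader_id, session))
            if labels is None:
                raise SchemaError(
                    f"no annotations for reader {reader.reader_id}, "
                    f"session {session.value}"
                )
            counts[(reader.reader_id, session)] = confusion(labels, cases)
    return counts


def analyze_study(
    annotations: Sequence[Annotation],
    cases: Sequence[CaseRecord],
    readers: Sequence[ReaderProfile],
    config: StudyConfig | None = None,
    include_timing: bool | None = None,
) -> StudyResults:
    """Run the complete statistical analysis on one study's annotations.

    ``include_timing`` defaults to automatic: timing is analyzed when every
    annotation carries an entry time.
    """
    config = config or StudyConfig()
    counts = _per_reader_counts(annotations, cases, readers)
    rad_ids = [r.reader_id for r in radiologists(readers)]
    all_ids = [r.reader_id for r in readers]

    per_reader_rows = []
    for reader in readers:
        for session in Session:
            c = counts[(reader.reader_id, session)]
            row = {
                "reader_id": reader.reader_id,
                "specialty": reader.specialty.value,
                "session": session.value,
                "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn,
            }
            for m in METRICS:
                row[m] = metric(c, m)
            per_reader_rows.append(row)
    per_reader = pd.DataFrame(per_reader_rows)

    populations = {"all": all_ids}
    if len(rad_ids) >= 2 and rad_ids != all_ids:
        populations["radiologists"] = rad_ids

    comparisons: list[MetricComparison] = []
    p_unadjusted: dict[str, float] = {}
    for population, ids in populations.items():
        for m in METRICS:
            pooled = {
                s: microaverage(counts[(r, s)] for r in ids) for s in Session
            }
            values = {
                s: [metric(counts[(r, s)], m) for r in ids] for s in Session
            }
            test = paired_one_tailed_t(
                values[Session.UNAUGMENTED], values[Session.AUGMENTED],
                direction="greater",
            )
            comparisons.append(
                MetricComparison(
                    metric=m,
                    population=population,
                    micro_unaugmented=metric_with_ci(pooled[Session.UNAUGMENTED], m),
                    micro_augmented=metric_with_ci(pooled[Session.AUGMENTED], m),
                    test=test,
                )
            )
            p_unadjusted[f"{m}.{population}"] = test.p_one_tailed

    # ---- agreement ----
    matrices = {
        s: build_matrix(annotations, s, readers, cases) for s in Session
    }
    kappa: dict[tuple[str, str], KappaResult] = {}
    kappa_perm: dict[str, PermutationResult] = {}
    for population, ids in populations.items():
        mats = {
            s: matrices[s] if ids == all_ids else matrices[s].subset_readers(ids)
            for s in Session
        }
        for s in Session:
            kappa[(population, s.value)] = fleiss_exact_kappa(
                mats[s], variant=config.kappa_variant
            )
        kappa_perm[population] = kappa_difference_permutation(
            mats[Session.AUGMENTED],
            mats[Session.UNAUGMENTED],
            n_permutations=config.n_permutations,
            seed=config.seed + 101,  # analysis stream, independent of simulation
            variant=config.kappa_variant,
            unit=config.permutation_unit,
        )
    p_unadjusted["kappa.all"] = kappa_perm["all"].p_value

    # ---- timing ----
    if include_timing is None:
        include_timing = all(a.entry_time_s is not None for a in annotations)
    timing: list[TimingSummary] = []
    timing_pooled: dict[str, TimingSummary] = {}
    timing_test: PairedTestResult | None = None
    if include_timing:
        by_key: dict[tuple[str, Session], list[Annotation]] = {}
        for ann in annotations:
            by_key.setdefault((ann.reader_id, ann.session), []).append(ann)
        trimmed: dict[tuple[str, Session], "object"] = {}
        for (reader_id, session), anns in by_key.items():
            durations = diagnosis_durations(anns)
            kept = trim_durations(durations, k=config.trim_k)
            trimmed[(reader_id, session)] = kept
            timing.append(
                mean_time_ci(kept, reader_id=reader_id, session=session,
                             n_raw=durations.size)
            )
        timing.sort(key=lambda t: (t.reader_id, t.session.value))
        for session in Session:
            pooled_durations = [
                d for (r, s), kept in trimmed.items() if s is session for d in kept
            ]
            timing_pooled[session.value] = mean_time_ci(
                pooled_durations, reader_id="pooled", session=session
            )
        means = {
            s: [float(trimmed[(r, s)].mean()) for r in all_ids] for s in Session
        }
        timing_test = paired_one_tailed_t(
            means[Session.UNAUGMENTED], means[Session.AUGMENTED], direction="less"
        )
        p_unadjusted["time.all"] = timing_test.p_one_tailed

    # ---- multiplicity ----
    family = [h for h in config.hypothesis_family if h in p_unadjusted]
    hypotheses = bh_adjust([p_unadjusted[h] for h in family], ids=family) if family else []

    return StudyResults(
        config=config,
        seed=config.seed,
        per_reader=per_reader,
        comparisons=comparisons,
        kappa=kappa,
        kappa_permutation=kappa_perm,
        timing=timing,
        timing_pooled=timing_pooled,
        timing_test=timing_test,
        hypotheses=hypotheses,
    )


def run_full_study(
    config: StudyConfig, outdir: str | Path | None = None, seed: int | None = None
) -> StudyResults:
    """Simulate one study under ``config`` and run the complete analysis.

    When ``outdir`` is given, writes the simulated tables, report files and
    a run manifest (config hash, seed, versions, results hash).
    """
    if seed is not None:
        config = StudyConfig.from_dict({**config.to_dict(), "seed": seed})
    cases, readers, annotations = simulate_study(config)
    results = analyze_study(annotations, cases, readers, config)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_truth(cases, outdir / "truth.csv")
        write_readers(readers, outdir / "readers.csv")
        write_annotations(annotations, outdir / "annotations.csv")
        paths = write_report(results, outdir)
        manifest = {
            "package_version": _version,
            "config_hash": config.config_hash(),
            "config": config.to_dict(),
            "seed": config.seed,
            "n_permutations": config.n_permutations,
            "hypothesis_family": [h.id for h in results.hypotheses],
            "results_hash": results.results_hash(),
            "outputs": {k: str(v) for k, v in paths.items()},
            "written_at": datetime.now(timezone.utc).isoformat(),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return results
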