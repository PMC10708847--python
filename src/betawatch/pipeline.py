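"""End-to-end composition: simulate -> transport -> PSD -> stats -> classifier.

These helpers chain the per-module operations in the order the live
platform applies them, so tests, the command-line runner and parameter-
recovery studies share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import acquisition, classify, dsp, stats
from .core import RawTrace, SessionAnnotation
from .synthetic import CohortBundle

__all__ = ["CohortResult", "process_trace", "process_cohort", "analyze_cohort"]


@dataclass
class CohortResult:
    """Processed cohort: per-subject summaries plus optional analyses."""

    summaries: list[dsp.SubjectSummary]
    annotation: SessionAnnotation
    scores: np.ndarray | None = None
    correlation: stats.CorrelationResult | None = None
    group_assignment: stats.GroupAssignment | None = None
    group_test: stats.GroupTestResult | None = None
    classifier: classify.ClassifierReport | None = None
    assembly_logs: list[acquisition.AssemblyLog] = field(default_factory=list)

    @property
    def normalized_betas(self) -> np.ndarray:
        return np.array([s.normalized_beta if s.normalized_beta is not None else np.nan
                         for s in self.summaries])

    @property
    def total_betas(self) -> np.ndarray:
        return np.array([s.total_mean_beta for s in self.summaries])


def process_trace(trace: RawTrace, annotation: SessionAnnotation,
                  cfg: dsp.ProcessingConfig = dsp.ProcessingConfig(),
                  packet_size: int = acquisition.DEFAULT_PACKET_SIZE,
                  ) -> tuple[dsp.SubjectSummary, acquisition.AssemblyLog]:
    """One subject through transport emulation and the per-epoch chain."""
    packets = acquisition.packetize(trace, packet_size=packet_size)
    epochs, log = acquisition.assemble_epochs(packets, epoch_len=cfg.epoch_len, fs=cfg.fs)
    summary = dsp.summarize_subject(epochs, annotation, cfg, subject_id=trace.subject_id)
    return summary, log


def process_cohort(traces: list[RawTrace], annotation: SessionAnnotation,
                   cfg: dsp.ProcessingConfig = dsp.ProcessingConfig(),
                   packet_size: int = acquisition.DEFAULT_PACKET_SIZE) -> CohortResult:
    """All subjects through the chain, then cohort min-max normalization."""
    summaries, logs = [], []
    for trace in traces:
        s, log = process_trace(trace, annotation, cfg, packet_size)
        summaries.append(s)
        logs.append(log)
    summaries = dsp.normalize_cohort(summaries)
    return CohortResult(summaries=summaries, annotation=annotation, assembly_logs=logs)


def analyze_cohort(bundle: CohortBundle,
                   cfg: dsp.ProcessingConfig = dsp.ProcessingConfig(),
                   model: str = "skipped",
                   n_boot: int = 2000,
                   seed: int = 0,
                   pass_mark: float = 5.0,
                   run_group_test: bool = True,
                   run_classifier: bool = False,
                   grid: dict | None = None) -> CohortResult:
    """Full study replay on a synthetic cohort.

    Correlates the normalized beta summary with the task score under the
    requested model, optionally runs the best/worst group comparison and
    the LOOCV classifier.  Group or classifier stages that cannot run on
    a given cohort (e.g. an empty group after exclusions) surface their
    own errors; callers replaying degenerate cohorts should catch them.
    """
    result = process_cohort(bundle.traces, bundle.annotation, cfg)
    result.scores = np.asarray(bundle.scores, dtype=float)
    betas = result.normalized_betas
    result.correlation = stats.correlate(betas, result.scores, model=model,
                                         n_boot=n_boot, seed=seed)
    if run_group_test:
        ga = stats.form_groups(result.scores, betas, pass_mark=pass_mark)
        result.group_assignment = ga
        result.group_test = stats.compare_groups(ga.worst_betas, ga.best_betas)
    if run_classifier:
        features = classify.build_features(result.summaries, bundle.annotation,
                                           result.scores, pass_mark=pass_mark, cfg=cfg)
        probs, chosen = classify.loocv_predict(features, grid=grid, seed=seed)
        result.classifier = classify.evaluate(probs, features.y,
                                              chosen_hyperparams=chosen)
    return result
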