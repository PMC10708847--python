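"""Plain-text serialization of every pipeline product.

Traces travel as two-column CSV (`sample_index,raw_value`) with a JSON
sidecar of subject metadata; annotations and analysis reports are JSON;
tabular products (cohort table, epoch table, cohort summary, correlation
table, ROC points) are CSV.  Packet streams replay from JSON-lines.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .acquisition import SamplePacket
from .classify import ClassifierReport
from .core import EpochStatus, RawTrace, Segment, SessionAnnotation
from .dsp import SubjectSummary
from .stats import CorrelationResult, GroupTestResult
from .synthetic import CohortBundle

__all__ = [
    "write_trace", "read_trace",
    "write_annotation", "read_annotation",
    "write_cohort_table", "read_cohort_table",
    "write_packets_jsonl", "read_packets_jsonl",
    "write_epoch_table", "write_summary_table", "read_summary_table",
    "write_correlation_table", "write_group_report", "write_classifier_report",
    "write_cohort", "write_roc_points",
]


def write_trace(trace: RawTrace, csv_path: str | Path) -> None:
    """Write `sample_index,raw_value` CSV plus a `.json` metadata sidecar."""
    csv_path = Path(csv_path)
    df = pd.DataFrame({
        "sample_index": np.arange(len(trace.samples)),
        "raw_value": trace.samples,
    })
    df.to_csv(csv_path, index=False)
    sidecar = {
        "subject_id": trace.subject_id,
        "fs": trace.fs,
        "seed": trace.seed,
        "n_clipped": trace.n_clipped,
        "spec": trace.meta,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_trace(csv_path: str | Path) -> RawTrace:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    side_path = csv_path.with_suffix(".json")
    side = json.loads(side_path.read_text()) if side_path.exists() else {}
    return RawTrace(
        subject_id=side.get("subject_id", csv_path.stem),
        fs=float(side.get("fs", 512.0)),
        samples=df["raw_value"].to_numpy(dtype=np.int32),
        seed=side.get("seed"),
        n_clipped=int(side.get("n_clipped", 0)),
        meta=side.get("spec", {}),
    )


def write_annotation(annotation: SessionAnnotation, path: str | Path) -> None:
    payload = {"segments": [[s.label, s.start_s, s.end_s] for s in annotation.segments]}
    Path(path).write_text(json.dumps(payload, indent=2))


def read_annotation(path: str | Path) -> SessionAnnotation:
    payload = json.loads(Path(path).read_text())
    return SessionAnnotation([Segment(lbl, float(a), float(b))
                              for lbl, a, b in payload["segments"]])


COHORT_COLUMNS = ["subject_id", "score", "attention", "stress", "relaxation",
                  "interest", "fatigue", "effort"]


def write_cohort_table(bundle: CohortBundle, path: str | Path) -> None:
    df = bundle.answers.copy()
    df.insert(1, "score", bundle.scores)
    df[COHORT_COLUMNS].to_csv(path, index=False)


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    return df


def write_cohort(bundle: CohortBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write a full synthetic cohort: traces, annotation, cohort table."""
    out_dir = Path(out_dir)
    traces_dir = out_dir / "traces"
    traces_dir.mkdir(parents=True, exist_ok=True)
    for trace in bundle.traces:
        write_trace(trace, traces_dir / f"{trace.subject_id}.csv")
    ann_path = out_dir / "annotation.json"
    write_annotation(bundle.annotation, ann_path)
    cohort_path = out_dir / "cohort.csv"
    write_cohort_table(bundle, cohort_path)
    truth_path = out_dir / "truth.csv"
    pd.DataFrame({
        "subject_id": [t.subject_id for t in bundle.traces],
        "beta_gain_uV": bundle.truth,
    }).to_csv(truth_path, index=False)
    return {"traces": traces_dir, "annotation": ann_path,
            "cohort": cohort_path, "truth": truth_path}


def write_packets_jsonl(packets: list[SamplePacket], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in packets:
            fh.write(json.dumps({"subject_id": p.subject_id, "seq": p.seq,
                                 "samples": p.samples.tolist()}) + "\n")


def read_packets_jsonl(path: str | Path) -> list[SamplePacket]:
    packets = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                d = json.loads(line)
                packets.append(SamplePacket(d["subject_id"], d["seq"],
                                            np.asarray(d["samples"], dtype=np.int32)))
    return packets


def write_epoch_table(summary: SubjectSummary, path: str | Path) -> None:
    pd.DataFrame([
        {"epoch_index": r.index, "start_s": r.start_s, "status": r.status.value,
         "beta_power": r.beta_power if r.beta_power is not None else ""}
        for r in summary.epoch_records
    ]).to_csv(path, index=False)


def summary_frame(summaries: list[SubjectSummary]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "subject_id": s.subject_id,
            "total_mean_beta": s.total_mean_beta,
            "normalized_beta": s.normalized_beta,
            "n_epochs": s.n_epochs_total,
            "n_accepted": s.n_accepted,
            "n_rejected": s.n_rejected_artifact + s.n_rejected_degenerate,
            "n_excluded_by_mask": s.n_excluded_by_mask,
            "valid": s.valid,
        }
        for s in summaries
    ])


def write_summary_table(summaries: list[SubjectSummary], path: str | Path) -> None:
    summary_frame(summaries).to_csv(path, index=False)


def read_summary_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_correlation_table(results: dict[str, dict[str, CorrelationResult]],
                            path: str | Path) -> None:
    """Correlation report shaped variable x model, one row per fit."""
    rows = []
    for variable, by_model in results.items():
        for model, res in by_model.items():
            rows.append({
                "variable": variable, "model": model, "outliers": res.n_outliers,
                "r": res.r, "ci_lo": res.ci95[0], "ci_hi": res.ci95[1],
                "p": res.p_value, "power": res.power,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_group_report(result: GroupTestResult, path: str | Path,
                       extra: dict | None = None) -> None:
    payload = dataclasses.asdict(result)
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2))


def write_classifier_report(report: ClassifierReport, path: str | Path) -> None:
    tp, fp, fn, tn = report.confusion
    payload = {
        "confusion": {"TP": tp, "FP": fp, "FN": fn, "TN": tn},
        "metrics": report.rounded(),
        "metrics_full": {"recall": report.recall, "precision": report.precision,
                         "accuracy": report.accuracy, "f1": report.f1,
                         "auc": report.auc},
        "threshold": report.threshold,
        "probabilities": report.probabilities.tolist(),
        "labels": report.labels.tolist(),
        "chosen_hyperparams": [
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
            for d in report.chosen_hyperparams
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_roc_points(report: ClassifierReport, path: str | Path) -> None:
    pd.DataFrame(report.roc_points, columns=["fpr", "tpr"]).to_csv(path, index=False)
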