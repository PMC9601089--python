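"""Reading and writing the toolkit's flat-file formats.

Frame-probability manifests travel as long-form CSV (one row per frame:
clip_id, patient_id, frame_index, prob, optional true_label) or as JSON
with one record per clip holding the ordered probability array.  Event
logs, predictions, grid reports and metrics use plain CSV/JSON so every
artifact round-trips and is inspectable with standard tools.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, List, Sequence

import pandas as pd

from .annotation_efficiency import AnnotationAction, AnnotationEvent, SprintKind
from .clip_aggregation import ClipPrediction, FrameProbSeries, ViewLabel
from .validation import GridSearchResult, MetricsReport

__all__ = [
    "read_manifest_csv",
    "write_manifest_csv",
    "read_manifest_json",
    "write_manifest_json",
    "write_predictions_csv",
    "read_predictions_csv",
    "write_smoothed_series_csv",
    "read_event_log_csv",
    "write_event_log_csv",
    "write_grid_report_csv",
    "write_metrics_json",
]


def _label_or_none(value) -> ViewLabel | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return ViewLabel(value)


def read_manifest_csv(path: str | Path) -> List[FrameProbSeries]:
    """Load a long-form frame-probability manifest.

    Frames must be dense and 0-based within each clip; rows may appear
    in any order.
    """
    df = pd.read_csv(path, dtype={"clip_id": str, "patient_id": str},
                     float_precision="round_trip")
    required = {"clip_id", "patient_id", "frame_index", "prob"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} is missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError(f"manifest {path} contains no rows")
    series: List[FrameProbSeries] = []
    for clip_id, grp in df.groupby("clip_id", sort=True):
        grp = grp.sort_values("frame_index")
        idx = grp["frame_index"].to_numpy()
        if idx[0] != 0 or (idx[1:] - idx[:-1] != 1).any():
            raise ValueError(
                f"clip {clip_id!r}: frame_index must be dense and 0-based"
            )
        label = None
        if "true_label" in grp.columns:
            labels = {_label_or_none(v) for v in grp["true_label"]}
            if len(labels) > 1:
                raise ValueError(f"clip {clip_id!r}: inconsistent true_label values")
            label = labels.pop()
        series.append(
            FrameProbSeries(
                clip_id=str(clip_id),
                patient_id=str(grp["patient_id"].iloc[0]),
                probs=tuple(grp["prob"]),
                true_label=label,
            )
        )
    return series


def write_manifest_csv(series: Iterable[FrameProbSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for i, p in enumerate(s.probs):
            rows.append(
                {
                    "clip_id": s.clip_id,
                    "patient_id": s.patient_id,
                    "frame_index": i,
                    "prob": p,
                    "true_label": s.true_label.value if s.true_label else "",
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_manifest_json(path: str | Path) -> List[FrameProbSeries]:
    records = json.loads(Path(path).read_text())
    if not records:
        raise ValueError(f"manifest {path} contains no clips")
    return [
        FrameProbSeries(
            clip_id=r["clip_id"],
            patient_id=r["patient_id"],
            probs=tuple(r["probs"]),
            true_label=_label_or_none(r.get("true_label")),
        )
        for r in records
    ]


def write_manifest_json(series: Iterable[FrameProbSeries], path: str | Path) -> None:
    records = [
        {
            "clip_id": s.clip_id,
            "patient_id": s.patient_id,
            "probs": list(s.probs),
            "true_label": s.true_label.value if s.true_label else None,
        }
        for s in series
    ]
    Path(path).write_text(json.dumps(records, indent=1))


def write_predictions_csv(
    predictions: Iterable[ClipPrediction], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "clip_id": p.clip_id,
                "predicted_label": p.predicted.value,
                "longest_qualifying_run": p.longest_qualifying_run,
                "mean_raw_prob": p.mean_raw_prob,
            }
            for p in predictions
        ]
    ).to_csv(path, index=False)


def read_predictions_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"clip_id": str}, float_precision="round_trip")
    required = {"clip_id", "predicted_label", "longest_qualifying_run", "mean_raw_prob"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"predictions {path} missing columns: {sorted(missing)}")
    return df


def write_smoothed_series_csv(prediction: ClipPrediction, raw_probs: Sequence[float], path: str | Path) -> None:
    """Per-clip raw and smoothed time series, for external plotting."""
    n_raw, n_sm = len(raw_probs), len(prediction.smoothed)
    rows = [
        {
            "frame_index": i,
            "raw_prob": raw_probs[i] if i < n_raw else "",
            "smoothed_prob": prediction.smoothed[i] if i < n_sm else "",
        }
        for i in range(max(n_raw, n_sm))
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_event_log_csv(path: str | Path) -> List[AnnotationEvent]:
    df = pd.read_csv(path, dtype={"clip_id": str, "annotator_id": str, "sprint_id": str},
                     float_precision="round_trip")
    required = {"clip_id", "annotator_id", "sprint_id", "sprint_kind", "action", "duration_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"event log {path} missing columns: {sorted(missing)}")
    return [
        AnnotationEvent(
            clip_id=row.clip_id,
            annotator_id=row.annotator_id,
            sprint_id=row.sprint_id,
            sprint_kind=SprintKind(row.sprint_kind),
            action=AnnotationAction(row.action),
            duration_s=float(row.duration_s),
        )
        for row in df.itertuples()
    ]


def write_event_log_csv(events: Iterable[AnnotationEvent], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "clip_id": e.clip_id,
                "annotator_id": e.annotator_id,
                "sprint_id": e.sprint_id,
                "sprint_kind": e.sprint_kind.value,
                "action": e.action.value,
                "duration_s": repr(e.duration_s),  # full-precision text
            }
            for e in events
        ]
    ).to_csv(path, index=False)


def write_grid_report_csv(result: GridSearchResult, path: str | Path) -> None:
    result.to_frame().to_csv(path, index=False)


def write_metrics_json(reports: Iterable[MetricsReport], path: str | Path) -> None:
    Path(path).write_text(json.dumps([r.to_dict() for r in reports], indent=2))
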