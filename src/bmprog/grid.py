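"""The 14-definition experiment grid and its end-to-end orchestration.

Three categories share an anchor cell (<24 months, >=25% volume, true
progression only): the follow-up-period category varies the window, the
size-change category varies the metric, and the TRSC category varies which
treatment-related size changes count as progression. The anchor appears in
all three categories but is computed once and referenced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .labeling import (
    LabelableLesion,
    Metric,
    ProgressionDefinition,
    TaskMode,
    TrscScheme,
    binary_outcome,
    label_cohort,
)
from .evaluation import ExperimentResult, HarnessConfig, run_experiment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GridRow:
    definition_id: str
    category: str  # F (follow-up period), S (size change metric), T (TRSC)
    definition: ProgressionDefinition


@dataclass
class GridSpec:
    rows: list[GridRow]
    task_mode: TaskMode = TaskMode.PROG_VS_REST

    def __post_init__(self) -> None:
        ids = [r.definition_id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("definition ids must be unique")

    def __len__(self) -> int:
        return len(self.rows)

    def by_id(self, definition_id: str) -> GridRow:
        for row in self.rows:
            if row.definition_id == definition_id:
                return row
        raise KeyError(f"unknown definition {definition_id!r}")


def build_default_grid(task_mode: TaskMode = TaskMode.PROG_VS_REST) -> GridSpec:
    """The 14 grid rows: 5 follow-up windows, 5 size metrics, 4 TRSC schemes."""
    rows: list[GridRow] = []
    for w in (9, 12, 15, 18, 24):
        rows.append(
            GridRow(
                f"F_lt{w}",
                "F",
                ProgressionDefinition(w, Metric.VOL_25, TrscScheme.TRUE_ONLY),
            )
        )
    for metric in (Metric.RANO_20, Metric.VOL_10, Metric.VOL_15, Metric.VOL_20, Metric.VOL_25):
        rows.append(
            GridRow(
                f"S_{metric.value.lower()}",
                "S",
                ProgressionDefinition(24, metric, TrscScheme.TRUE_ONLY),
            )
        )
    for scheme in (
        TrscScheme.TRUE_ONLY,
        TrscScheme.TRUE_PLUS_RN,
        TrscScheme.TRUE_PLUS_PP,
        TrscScheme.TRUE_PLUS_RN_PP,
    ):
        rows.append(
            GridRow(
                f"T_{scheme.value.lower()}",
                "T",
                ProgressionDefinition(24, Metric.VOL_25, scheme),
            )
        )
    return GridSpec(rows, task_mode)


@dataclass
class GridResult:
    summary: pd.DataFrame  # one row per definition
    label_counts: pd.DataFrame
    importance: pd.DataFrame  # features x definitions, NaN for degenerate cells
    ranges: pd.DataFrame  # per category: max - min of each mean metric
    experiments: dict[str, ExperimentResult] = field(default_factory=dict)
    labels: pd.DataFrame | None = None
    test_records: pd.DataFrame | None = None


def run_grid(
    lesions: list[LabelableLesion],
    features: pd.DataFrame,
    groups: pd.Series,
    grid: GridSpec | None = None,
    config: HarnessConfig | None = None,
    seed: int = 0,
    lesion_metadata: pd.DataFrame | None = None,
) -> GridResult:
    """Label the cohort under every grid definition and evaluate each one.

    ``features`` is indexed by lesion_id; ``groups`` maps lesion_id to the
    bootstrap unit (patient). Duplicate grid cells (the shared anchor) are
    computed once. Definitions yielding a single class are reported as
    degenerate; the rest are unaffected.
    """
    grid = grid or build_default_grid()
    config = config or HarnessConfig()
    lesions = [l.as_labelable() if hasattr(l, "as_labelable") else l for l in lesions]
    lesion_ids = [l.lesion_id for l in lesions]
    features = features.loc[lesion_ids]
    groups = groups.loc[lesion_ids]

    cell_cache: dict[tuple, dict] = {}
    all_labels, summary_rows, count_rows = [], [], []
    importance_cols: dict[str, np.ndarray] = {}
    experiments: dict[str, ExperimentResult] = {}
    records_frames = []

    for k, row in enumerate(grid.rows):
        cell = row.definition.cell_key
        if cell not in cell_cache:
            labels_df = label_cohort(lesions, row.definition)
            y = np.array(
                [binary_outcome(t, grid.task_mode) for t in labels_df["three_way"]]
            )
            counts = labels_df["three_way"].value_counts()
            entry: dict = {
                "labels_df": labels_df,
                "y": y,
                "counts": {
                    "n_progressing": int(counts.get("progressing", 0)),
                    "n_stable": int(counts.get("stable", 0)),
                    "n_regressing": int(counts.get("regressing", 0)),
                },
                "degenerate": len(np.unique(y)) < 2,
                "experiment": None,
            }
            if entry["degenerate"]:
                logger.warning(
                    "definition %s is degenerate (single class); skipping evaluation",
                    row.definition_id,
                )
            else:
                entry["experiment"] = run_experiment(
                    features, y, groups.to_numpy(), config, seed=seed
                )
            cell_cache[cell] = entry
        entry = cell_cache[cell]

        labels_df = entry["labels_df"].copy()
        labels_df["definition_id"] = row.definition_id
        labels_df["binary_failure"] = entry["y"]
        all_labels.append(labels_df)
        count_rows.append({"definition_id": row.definition_id, **entry["counts"]})

        srow = {
            "definition_id": row.definition_id,
            "category": row.category,
            "window_months": row.definition.window_months,
            "metric": row.definition.metric.value,
            "trsc_scheme": row.definition.trsc_scheme.value,
            **entry["counts"],
            "degenerate": entry["degenerate"],
        }
        exp = entry["experiment"]
        if exp is not None:
            experiments[row.definition_id] = exp
            for m, (mean, lo, hi) in exp.metrics.items():
                srow[f"{m}_mean"], srow[f"{m}_ci_low"], srow[f"{m}_ci_high"] = mean, lo, hi
            srow["baseline_auprc"] = exp.baseline_auprc
            srow["mean_test_fraction_pct"] = exp.mean_test_fraction_pct
            importance_cols[row.definition_id] = exp.aggregated_importance
            rec = exp.test_records.copy()
            rec.insert(0, "definition_id", row.definition_id)
            records_frames.append(rec)
        else:
            importance_cols[row.definition_id] = np.full(features.shape[1], np.nan)
        summary_rows.append(srow)

    summary = pd.DataFrame(summary_rows)
    range_rows = []
    for cat, sub in summary[~summary["degenerate"]].groupby("category"):
        row = {"category": cat, "n_definitions": len(sub)}
        for m in ("auc", "auprc", "sensitivity", "specificity"):
            col = f"{m}_mean"
            if col in sub:
                row[f"{m}_range"] = float(sub[col].max() - sub[col].min())
                row[f"{m}_min"] = float(sub[col].min())
                row[f"{m}_max"] = float(sub[col].max())
        range_rows.append(row)

    importance = pd.DataFrame(importance_cols, index=list(features.columns))
    result = GridResult(
        summary=summary,
        label_counts=pd.DataFrame(count_rows),
        importance=importance,
        ranges=pd.DataFrame(range_rows),
        experiments=experiments,
        labels=pd.concat(all_labels, ignore_index=True),
        test_records=pd.concat(records_frames, ignore_index=True)
        if records_frames
        else None,
    )
    if lesion_metadata is not None and result.test_records is not None:
        result.test_records = result.test_records.merge(
            lesion_metadata, on="lesion_id", how="left"
        )
    return result
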