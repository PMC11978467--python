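"""Per-lesion progression labeling under configurable definitions of progression.

A lesion's post-treatment course is summarized by serial size measurements
(three orthogonal diameters and a RANO-BM nodal diameter). A *definition of
progression* is one cell of a three-axis grid:

* follow-up window — only measurements strictly before the window bound count;
* size-change metric — a relative volume increase (10/15/20/25%, with a
  27 mm^3 absolute floor derived from the 3 mm RANO-BM rule applied in three
  dimensions) or a RANO-BM diameter increase (>=20%, with a 3 mm minimum
  absolute increase for lesions under 10 mm at baseline);
* treatment-related size change (TRSC) scheme — whether lesions whose apparent
  growth was adjudicated as pseudo-progression (PP) or radiation necrosis (RN)
  still count as progression.

Volume is estimated as the product of the three orthogonal diameters, and all
comparisons are against the pre-treatment baseline (never a nadir). Thresholds
are inclusive (>=). Lesions that do not progress are split into *regressing*
(mirrored shrinkage criterion on the last in-window measurement; the RANO
branch uses the 30% partial-response convention) and *stable*; lesions with no
in-window follow-up default to stable.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VOLUME_FLOOR_MM3 = 27.0  # 3 mm minimum diameter change, cubed
RANO_SMALL_LESION_MM = 10.0
RANO_MIN_INCREASE_MM = 3.0
RANO_PARTIAL_RESPONSE_FRACTION = 0.7  # <=70% of baseline diameter = regression


class Metric(str, enum.Enum):
    """Size-change metric denoting progression."""

    VOL_10 = "VOL_10"
    VOL_15 = "VOL_15"
    VOL_20 = "VOL_20"
    VOL_25 = "VOL_25"
    RANO_20 = "RANO_20"

    @property
    def volume_threshold_pct(self) -> float:
        if self is Metric.RANO_20:
            raise ValueError("RANO_20 is a diameter metric")
        return float(self.value.split("_")[1])


class TrscScheme(str, enum.Enum):
    """Which adjudicated treatment-related size changes count as progression."""

    TRUE_ONLY = "TRUE_ONLY"
    TRUE_PLUS_RN = "TRUE_PLUS_RN"
    TRUE_PLUS_PP = "TRUE_PLUS_PP"
    TRUE_PLUS_RN_PP = "TRUE_PLUS_RN_PP"


class TrscAnnotation(str, enum.Enum):
    NONE = "none"
    PP = "PP"
    RN = "RN"


class TaskMode(str, enum.Enum):
    """Binary task: progression vs rest, or progression+stable vs regression."""

    PROG_VS_REST = "PROG_VS_REST"
    PROG_AND_STABLE_VS_REGRESS = "PROG_AND_STABLE_VS_REGRESS"


WINDOWS_MONTHS = (9, 12, 15, 18, 24)


@dataclass(frozen=True)
class Timepoint:
    months: float
    d_pa_mm: float
    d_ml_mm: float
    d_si_mm: float
    rano_mm: float | None  # None when the nodal diameter was not measurable
    measurable: bool = True


@dataclass
class MeasurementSeries:
    """Ordered longitudinal size record of one lesion (post-treatment)."""

    timepoints: list[Timepoint] = field(default_factory=list)

    def __post_init__(self) -> None:
        months = [tp.months for tp in self.timepoints]
        if any(m < 0 for m in months):
            raise ValueError("months post-treatment must be >= 0")
        if any(b <= a for a, b in zip(months, months[1:])):
            raise ValueError("months must be strictly increasing")
        for tp in self.timepoints:
            if tp.measurable and min(tp.d_pa_mm, tp.d_ml_mm, tp.d_si_mm) <= 0:
                raise ValueError("diameters must be > 0 when measurable")

    def __len__(self) -> int:
        return len(self.timepoints)

    def __iter__(self):
        return iter(self.timepoints)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "MeasurementSeries":
        """Build a series from rows of a measurements table (one lesion)."""
        df = df.sort_values("months")
        tps = []
        for row in df.itertuples(index=False):
            rano = getattr(row, "rano_mm", None)
            if rano is not None and (isinstance(rano, float) and math.isnan(rano)):
                rano = None
            tps.append(
                Timepoint(
                    months=float(row.months),
                    d_pa_mm=float(row.d_pa_mm),
                    d_ml_mm=float(row.d_ml_mm),
                    d_si_mm=float(row.d_si_mm),
                    rano_mm=None if rano is None else float(rano),
                    measurable=bool(getattr(row, "measurable", True)),
                )
            )
        return cls(tps)


@dataclass(frozen=True)
class ProgressionDefinition:
    """One cell of the definition grid: window x metric x TRSC scheme."""

    window_months: int
    metric: Metric
    trsc_scheme: TrscScheme

    def __post_init__(self) -> None:
        if self.window_months not in WINDOWS_MONTHS:
            raise ValueError(f"window must be one of {WINDOWS_MONTHS}")

    @property
    def cell_key(self) -> tuple[int, str, str]:
        return (self.window_months, self.metric.value, self.trsc_scheme.value)

    @property
    def name(self) -> str:
        metric = self.metric.value.lower()
        scheme = self.trsc_scheme.value.lower()
        return f"{metric}_w{self.window_months}_{scheme}"


@dataclass(frozen=True)
class LesionLabel:
    three_way: str  # progressing | stable | regressing
    size_based_progression: bool
    adjudicated_progression: bool

    def __post_init__(self) -> None:
        if (self.three_way == "progressing") != self.adjudicated_progression:
            raise ValueError("three_way/adjudicated_progression inconsistent")


def estimate_volume(d_pa: float, d_ml: float, d_si: float) -> float:
    """Volume proxy: product of the three orthogonal diameters (mm^3)."""
    if min(d_pa, d_ml, d_si) <= 0:
        raise ValueError("diameters must be positive")
    return d_pa * d_ml * d_si


def within_window(series: MeasurementSeries, window_months: float) -> MeasurementSeries:
    """Keep timepoints strictly before the window bound ("<9 months" etc.)."""
    return MeasurementSeries([tp for tp in series if tp.months < window_months])


def volume_progression(
    baseline: tuple[float, float, float],
    series: MeasurementSeries,
    pct_threshold: float,
) -> bool:
    """Any in-window volume >= baseline*(1+pct/100) with an absolute 27 mm^3 floor."""
    v0 = estimate_volume(*baseline)
    for tp in series:
        if not tp.measurable:
            continue
        v = estimate_volume(tp.d_pa_mm, tp.d_ml_mm, tp.d_si_mm)
        if v >= v0 * (1.0 + pct_threshold / 100.0) and v - v0 >= VOLUME_FLOOR_MM3:
            return True
    return False


def rano_progression(baseline_rano: float | None, series: MeasurementSeries) -> bool:
    """RANO-BM: >=20% nodal-diameter increase; <10 mm lesions also need >=3 mm.

    Timepoints without a measurable nodal diameter are skipped, mirroring the
    exclusion of cystic measurements in the RANO-BM guidelines.
    """
    if baseline_rano is None or not math.isfinite(baseline_rano):
        raise ValueError("baseline RANO-BM diameter is not measurable")
    for tp in series:
        if tp.rano_mm is None:
            continue
        if tp.rano_mm >= 1.2 * baseline_rano and (
            baseline_rano >= RANO_SMALL_LESION_MM
            or tp.rano_mm - baseline_rano >= RANO_MIN_INCREASE_MM
        ):
            return True
    return False


def size_based_progression(
    baseline: tuple[float, float, float],
    baseline_rano: float | None,
    series: MeasurementSeries,
    metric: Metric,
) -> bool:
    if metric is Metric.RANO_20:
        return rano_progression(baseline_rano, series)
    return volume_progression(baseline, series, metric.volume_threshold_pct)


def classify_non_progressors(
    baseline: tuple[float, float, float],
    baseline_rano: float | None,
    series: MeasurementSeries,
    metric: Metric,
) -> str:
    """Split non-progressing lesions into regressing vs stable.

    Regression mirrors the progression criterion on the LAST in-window
    measurement; the RANO branch uses the 30% partial-response convention.
    An empty in-window series defaults to stable.
    """
    if metric is Metric.RANO_20:
        usable = [tp for tp in series if tp.rano_mm is not None]
        if not usable:
            return "stable"
        if baseline_rano is None:
            raise ValueError("baseline RANO-BM diameter is not measurable")
        last = usable[-1]
        if last.rano_mm <= RANO_PARTIAL_RESPONSE_FRACTION * baseline_rano:
            return "regressing"
        return "stable"
    usable = [tp for tp in series if tp.measurable]
    if not usable:
        return "stable"
    v0 = estimate_volume(*baseline)
    last = usable[-1]
    v = estimate_volume(last.d_pa_mm, last.d_ml_mm, last.d_si_mm)
    pct = metric.volume_threshold_pct
    if v <= v0 * (1.0 - pct / 100.0) and v0 - v >= VOLUME_FLOOR_MM3:
        return "regressing"
    return "stable"


def apply_trsc_scheme(
    size_progression: bool,
    annotation: TrscAnnotation | str,
    scheme: TrscScheme,
) -> bool:
    """Adjudicate a size-based progression flag under a TRSC scheme."""
    annotation = TrscAnnotation(annotation)
    if not size_progression:
        return False
    if annotation is TrscAnnotation.NONE:
        return True
    if annotation is TrscAnnotation.PP:
        return scheme in (TrscScheme.TRUE_PLUS_PP, TrscScheme.TRUE_PLUS_RN_PP)
    if annotation is TrscAnnotation.RN:
        return scheme in (TrscScheme.TRUE_PLUS_RN, TrscScheme.TRUE_PLUS_RN_PP)
    raise ValueError(f"unknown annotation {annotation!r}")


@dataclass(frozen=True)
class LabelableLesion:
    """Minimal view of a lesion required by the labeling engine."""

    lesion_id: str
    baseline_d_pa_mm: float
    baseline_d_ml_mm: float
    baseline_d_si_mm: float
    baseline_rano_mm: float | None
    series: MeasurementSeries
    trsc_annotation: TrscAnnotation = TrscAnnotation.NONE

    @property
    def baseline_diameters(self) -> tuple[float, float, float]:
        return (self.baseline_d_pa_mm, self.baseline_d_ml_mm, self.baseline_d_si_mm)


def label_lesion(lesion: LabelableLesion, definition: ProgressionDefinition) -> LesionLabel:
    """Window-filter, apply the size metric, adjudicate TRSC, then classify."""
    windowed = within_window(lesion.series, definition.window_months)
    size_prog = size_based_progression(
        lesion.baseline_diameters, lesion.baseline_rano_mm, windowed, definition.metric
    )
    adjudicated = apply_trsc_scheme(size_prog, lesion.trsc_annotation, definition.trsc_scheme)
    if adjudicated:
        three_way = "progressing"
    else:
        three_way = classify_non_progressors(
            lesion.baseline_diameters, lesion.baseline_rano_mm, windowed, definition.metric
        )
    return LesionLabel(
        three_way=three_way,
        size_based_progression=size_prog,
        adjudicated_progression=adjudicated,
    )


def label_cohort(
    lesions: Iterable[LabelableLesion], definition: ProgressionDefinition
) -> pd.DataFrame:
    rows = []
    for lesion in lesions:
        lab = label_lesion(lesion, definition)
        rows.append(
            {
                "lesion_id": lesion.lesion_id,
                "definition": definition.name,
                "three_way": lab.three_way,
                "size_based_progression": lab.size_based_progression,
                "adjudicated_progression": lab.adjudicated_progression,
            }
        )
    return pd.DataFrame(rows)


def label_counts(
    lesions: Sequence[LabelableLesion], definition: ProgressionDefinition
) -> tuple[int, int, int]:
    """(n_progressing, n_stable, n_regressing); sums to the number of lesions."""
    counts = {"progressing": 0, "stable": 0, "regressing": 0}
    for lesion in lesions:
        counts[label_lesion(lesion, definition).three_way] += 1
    return counts["progressing"], counts["stable"], counts["regressing"]


def binary_outcome(label: LesionLabel | str, task: TaskMode) -> int:
    """1 = treatment failure, 0 = treatment success, under the task mode."""
    three_way = label.three_way if isinstance(label, LesionLabel) else label
    if three_way not in ("progressing", "stable", "regressing"):
        raise ValueError(f"unknown label {three_way!r}")
    if task is TaskMode.PROG_VS_REST:
        return int(three_way == "progressing")
    return int(three_way in ("progressing", "stable"))


def binary_outcomes(labels: pd.DataFrame, task: TaskMode) -> pd.Series:
    """Vectorized :func:`binary_outcome` over a labels table."""
    return labels["three_way"].map(lambda t: binary_outcome(t, task)).astype(int)


def lesions_from_tables(
    lesions_df: pd.DataFrame, measurements_df: pd.DataFrame
) -> list[LabelableLesion]:
    """Assemble labelable lesions from lesions.csv / measurements.csv tables."""
    grouped = dict(tuple(measurements_df.groupby("lesion_id")))
    out = []
    for row in lesions_df.itertuples(index=False):
        meas = grouped.get(row.lesion_id)
        series = (
            MeasurementSeries.from_dataframe(meas) if meas is not None else MeasurementSeries()
        )
        rano = row.baseline_rano_mm
        if isinstance(rano, float) and math.isnan(rano):
            rano = None
        out.append(
            LabelableLesion(
                lesion_id=str(row.lesion_id),
                baseline_d_pa_mm=float(row.baseline_d_pa_mm),
                baseline_d_ml_mm=float(row.baseline_d_ml_mm),
                baseline_d_si_mm=float(row.baseline_d_si_mm),
                baseline_rano_mm=None if rano is None else float(rano),
                series=series,
                trsc_annotation=TrscAnnotation(row.trsc_annotation),
            )
        )
    return out
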