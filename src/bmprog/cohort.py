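"""Synthetic longitudinal cohort of brain metastases treated with SRS.

The generator emulates the phenomena the labeling engine must discriminate:

* per-lesion volume trajectories following a deterministic exponential kernel
  ``V(t) = V0 * exp(g*t) * (1 + bump(t))`` with per-class growth rate ``g``;
* transient pseudo-progression (PP) bumps with onset 3-6 months that resolve
  within 6 months of onset, and delayed radiation-necrosis (RN) bumps with
  onset >= 6 months that do not resolve;
* a ``late_progressor`` class whose growth only starts after a configurable
  onset, so that follow-up-window sensitivity is exercisable;
* three orthogonal diameters derived from volume through per-lesion shape
  fractions held constant over time (their product tracks the kernel volume
  exactly in the noiseless limit), each perturbed by multiplicative log-normal
  measurement noise; the RANO-BM nodal diameter is the largest orthogonal
  diameter with its own noise term;
* feature tables with a controlled number of outcome-informative columns
  (class-conditional unit-variance Gaussians separated by a standardized
  effect size d, so the single-feature AUC has the closed form Phi(d/sqrt 2))
  and block-equicorrelated noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .labeling import (
    LabelableLesion,
    MeasurementSeries,
    Timepoint,
    TrscAnnotation,
)

CLASSES = (
    "true_progressor",
    "late_progressor",
    "stable",
    "regressor",
    "pseudo_progression",
    "radiation_necrosis",
)

#: classes whose tumor genuinely progresses eventually (ground-truth failures)
EVENTUAL_PROGRESSOR_CLASSES = ("true_progressor", "late_progressor")


@dataclass(frozen=True)
class ClassKinetics:
    """Noiseless growth-kernel parameters for one lesion class."""

    growth_rate_per_month: float
    onset_months: float = 0.0  # growth starts here (late progressors)


@dataclass
class CohortConfig:
    n_patients: int = 62
    #: categorical distribution over 1..k lesions per patient
    lesions_per_patient_probs: tuple[float, ...] = (0.55, 0.25, 0.12, 0.05, 0.03)
    class_probs: dict[str, float] = field(
        default_factory=lambda: {
            "true_progressor": 0.15,
            "late_progressor": 0.10,
            "stable": 0.30,
            "regressor": 0.30,
            "pseudo_progression": 0.10,
            "radiation_necrosis": 0.05,
        }
    )
    #: log-normal baseline geometric-mean diameter (median ~6.2 mm gives a
    #: median product-volume ~241 mm^3)
    baseline_diameter_median_mm: float = 6.2
    baseline_diameter_sigma_ln: float = 0.40
    growth: dict[str, ClassKinetics] = field(
        default_factory=lambda: {
            "true_progressor": ClassKinetics(math.log(2) / 6.0),
            "late_progressor": ClassKinetics(math.log(2) / 6.0, onset_months=12.0),
            "stable": ClassKinetics(0.0),
            "regressor": ClassKinetics(-math.log(2) / 6.0),
            "pseudo_progression": ClassKinetics(0.0),
            "radiation_necrosis": ClassKinetics(0.0),
        }
    )
    bump_amplitude: float = 0.8  # relative peak volume excess for PP/RN
    pp_onset_window_months: tuple[float, float] = (3.0, 6.0)
    pp_duration_months: float = 6.0  # PP bump fully resolved by onset+duration
    rn_onset_months_min: float = 6.0
    rn_rise_months: float = 6.0  # months for the RN bump to reach ~63% of peak
    followup_schedule_months: tuple[float, ...] = (3, 6, 9, 12, 15, 18, 21, 24)
    diameter_noise_cv: float = 0.05
    shape_ratio_sigma_ln: float = 0.15  # anisotropy of the per-lesion axes
    rano_unmeasurable_prob: float = 0.02
    primary_site_probs: dict[str, float] = field(
        default_factory=lambda: {"lung": 88 / 115, "other": 27 / 115}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if abs(sum(self.class_probs.values()) - 1.0) > 1e-9:
            raise ValueError("class_probs must sum to 1")
        if set(self.class_probs) - set(CLASSES):
            raise ValueError(f"unknown classes {set(self.class_probs) - set(CLASSES)}")
        if abs(sum(self.lesions_per_patient_probs) - 1.0) > 1e-9:
            raise ValueError("lesions_per_patient_probs must sum to 1")
        sched = self.followup_schedule_months
        if not all(b > a for a, b in zip(sched, sched[1:])):
            raise ValueError("followup schedule must be strictly increasing")
        if max(sched) > 24:
            raise ValueError("followup schedule must not exceed 24 months")
        for name, kin in self.growth.items():
            if not math.isfinite(kin.growth_rate_per_month):
                raise ValueError(f"non-finite growth rate for {name}")
        if not math.isfinite(self.bump_amplitude) or self.bump_amplitude < 0:
            raise ValueError("bump_amplitude must be finite and >= 0")


@dataclass(frozen=True)
class LesionKernelParams:
    """Per-lesion realization of the noiseless kernel."""

    v0_mm3: float
    growth_rate_per_month: float
    growth_onset_months: float
    bump_amplitude: float
    bump_onset_months: float | None  # None for classes without a bump
    bump_duration_months: float | None  # None = non-resolving (RN)


def _bump(params: LesionKernelParams, t: float) -> float:
    onset = params.bump_onset_months
    if onset is None or t <= onset or params.bump_amplitude == 0.0:
        return 0.0
    if params.bump_duration_months is None:
        # radiation necrosis: saturating, non-resolving (time constant 6 months)
        return params.bump_amplitude * (1.0 - math.exp(-(t - onset) / 6.0))
    if t >= onset + params.bump_duration_months:
        return 0.0
    # pseudo-progression: unimodal raised-sine pulse, zero at both ends
    phase = (t - onset) / params.bump_duration_months
    return params.bump_amplitude * math.sin(math.pi * phase) ** 2


def expected_volume(lesion_class: str, params: LesionKernelParams, t: float) -> float:
    """Noiseless kernel volume V(t) in mm^3 at t months post-treatment."""
    if lesion_class not in CLASSES:
        raise ValueError(f"unknown lesion class {lesion_class!r}")
    if t < 0:
        raise ValueError("t must be >= 0")
    g = params.growth_rate_per_month
    t_eff = max(0.0, t - params.growth_onset_months)
    return params.v0_mm3 * math.exp(g * t_eff) * (1.0 + _bump(params, t))


@dataclass
class SimulatedLesion:
    lesion_id: str
    patient_id: str
    true_class: str
    primary_site: str
    baseline_dpa_mm: float
    baseline_dml_mm: float
    baseline_dsi_mm: float
    baseline_rano_mm: float
    series: MeasurementSeries
    trsc_annotation: TrscAnnotation
    kernel: LesionKernelParams
    shape_fractions: tuple[float, float, float]

    @property
    def eventual_progressor(self) -> bool:
        return self.true_class in EVENTUAL_PROGRESSOR_CLASSES

    def as_labelable(self) -> LabelableLesion:
        return LabelableLesion(
            lesion_id=self.lesion_id,
            baseline_d_pa_mm=self.baseline_dpa_mm,
            baseline_d_ml_mm=self.baseline_dml_mm,
            baseline_d_si_mm=self.baseline_dsi_mm,
            baseline_rano_mm=self.baseline_rano_mm,
            series=self.series,
            trsc_annotation=self.trsc_annotation,
        )


def _sample_lesion_counts(
    rng: np.random.Generator, config: CohortConfig, total_lesions: int | None
) -> np.ndarray:
    probs = np.asarray(config.lesions_per_patient_probs, dtype=float)
    counts = rng.choice(np.arange(1, len(probs) + 1), size=config.n_patients, p=probs)
    if total_lesions is None:
        return counts
    kmax = len(probs)
    if not config.n_patients <= total_lesions <= config.n_patients * kmax:
        raise ValueError("total_lesions unreachable for this per-patient distribution")
    # repair toward the exact total, one lesion at a time
    while counts.sum() != total_lesions:
        if counts.sum() < total_lesions:
            eligible = np.flatnonzero(counts < kmax)
            counts[rng.choice(eligible)] += 1
        else:
            eligible = np.flatnonzero(counts > 1)
            counts[rng.choice(eligible)] -= 1
    return counts


def _draw_shape_fractions(rng: np.random.Generator, sigma: float) -> tuple[float, float, float]:
    """Axis fractions c with prod(c) = 1 so diameter products track volume."""
    logs = rng.normal(0.0, sigma, size=3)
    logs -= logs.mean()
    return tuple(np.exp(logs))


def _noise(rng: np.random.Generator, cv: float) -> float:
    if cv <= 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))


def generate_cohort(
    config: CohortConfig, total_lesions: int | None = None
) -> list[SimulatedLesion]:
    """Draw a reproducible cohort of lesions with longitudinal measurements.

    When ``total_lesions`` is given, per-patient lesion counts are resampled
    toward that exact total (e.g. 62 patients carrying 115 lesions).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    counts = _sample_lesion_counts(rng, config, total_lesions)
    class_names = list(config.class_probs)
    class_p = np.asarray([config.class_probs[c] for c in class_names])
    site_names = list(config.primary_site_probs)
    site_p = np.asarray([config.primary_site_probs[s] for s in site_names])

    lesions: list[SimulatedLesion] = []
    for p_idx, n_lesions in enumerate(counts):
        patient_id = f"P{p_idx:03d}"
        site = site_names[rng.choice(len(site_names), p=site_p)]
        for l_idx in range(n_lesions):
            lesion_id = f"{patient_id}L{l_idx}"
            true_class = class_names[rng.choice(len(class_names), p=class_p)]
            kin = config.growth[true_class]
            d_gm = config.baseline_diameter_median_mm * math.exp(
                rng.normal(0.0, config.baseline_diameter_sigma_ln)
            )
            v0 = d_gm**3
            if true_class == "pseudo_progression":
                lo, hi = config.pp_onset_window_months
                bump_onset = float(rng.uniform(lo, hi))
                bump_dur = config.pp_duration_months
                amp = config.bump_amplitude
            elif true_class == "radiation_necrosis":
                bump_onset = config.rn_onset_months_min + float(rng.uniform(0.0, 3.0))
                bump_dur = None
                amp = config.bump_amplitude
            else:
                bump_onset, bump_dur, amp = None, None, 0.0
            kernel = LesionKernelParams(
                v0_mm3=v0,
                growth_rate_per_month=kin.growth_rate_per_month,
                growth_onset_months=kin.onset_months,
                bump_amplitude=amp,
                bump_onset_months=bump_onset,
                bump_duration_months=bump_dur,
            )
            fractions = _draw_shape_fractions(rng, config.shape_ratio_sigma_ln)

            def measured_diams(t: float) -> tuple[float, float, float]:
                v = expected_volume(true_class, kernel, t)
                side = v ** (1.0 / 3.0)
                return tuple(
                    side * c * _noise(rng, config.diameter_noise_cv) for c in fractions
                )

            d0 = measured_diams(0.0)
            rano0 = max(d0) * _noise(rng, config.diameter_noise_cv)
            tps = []
            for t in config.followup_schedule_months:
                d = measured_diams(float(t))
                rano_measurable = rng.random() >= config.rano_unmeasurable_prob
                rano = max(d) * _noise(rng, config.diameter_noise_cv)
                tps.append(
                    Timepoint(
                        months=float(t),
                        d_pa_mm=d[0],
                        d_ml_mm=d[1],
                        d_si_mm=d[2],
                        rano_mm=rano if rano_measurable else None,
                        measurable=True,
                    )
                )
            annotation = {
                "pseudo_progression": TrscAnnotation.PP,
                "radiation_necrosis": TrscAnnotation.RN,
            }.get(true_class, TrscAnnotation.NONE)
            lesions.append(
                SimulatedLesion(
                    lesion_id=lesion_id,
                    patient_id=patient_id,
                    true_class=true_class,
                    primary_site=site,
                    baseline_dpa_mm=d0[0],
                    baseline_dml_mm=d0[1],
                    baseline_dsi_mm=d0[2],
                    baseline_rano_mm=rano0,
                    series=MeasurementSeries(tps),
                    trsc_annotation=annotation,
                    kernel=kernel,
                    shape_fractions=fractions,
                )
            )
    return lesions


def cohort_to_tables(lesions: list[SimulatedLesion]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Serialize a cohort as (lesions.csv, measurements.csv) DataFrames."""
    lesion_rows, meas_rows = [], []
    for les in lesions:
        lesion_rows.append(
            {
                "lesion_id": les.lesion_id,
                "patient_id": les.patient_id,
                "primary_site": les.primary_site,
                "true_class": les.true_class,
                "trsc_annotation": les.trsc_annotation.value,
                "baseline_d_pa_mm": les.baseline_dpa_mm,
                "baseline_d_ml_mm": les.baseline_dml_mm,
                "baseline_d_si_mm": les.baseline_dsi_mm,
                "baseline_rano_mm": les.baseline_rano_mm,
            }
        )
        for tp in les.series:
            meas_rows.append(
                {
                    "lesion_id": les.lesion_id,
                    "months": tp.months,
                    "d_pa_mm": tp.d_pa_mm,
                    "d_ml_mm": tp.d_ml_mm,
                    "d_si_mm": tp.d_si_mm,
                    "rano_mm": np.nan if tp.rano_mm is None else tp.rano_mm,
                    "measurable": int(tp.measurable),
                }
            )
    return pd.DataFrame(lesion_rows), pd.DataFrame(meas_rows)


@dataclass
class FeatureTableConfig:
    n_features: int = 107
    n_informative: int = 10
    effect_size_d: float = 1.0
    block_size: int = 1
    within_block_rho: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("n_informative must be <= n_features")
        if not -1.0 < self.within_block_rho <= 1.0:
            raise ValueError("within_block_rho must be in (-1, 1]")
        if self.effect_size_d < 0:
            raise ValueError("effect_size_d must be >= 0")


def feature_names(n_features: int) -> list[str]:
    """Stable feature names; the 107-column default reuses the radiomic names."""
    if n_features == 107:
        from .radiomics.extract import FEATURE_NAMES

        return list(FEATURE_NAMES)
    return [f"f{i:03d}" for i in range(n_features)]


def generate_feature_table(
    labels: np.ndarray | pd.Series,
    config: FeatureTableConfig,
    lesion_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Class-conditional Gaussian feature matrix with block correlation.

    Informative columns are N(d*y, 1); the rest N(0, 1). Columns within each
    consecutive block of ``block_size`` share an equicorrelated Gaussian noise
    component with correlation ``within_block_rho``.
    """
    config.validate()
    y = np.asarray(labels, dtype=int)
    n = len(y)
    rng = np.random.default_rng(config.seed)
    p = config.n_features
    rho = config.within_block_rho
    if config.block_size > 1 and rho != 0.0:
        if rho < 0:
            raise ValueError("within_block_rho must be >= 0 for blocks wider than 1")
        z = np.empty((n, p))
        for start in range(0, p, config.block_size):
            width = min(config.block_size, p - start)
            shared = rng.standard_normal((n, 1))
            own = rng.standard_normal((n, width))
            z[:, start : start + width] = (
                math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * own
            )
    else:
        z = rng.standard_normal((n, p))
    x = z.copy()
    x[:, : config.n_informative] += config.effect_size_d * y[:, None]
    df = pd.DataFrame(x, columns=feature_names(p))
    if lesion_ids is not None:
        df.insert(0, "lesion_id", lesion_ids)
        df = df.set_index("lesion_id")
    return df


def cohort_feature_table(
    lesions: list[SimulatedLesion], config: FeatureTableConfig
) -> pd.DataFrame:
    """Feature table informative of ground-truth eventual progression."""
    y = np.array([int(l.eventual_progressor) for l in lesions])
    ids = [l.lesion_id for l in lesions]
    return generate_feature_table(y, config, lesion_ids=ids)
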