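import numpy as np
import pytest

from bmprog.labeling import (
    LabelableLesion,
    MeasurementSeries,
    Timepoint,
    TrscAnnotation,
)


def random_lesion(rng: np.random.Generator, lesion_id: str = "L0") -> LabelableLesion:
    """A random lesion series that stresses the labeling rule boundaries:
    small and large baselines, shrinking/growing follow-ups, occasional
    missing RANO measurements, all three TRSC annotations."""
    base = float(rng.uniform(1.5, 25.0))
    diams = base * rng.uniform(0.7, 1.3, size=3)
    rano0 = float(diams.max() * rng.uniform(0.95, 1.05))
    months = np.sort(rng.choice(np.arange(1, 25), size=rng.integers(0, 8), replace=False))
    tps = []
    for m in months:
        factor = float(rng.uniform(0.4, 2.2))  # spans regression to progression
        d = diams * factor * rng.uniform(0.95, 1.05, size=3)
        rano = float(d.max() * rng.uniform(0.95, 1.05))
        tps.append(
            Timepoint(
                months=float(m),
                d_pa_mm=float(d[0]),
                d_ml_mm=float(d[1]),
                d_si_mm=float(d[2]),
                rano_mm=None if rng.random() < 0.1 else rano,
                measurable=True,
            )
        )
    annotation = [TrscAnnotation.NONE, TrscAnnotation.PP, TrscAnnotation.RN][
        rng.choice(3, p=[0.6, 0.2, 0.2])
    ]
    return LabelableLesion(
        lesion_id=lesion_id,
        baseline_d_pa_mm=float(diams[0]),
        baseline_d_ml_mm=float(diams[1]),
        baseline_d_si_mm=float(diams[2]),
        baseline_rano_mm=rano0,
        series=MeasurementSeries(tps),
        trsc_annotation=annotation,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
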