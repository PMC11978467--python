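"""Independent straight-line oracles used to cross-check the package.

These deliberately re-derive the rules with plain loops and no shared code
with the implementation under test.
"""

from __future__ import annotations

import numpy as np


def oracle_label(lesion, window_months, metric, scheme) -> str:
    """Three-way label from a literal reading of the definition grid rules."""
    tps = [tp for tp in lesion.series if tp.months < window_months]
    b_pa, b_ml, b_si = (
        lesion.baseline_d_pa_mm,
        lesion.baseline_d_ml_mm,
        lesion.baseline_d_si_mm,
    )
    v0 = b_pa * b_ml * b_si
    rano0 = lesion.baseline_rano_mm

    # --- size-based progression -------------------------------------------
    prog = False
    if metric == "RANO_20":
        if rano0 is None:
            raise ValueError("baseline RANO diameter missing")
        for tp in tps:
            if tp.rano_mm is None:
                continue
            pct_ok = tp.rano_mm >= 1.2 * rano0
            small_rule_ok = rano0 >= 10.0 or (tp.rano_mm - rano0) >= 3.0
            if pct_ok and small_rule_ok:
                prog = True
    else:
        pct = {"VOL_10": 10.0, "VOL_15": 15.0, "VOL_20": 20.0, "VOL_25": 25.0}[metric]
        for tp in tps:
            if not tp.measurable:
                continue
            v = tp.d_pa_mm * tp.d_ml_mm * tp.d_si_mm
            if v >= v0 * (1.0 + pct / 100.0) and (v - v0) >= 27.0:
                prog = True

    # --- TRSC adjudication -------------------------------------------------
    ann = getattr(lesion.trsc_annotation, "value", lesion.trsc_annotation)
    if prog:
        if ann == "PP" and scheme not in ("TRUE_PLUS_PP", "TRUE_PLUS_RN_PP"):
            prog = False
        if ann == "RN" and scheme not in ("TRUE_PLUS_RN", "TRUE_PLUS_RN_PP"):
            prog = False
    if prog:
        return "progressing"

    # --- stable vs regressing ---------------------------------------------
    if metric == "RANO_20":
        usable = [tp for tp in tps if tp.rano_mm is not None]
        if usable and usable[-1].rano_mm <= 0.7 * rano0:
            return "regressing"
        return "stable"
    usable = [tp for tp in tps if tp.measurable]
    if not usable:
        return "stable"
    last = usable[-1]
    v = last.d_pa_mm * last.d_ml_mm * last.d_si_mm
    pct = {"VOL_10": 10.0, "VOL_15": 15.0, "VOL_20": 20.0, "VOL_25": 25.0}[metric]
    if v <= v0 * (1.0 - pct / 100.0) and (v0 - v) >= 27.0:
        return "regressing"
    return "stable"


def pairwise_auc(scores, labels) -> float:
    """Concordance AUC by exhaustive positive/negative pair enumeration."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = concordant = 0.0
    for p in pos:
        for q in neg:
            total += 1.0
            if p > q:
                concordant += 1.0
            elif p == q:
                concordant += 0.5
    return concordant / total
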