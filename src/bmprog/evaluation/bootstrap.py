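"""Bootstrap-with-resampling train/test splits.

The resampling unit is the patient by default: all of a patient's lesions
travel together into the training multiset, which prevents within-patient
leakage between partitions. The out-of-bag lesions (those of never-sampled
patients) form the test set, ~1/e of units in expectation. A lesion-level
unit is available as a config switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class BootstrapSplit:
    """Row indices: train is a multiset (duplicates allowed), test a set."""

    train_rows: np.ndarray
    test_rows: np.ndarray

    @property
    def test_fraction(self) -> float:
        n = len(set(self.train_rows.tolist())) + len(self.test_rows)
        return len(self.test_rows) / n


def bootstrap_split(
    groups: np.ndarray | pd.Series,
    seed: int | np.random.Generator,
    unit: str = "patient",
) -> BootstrapSplit:
    """One bootstrap resample; train support and test partition the rows."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    groups = np.asarray(groups)
    n = len(groups)
    if unit == "lesion":
        sampled = rng.integers(0, n, size=n)
        in_bag = np.zeros(n, dtype=bool)
        in_bag[sampled] = True
        return BootstrapSplit(np.sort(sampled), np.flatnonzero(~in_bag))
    if unit != "patient":
        raise ValueError(f"unknown bootstrap unit {unit!r}")
    patients, first_idx = np.unique(groups, return_index=True)
    patients = patients[np.argsort(first_idx)]  # order of appearance
    n_patients = len(patients)
    if n_patients < 2:
        raise ValueError("need at least 2 patients to bootstrap")
    rows_of = {p: np.flatnonzero(groups == p) for p in patients}
    sampled = rng.integers(0, n_patients, size=n_patients)
    train = np.concatenate([rows_of[patients[k]] for k in sampled])
    in_bag_patients = set(patients[np.unique(sampled)].tolist())
    test = np.flatnonzero([g not in in_bag_patients for g in groups])
    return BootstrapSplit(np.sort(train), test)
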