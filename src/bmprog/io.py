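"""CSV/JSON/YAML interchange for cohorts, features, labels and results."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

LESIONS_COLUMNS = [
    "lesion_id",
    "patient_id",
    "primary_site",
    "true_class",
    "trsc_annotation",
    "baseline_d_pa_mm",
    "baseline_d_ml_mm",
    "baseline_d_si_mm",
    "baseline_rano_mm",
]
MEASUREMENTS_COLUMNS = [
    "lesion_id",
    "months",
    "d_pa_mm",
    "d_ml_mm",
    "d_si_mm",
    "rano_mm",
    "measurable",
]


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing columns: {', '.join(missing)}")


def read_lesions_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(
        df,
        [c for c in LESIONS_COLUMNS if c not in ("patient_id", "primary_site", "true_class")],
        "lesions table",
    )
    return df


def read_measurements_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, [c for c in MEASUREMENTS_COLUMNS if c != "measurable"], "measurements table")
    if "measurable" not in df.columns:
        df["measurable"] = 1
    return df


def read_features_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["lesion_id"], "features table")
    return df.set_index("lesion_id")


def write_csv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        if str(path).endswith((".yaml", ".yml")):
            return yaml.safe_load(fh)
        return json.load(fh)


def write_yaml(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
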