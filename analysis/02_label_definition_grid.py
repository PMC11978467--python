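#!/usr/bin/env python
"""Label the simulated cohort under all 14 definitions of progression.

For each grid cell (follow-up window x size-change metric x TRSC scheme)
every lesion is assigned progressing / stable / regressing, and the
per-definition label counts — the analog of a labeling-breakdown figure —
are tabulated. Expects 01_simulate_cohort.py to have run.

Writes results/labels/{labels,label_counts}.csv.
"""

from pathlib import Path

import pandas as pd

from bmprog import io
from bmprog.grid import build_default_grid
from bmprog.labeling import TaskMode, binary_outcome, label_cohort, lesions_from_tables

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    lesions = lesions_from_tables(
        io.read_lesions_csv(ROOT / "cohort" / "lesions.csv"),
        io.read_measurements_csv(ROOT / "cohort" / "measurements.csv"),
    )
    grid = build_default_grid()
    frames, counts = [], []
    for row in grid.rows:
        df = label_cohort(lesions, row.definition)
        df["definition_id"] = row.definition_id
        df["binary_failure"] = [
            binary_outcome(t, TaskMode.PROG_VS_REST) for t in df["three_way"]
        ]
        c = df["three_way"].value_counts()
        counts.append(
            {
                "definition_id": row.definition_id,
                "category": row.category,
                "n_progressing": int(c.get("progressing", 0)),
                "n_stable": int(c.get("stable", 0)),
                "n_regressing": int(c.get("regressing", 0)),
            }
        )
        frames.append(df)
    labels = pd.concat(frames, ignore_index=True)
    count_df = pd.DataFrame(counts)
    io.write_csv(labels, ROOT / "labels" / "labels.csv")
    io.write_csv(count_df, ROOT / "labels" / "label_counts.csv")

    print("label counts per definition (rows sum to the cohort size):")
    print(count_df.to_string(index=False))
    print(f"wrote {ROOT / 'labels'}/")


if __name__ == "__main__":
    main()
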