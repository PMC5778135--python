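#!/usr/bin/env python
"""Format the raw burden and sensitivity outputs into the final tables.

Reads results/matrix_raw.csv and results/sa*_raw.csv (from steps 03-04),
writes the burden matrix in millions/yr, the SA deltas in thousands/yr
and the cross-SSP RCP8.5-vs-RCP4.5 percentage-increase table under
results/tables/, and cross-checks the percentage-increase routine
against the shipped published burden table.
"""

from pathlib import Path

import pandas as pd

from pm25burden import load_reference_burden_table, pct_increase_bounds, report_tables
from pm25burden.attribution import SensitivityResult

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    results = ROOT / "results"
    matrix = pd.read_csv(results / "matrix_raw.csv")
    sensitivities = [
        SensitivityResult(study, pd.read_csv(results / f"{study.lower()}_raw.csv"))
        for study in ("SA1", "SA2", "SA3", "SA4")
        if (results / f"{study.lower()}_raw.csv").exists()
    ]
    written = report_tables(matrix, sensitivities, results / "tables")
    for name, path in written.items():
        print(f"wrote {name}: {path.relative_to(ROOT)}")

    print("\nsynthetic-study RCP8.5 excess burden across SSPs (% of RCP4.5):")
    print(pd.read_csv(written["rcp_increase"]).to_string(index=False))

    ref = pct_increase_bounds(load_reference_burden_table())
    near = ref[ref.decade == "2031-2040"].iloc[0]
    far = ref[ref.decade == "2091-2100"].iloc[0]
    print("\npublished-table consistency check (same routine, shipped table):")
    print(f"  2031-2040: {near['min']:.1f}-{near['max']:.1f}%   "
          f"2091-2100: {far['min']:.1f}-{far['max']:.1f}%")


if __name__ == "__main__":
    main()
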