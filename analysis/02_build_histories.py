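#!/usr/bin/env python
"""Classify migration histories from the observed residence sequences,
impute censored migration ages, and aggregate deaths and person-years into
the model's exposure table."""

from pathlib import Path

import pandas as pd

from migmort.pipeline import PipelineConfig, run

ROOT = Path(__file__).resolve().parents[1]
RUN = ROOT / "results" / "study"


def main():
    cfg = PipelineConfig.from_yaml(ROOT / "analysis" / "config.yaml")
    run(cfg, RUN, through="build-table")
    imputed = pd.read_csv(RUN / "imputed_ages.csv")
    table = pd.read_csv(RUN / "exposure_table.csv")
    print(f"imputed/observed event ages for {len(imputed):,} move events")
    print(f"exposure table: {len(table):,} cells, "
          f"{table.E.sum():,.0f} person-years, {table.D_total.sum():,.0f} deaths")
    print("status composition of exposure:")
    print(table.groupby("status")[["E", "D_total"]].sum().round(0))


if __name__ == "__main__":
    main()
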