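#!/usr/bin/env python
"""Average marginal age-specific mortality rates per migration status and
stayer-over-mover rate ratios with 90% simulation bands; plots the
log-rate and ratio panels."""

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from migmort.pipeline import PipelineConfig, run

ROOT = Path(__file__).resolve().parents[1]
RUN = ROOT / "results" / "study"


def main():
    cfg = PipelineConfig.from_yaml(ROOT / "analysis" / "config.yaml")
    run(cfg, RUN, through="marginalize")
    rates = pd.read_csv(RUN / "marginal_rates.csv")
    ratios = pd.read_csv(RUN / "rate_ratios.csv")
    allc = ratios[ratios.cause == "total"]
    for (sex, status), grp in allc.groupby(["sex", "status"]):
        young = grp.loc[grp.age.idxmin()]
        print(f"[{sex}] stayer/{status} ratio at age {young.age}: "
              f"{young.ratio:.2f} [{young.lower90:.2f}, {young.upper90:.2f}]")

    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharex=True)
    for status, grp in rates[rates.cause == "total"].groupby("status"):
        g = grp[grp.sex == "m"]
        axes[0].plot(g.age, np.log(g.rate), label=status)
    axes[0].set(title="log mortality rate (males)", xlabel="age", ylabel="log rate")
    axes[0].legend()
    for status, grp in allc[allc.sex == "m"].groupby("status"):
        axes[1].plot(grp.age, grp.ratio, label=status)
        axes[1].fill_between(grp.age, grp.lower90, grp.upper90, alpha=0.2)
    axes[1].axhline(1.0, color="k", lw=0.5)
    axes[1].set(title="stayer / mover rate ratio (males)", xlabel="age")
    fig.tight_layout()
    fig.savefig(RUN / "rates_and_ratios.png", dpi=120)
    print(f"wrote {RUN / 'rates_and_ratios.png'}")


if __name__ == "__main__":
    main()
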