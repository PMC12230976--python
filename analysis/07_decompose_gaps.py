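#!/usr/bin/env python
"""Decompose the mover-versus-stayer temporary-life-expectancy gaps into
age x cause contributions by the line-integral method; plots stacked
contribution bars."""

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
    run(cfg, RUN, through="report")
    shares = pd.read_csv(RUN / "cause_shares.csv")
    for (sex, status), grp in shares.groupby(["sex", "status"]):
        total = grp.total_gap_years.iloc[0] * 12
        print(f"[{sex}] {status} vs stayer gap {total:+.1f} months; cause shares:")
        for _, row in grp.sort_values("share", ascending=False).iterrows():
            print(f"    {row.cause:20s} {100 * row.share:+6.1f}%")

    decomp = pd.read_csv(RUN / "decomposition.csv")
    sub = decomp[(decomp.sex == "m")]
    statuses = sub.status.unique()
    fig, axes = plt.subplots(1, len(statuses), figsize=(5 * len(statuses), 4),
                             squeeze=False)
    for ax, status in zip(axes[0], statuses):
        pv = sub[sub.status == status].pivot(index="age", columns="cause",
                                             values="years")
        bottom_pos = np.zeros(len(pv))
        bottom_neg = np.zeros(len(pv))
        for cause in pv.columns:
            vals = pv[cause].to_numpy()
            base = np.where(vals >= 0, bottom_pos, bottom_neg)
            ax.bar(pv.index, vals, width=2.5, bottom=base, label=cause)
            bottom_pos += np.clip(vals, 0, None)
            bottom_neg += np.clip(vals, None, 0)
        ax.axhline(0, color="k", lw=0.5)
        ax.set(title=f"{status} vs stayer (males)", xlabel="age", ylabel="years")
    axes[0][0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(RUN / "decomposition.png", dpi=120)
    print(f"wrote {RUN / 'decomposition.png'}")


if __name__ == "__main__":
    main()
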