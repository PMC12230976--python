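#!/usr/bin/env python
"""Fit the negative-binomial GAMs (per sex, all-cause and cause-specific)
and report overdispersion, smooth complexity and convergence."""

from pathlib import Path

from migmort.pipeline import PipelineConfig, PipelineRun

ROOT = Path(__file__).resolve().parents[1]
RUN = ROOT / "results" / "study"


def main():
    cfg = PipelineConfig.from_yaml(ROOT / "analysis" / "config.yaml")
    r = PipelineRun(cfg, RUN)
    models = r.stage_fit()
    for (sex, cause), model in sorted(models.items()):
        edf = sum(model.edf.values())
        print(f"[{sex} {cause:12s}] theta={model.theta:9.1f}  "
              f"total smooth edf={edf:5.1f}  deviance={model.deviance:9.1f}  "
              f"converged={model.converged}")


if __name__ == "__main__":
    main()
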