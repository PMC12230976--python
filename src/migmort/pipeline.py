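"""End-to-end orchestration: simulate -> observe -> classify -> impute ->
aggregate -> fit -> marginalise -> life tables -> decompose -> report.

A run directory holds every stage's artifacts (CSV tables, model bundles, a
JSON manifest with the config hash, seed and stage log).  Re-running with
an unchanged config and seed reuses completed stage artifacts (hash check),
so a finished run is a no-op; numeric artifacts are byte-identical across
repeated runs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import censoring, gam, histories, lifetable, marginal, simulate
from .decompose import decompose, summarize_contributions
from .simulate import CAUSES, Population, SimulationConfig

STAGES = ("simulate", "build-table", "impute", "fit", "marginalize",
          "lifetable", "decompose", "report")

_SIM_KEYS = {
    "n_individuals", "n_regions", "years", "cohort_range", "sex_ratio",
    "return_hazard", "onward_hazard", "illdefined_fraction",
    "death_year_residence", "death_year_exposure", "status_effects",
    "out_migration_hazard",
}


@dataclass
class PipelineConfig:
    """Validated pipeline settings; unknown keys are rejected."""

    seed: int
    n_individuals: int = 20_000
    simulation: dict = field(default_factory=dict)
    observed_years: list | None = None
    status_detail: str = "coarse"       # "coarse" (stayer/leaver/returnee) or "bands"
    causes: bool = False                # fit cause-specific models and decompose
    model: dict = field(default_factory=dict)
    n_draws: int = 1000
    exposure_weighted: bool = False
    gap_from_ages: tuple = (20, 50, 80)
    n_steps: int = 1000
    age_range: tuple = (20, 95)
    group_width: int = 3

    def __post_init__(self):
        if self.status_detail not in ("coarse", "bands"):
            raise ValueError("status_detail must be 'coarse' or 'bands'")
        unknown = set(self.simulation) - _SIM_KEYS
        if unknown:
            raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
        gam.ModelSpec(**self.model)  # validates model keys

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def simulation_config(self) -> SimulationConfig:
        kw = dict(self.simulation)
        if "out_migration_hazard" in kw and isinstance(kw["out_migration_hazard"], dict):
            kw["out_migration_hazard"] = simulate.AgeBandHazard.from_dict(
                kw["out_migration_hazard"])
        for key in ("years", "cohort_range"):
            if key in kw:
                kw[key] = tuple(kw[key])
        kw.setdefault("n_individuals", self.n_individuals)
        kw.setdefault("seed", self.seed)
        return SimulationConfig(**kw)

    def model_spec(self) -> gam.ModelSpec:
        return gam.ModelSpec(**self.model)


class PipelineRun:
    """Stage runner bound to a run directory; see module docstring."""

    def __init__(self, config: PipelineConfig, outdir):
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.outdir / "manifest.json"
        self.manifest = self._load_manifest()
        self._pop: Population | None = None
        self._status = None
        self._table = None
        self._models: dict = {}

    # -- manifest ------------------------------------------------------
    def _load_manifest(self) -> dict:
        if self.manifest_path.exists():
            m = json.loads(self.manifest_path.read_text())
            if m.get("config_hash") == self.config.config_hash():
                return m
        return {"config_hash": self.config.config_hash(),
                "seed": self.config.seed, "stages": {}}

    def _save_manifest(self) -> None:
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1))

    def _done(self, stage: str, outputs: list) -> bool:
        rec = self.manifest["stages"].get(stage)
        return bool(rec and rec.get("complete")
                    and all((self.outdir / f).exists() for f in outputs))

    def _mark(self, stage: str, outputs: list, t0: float, **extra) -> None:
        self.manifest["stages"][stage] = {
            "complete": True, "outputs": outputs,
            "seconds": round(time.time() - t0, 3), **extra}
        self._save_manifest()

    # -- stages --------------------------------------------------------
    def stage_simulate(self) -> Population:
        outputs = ["persons.csv", "residence.csv", "truth_sidecar.csv"]
        cfg = self.config.simulation_config()
        if self._pop is None and self._done("simulate", outputs):
            self._pop = simulate.population_from_frames(
                pd.read_csv(self.outdir / "persons.csv"),
                pd.read_csv(self.outdir / "residence.csv"),
                pd.read_csv(self.outdir / "truth_sidecar.csv"),
                follow_up=cfg.years,
                observed_years=self.manifest["stages"]["simulate"]["observed_years"])
        if self._pop is None:
            t0 = time.time()
            pop = simulate.simulate_population(cfg)
            pop = simulate.apply_observation_scheme(pop, self.config.observed_years)
            pop.person_table().to_csv(self.outdir / "persons.csv", index=False)
            pop.residence_long().to_csv(self.outdir / "residence.csv", index=False)
            # ground truth lives in a sidecar for test harnesses only
            pop.truth_table().to_csv(self.outdir / "truth_sidecar.csv", index=False)
            self._mark("simulate", outputs, t0, n=pop.n,
                       observed_years=pop.observed_years.tolist())
            self._pop = pop
        return self._pop

    def stage_impute(self):
        pop = self.stage_simulate()
        outputs = ["imputed_ages.csv"]
        t0 = time.time()
        cats, n_uncl = histories.classify_population(pop)
        if self._done("impute", outputs):
            imputed = pd.read_csv(self.outdir / "imputed_ages.csv")
            records = censoring.extract_censoring_records(pop, cats)
        else:
            records = censoring.extract_censoring_records(pop, cats)
            if records.empty:
                imputed = pd.DataFrame(columns=["person_id", "event", "age"])
            else:
                rc = censoring.extract_right_censored(pop, cats)
                model = censoring.fit_event_age_model(records, "first_migration",
                                                      right_censored=rc)
                first = censoring.impute_ages(
                    records[records["event"] == "first_migration"], model,
                    seed=self.config.seed + 1)
                ret_rec = records[records["event"] == "return"]
                if len(ret_rec):
                    rmodel = censoring.fit_event_age_model(records, "return")
                    ret = censoring.impute_ages(ret_rec, rmodel,
                                                seed=self.config.seed + 2)
                    imputed = pd.concat([first, ret], ignore_index=True)
                else:
                    imputed = first
            imputed.to_csv(self.outdir / "imputed_ages.csv", index=False)
            self._mark("impute", outputs, t0, n_unclassifiable=n_uncl,
                       n_records=len(records))
        return pop, cats, imputed

    def stage_build_table(self) -> pd.DataFrame:
        outputs = ["exposure_table.csv"]
        if self._table is None and self._done("build-table", outputs):
            self._table = pd.read_csv(self.outdir / "exposure_table.csv")
            self._table.attrs["group_width"] = self.config.group_width
        if self._table is None:
            pop, cats, imputed = self.stage_impute()
            t0 = time.time()
            if self.config.status_detail == "bands":
                ages = censoring.event_ages_for_bands(pop, cats, imputed)
                status = histories.assign_status_bands(cats, ages)
            else:
                status = cats
            cfg = self.config.simulation_config()
            table = histories.build_exposure_table(
                pop, status, age_range=tuple(self.config.age_range),
                group_width=self.config.group_width,
                death_year_fraction=cfg.death_year_exposure)
            table = histories.redistribute_illdefined(table)
            table.to_csv(self.outdir / "exposure_table.csv", index=False)
            self._mark("build-table", outputs, t0, n_rows=len(table),
                       total_E=float(table["E"].sum()),
                       total_D=float(table["D_total"].sum()))
            self._table = table
        return self._table

    def _cause_list(self):
        return ["total"] + (list(CAUSES) if self.config.causes else [])

    def stage_fit(self) -> dict:
        table = self.stage_build_table()
        spec = self.config.model_spec()
        t0 = time.time()
        fitted_any = False
        for sex in ("f", "m"):
            sub = table[table["sex"] == sex]
            if sub.empty:
                continue
            for cause in self._cause_list():
                key = (sex, cause)
                bundle = self.outdir / f"model_{sex}_{cause}"
                if key in self._models:
                    continue
                if self._done(f"fit:{sex}:{cause}", [bundle.name + "/model.json"]):
                    self._models[key] = gam.FittedMortalityModel.load(bundle)
                    continue
                fit_tab = sub
                if cause != "total":
                    lo, hi = gam.restrict_cause_ages(sub, cause,
                                                     age_range=tuple(self.config.age_range))
                    fit_tab = sub[(sub["age_mid"] >= lo) & (sub["age_mid"] <= hi)]
                design = gam.build_design(fit_tab, spec,
                                          response="D_total" if cause == "total"
                                          else "D_" + cause)
                model = gam.fit(design, spec)
                model.save(bundle)
                self._mark(f"fit:{sex}:{cause}", [bundle.name + "/model.json"],
                           t0, theta=model.theta, deviance=model.deviance,
                           converged=model.converged)
                self._models[key] = model
                fitted_any = True
        if fitted_any or "fit" not in self.manifest["stages"]:
            self._mark("fit", [], t0)
        return self._models

    def stage_marginalize(self):
        models = self.stage_fit()
        t0 = time.time()
        sched_frames, ratio_frames = [], []
        self._schedules = {}
        self._ratios = {}
        for (sex, cause), model in models.items():
            schedules = marginal.average_marginal_rates(
                model, n_draws=self.config.n_draws, seed=self.config.seed + 3,
                exposure_weighted=self.config.exposure_weighted, sex=sex, cause=cause)
            ratios = marginal.rate_ratios(schedules)
            self._schedules[(sex, cause)] = schedules
            self._ratios[(sex, cause)] = ratios
            sched_frames += [s.to_frame() for s in schedules.values()]
            ratio_frames += [r.to_frame() for r in ratios.values()]
        pd.concat(sched_frames, ignore_index=True).to_csv(
            self.outdir / "marginal_rates.csv", index=False)
        if ratio_frames:
            pd.concat(ratio_frames, ignore_index=True).to_csv(
                self.outdir / "rate_ratios.csv", index=False)
        self._mark("marginalize", ["marginal_rates.csv"], t0)
        return self._schedules, self._ratios

    def stage_lifetable(self):
        schedules, _ = self.stage_marginalize()
        t0 = time.time()
        width = self.config.group_width
        close = float(self.config.age_range[1])
        lt_frames, gap_frames = [], []
        self._expectancies = {}
        for (sex, cause), sch in schedules.items():
            if cause != "total":
                continue
            for status, s in sch.items():
                starts = s.ages - width / 2.0
                lt = lifetable.build_partial_life_table(starts, s.rate,
                                                        closeout_age=min(close, starts[-1] + width))
                lt.insert(0, "status", status)
                lt.insert(0, "sex", sex)
                lt_frames.append(lt)
                for a in self.config.gap_from_ages:
                    if a >= starts[0] and a < starts[-1] + width:
                        self._expectancies.setdefault((sex, float(a)), {})[status] = \
                            lifetable.temporary_expectancy(lt, float(a))
        for (sex, a), exp_map in self._expectancies.items():
            if "stayer" not in exp_map:
                continue
            g = lifetable.gap_table(exp_map)
            g.insert(0, "from_age", a)
            g.insert(0, "sex", sex)
            gap_frames.append(g)
        pd.concat(lt_frames, ignore_index=True).to_csv(
            self.outdir / "life_tables.csv", index=False)
        if gap_frames:
            pd.concat(gap_frames, ignore_index=True).to_csv(
                self.outdir / "expectancy_gaps.csv", index=False)
        self._mark("lifetable", ["life_tables.csv"], t0)
        return self._expectancies

    def stage_decompose(self):
        if not self.config.causes:
            return {}
        schedules, _ = self.stage_marginalize()
        t0 = time.time()
        width = self.config.group_width
        close = float(self.config.age_range[1])
        self._decomps = {}
        frames, share_frames = [], []
        for sex in ("f", "m"):
            if (sex, "total") not in schedules:
                continue
            all_cause = schedules[(sex, "total")]
            for status in all_cause:
                if status == "stayer":
                    continue
                ages = np.intersect1d(all_cause["stayer"].ages, all_cause[status].ages)
                if ages.size < 2:
                    continue

                def rate_matrix(st):
                    R = np.zeros((ages.size, len(CAUSES)))
                    for j, c in enumerate(CAUSES):
                        sch = schedules.get((sex, c), {}).get(st)
                        if sch is None:
                            continue
                        common, ia, ib = np.intersect1d(ages, sch.ages,
                                                        return_indices=True)
                        R[ia, j] = sch.rate[ib]
                    return R

                starts = ages - width / 2.0
                res = decompose(rate_matrix("stayer"), rate_matrix(status),
                                starts, causes=list(CAUSES),
                                n_steps=self.config.n_steps,
                                closeout_age=min(close, starts[-1] + width),
                                pair=(status, "stayer"), sex=sex)
                self._decomps[(sex, status)] = res
                f = res.to_frame()
                f.insert(0, "status", status)
                f.insert(0, "sex", sex)
                frames.append(f)
                s = summarize_contributions(res)
                s.insert(0, "status", status)
                s.insert(0, "sex", sex)
                s["total_gap_years"] = res.total_gap
                share_frames.append(s)
        if frames:
            pd.concat(frames, ignore_index=True).to_csv(
                self.outdir / "decomposition.csv", index=False)
            pd.concat(share_frames, ignore_index=True).to_csv(
                self.outdir / "cause_shares.csv", index=False)
        self._mark("decompose", [], t0)
        return self._decomps

    def stage_report(self) -> str:
        expect = self.stage_lifetable()
        decomps = self.stage_decompose()
        _, ratios = self._schedules, self._ratios
        t0 = time.time()
        lines = [f"migmort pipeline run (seed {self.config.seed}, "
                 f"config {self.config.config_hash()})", ""]
        for (sex, cause), rr in ratios.items():
            if cause != "total":
                continue
            if not rr:
                lines.append(f"[{sex}] no mover groups present; "
                             "only stayer schedules were produced")
                continue
            for status, r in rr.items():
                i = 0
                lines.append(
                    f"[{sex}] stayer/{status} rate ratio at age {r.ages[i]}: "
                    f"{r.ratio[i]:.2f} [{r.lower90[i]:.2f}, {r.upper90[i]:.2f}]")
        for (sex, a), em in sorted(expect.items()):
            for status, e in em.items():
                if status == "stayer" or "stayer" not in em:
                    continue
                gap = (e - em["stayer"]) * 12.0
                pct = 100.0 * (e - em["stayer"]) / em["stayer"]
                lines.append(f"[{sex}] {status} vs stayer, years lived {a:.0f}-"
                             f"{self.config.age_range[1]}: gap {gap:+.1f} months "
                             f"({pct:+.1f}% of stayers')")
        for (sex, status), res in decomps.items():
            s = summarize_contributions(res)
            top = s.iloc[s["years"].abs().argmax()]
            lines.append(f"[{sex}] {status} vs stayer gap {res.total_gap*12:+.1f} "
                         f"months; largest cause contribution: {top['cause']} "
                         f"({100*top['share']:+.1f}%)")
        text = "\n".join(lines) + "\n"
        (self.outdir / "report.txt").write_text(text)
        self._mark("report", ["report.txt"], t0)
        return text


def run(config: PipelineConfig, outdir, through: str = "report") -> Path:
    """Execute the pipeline up to and including ``through`` (a STAGES name);
    returns the run directory."""
    if through not in STAGES:
        raise ValueError(f"unknown stage {through!r}")
    r = PipelineRun(config, outdir)
    order = {
        "simulate": r.stage_simulate, "impute": r.stage_impute,
        "build-table": r.stage_build_table, "fit": r.stage_fit,
        "marginalize": r.stage_marginalize, "lifetable": r.stage_lifetable,
        "decompose": r.stage_decompose, "report": r.stage_report,
    }
    for st in ("simulate", "impute", "build-table", "fit", "marginalize",
               "lifetable", "decompose", "report"):
        order[st]()
        if st == through:
            break
    return r.outdir
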