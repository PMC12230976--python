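"""Synthetic population register with migration and mortality.

Simulates individual residential histories between regions of a country
together with death times and causes, under a log-linear mortality model
whose linear predictor mirrors the mortality model fitted downstream:

    log rate(age, year, person) = baseline(age) + region_effect[birth region]
                                  + year_effect[year] + status_effect(latent status, age)

where the latent status is "stayer" (never left the birth region), "leaver"
(currently outside it) or "returnee" (left and currently back).  Time is
discrete (calendar years); within a year a person first moves, then faces a
death draw, and the year-end region is what a register would record on
December 31st.  Migration operates from birth, while mortality operates only
inside the follow-up window, so cohorts born before the window enter it
conditional on being alive — exactly the situation that produces left
censoring of migration ages once the observation scheme is applied.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

CAUSES = (
    "neoplasms",
    "dementia_alzheimers",
    "circulatory",
    "respiratory",
    "alcohol_related",
    "external",
)
ILL_DEFINED = "ill_defined"
ALL_CAUSE_LABELS = CAUSES + (ILL_DEFINED,)

#: latent status codes used by the generator
STAYER, LEAVER, RETURNEE = 0, 1, 2
LATENT_STATUS_NAMES = ("stayer", "leaver", "returnee")


class AgeBandHazard:
    """Piecewise-constant annual event probability by age band.

    ``bands`` maps ``(low, high)`` age intervals (closed-open) to annual
    probabilities.  Ages not covered get probability 0.  An optional
    per-sex multiplier scales the probability (clipped to [0, 1]).
    """

    def __init__(self, bands: Mapping[tuple[float, float], float],
                 sex_multiplier: tuple[float, float] = (1.0, 1.0)):
        self.bands = dict(bands)
        self.sex_multiplier = tuple(sex_multiplier)
        for (lo, hi), p in self.bands.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"hazard {p} for band [{lo},{hi}) outside [0,1]")

    def __call__(self, age: np.ndarray, sex: np.ndarray | None = None) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        p = np.zeros_like(age)
        for (lo, hi), v in self.bands.items():
            p[(age >= lo) & (age < hi)] = v
        if sex is not None:
            mult = np.asarray(self.sex_multiplier, dtype=float)[np.asarray(sex)]
            p = np.clip(p * mult, 0.0, 1.0)
        return p

    def to_dict(self) -> dict:
        return {"bands": {f"{lo}-{hi}": v for (lo, hi), v in self.bands.items()},
                "sex_multiplier": list(self.sex_multiplier)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "AgeBandHazard":
        bands = {}
        for key, v in d["bands"].items():
            lo, hi = key.split("-")
            bands[(float(lo), float(hi))] = float(v)
        return cls(bands, tuple(d.get("sex_multiplier", (1.0, 1.0))))


def _as_hazard(h) -> Callable:
    if callable(h):
        return h
    value = float(h)
    return lambda age, sex=None, _v=value: np.full(np.shape(age), _v, dtype=float)


def gompertz_log_mortality(a: float = 9e-5, b: float = 0.077) -> Callable:
    """Gompertz baseline: log rate(x) = log(a) + b*x."""
    log_a = np.log(a) if a > 0 else -np.inf
    return lambda age: log_a + b * np.asarray(age, dtype=float)


def default_out_migration_hazard() -> AgeBandHazard:
    # childhood moves with parents, peak at young-adult ages, low later;
    # together with the default return hazard this yields roughly 57% stayers,
    # 35% leavers and 8% returnees over the emulated cohorts
    return AgeBandHazard({(0, 17): 0.007, (17, 30): 0.030,
                          (30, 60): 0.005, (60, 120): 0.002})


def default_cause_mix(age: np.ndarray, status: np.ndarray) -> np.ndarray:
    """Cause-of-death mix over the 6 named groups, by broad age band.

    Young-adult deaths are dominated by external and alcohol-related causes,
    older deaths by circulatory disease and neoplasms, with dementia emerging
    at the oldest ages — the qualitative pattern of a high-income country.
    """
    age = np.asarray(age, dtype=float)
    out = np.empty((age.size, len(CAUSES)), dtype=float)
    young = age < 45
    old = age >= 75
    mid = ~young & ~old
    #            neopl  dement circ  resp  alcohol external
    out[young] = [0.18, 0.01, 0.14, 0.04, 0.23, 0.40]
    out[mid] = [0.34, 0.03, 0.31, 0.05, 0.13, 0.14]
    out[old] = [0.24, 0.14, 0.42, 0.10, 0.03, 0.07]
    return out


def default_region_effects(n_regions: int, scale: float = 0.12) -> np.ndarray:
    r = np.arange(n_regions)
    eff = scale * np.sin(2.0 * np.pi * r / max(n_regions, 1))
    return eff - eff.mean()


def default_year_effects(years: Sequence[int], slope: float = -0.012) -> dict[int, float]:
    ys = np.arange(years[0], years[1] + 1)
    eff = slope * (ys - ys.mean())
    return dict(zip(ys.tolist(), eff.tolist()))


@dataclass(kw_only=True)
class SimulationConfig:
    """Parameters of the synthetic register.

    Defaults describe the emulated study population: 21 birth regions,
    follow-up 1970-2018, cohorts spanning the twentieth century, Gompertz
    baseline mortality with region and period offsets, and constant
    log-rate advantages for movers.
    """

    n_individuals: int
    seed: int
    n_regions: int = 21
    years: tuple[int, int] = (1970, 2018)
    cohort_range: tuple[int, int] = (1905, 1998)
    sex_ratio: float = 0.5  # proportion female
    out_migration_hazard: Callable | float = field(default_factory=default_out_migration_hazard)
    return_hazard: Callable | float = 0.009
    onward_hazard: Callable | float = 0.004
    destination_rule: str = "uniform"
    baseline_log_mortality: Callable = field(default_factory=gompertz_log_mortality)
    region_effects: np.ndarray | None = None
    year_effects: Mapping[int, float] | None = None
    status_effects: Mapping[str, float] = field(
        default_factory=lambda: {"stayer": 0.0, "leaver": -0.15, "returnee": -0.30})
    status_age_interaction: Mapping[str, Callable] | None = None
    cause_mix: Callable = default_cause_mix
    illdefined_fraction: float = 0.021
    death_year_residence: str = "snapshot"  # or "drop"
    death_year_exposure: float = 0.5

    def __post_init__(self):
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if not (0.0 <= self.sex_ratio <= 1.0):
            raise ValueError("sex_ratio must be in [0,1]")
        if not (0.0 <= self.illdefined_fraction <= 1.0):
            raise ValueError("illdefined_fraction must be in [0,1]")
        if self.years[0] > self.years[1]:
            raise ValueError("years interval reversed")
        if self.destination_rule != "uniform":
            raise ValueError("only the 'uniform' destination rule is implemented")
        if self.death_year_residence not in ("snapshot", "drop"):
            raise ValueError("death_year_residence must be 'snapshot' or 'drop'")
        if self.region_effects is None:
            self.region_effects = default_region_effects(self.n_regions)
        self.region_effects = np.asarray(self.region_effects, dtype=float)
        if self.region_effects.size != self.n_regions:
            raise ValueError("region_effects length must equal n_regions")
        if abs(self.region_effects.sum()) > 1e-8:
            raise ValueError("region_effects must sum to zero")
        if self.year_effects is None:
            self.year_effects = default_year_effects(self.years)
        ye = np.array([self.year_effects[y] for y in range(self.years[0], self.years[1] + 1)])
        if abs(ye.sum()) > 1e-6 * max(1.0, np.abs(ye).max()):
            raise ValueError("year_effects must sum to zero over the follow-up years")


@dataclass
class SimulationTruth:
    """Ground-truth fields hidden from the analysis (test harness only)."""

    residence: np.ndarray            # full (n, n_years) residence, -1 = not alive
    age_first_migration: np.ndarray  # nan if never migrated
    age_return: np.ndarray           # age at last return to birth region, nan if none
    latent_status: np.ndarray        # final latent status code


@dataclass
class IndividualHistory:
    """One person's observable record: birth info, residence map, vital outcome."""

    person_id: int
    sex: str                      # 'f' or 'm'
    birth_year: int
    birth_region: int
    residence: dict[int, int]     # calendar year -> region, observed years only
    death_year: int | None = None
    death_age: int | None = None
    cause: str | None = None
    true_age_first_migration: float | None = None
    true_age_return: float | None = None


@dataclass
class Population:
    """Column store of simulated histories; iterates as `IndividualHistory`."""

    person_id: np.ndarray
    sex: np.ndarray          # 0 = female, 1 = male
    birth_year: np.ndarray
    birth_region: np.ndarray
    residence: np.ndarray    # (n, n_years) region or -1
    year0: int               # calendar year of residence column 0
    follow_up: tuple[int, int]
    death_year: np.ndarray   # -1 = censored alive
    death_age: np.ndarray
    cause: np.ndarray        # index into ALL_CAUSE_LABELS, -1 = no death
    truth: SimulationTruth
    observed_years: np.ndarray | None = None  # set by apply_observation_scheme
    config: SimulationConfig | None = None

    @property
    def n(self) -> int:
        return self.person_id.size

    def __len__(self) -> int:
        return self.n

    @property
    def years_axis(self) -> np.ndarray:
        return self.year0 + np.arange(self.residence.shape[1])

    def __getitem__(self, i: int) -> IndividualHistory:
        years = self.years_axis
        res = self.residence[i]
        residence = {int(y): int(r) for y, r in zip(years, res) if r >= 0}
        dead = self.death_year[i] >= 0
        return IndividualHistory(
            person_id=int(self.person_id[i]),
            sex="f" if self.sex[i] == 0 else "m",
            birth_year=int(self.birth_year[i]),
            birth_region=int(self.birth_region[i]),
            residence=residence,
            death_year=int(self.death_year[i]) if dead else None,
            death_age=int(self.death_age[i]) if dead else None,
            cause=ALL_CAUSE_LABELS[self.cause[i]] if dead else None,
            true_age_first_migration=(float(self.truth.age_first_migration[i])
                                      if np.isfinite(self.truth.age_first_migration[i]) else None),
            true_age_return=(float(self.truth.age_return[i])
                             if np.isfinite(self.truth.age_return[i]) else None),
        )

    def __iter__(self) -> Iterator[IndividualHistory]:
        for i in range(self.n):
            yield self[i]

    # -- persistence ---------------------------------------------------
    def person_table(self) -> pd.DataFrame:
        dead = self.death_year >= 0
        return pd.DataFrame({
            "person_id": self.person_id,
            "sex": np.where(self.sex == 0, "f", "m"),
            "birth_year": self.birth_year,
            "birth_region": self.birth_region,
            "death_year": np.where(dead, self.death_year, pd.NA),
            "death_age": np.where(dead, self.death_age, pd.NA),
            "cause": [ALL_CAUSE_LABELS[c] if c >= 0 else pd.NA for c in self.cause],
        })

    def residence_long(self) -> pd.DataFrame:
        """Long-format observed residence: person_id, year, region."""
        ii, jj = np.nonzero(self.residence >= 0)
        return pd.DataFrame({
            "person_id": self.person_id[ii],
            "year": self.year0 + jj,
            "region": self.residence[ii, jj],
        })

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "person_id": self.person_id,
            "true_age_first_migration": self.truth.age_first_migration,
            "true_age_return": self.truth.age_return,
            "latent_status": [LATENT_STATUS_NAMES[s] for s in self.truth.latent_status],
        })


def population_from_frames(person: pd.DataFrame, residence: pd.DataFrame,
                           truth: pd.DataFrame | None, follow_up: tuple[int, int],
                           observed_years=None) -> Population:
    """Rebuild a Population from its persisted tables (inverse of
    person_table / residence_long / truth_table)."""
    person = person.sort_values("person_id").reset_index(drop=True)
    n = len(person)
    pid_index = pd.Series(np.arange(n), index=person["person_id"].to_numpy())
    year0 = int(min(residence["year"].min(), follow_up[0], person["birth_year"].min()))
    n_years = int(follow_up[1]) - year0 + 1
    res = np.full((n, n_years), -1, dtype=np.int16)
    ii = pid_index[residence["person_id"].to_numpy()].to_numpy()
    jj = residence["year"].to_numpy() - year0
    res[ii, jj] = residence["region"].to_numpy()
    dead = person["death_year"].notna().to_numpy()
    cause_idx = np.full(n, -1, dtype=np.int8)
    for k, c in enumerate(ALL_CAUSE_LABELS):
        cause_idx[(person["cause"] == c).to_numpy()] = k
    if truth is not None:
        truth = truth.sort_values("person_id").reset_index(drop=True)
        tr = SimulationTruth(
            residence=res.copy(),
            age_first_migration=truth["true_age_first_migration"].to_numpy(dtype=float),
            age_return=truth["true_age_return"].to_numpy(dtype=float),
            latent_status=np.array([LATENT_STATUS_NAMES.index(s)
                                    for s in truth["latent_status"]], dtype=np.int8))
    else:
        tr = SimulationTruth(residence=res.copy(),
                             age_first_migration=np.full(n, np.nan),
                             age_return=np.full(n, np.nan),
                             latent_status=np.zeros(n, dtype=np.int8))
    return Population(
        person_id=person["person_id"].to_numpy(dtype=np.int64),
        sex=(person["sex"] == "m").to_numpy(dtype=np.int8),
        birth_year=person["birth_year"].to_numpy(dtype=int),
        birth_region=person["birth_region"].to_numpy(dtype=np.int16),
        residence=res, year0=year0, follow_up=tuple(follow_up),
        death_year=np.where(dead, person["death_year"].to_numpy(dtype=float), -1).astype(np.int32),
        death_age=np.where(dead, person["death_age"].to_numpy(dtype=float), -1).astype(np.int32),
        cause=cause_idx, truth=tr,
        observed_years=(np.asarray(sorted(observed_years), dtype=int)
                        if observed_years is not None else None),
    )


def default_observed_years(follow_up: tuple[int, int] = (1970, 2018)) -> np.ndarray:
    """Census years 1970/75/80/85 followed by annual registers from 1987."""
    years = [y for y in (1970, 1975, 1980, 1985) if follow_up[0] <= y <= follow_up[1]]
    years += [y for y in range(1987, follow_up[1] + 1) if y >= follow_up[0]]
    return np.array(sorted(set(years)), dtype=int)


def _check_probs(p: np.ndarray, what: str, year: int) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(p)):
        bad = np.nonzero(~np.isfinite(p))[0][:3]
        raise ValueError(f"non-finite {what} in year {year} (first offending indices {bad.tolist()})")
    if np.any((p < 0) | (p > 1)):
        raise ValueError(f"{what} outside [0,1] in year {year}")
    return p


def simulate_population(config: SimulationConfig) -> Population:
    """Run the annual-step microsimulation and return the full population.

    Residence is recorded for every simulated year (the observation scheme is
    applied separately); migration runs from birth while the death draw is
    active only inside the follow-up window.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    R = config.n_regions
    y_start, y_end = config.years

    sex = (rng.random(n) >= config.sex_ratio).astype(np.int8)  # 0 female, 1 male
    birth_year = rng.integers(config.cohort_range[0], config.cohort_range[1] + 1, n)
    birth_region = rng.integers(0, R, n).astype(np.int16)

    year0 = min(int(birth_year.min()), y_start)
    n_years = y_end - year0 + 1
    residence = np.full((n, n_years), -1, dtype=np.int16)

    out_h = _as_hazard(config.out_migration_hazard)
    ret_h = _as_hazard(config.return_hazard)
    onw_h = _as_hazard(config.onward_hazard)
    status_offset = np.array([config.status_effects.get(name, 0.0)
                              for name in LATENT_STATUS_NAMES])

    cur = birth_region.copy()
    ever_left = np.zeros(n, dtype=bool)
    dead = np.zeros(n, dtype=bool)
    age_first_mig = np.full(n, np.nan)
    age_return = np.full(n, np.nan)
    death_year = np.full(n, -1, dtype=np.int32)
    death_age = np.full(n, -1, dtype=np.int32)
    cause = np.full(n, -1, dtype=np.int8)

    for y in range(year0, y_end + 1):
        col = y - year0
        alive = (birth_year <= y) & ~dead
        if not alive.any():
            continue
        ages = (y - birth_year).astype(float)

        in_birth = cur == birth_region
        # out-migration from the birth region
        cand = alive & in_birth
        if cand.any():
            idx = np.nonzero(cand)[0]
            p = _check_probs(out_h(ages[idx], sex[idx]), "out-migration hazard", y)
            move = idx[rng.random(idx.size) < p]
            if move.size:
                # uniform over the R-1 non-birth regions
                d = rng.integers(0, R - 1, move.size).astype(np.int16)
                d = np.where(d >= birth_region[move], d + 1, d)
                cur[move] = d
                first = np.isnan(age_first_mig[move])
                age_first_mig[move[first]] = ages[move[first]]
                ever_left[move] = True
        # returns and onward moves among those outside at the start of the year
        outside = alive & ~in_birth
        if outside.any():
            idx = np.nonzero(outside)[0]
            p_ret = _check_probs(ret_h(ages[idx], sex[idx]), "return hazard", y)
            u = rng.random(idx.size)
            back = idx[u < p_ret]
            cur[back] = birth_region[back]
            age_return[back] = ages[back]
            stay_out = idx[u >= p_ret]
            if stay_out.size:
                p_on = _check_probs(onw_h(ages[stay_out], sex[stay_out]), "onward hazard", y)
                onw = stay_out[rng.random(stay_out.size) < p_on]
                if onw.size and R > 2:
                    # uniform over regions other than birth and current
                    d = rng.integers(0, R - 2, onw.size).astype(np.int16)
                    lo = np.minimum(birth_region[onw], cur[onw])
                    hi = np.maximum(birth_region[onw], cur[onw])
                    d = np.where(d >= lo, d + 1, d)
                    d = np.where(d >= hi, d + 1, d)
                    cur[onw] = d

        residence[alive, col] = cur[alive]

        # death draw, active only inside follow-up
        if y >= y_start:
            idx = np.nonzero(alive)[0]
            status = np.where(~ever_left[idx], STAYER,
                              np.where(cur[idx] == birth_region[idx], RETURNEE, LEAVER))
            log_rate = (np.asarray(config.baseline_log_mortality(ages[idx]), dtype=float)
                        + config.region_effects[birth_region[idx]]
                        + config.year_effects[y]
                        + status_offset[status])
            if config.status_age_interaction:
                for s_code, s_name in enumerate(LATENT_STATUS_NAMES):
                    f = config.status_age_interaction.get(s_name)
                    if f is not None:
                        m = status == s_code
                        log_rate[m] = log_rate[m] + np.asarray(f(ages[idx][m]), dtype=float)
            rate = np.exp(log_rate)
            if not np.all(np.isfinite(rate) | (rate == 0.0)):
                bad = idx[~np.isfinite(rate)][:1]
                raise ValueError(
                    f"non-finite mortality rate in year {y} at age {ages[bad][0] if bad.size else '?'}")
            q = -np.expm1(-rate)
            die = idx[rng.random(idx.size) < q]
            if die.size:
                dead[die] = True
                death_year[die] = y
                death_age[die] = ages[die].astype(int)
                probs = np.asarray(config.cause_mix(ages[die], status[np.searchsorted(idx, die)]),
                                   dtype=float)
                if probs.shape != (die.size, len(CAUSES)):
                    raise ValueError("cause_mix must return one probability row per death")
                rowsum = probs.sum(axis=1)
                if np.any(np.abs(rowsum - 1.0) > 1e-8):
                    raise ValueError("cause_mix rows must sum to 1")
                cum = np.cumsum(probs, axis=1)
                u = rng.random(die.size)[:, None]
                cause[die] = (u < cum).argmax(axis=1).astype(np.int8)
                if config.death_year_residence == "drop":
                    residence[die, col] = -1

    # relabel a random fraction of deaths as ill-defined, without structure
    died = np.nonzero(dead)[0]
    if died.size and config.illdefined_fraction > 0:
        relabel = died[rng.random(died.size) < config.illdefined_fraction]
        cause[relabel] = len(CAUSES)  # ill_defined index

    latent = np.where(~ever_left, STAYER,
                      np.where(cur == birth_region, RETURNEE, LEAVER)).astype(np.int8)
    truth = SimulationTruth(residence=residence.copy(),
                            age_first_migration=age_first_mig,
                            age_return=age_return,
                            latent_status=latent)
    return Population(
        person_id=np.arange(n, dtype=np.int64), sex=sex, birth_year=birth_year,
        birth_region=birth_region, residence=residence, year0=year0,
        follow_up=(y_start, y_end), death_year=death_year, death_age=death_age,
        cause=cause, truth=truth, config=config,
    )


def apply_observation_scheme(pop: Population,
                             observed_years: Sequence[int] | None = None) -> Population:
    """Restrict residence records to the years a register would observe.

    The default scheme is the four census years 1970/1975/1980/1985 followed
    by annual observation 1987-2018.  Ground truth (full residence paths and
    true migration ages) is retained in ``pop.truth`` for test harnesses;
    the birth region remains known for everyone.
    """
    if observed_years is None:
        observed_years = default_observed_years(pop.follow_up)
    observed_years = np.array(sorted(set(int(y) for y in observed_years)), dtype=int)
    if observed_years.size == 0:
        raise ValueError("observed_years must be non-empty")
    years = pop.years_axis
    if observed_years.min() < years[0] or observed_years.max() > years[-1]:
        raise ValueError("observed_years outside the simulation horizon")
    mask = np.isin(years, observed_years)
    residence = pop.truth.residence.copy()
    residence[:, ~mask] = -1
    return dataclasses.replace(pop, residence=residence, observed_years=observed_years)


def person_years_alive(pop: Population) -> float:
    """Total alive-time inside the follow-up window, in whole person-years.

    Each person contributes one year for every calendar year of the follow-up
    in which they are alive at some point (annual granularity), i.e.
    min(death_year, horizon end) - entry year + 1.
    """
    entry = np.maximum(pop.birth_year, pop.follow_up[0])
    exit_ = np.where(pop.death_year >= 0,
                     np.minimum(pop.death_year, pop.follow_up[1]), pop.follow_up[1])
    dur = np.maximum(exit_ - entry + 1, 0)
    dur[pop.birth_year > pop.follow_up[1]] = 0
    return float(dur.sum())
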