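"""Shared fixtures: small simulated populations and hand-built histories."""

import numpy as np
import pandas as pd
import pytest

import migmort as mm
from migmort.simulate import SimulationTruth


@pytest.fixture(scope="session")
def small_pop():
    """Small default-structure population with the census observation scheme."""
    cfg = mm.SimulationConfig(n_individuals=4000, seed=42, n_regions=6,
                              cohort_range=(1930, 1995))
    pop = mm.simulate_population(cfg)
    return mm.apply_observation_scheme(pop)


@pytest.fixture(scope="session")
def small_classified(small_pop):
    cats, n_uncl = mm.classify_population(small_pop)
    return small_pop, cats, n_uncl


@pytest.fixture(scope="session")
def small_table(small_classified):
    pop, cats, _ = small_classified
    records = mm.extract_censoring_records(pop, cats)
    model = mm.fit_event_age_model(records)
    imputed = mm.impute_ages(records[records["event"] == "first_migration"],
                             model, seed=1)
    ret = records[records["event"] == "return"]
    if len(ret):
        rmodel = mm.fit_event_age_model(records, "return")
        imputed = pd.concat([imputed, mm.impute_ages(ret, rmodel, seed=2)],
                            ignore_index=True)
    from migmort.censoring import event_ages_for_bands
    ages = event_ages_for_bands(pop, cats, imputed)
    status = mm.assign_status_bands(cats, ages)
    table = mm.build_exposure_table(pop, status)
    return pop, status, table


def make_population(rows, follow_up=(1970, 2018), death=None, sexes=None,
                    observed_years=None):
    """Hand-build a Population.

    ``rows``: list of (person_id, birth_year, birth_region,
    {year: region, ...}).  ``death``: {person_id: (death_year, cause_index)}.
    """
    n = len(rows)
    pid = np.array([r[0] for r in rows], dtype=np.int64)
    by = np.array([r[1] for r in rows])
    br = np.array([r[2] for r in rows], dtype=np.int16)
    year0 = int(min(min(by), follow_up[0]))
    n_years = follow_up[1] - year0 + 1
    res = np.full((n, n_years), -1, dtype=np.int16)
    for i, r in enumerate(rows):
        for y, reg in r[3].items():
            res[i, y - year0] = reg
    death = death or {}
    dy = np.array([death.get(p, (-1, -1))[0] for p in pid], dtype=np.int32)
    cause = np.array([death.get(p, (-1, -1))[1] for p in pid], dtype=np.int8)
    da = np.where(dy >= 0, dy - by, -1).astype(np.int32)
    sex = np.asarray(sexes if sexes is not None else np.zeros(n), dtype=np.int8)
    truth = SimulationTruth(residence=res.copy(),
                            age_first_migration=np.full(n, np.nan),
                            age_return=np.full(n, np.nan),
                            latent_status=np.zeros(n, dtype=np.int8))
    return mm.Population(
        person_id=pid, sex=sex, birth_year=by, birth_region=br, residence=res,
        year0=year0, follow_up=follow_up, death_year=dy, death_age=da,
        cause=cause, truth=truth,
        observed_years=(np.array(sorted(observed_years), dtype=int)
                        if observed_years is not None else None))
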