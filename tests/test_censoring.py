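"""Censoring-record extraction, interval-censored MLE and imputation."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

import migmort as mm
from migmort.censoring import PiecewiseHazard, event_ages_for_bands
from conftest import make_population


def _observe(pop):
    return mm.apply_observation_scheme(pop)


class TestExtraction:
    def test_census_interval(self):
        # born 1950, in birth region at the 1975 census, outside at the 1980
        # census: the move's attained age lies in [26, 31)
        pop = make_population([(0, 1950, 0, {y: (0 if y < 1978 else 1)
                                             for y in range(1970, 2019)})])
        rec = mm.extract_censoring_records(_observe(pop),
                                           np.array(["leaver"], dtype=object))
        r = rec.iloc[0]
        assert (r.low, r.high) == (26.0, 31.0) and not r.exact

    def test_annual_change_is_exact(self):
        # annual era: observed in region 0 in 2001, region 1 in 2002, born 1980
        pop = make_population([(0, 1980, 0, {y: (0 if y < 2002 else 1)
                                             for y in range(1987, 2019)})])
        rec = mm.extract_censoring_records(_observe(pop),
                                           np.array(["leaver"], dtype=object))
        r = rec.iloc[0]
        assert (r.low, r.high) == (22.0, 23.0) and r.exact

    def test_fully_left_censored(self):
        # already outside the birth region at the first observation
        pop = make_population([(0, 1940, 0, {y: 1 for y in range(1970, 2019)})])
        rec = mm.extract_censoring_records(_observe(pop),
                                           np.array(["leaver"], dtype=object))
        r = rec.iloc[0]
        assert r.low == 0.0 and r.high == 31.0 and not r.exact

    def test_return_record(self):
        pop = make_population([(0, 1950, 0,
                                {**{y: 1 for y in range(1970, 2000)},
                                 **{y: 0 for y in range(2000, 2019)}})])
        rec = mm.extract_censoring_records(_observe(pop),
                                           np.array(["returnee"], dtype=object))
        ret = rec[rec.event == "return"].iloc[0]
        assert ret.low == 50.0 and ret.high == 51.0 and ret.exact

    def test_inconsistent_classification_raises(self):
        pop = make_population([(0, 1950, 0, {y: 0 for y in range(1970, 2019)})])
        with pytest.raises(ValueError, match="never observed outside"):
            mm.extract_censoring_records(_observe(pop),
                                         np.array(["leaver"], dtype=object))


class TestHazardModel:
    def test_piecewise_quantile_inverts_cdf(self):
        hz = PiecewiseHazard(np.array([0., 17., 30., 60., 110.]),
                             np.array([0.01, 0.05, 0.008, 0.002]))
        a = np.array([5.0, 20.0, 45.0, 80.0])
        assert np.allclose(hz.quantile(hz.cdf(a)), a, atol=1e-9)

    def test_mle_recovers_known_hazard(self):
        """Interval-censored MLE recovers the generating piecewise hazard."""
        rng = np.random.default_rng(1)
        # nearly all mass before the last band edge, so the unconditional
        # likelihood sees an (almost) complete distribution
        true = PiecewiseHazard(np.array([0., 17., 30., 60., 110.]),
                               np.array([0.012, 0.04, 0.02, 0.08]))
        ages = true.quantile(rng.random(30_000) * true.cdf(110.0)[0])
        low = np.floor(ages)
        # half the records exact, half widened to 5-year intervals
        wide = rng.random(ages.size) < 0.5
        high = np.where(wide, np.floor(ages / 5) * 5 + 5, low + 1)
        low = np.where(wide, np.floor(ages / 5) * 5, low)
        rec = pd.DataFrame({"person_id": np.arange(ages.size),
                            "event": "first_migration", "low": low, "high": high,
                            "sex": "f", "birth_year": 1950, "birth_region": 0})
        rec["exact"] = (rec.high - rec.low) <= 1
        model = mm.fit_event_age_model(rec, min_exact=10)
        assert np.allclose(model.pooled.hazards[:3], true.hazards[:3], rtol=0.15)

    def test_empty_event_raises(self):
        rec = pd.DataFrame({"person_id": [], "event": [], "low": [], "high": [],
                            "sex": [], "birth_year": [], "birth_region": [],
                            "exact": []})
        with pytest.raises(ValueError):
            mm.fit_event_age_model(rec)


class TestImputation:
    def _records(self, low, high, n=1):
        return pd.DataFrame({
            "person_id": np.arange(n), "event": "first_migration",
            "low": np.full(n, low, dtype=float), "high": np.full(n, high, dtype=float),
            "sex": "f", "birth_year": 1950, "birth_region": 0,
            "exact": (high - low) <= 1})

    def _flat_model(self, h=0.03):
        m = mm.EventAgeModel(edges=np.array([0., 17., 30., 60., 110.]),
                             cohort_edges=(1940, 1960, 1980))
        m.pooled = PiecewiseHazard(m.edges, np.full(4, h))
        return m

    def test_degenerate_interval_forced(self):
        out = mm.impute_ages(self._records(22.0, 23.0, n=50), self._flat_model(), seed=0)
        assert (out["age"] == 22.0).all()

    def test_truncated_mean_matches_quadrature(self):
        """Uniform-hazard draws on [20,30) have the mean of the truncated
        exponential computed by numerical integration."""
        h = 0.03
        out = mm.impute_ages(self._records(20.0, 30.0, n=10_000),
                             self._flat_model(h), seed=3)
        num = integrate.quad(lambda a: a * h * np.exp(-h * a), 20, 30)[0]
        den = integrate.quad(lambda a: h * np.exp(-h * a), 20, 30)[0]
        assert abs(out["age"].mean() - num / den) < 0.2

    def test_imputed_inside_bounds(self, small_classified):
        pop, cats, _ = small_classified
        rec = mm.extract_censoring_records(pop, cats)
        model = mm.fit_event_age_model(rec)
        first = rec[rec.event == "first_migration"].reset_index(drop=True)
        out = mm.impute_ages(first, model, seed=9)
        assert (out["age"].to_numpy() >= first["low"].to_numpy()).all()
        assert (out["age"].to_numpy() < first["high"].to_numpy()).all()

    def test_zero_mass_midpoint_fallback(self):
        m = self._flat_model(0.0)  # no mass anywhere
        m.pooled.hazards[:] = 0.0
        with pytest.warns(UserWarning, match="midpoint"):
            out = mm.impute_ages(self._records(20.0, 30.0, n=5), m, seed=0)
        assert (out["age"] == 25.0).all()

    def test_determinism(self):
        r = self._records(20.0, 30.0, n=100)
        a = mm.impute_ages(r, self._flat_model(), seed=11)
        b = mm.impute_ages(r, self._flat_model(), seed=11)
        c = mm.impute_ages(r, self._flat_model(), seed=12)
        assert a["age"].equals(b["age"]) and not a["age"].equals(c["age"])


def _band_mismatch_share(scheme_years):
    cfg = mm.SimulationConfig(n_individuals=6000, seed=23, n_regions=5,
                              cohort_range=(1930, 1995))
    pop = mm.simulate_population(cfg)
    obs = mm.apply_observation_scheme(pop, scheme_years)
    cats, _ = mm.classify_population(obs)
    rec = mm.extract_censoring_records(obs, cats)
    model = mm.fit_event_age_model(rec)
    imp = mm.impute_ages(rec[rec.event == "first_migration"], model, seed=5)
    ret = rec[rec.event == "return"]
    if len(ret):
        rm = mm.fit_event_age_model(rec, "return")
        imp = pd.concat([imp, mm.impute_ages(ret, rm, seed=6)], ignore_index=True)
    ages = event_ages_for_bands(obs, cats, imp)
    movers = np.isin(cats, ("leaver", "returnee"))
    truth = np.where(cats == "leaver", pop.truth.age_first_migration,
                     pop.truth.age_return)
    got = mm.assign_status_bands(cats, ages)
    want = mm.assign_status_bands(cats, truth)
    return np.mean(got[movers] != want[movers])


def test_band_stability_improves_with_denser_observation():
    """Mismatch between imputed and true age bands shrinks as observation
    becomes denser, and vanishes under annual observation."""
    census = mm.default_observed_years()
    dense = sorted(set(census) | set(range(1930, 2019, 2)))
    annual = range(1930, 2019)  # full horizon: no left censoring remains
    m_census = _band_mismatch_share(census)
    m_dense = _band_mismatch_share(dense)
    m_annual = _band_mismatch_share(annual)
    assert m_annual == 0.0
    assert m_annual <= m_dense <= m_census
    assert m_census > 0.0
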