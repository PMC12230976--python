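"""Negative-binomial GAM: closed-form limits, an independent GLM oracle,
identifiability constraints, penalty behaviour and prediction."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import migmort as mm
from migmort import gam


def _table(rows):
    df = pd.DataFrame(rows)
    for c in mm.CAUSES:
        if "D_" + c not in df.columns:
            df["D_" + c] = 0.0
    if "D_total" not in df.columns:
        df["D_total"] = df[["D_" + c for c in mm.CAUSES]].sum(axis=1)
    return df


def _row(age_mid, year, region, status, E, D):
    return {"year": year, "sex": "m", "birth_region": region, "status": status,
            "age_mid": age_mid, "E": E, "D_total": D, "D_neoplasms": D,
            **{"D_" + c: 0.0 for c in mm.CAUSES if c != "neoplasms"}}


@pytest.fixture(scope="module")
def fixture_table():
    """Small deterministic multi-age/region/year table with Poisson-ish counts."""
    rng = np.random.default_rng(8)
    rows = []
    for age in np.arange(21.5, 95, 3):
        for year in (2000, 2001, 2002):
            for region in (0, 1):
                for status in ("stayer", "leaver"):
                    E = float(rng.integers(500, 2000))
                    rate = np.exp(-9.5 + 0.085 * age
                                  + (-0.3 if status == "leaver" else 0.0)
                                  + (0.1 if region == 1 else 0.0))
                    D = float(rng.poisson(rate * E))
                    rows.append(_row(age, year, region, status, E, D))
    return _table(rows)


class TestClosedFormLimits:
    def test_intercept_only_poisson(self):
        """One stratum, no smooth: fitted log rate is log(sum D / sum E)."""
        tab = _table([_row(50.5, 2000, 0, "stayer", 1000.0, 13.0)])
        spec = gam.ModelSpec(response_family="poisson")
        model = gam.fit(gam.build_design(tab, spec), spec)
        assert model.beta[0] == pytest.approx(np.log(13.0 / 1000.0), abs=1e-8)

    def test_saturated_tiny_model_reproduces_observed(self):
        """Unpenalised saturated fit returns log(D/E) at every data point."""
        ages = np.arange(21.5, 36, 3)
        D = np.array([5.0, 9.0, 14.0, 22.0, 30.0])
        tab = _table([_row(a, 2000, 0, "stayer", 1000.0, d) for a, d in zip(ages, D)])
        spec = gam.ModelSpec(response_family="poisson", smoothing_selection="fixed",
                             fixed_lambda=1e-9, basis_size=5)
        model = gam.fit(gam.build_design(tab, spec), spec)
        for a, d in zip(ages, D):
            eta, se = model.predict_log_rate(a, 2000, 0, "stayer")
            assert eta == pytest.approx(np.log(d / 1000.0), abs=1e-6)

    def test_unpenalised_matches_statsmodels(self, fixture_table):
        """Penalty -> 0: coefficients match an independent GLM fit (Poisson,
        and negative binomial at the same theta)."""
        spec = gam.ModelSpec(response_family="poisson", smoothing_selection="fixed",
                             fixed_lambda=1e-8)
        design = gam.build_design(fixture_table, spec)
        model = gam.fit(design, spec)
        ref = sm.GLM(design.y, design.X, family=sm.families.Poisson(),
                     offset=design.offset).fit()
        assert np.allclose(model.beta, ref.params, atol=1e-6)

        spec_nb = gam.ModelSpec(response_family="negbin", smoothing_selection="fixed",
                                fixed_lambda=1e-8)
        model_nb = gam.fit(gam.build_design(fixture_table, spec_nb), spec_nb)
        ref_nb = sm.GLM(design.y, design.X,
                        family=sm.families.NegativeBinomial(alpha=1.0 / model_nb.theta),
                        offset=design.offset).fit()
        assert np.allclose(model_nb.beta, ref_nb.params, atol=1e-5)

    def test_poisson_nesting_at_large_theta(self, fixture_table):
        """Fixed theta -> infinity reproduces the Poisson coefficients."""
        spec = gam.ModelSpec(smoothing_selection="fixed", fixed_lambda=1.0)
        design = gam.build_design(fixture_table, spec)
        pois = gam._pirls(design, [1.0] * len(design.smooths), np.inf, "poisson",
                          tol=1e-12)
        nb = gam._pirls(design, [1.0] * len(design.smooths), 1e6, "negbin",
                        tol=1e-12)
        assert np.max(np.abs(pois["beta"] - nb["beta"])) < 1e-4


class TestIdentifiability:
    def test_sum_to_zero_every_status(self, fixture_table):
        spec = gam.ModelSpec()
        model = gam.fit(gam.build_design(fixture_table, spec), spec)
        for smb in model.smooths:
            s_vals = smb.basis_row(smb.points) @ model.beta[smb.sl]
            assert abs(s_vals.mean()) < 1e-8

    def test_reference_coding_invariance(self, fixture_table):
        """Marginal rates agree to 1e-8 between fits differing only in the
        categorical reference levels (same fixed smoothing)."""
        spec = gam.ModelSpec(smoothing_selection="fixed", fixed_lambda=10.0,
                             tol=1e-12)
        m1 = gam.fit(gam.build_design(fixture_table, spec), spec)
        m2 = gam.fit(gam.build_design(fixture_table, spec,
                                      refs={"region": 1, "year": 2002,
                                            "status": "leaver"}), spec)
        for status in ("stayer", "leaver"):
            s1 = mm.average_marginal_rates(m1, n_draws=100, seed=0,
                                           statuses=[status])[status]
            s2 = mm.average_marginal_rates(m2, n_draws=100, seed=0,
                                           statuses=[status])[status]
            assert np.allclose(s1.rate, s2.rate, rtol=1e-8)

    def test_rank_deficiency_detected(self):
        # a status with a single age level duplicated as region: two identical
        # indicator columns alias each other
        rows = [_row(50.5, 2000, r, s, 1000.0, 10.0)
                for r, s in [(0, "stayer"), (1, "leaver")]]
        with pytest.raises(ValueError, match="rank deficient"):
            gam.build_design(_table(rows), gam.ModelSpec())


class TestPenalty:
    def test_edf_monotone_in_lambda(self, fixture_table):
        edfs = []
        for lam in (1e-4, 1.0, 1e4):
            spec = gam.ModelSpec(smoothing_selection="fixed", fixed_lambda=lam,
                                 response_family="poisson")
            model = gam.fit(gam.build_design(fixture_table, spec), spec)
            edfs.append(sum(model.edf.values()))
        assert edfs[0] > edfs[1] > edfs[2]

    def test_curvature_penalty_null_space_is_linear(self):
        knots = gam.bspline_knots(20.0, 90.0, 10)
        S = gam.curvature_penalty(knots)
        x = np.linspace(20, 90, 10)
        B = gam.bspline_basis(x, knots)
        # coefficients reproducing a straight line have zero penalty
        coef = np.linalg.lstsq(B, 2.0 + 0.5 * x, rcond=None)[0]
        assert coef @ S @ coef < 1e-6 * (coef @ coef)


class TestPrediction:
    def test_symmetric_statuses_predict_identically(self):
        rows = []
        for age in np.arange(21.5, 95, 3):
            for status in ("stayer", "leaver"):
                D = float(np.round(np.exp(-9.0 + 0.08 * age) * 5000))
                rows.append(_row(age, 2000, 0, status, 5000.0, D))
        spec = gam.ModelSpec(smoothing_selection="fixed", fixed_lambda=1.0,
                             tol=1e-12)
        model = gam.fit(gam.build_design(_table(rows), spec), spec)
        for age in (21.5, 45.5, 75.5):
            e1, _ = model.predict_log_rate(age, 2000, 0, "stayer")
            e2, _ = model.predict_log_rate(age, 2000, 0, "leaver")
            assert e1 == pytest.approx(e2, abs=1e-6)

    def test_structural_zero_sentinel(self, fixture_table):
        tab = fixture_table.copy()
        tab.loc[tab.status == "leaver", "status"] = "returnee_60p"
        tab = tab[(tab.status != "returnee_60p") | (tab.age_mid >= 60)]
        spec = gam.ModelSpec()
        model = gam.fit(gam.build_design(tab, spec), spec)
        assert model.predict_log_rate(45.5, 2000, 0, "returnee_60p") == \
            ("structural_zero", None)
        eta, se = model.predict_log_rate(70.5, 2000, 0, "returnee_60p")
        assert np.isfinite(eta) and se > 0

    def test_unseen_level_raises(self, fixture_table):
        spec = gam.ModelSpec()
        model = gam.fit(gam.build_design(fixture_table, spec), spec)
        with pytest.raises(ValueError, match="unseen"):
            model.predict_log_rate(45.5, 2000, 99, "stayer")
        with pytest.raises(ValueError, match="unseen"):
            model.predict_log_rate(45.5, 1950, 0, "stayer")

    def test_delta_se_matches_simulation(self, fixture_table):
        """Analytic SE of the linear predictor agrees with the SD of 2000
        coefficient draws (the predictor is linear, so closely)."""
        spec = gam.ModelSpec()
        model = gam.fit(gam.build_design(fixture_table, spec), spec)
        eta, se = model.predict_log_rate(45.5, 2001, 1, "leaver")
        rng = np.random.default_rng(4)
        L = np.linalg.cholesky(model.cov + 1e-14 * np.eye(model.cov.shape[0]))
        draws = model.beta[None, :] + rng.standard_normal((2000, model.beta.size)) @ L.T
        v = model._row(45.5, 2001, 1, "leaver")
        sd = (draws @ v).std()
        assert abs(sd - se) / se < 0.05

    def test_serialization_round_trip(self, fixture_table, tmp_path):
        spec = gam.ModelSpec()
        model = gam.fit(gam.build_design(fixture_table, spec), spec)
        model.save(tmp_path / "bundle")
        loaded = gam.FittedMortalityModel.load(tmp_path / "bundle")
        e1 = model.predict_log_rate(45.5, 2001, 1, "leaver")
        e2 = loaded.predict_log_rate(45.5, 2001, 1, "leaver")
        assert e1 == pytest.approx(e2)
        assert loaded.theta == pytest.approx(model.theta)


class TestCauseAgeRestriction:
    def _cause_table(self, deaths_by_age, total_by_age=None):
        rows = []
        for age, d in deaths_by_age.items():
            r = _row(age, 2000, 0, "stayer", 1000.0, d)
            r["D_neoplasms"] = d
            rows.append(r)
        return _table(rows)

    def test_deaths_only_above_50(self):
        ages = np.arange(21.5, 95, 3)
        tab = self._cause_table({a: (100.0 if a >= 50 else 0.0) for a in ages})
        lo, hi = mm.restrict_cause_ages(tab, "neoplasms")
        assert lo == 50.0  # group 50-52 is the first at/above 50
        assert hi == 95.0

    def test_all_groups_pass_full_domain(self):
        ages = np.arange(21.5, 95, 3)
        tab = self._cause_table({a: 100.0 for a in ages})
        assert mm.restrict_cause_ages(tab, "neoplasms") == (20.0, 95.0)

    def test_or_rule_keeps_large_young_group(self):
        ages = np.arange(21.5, 95, 3)
        deaths = {a: (50_000.0 if a >= 50 else 0.0) for a in ages}
        deaths[21.5] = 1000.0  # < 0.5% of the total but >= 1000 deaths
        tab = self._cause_table(deaths)
        lo, hi = mm.restrict_cause_ages(tab, "neoplasms")
        assert lo == 20.0

    def test_no_group_passes_raises(self):
        tab = self._cause_table({45.5: 0.0})
        with pytest.raises(ValueError, match="neoplasms"):
            mm.restrict_cause_ages(tab, "neoplasms")
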