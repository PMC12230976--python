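"""Censored age-at-migration extraction, modelling and imputation.

Under the census-then-annual observation scheme the age at first
out-migration (and at return) is only known to lie between the last age
observed in the origin state and the first age observed in the destination
state; histories already outside the birth region at first observation are
left-censored down to age 0.  We treat this as a missing-data problem:
a parametric age-at-event distribution (piecewise-constant hazard on the
age bands 0-16, 17-29, 30-59, 60+) is estimated by maximum likelihood from
interval-censored contributions, stratified by sex and birth-cohort band,
and censored ages are imputed by sampling the fitted distribution truncated
to each record's bounds.

Age bounds convention: a region change between observation years yL and yH
places the move's attained age in [age(yL)+1, age(yH)+1); annual
observation therefore yields a width-1 interval, treated as exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .simulate import Population

DEFAULT_EVENT_BANDS = (0.0, 17.0, 30.0, 60.0, 110.0)
DEFAULT_COHORT_EDGES = (1940, 1960, 1980)


@dataclass
class CensoringRecord:
    person_id: int
    event: str                 # "first_migration" or "return"
    low: float                 # event age >= low
    high: float                # event age < high
    sex: str
    birth_year: int
    birth_region: int

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError(f"person {self.person_id}: empty bounds [{self.low},{self.high})")

    @property
    def exact(self) -> bool:
        return self.high - self.low <= 1.0


def extract_censoring_records(pop: Population, categories: np.ndarray,
                              end_of_follow_up: int | None = None) -> pd.DataFrame:
    """Bounds on age at first out-migration (all movers) and age at the
    final return (returnees), implied by the observed residence sequence.

    Returns a tidy frame (person_id, event, low, high, sex, birth_year,
    birth_region, exact).
    """
    if pop.observed_years is None:
        raise ValueError("apply_observation_scheme must run before extraction")
    if end_of_follow_up is None:
        end_of_follow_up = pop.follow_up[1]
    years = pop.years_axis
    res = pop.residence
    limit = np.where(pop.death_year >= 0,
                     np.minimum(pop.death_year, end_of_follow_up), end_of_follow_up)
    valid = (res >= 0) & (years[None, :] <= limit[:, None])
    is_birth = res == pop.birth_region[:, None]
    ncol = res.shape[1]
    cols = np.arange(ncol)

    outside = valid & ~is_birth
    has_out = outside.any(axis=1)
    # first observation outside the birth region
    first_out = np.where(has_out, np.where(outside, cols[None, :], ncol).min(axis=1), -1)
    # last observation in the birth region strictly before first_out
    before = valid & is_birth & (cols[None, :] < first_out[:, None])
    last_in = np.where(before.any(axis=1), np.where(before, cols[None, :], -1).max(axis=1), -1)

    rows = []
    cats = np.asarray(categories, dtype=object)
    sex_label = np.where(pop.sex == 0, "f", "m")
    for i in np.nonzero(np.isin(cats, ("leaver", "returnee")))[0]:
        if first_out[i] < 0:
            raise ValueError(f"person {pop.person_id[i]} classified {cats[i]} "
                             "but never observed outside the birth region")
        by = int(pop.birth_year[i])
        high = years[first_out[i]] - by + 1.0
        low = years[last_in[i]] - by + 1.0 if last_in[i] >= 0 else 0.0
        low = max(low, 0.0)
        rows.append((int(pop.person_id[i]), "first_migration", low, high,
                     sex_label[i], by, int(pop.birth_region[i])))
        if cats[i] == "returnee":
            # final return: last observation outside, then first back in birth
            out_cols = np.nonzero(outside[i])[0]
            last_out = out_cols[-1]
            back = valid[i] & is_birth[i] & (cols > last_out)
            first_back = np.nonzero(back)[0][0]
            rlow = years[last_out] - by + 1.0
            rhigh = years[first_back] - by + 1.0
            rows.append((int(pop.person_id[i]), "return", rlow, rhigh,
                         sex_label[i], by, int(pop.birth_region[i])))

    df = pd.DataFrame(rows, columns=["person_id", "event", "low", "high",
                                     "sex", "birth_year", "birth_region"])
    if len(df) and not (df["low"] < df["high"]).all():
        bad = df.loc[df["low"] >= df["high"], "person_id"].iloc[0]
        raise ValueError(f"person {bad}: inconsistent bounds")
    df["exact"] = (df["high"] - df["low"]) <= 1.0
    return df


# ---------------------------------------------------------------------------
# piecewise-constant hazard model for the age-at-event distribution


@dataclass
class PiecewiseHazard:
    """Piecewise-constant hazard on age bands; closed-form survival/CDF."""

    edges: np.ndarray     # band edges, length k+1
    hazards: np.ndarray   # per-band hazard, length k

    def cumulative_hazard(self, a) -> np.ndarray:
        a = np.atleast_1d(np.asarray(a, dtype=float))
        widths = np.clip(np.minimum(a[:, None], self.edges[1:][None, :])
                         - self.edges[:-1][None, :], 0.0, None)
        return widths @ self.hazards

    def survival(self, a) -> np.ndarray:
        return np.exp(-self.cumulative_hazard(a))

    def cdf(self, a) -> np.ndarray:
        return 1.0 - self.survival(a)

    def quantile(self, q) -> np.ndarray:
        """Invert the CDF (piecewise-exponential)."""
        q = np.atleast_1d(np.asarray(q, dtype=float))
        target = -np.log1p(-np.clip(q, 0.0, 1.0 - 1e-15))
        cum_edges = np.concatenate([[0.0], np.cumsum(np.diff(self.edges) * self.hazards)])
        band = np.clip(np.searchsorted(cum_edges, target, side="right") - 1,
                       0, len(self.hazards) - 1)
        h = self.hazards[band]
        with np.errstate(divide="ignore", invalid="ignore"):
            extra = np.where(h > 0, (target - cum_edges[band]) / h, np.inf)
        return np.minimum(self.edges[band] + extra, self.edges[-1])


@dataclass
class EventAgeModel:
    """Stratified piecewise-constant-hazard age-at-event model.

    Strata are sex x birth-cohort band; a pooled model serves as fallback
    for strata with too few exactly-observed events.
    """

    edges: np.ndarray
    cohort_edges: tuple
    strata: dict = field(default_factory=dict)     # (sex, cohort_band) -> PiecewiseHazard
    pooled: PiecewiseHazard | None = None
    fallback_strata: list = field(default_factory=list)

    def cohort_band(self, birth_year) -> np.ndarray:
        return np.searchsorted(np.asarray(self.cohort_edges), np.asarray(birth_year),
                               side="right")

    def lookup(self, sex: str, birth_year: int) -> PiecewiseHazard:
        key = (sex, int(self.cohort_band(birth_year)))
        return self.strata.get(key, self.pooled)


def _neg_loglik(log_h: np.ndarray, edges: np.ndarray, low: np.ndarray,
                high: np.ndarray, rc_ages: np.ndarray) -> float:
    hz = PiecewiseHazard(edges, np.exp(log_h))
    s_lo = hz.survival(low)
    s_hi = hz.survival(np.minimum(high, edges[-1]))
    p = np.clip(s_lo - s_hi, 1e-300, None)
    nll = -float(np.log(p).sum())
    if rc_ages.size:
        nll += float(hz.cumulative_hazard(np.minimum(rc_ages, edges[-1])).sum())
    return nll


def _fit_hazard(edges: np.ndarray, low: np.ndarray, high: np.ndarray,
                rc_ages: np.ndarray) -> PiecewiseHazard:
    x0 = np.full(len(edges) - 1, np.log(0.02))
    res = optimize.minimize(_neg_loglik, x0, args=(edges, low, high, rc_ages),
                            method="L-BFGS-B", bounds=[(-14.0, 3.0)] * x0.size)
    return PiecewiseHazard(edges, np.exp(res.x))


def extract_right_censored(pop: Population, categories: np.ndarray,
                           end_of_follow_up: int | None = None) -> pd.DataFrame:
    """Ages at which never-migrating individuals stop being observable:
    right-censored contributions to the age-at-first-migration likelihood."""
    if end_of_follow_up is None:
        end_of_follow_up = pop.follow_up[1]
    cats = np.asarray(categories, dtype=object)
    idx = np.nonzero(cats == "stayer")[0]
    limit = np.where(pop.death_year[idx] >= 0,
                     np.minimum(pop.death_year[idx], end_of_follow_up),
                     end_of_follow_up)
    return pd.DataFrame({
        "person_id": pop.person_id[idx],
        "age": np.maximum(limit - pop.birth_year[idx], 0.0).astype(float),
        "sex": np.where(pop.sex[idx] == 0, "f", "m"),
        "birth_year": pop.birth_year[idx],
    })


def fit_event_age_model(records: pd.DataFrame, event: str = "first_migration",
                        edges=DEFAULT_EVENT_BANDS, cohort_edges=DEFAULT_COHORT_EDGES,
                        min_exact: int = 30, min_exact_per_band: int = 10,
                        right_censored: pd.DataFrame | None = None) -> EventAgeModel:
    """Maximum-likelihood fit of the age-at-event distribution from exact,
    interval-censored and (optionally) right-censored contributions,
    stratified by sex x birth-cohort band.

    ``right_censored`` rows (columns age, sex, birth_year) represent
    individuals observed event-free up to an age; including them makes the
    fitted hazard unconditional, which is what truncated-to-bounds
    imputation assumes.

    A stratum is fit on its own only when every hazard band below age 60
    contains at least ``min_exact_per_band`` exactly observed events —
    otherwise the young-age hazard is unidentified there (old cohorts have
    no exactly placed early-life moves) and the pooled model is used.
    """
    rec = records[records["event"] == event]
    if rec.empty:
        raise ValueError(f"no records for event {event!r}")
    edges = np.asarray(edges, dtype=float)
    rc = right_censored if right_censored is not None else \
        pd.DataFrame(columns=["age", "sex", "birth_year"])
    model = EventAgeModel(edges=edges, cohort_edges=tuple(cohort_edges))
    model.pooled = _fit_hazard(edges, rec["low"].to_numpy(dtype=float),
                               rec["high"].to_numpy(dtype=float),
                               rc["age"].to_numpy(dtype=float))
    band = model.cohort_band(rec["birth_year"].to_numpy())
    rc_band = model.cohort_band(rc["birth_year"].to_numpy()) if len(rc) else None
    for (sex, b), grp in rec.groupby([rec["sex"], band]):
        exact_low = grp.loc[grp["exact"], "low"].to_numpy(dtype=float)
        per_band = np.histogram(exact_low, bins=edges)[0]
        identified = all(per_band[j] >= min_exact_per_band
                         for j in range(len(edges) - 1) if edges[j + 1] <= 60)
        if int(grp["exact"].sum()) < min_exact or not identified:
            model.fallback_strata.append((sex, int(b)))
            continue
        rc_ages = (rc["age"].to_numpy(dtype=float)[(rc["sex"] == sex).to_numpy()
                                                   & (rc_band == b)]
                   if len(rc) else np.empty(0))
        model.strata[(sex, int(b))] = _fit_hazard(
            edges, grp["low"].to_numpy(dtype=float),
            grp["high"].to_numpy(dtype=float), rc_ages)
    if model.fallback_strata:
        warnings.warn(f"{len(model.fallback_strata)} strata below {min_exact} exact "
                      "events; pooled model used there")
    return model


def impute_ages(records: pd.DataFrame, model: EventAgeModel, n_draws: int = 1,
                seed: int = 0) -> pd.DataFrame:
    """Draw event ages from the fitted distribution truncated to each
    record's bounds.

    Width-1 intervals are forced to their lower bound.  Bounds carrying no
    model mass fall back to the interval midpoint (counted in
    ``attrs['midpoint_fallbacks']``).  Deterministic under ``seed``; columns
    ``age`` (first draw) and ``age_0..age_{n-1}`` if ``n_draws > 1``.
    """
    rng = np.random.default_rng(seed)
    low = records["low"].to_numpy(dtype=float)
    high = records["high"].to_numpy(dtype=float)
    n = len(records)
    draws = np.empty((n, n_draws))
    n_fallback = 0

    exact = (high - low) <= 1.0
    draws[exact] = low[exact, None]

    # group censored records by model stratum so sampling is vectorised
    cens = np.nonzero(~exact)[0]
    if cens.size:
        band = model.cohort_band(records["birth_year"].to_numpy())
        strat_key = [(records["sex"].iat[i], int(band[i])) for i in cens]
        groups: dict[tuple, list[int]] = {}
        for i, key in zip(cens, strat_key):
            groups.setdefault(key if key in model.strata else ("pooled",), []).append(i)
        for key, idx in groups.items():
            hz = model.strata[key] if key != ("pooled",) else model.pooled
            idx = np.asarray(idx)
            f_lo = hz.cdf(low[idx])
            f_hi = hz.cdf(np.minimum(high[idx], hz.edges[-1]))
            mass = f_hi - f_lo
            ok = mass > 1e-12
            if (~ok).any():
                n_fallback += int((~ok).sum())
                draws[idx[~ok]] = ((low[idx[~ok]] + high[idx[~ok]]) / 2.0)[:, None]
            if ok.any():
                u = rng.random((ok.sum(), n_draws))
                q = f_lo[ok, None] + u * mass[ok, None]
                a = hz.quantile(q.ravel()).reshape(ok.sum(), n_draws)
                # guard against edge rounding
                draws[idx[ok]] = np.clip(a, low[idx[ok], None],
                                         np.nextafter(high[idx[ok], None], -np.inf))

    if n_fallback:
        warnings.warn(f"{n_fallback} records had no model mass inside their bounds; "
                      "midpoint fallback used")
    out = records[["person_id", "event"]].copy()
    out["age"] = draws[:, 0]
    if n_draws > 1:
        for j in range(n_draws):
            out[f"age_{j}"] = draws[:, j]
    out.attrs["midpoint_fallbacks"] = n_fallback
    return out


def event_ages_for_bands(pop: Population, categories: np.ndarray,
                         imputed: pd.DataFrame) -> np.ndarray:
    """Per-person event age used for band assignment: age at first
    out-migration for leavers, age at the final return for returnees."""
    cats = np.asarray(categories, dtype=object)
    ages = np.full(pop.n, np.nan)
    want = {"leaver": "first_migration", "returnee": "return"}
    merged = imputed.set_index(["person_id", "event"])["age"]
    pid_to_idx = {int(p): i for i, p in enumerate(pop.person_id)}
    for (pid, event), age in merged.items():
        i = pid_to_idx.get(int(pid))
        if i is None:
            continue
        if want.get(cats[i]) == event:
            ages[i] = age
    return ages
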