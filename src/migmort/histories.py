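"""Migration-status classification and exposure/death aggregation.

A person is a *stayer* if never observed outside the birth region, a
*leaver* if the last relevant observation (end of follow-up or year of
death) is outside it, and a *returnee* if they were observed outside but
the last relevant observation is back in the birth region.  Leavers are
banded by age at first out-migration (<17, 17-29, 30-59, 60+) and
returnees by age at return (<30, 30-59, 60+).

Deaths and person-years are aggregated by calendar year, 3-year age group
(20-22, 23-25, ..., 92-94, midpoints 21.5, ..., 93.5), sex, birth region
and status.  Because a mover banded at age a must have survived to a,
person-years and deaths below the band's lower bound are structural zeros
and excluded from the table; the "returnee before 30" group is capped at
age 77.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import ALL_CAUSE_LABELS, CAUSES, ILL_DEFINED, IndividualHistory, Population

#: analysis status categories, stayer first (the model's reference level)
STATUS_LEVELS = (
    "stayer",
    "leaver_lt17", "leaver_17_29", "leaver_30_59", "leaver_60p",
    "returnee_lt30", "returnee_30_59", "returnee_60p",
)

#: default band edges keyed to age at first out-migration / age at return
LEAVER_BANDS = ((0, 17, "leaver_lt17"), (17, 30, "leaver_17_29"),
                (30, 60, "leaver_30_59"), (60, 200, "leaver_60p"))
RETURNEE_BANDS = ((0, 30, "returnee_lt30"), (30, 60, "returnee_30_59"),
                  (60, 200, "returnee_60p"))

#: four descriptive returnee bands, for summary tables only (not modeled)
RETURNEE_BANDS_DESCRIPTIVE = ((0, 17, "returnee_lt17"), (17, 30, "returnee_17_29"),
                              (30, 60, "returnee_30_59"), (60, 200, "returnee_60p"))

#: structural age domain [low, high] (inclusive single years) per status:
#: movers banded at age a survived to a, so mortality below the band's lower
#: bound is zero by definition; returnees before 30 are capped at age 77.
STRUCTURAL_DOMAIN = {
    "stayer": (0, 200), "leaver": (0, 200), "returnee": (0, 200),
    "leaver_lt17": (0, 200), "leaver_17_29": (0, 200),
    "leaver_30_59": (30, 200), "leaver_60p": (60, 200),
    "returnee_lt30": (0, 77), "returnee_30_59": (30, 200), "returnee_60p": (60, 200),
}

D_COLS = tuple("D_" + c for c in ALL_CAUSE_LABELS)
KEY_COLS = ("year", "sex", "birth_region", "status", "age_mid")


@dataclass
class MigrationStatus:
    category: str                 # stayer / leaver / returnee
    age_band: str | None = None   # full status label for movers, None for stayers

    @property
    def label(self) -> str:
        return self.age_band if self.age_band is not None else "stayer"


def _band_label(age: float, bands) -> str:
    for lo, hi, name in bands:
        if lo <= age < hi:
            return name
    raise ValueError(f"event age {age} outside all bands")


def classify(history: IndividualHistory, event_age: float | None = None,
             end_of_follow_up: int = 2018) -> MigrationStatus:
    """Classify a single history; ``event_age`` is the (possibly imputed)
    age at first out-migration (leavers) or at return (returnees)."""
    if not history.residence and history.death_year is None:
        raise ValueError(f"person {history.person_id}: no observations and no death record")
    last_year = min(end_of_follow_up, history.death_year
                    if history.death_year is not None else end_of_follow_up)
    obs = {y: r for y, r in history.residence.items() if y <= last_year}
    outside = [y for y, r in obs.items() if r != history.birth_region]
    if not outside:
        return MigrationStatus("stayer")
    last_obs_year = max(obs)
    category = "returnee" if obs[last_obs_year] == history.birth_region else "leaver"
    band = None
    if event_age is not None:
        bands = LEAVER_BANDS if category == "leaver" else RETURNEE_BANDS
        band = _band_label(event_age, bands)
    return MigrationStatus(category, band)


def classify_population(pop: Population, end_of_follow_up: int | None = None
                        ) -> tuple[np.ndarray, int]:
    """Vectorised classification into stayer/leaver/returnee categories.

    Returns (categories, n_unclassifiable); unclassifiable persons (no
    observation and no death record) get category ''.
    """
    if end_of_follow_up is None:
        end_of_follow_up = pop.follow_up[1]
    years = pop.years_axis
    res = pop.residence
    # observations at or before min(end of follow-up, year of death)
    limit = np.where(pop.death_year >= 0,
                     np.minimum(pop.death_year, end_of_follow_up), end_of_follow_up)
    valid = (res >= 0) & (years[None, :] <= limit[:, None])
    outside_any = ((res != pop.birth_region[:, None]) & valid).any(axis=1)
    has_obs = valid.any(axis=1)
    # region at the last valid observation
    last_col = np.where(valid, np.arange(res.shape[1])[None, :], -1).max(axis=1)
    last_region = np.where(last_col >= 0, res[np.arange(pop.n), np.clip(last_col, 0, None)], -1)

    cats = np.full(pop.n, "", dtype=object)
    classifiable = has_obs | (pop.death_year >= 0)
    cats[classifiable & ~outside_any] = "stayer"
    cats[outside_any & (last_region != pop.birth_region)] = "leaver"
    cats[outside_any & (last_region == pop.birth_region)] = "returnee"
    return cats, int((~classifiable).sum())


def assign_status_bands(categories: np.ndarray, event_ages: np.ndarray) -> np.ndarray:
    """Combine categories with event ages into full status labels.

    ``event_ages[i]`` is the age at first out-migration for leavers and the
    age at return for returnees (observed exactly or imputed); ignored for
    stayers.  Unclassifiable persons keep the empty label.
    """
    out = np.asarray(categories, dtype=object).copy()
    for cat, bands in (("leaver", LEAVER_BANDS), ("returnee", RETURNEE_BANDS)):
        idx = np.nonzero(out == cat)[0]
        for i in idx:
            a = event_ages[i]
            if not np.isfinite(a):
                raise ValueError(f"mover at index {i} has no event age for band assignment")
            out[i] = _band_label(float(a), bands)
    return out


def age_group_midpoint(age, age_start: int = 20, width: int = 3):
    """Midpoint of the containing age group: [20,23) -> 21.5, [23,26) -> 24.5, ..."""
    g = (np.asarray(age, dtype=int) - age_start) // width
    return age_start + g * width + width / 2.0


def build_exposure_table(pop: Population, status: np.ndarray,
                         age_range: tuple[int, int] = (20, 95), group_width: int = 3,
                         death_year_fraction: float = 0.5,
                         structural_zeros: bool = True) -> pd.DataFrame:
    """Aggregate deaths and person-years by (year, sex, birth region, status,
    3-year age group).

    Each calendar year a person is alive and aged inside ``[20, 95)``
    contributes one person-year (the death year contributes
    ``death_year_fraction``).  With ``structural_zeros=True``, person-years
    and deaths outside a status's structural age domain are excluded, so
    rows below a mover band's entry age are exact zeros.
    """
    status = np.asarray(status, dtype=object)
    if status.shape != (pop.n,):
        raise ValueError("status must have one label per person")
    a_lo, a_hi = age_range
    y_start, y_end = pop.follow_up
    classified = status != ""

    start = np.maximum(pop.birth_year + a_lo, y_start)
    end = np.minimum.reduce([
        np.where(pop.death_year >= 0, pop.death_year, y_end),
        pop.birth_year + a_hi - 1,
        np.full(pop.n, y_end),
    ])
    ok = classified & (end >= start)
    idx0 = np.nonzero(ok)[0]
    counts = (end[idx0] - start[idx0] + 1).astype(np.int64)
    idx = np.repeat(idx0, counts)
    offs = np.arange(counts.sum()) - np.repeat(np.cumsum(counts) - counts, counts)
    years_py = start[idx] + offs
    ages_py = years_py - pop.birth_year[idx]
    if np.any(ages_py < a_lo) or np.any(ages_py >= a_hi):
        raise AssertionError("internal error: person-year age outside range")

    expo = np.ones(idx.size)
    expo[years_py == pop.death_year[idx]] = death_year_fraction

    st = status[idx]
    if structural_zeros:
        lo = np.array([STRUCTURAL_DOMAIN[s][0] for s in st])
        hi = np.array([STRUCTURAL_DOMAIN[s][1] for s in st])
        keep = (ages_py >= lo) & (ages_py <= hi)
        idx, years_py, ages_py, expo, st = (a[keep] for a in (idx, years_py, ages_py, expo, st))

    py = pd.DataFrame({
        "year": years_py,
        "sex": np.where(pop.sex[idx] == 0, "f", "m"),
        "birth_region": pop.birth_region[idx],
        "status": st,
        "age_mid": age_group_midpoint(ages_py, a_lo, group_width),
        "E": expo,
    })
    table = py.groupby(list(KEY_COLS), as_index=False, sort=True)["E"].sum()

    # deaths, tallied by cause at the age attained in the death year
    dead = (pop.death_year >= 0) & classified & \
        (pop.death_age >= a_lo) & (pop.death_age < a_hi) & \
        (pop.death_year >= y_start) & (pop.death_year <= y_end)
    if structural_zeros:
        dlo = np.array([STRUCTURAL_DOMAIN[s][0] for s in status])
        dhi = np.array([STRUCTURAL_DOMAIN[s][1] for s in status])
        dead &= (pop.death_age >= dlo) & (pop.death_age <= dhi)
    di = np.nonzero(dead)[0]
    deaths = pd.DataFrame({
        "year": pop.death_year[di],
        "sex": np.where(pop.sex[di] == 0, "f", "m"),
        "birth_region": pop.birth_region[di],
        "status": status[di],
        "age_mid": age_group_midpoint(pop.death_age[di], a_lo, group_width),
        "cause": [ALL_CAUSE_LABELS[c] for c in pop.cause[di]],
    })
    dcounts = (deaths.groupby(list(KEY_COLS) + ["cause"]).size()
               .unstack("cause", fill_value=0).reset_index())
    for c in ALL_CAUSE_LABELS:
        if c not in dcounts.columns:
            dcounts[c] = 0
    dcounts = dcounts.rename(columns={c: "D_" + c for c in ALL_CAUSE_LABELS})

    table = table.merge(dcounts, on=list(KEY_COLS), how="outer")
    table[list(D_COLS)] = table[list(D_COLS)].fillna(0.0)
    table["E"] = table["E"].fillna(0.0)
    table["D_total"] = table[list(D_COLS)].sum(axis=1)
    table = table.sort_values(list(KEY_COLS)).reset_index(drop=True)
    table.attrs["age_range"] = age_range
    table.attrs["group_width"] = group_width
    table.attrs["structural_zeros"] = structural_zeros
    return table


def redistribute_illdefined(table: pd.DataFrame, period_width: int = 5,
                            age_width: int = 5) -> pd.DataFrame:
    """Reassign ill-defined deaths proportionally to the six named causes.

    Strata are 5-year calendar periods x 5-year age groups x sex; within a
    stratum each row's ill-defined deaths are split across causes in
    proportion to the stratum's named-cause totals.  A stratum with
    ill-defined deaths but no named-cause deaths falls back to progressively
    wider neighbourhoods (then the sex-wide margin), with a warning.
    Per-stratum total deaths are conserved exactly.
    """
    ill = "D_" + ILL_DEFINED
    named = ["D_" + c for c in CAUSES]
    out = table.copy()
    if ill not in out.columns or out[ill].sum() == 0:
        out = out.drop(columns=[ill], errors="ignore")
        out.attrs.update(table.attrs)
        out.attrs["illdefined_redistributed"] = True
        return out

    period = (out["year"] // period_width) * period_width
    age5 = (out["age_mid"].astype(int) // age_width) * age_width
    strat = pd.DataFrame({"period": period, "age5": age5, "sex": out["sex"]})
    sums = out[named + [ill]].groupby([strat.period, strat.age5, strat.sex]).transform("sum")
    named_tot = sums[named].sum(axis=1)

    props = pd.DataFrame(index=out.index, columns=named, dtype=float)
    good = named_tot > 0
    props.loc[good] = sums.loc[good, named].div(named_tot[good], axis=0)

    n_fallback = 0
    fb = ~good & (out[ill] > 0)
    if fb.any():
        n_fallback = int(fb.sum())
        # pool adjacent strata (double-width period and age windows), then
        # fall back to the sex-wide marginal cause distribution
        coarse_keys = [(out["year"] // (2 * period_width)) * (2 * period_width),
                       (out["age_mid"].astype(int) // (2 * age_width)) * (2 * age_width),
                       out["sex"]]
        coarse = out[named].groupby(coarse_keys).transform("sum")
        coarse_sum = coarse.sum(axis=1)
        use_c = fb & (coarse_sum > 0)
        props.loc[use_c] = coarse.loc[use_c, named].div(coarse_sum[use_c], axis=0)
        rest = fb & (coarse_sum <= 0)
        if rest.any():
            sex_tot = out.groupby(out["sex"])[named].transform("sum")
            sex_sum = sex_tot.sum(axis=1)
            use_sex = rest & (sex_sum > 0)
            props.loc[use_sex] = sex_tot.loc[use_sex, named].div(sex_sum[use_sex], axis=0)
            props.loc[rest & (sex_sum <= 0)] = 1.0 / len(named)
        warnings.warn(f"{n_fallback} rows with ill-defined deaths in strata without "
                      "named-cause deaths; used pooled fallback cause distribution")
    props = props.fillna(0.0)

    add = props.mul(out[ill], axis=0)
    out[named] = out[named].add(add, axis=0)
    out = out.drop(columns=[ill])
    out["D_total"] = out[named].sum(axis=1)
    out.attrs.update(table.attrs)
    out.attrs["illdefined_redistributed"] = True
    out.attrs["illdefined_fallback_rows"] = n_fallback
    return out


def write_exposure_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_exposure_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
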