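"""Average marginal mortality rates and rate ratios.

The fitted model conditions on birth region and calendar year; the reported
age-specific rate of a status is the average, on the rate scale, of the
predicted rate over every (region, year) combination present in the data —
the usual average-marginal-effect construction.  Uncertainty comes from
simulating coefficient vectors from the multivariate normal with the
model's covariance and recomputing; bands are the 5th and 95th percentiles
of the draws.  Rate ratios put the stayers' rate in the numerator, so
values above 1 mean higher mortality for stayers, and are computed draw by
draw before taking percentiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gam import YEAR_SMOOTH, FittedMortalityModel


@dataclass
class MarginalRateSchedule:
    status: str
    ages: np.ndarray
    rate: np.ndarray
    lower90: np.ndarray
    upper90: np.ndarray
    draws: np.ndarray = field(repr=False)   # (n_draws, n_ages) marginal rates
    sex: str | None = None
    cause: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "status": self.status, "sex": self.sex, "cause": self.cause,
            "age": self.ages, "rate": self.rate,
            "lower90": self.lower90, "upper90": self.upper90,
        })


def _combo_design(model: FittedMortalityModel, combos: pd.DataFrame) -> np.ndarray:
    """Rows of the (region, year) part of the linear predictor per combo."""
    p = model.beta.size
    M = np.zeros((len(combos), p))
    reg_sl = model.parametric_slices["region"]
    for i, (r, t) in enumerate(zip(combos["birth_region"], combos["year"])):
        if r not in model.region_levels:
            raise ValueError(f"unseen region {r!r}")
        if r != model.region_levels[0]:
            M[i, reg_sl.start + model.region_levels[1:].index(r)] = 1.0
        if model.spec.year_term == "categorical":
            if t not in model.year_levels:
                raise ValueError(f"unseen year {t!r}")
            if t != model.year_levels[0]:
                yr_sl = model.parametric_slices["year"]
                M[i, yr_sl.start + model.year_levels[1:].index(t)] = 1.0
        else:
            sm = model.smooth_for(YEAR_SMOOTH)
            if sm is not None:
                M[i, sm.sl] = sm.basis_row(float(t))[0]
    return M


def _status_design(model: FittedMortalityModel, status: str,
                   ages: np.ndarray) -> np.ndarray:
    """Rows of the (intercept, status, smooth-age) part per age."""
    p = model.beta.size
    A = np.zeros((ages.size, p))
    A[:, 0] = 1.0
    if status not in model.status_levels:
        raise ValueError(f"unseen status {status!r}")
    if status != model.status_levels[0]:
        sl = model.parametric_slices["status"]
        A[:, sl.start + model.status_levels[1:].index(status)] = 1.0
    sm = model.smooth_for(status)
    if sm is not None:
        A[:, sm.sl] = sm.basis_row(ages)
    return A


def average_marginal_rates(model: FittedMortalityModel,
                           reference_table: pd.DataFrame | None = None,
                           n_draws: int = 1000, seed: int = 0,
                           ages: np.ndarray | None = None,
                           statuses: list | None = None,
                           exposure_weighted: bool = False,
                           sex: str | None = None, cause: str | None = None,
                           ) -> dict[str, MarginalRateSchedule]:
    """Average marginal age-specific rates per status.

    ``reference_table`` supplies the (region, year) support to average over
    (defaults to the fitted support, equal weights; ``exposure_weighted``
    weights combinations by their person-years instead).
    """
    if not model.converged:
        raise RuntimeError("refusing to marginalise a non-converged model")
    if n_draws < 100:
        warnings.warn("fewer than 100 coefficient draws; percentile bands will be noisy")
    if reference_table is None:
        combos = model.marginal_support.copy()
        weights = np.ones(len(combos))
    else:
        if exposure_weighted:
            combos = (reference_table.groupby(["birth_region", "year"], as_index=False)
                      ["E"].sum())
            weights = combos["E"].to_numpy(dtype=float)
        else:
            combos = reference_table[["birth_region", "year"]].drop_duplicates()
            weights = np.ones(len(combos))
    weights = weights / weights.sum()

    M = _combo_design(model, combos)
    rng = np.random.default_rng(seed)
    cov = 0.5 * (model.cov + model.cov.T)
    try:
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0])
                               * max(np.trace(cov), 1.0) / cov.shape[0])
    except np.linalg.LinAlgError:
        # near-singular covariance: factor through clipped eigenvalues
        w, V = np.linalg.eigh(cov)
        L = V * np.sqrt(np.clip(w, 0.0, None))
    B = model.beta[None, :] + rng.standard_normal((n_draws, model.beta.size)) @ L.T

    out = {}
    for status in (statuses or model.status_levels):
        sm = model.smooth_for(status)
        if ages is None:
            a = sm.points if sm is not None else np.array([np.nan])
        else:
            a = np.asarray(ages, dtype=float)
            if sm is not None:
                a = a[(a >= sm.domain[0] - 1e-9) & (a <= sm.domain[1] + 1e-9)]
        A = _status_design(model, status, a)
        # marginal rate(x) = sum_c w_c exp(eta_base(x) + eta_combo(c))
        eta_a = A @ model.beta
        eta_c = M @ model.beta
        point = np.exp(eta_a) * np.sum(weights * np.exp(eta_c))
        eta_a_d = B @ A.T                      # (draws, ages)
        eta_c_d = B @ M.T                      # (draws, combos)
        mix = np.exp(eta_c_d) @ weights        # (draws,)
        draws = np.exp(eta_a_d) * mix[:, None]
        lo, hi = np.percentile(draws, [5, 95], axis=0)
        out[status] = MarginalRateSchedule(
            status=status, ages=a, rate=point, lower90=lo, upper90=hi,
            draws=draws, sex=sex, cause=cause)
    return out


@dataclass
class RateRatioSchedule:
    status: str                  # the comparison (denominator) status
    reference: str               # numerator status (stayer)
    ages: np.ndarray
    ratio: np.ndarray
    lower90: np.ndarray
    upper90: np.ndarray
    excluded_ages: np.ndarray
    sex: str | None = None
    cause: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "status": self.status, "reference": self.reference,
            "sex": self.sex, "cause": self.cause, "age": self.ages,
            "ratio": self.ratio, "lower90": self.lower90, "upper90": self.upper90,
        })


def rate_ratios(schedules: dict[str, MarginalRateSchedule],
                reference_status: str = "stayer") -> dict[str, RateRatioSchedule]:
    """ratio(x) = rate_reference(x) / rate_status(x); >1 means the mover has
    lower mortality than the reference (stayers).  Bands are percentiles of
    the draw-wise ratios."""
    if reference_status not in schedules:
        raise ValueError(f"reference schedule {reference_status!r} missing")
    ref = schedules[reference_status]
    out = {}
    for status, sch in schedules.items():
        if status == reference_status:
            continue
        common = np.intersect1d(ref.ages, sch.ages)
        excluded = np.setdiff1d(sch.ages, common)
        ia = np.searchsorted(ref.ages, common)
        ib = np.searchsorted(sch.ages, common)
        ratio = ref.rate[ia] / sch.rate[ib]
        rdraws = ref.draws[:, ia] / sch.draws[:, ib]
        lo, hi = np.percentile(rdraws, [5, 95], axis=0)
        out[status] = RateRatioSchedule(
            status=status, reference=reference_status, ages=common,
            ratio=ratio, lower90=lo, upper90=hi, excluded_ages=excluded,
            sex=sch.sex, cause=sch.cause)
    return out
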