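"""Partial (temporary) life tables for ages 20-95.

Standard grouped-age life-table columns built from age-specific death
rates: nqx = n*nmx / (1 + (n - nax)*nmx) with nax = n/2 (adult ages only),
radix 100,000, closed by truncation at the last group boundary (the table
is partial, so there is no open-ended interval).  The temporary life
expectancy between ages a and b is the person-years lived in [a, b) per
survivor at a.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

RADIX = 100_000.0


def build_partial_life_table(ages: np.ndarray, nmx: np.ndarray,
                             closeout_age: float | None = None,
                             nax_fraction: float = 0.5) -> pd.DataFrame:
    """Life table from group start ages and rates.

    ``ages`` are the lower bounds of the age groups (e.g. 20, 23, ..., 92);
    group widths come from their differences, the last group ending at
    ``closeout_age`` (default: previous width continued).  Rates producing
    nqx > 1 are capped with a warning.
    """
    ages = np.asarray(ages, dtype=float)
    nmx = np.asarray(nmx, dtype=float)
    if ages.ndim != 1 or ages.size != nmx.size or ages.size < 1:
        raise ValueError("ages and nmx must be 1-d arrays of equal length")
    if np.any(np.diff(ages) <= 0):
        raise ValueError("ages must be strictly increasing")
    if np.any(nmx < 0):
        raise ValueError("negative mortality rate")
    widths = np.diff(ages)
    last = closeout_age - ages[-1] if closeout_age is not None else \
        (widths[-1] if widths.size else 1.0)
    n = np.concatenate([widths, [last]])
    if n[-1] <= 0:
        raise ValueError("closeout_age must exceed the last group start")

    nax = nax_fraction * n
    nqx = n * nmx / (1.0 + (n - nax) * nmx)
    if np.any(nqx > 1.0):
        warnings.warn("death probabilities above 1 capped")
        nqx = np.minimum(nqx, 1.0)

    lx = np.empty(ages.size)
    lx[0] = RADIX
    for i in range(1, ages.size):
        lx[i] = lx[i - 1] * (1.0 - nqx[i - 1])
    ndx = lx * nqx
    lx_next = lx - ndx
    nLx = n * lx_next + nax * ndx
    Tx = np.cumsum(nLx[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ex = np.where(lx > 0, Tx / lx, 0.0)

    return pd.DataFrame({"age": ages, "n": n, "nmx": nmx, "nqx": nqx,
                         "nax": nax, "lx": lx, "ndx": ndx, "nLx": nLx,
                         "Tx": Tx, "ex_partial": ex})


def temporary_expectancy(lt: pd.DataFrame, from_age: float,
                         to_age: float | None = None) -> float:
    """Expected years lived between ``from_age`` and ``to_age`` per survivor
    at ``from_age`` (both must be group boundaries of the table)."""
    ages = lt["age"].to_numpy()
    ends = ages + lt["n"].to_numpy()
    if to_age is None:
        to_age = ends[-1]
    if from_age >= to_age:
        raise ValueError("from_age must be below to_age")
    if not np.any(np.isclose(ages, from_age)):
        raise ValueError(f"from_age {from_age} is not a group boundary")
    if not (np.any(np.isclose(ends, to_age)) or np.any(np.isclose(ages, to_age))):
        raise ValueError(f"to_age {to_age} is not a group boundary")
    sel = (ages >= from_age - 1e-9) & (ends <= to_age + 1e-9)
    i0 = int(np.argmax(np.isclose(ages, from_age)))
    lx0 = lt["lx"].to_numpy()[i0]
    if lx0 <= 0:
        return 0.0
    return float(lt["nLx"].to_numpy()[sel].sum() / lx0)


def expectancy_from_rates(ages: np.ndarray, nmx: np.ndarray,
                          from_age: float | None = None,
                          closeout_age: float | None = None,
                          nax_fraction: float = 0.5) -> float:
    """Temporary expectancy from ``from_age`` (default: first group) to the
    table's end, straight from a rate schedule."""
    lt = build_partial_life_table(ages, nmx, closeout_age=closeout_age,
                                  nax_fraction=nax_fraction)
    return temporary_expectancy(lt, ages[0] if from_age is None else from_age)


def expectancy_from_rates_batch(ages: np.ndarray, nmx: np.ndarray,
                                closeout_age: float | None = None,
                                nax_fraction: float = 0.5) -> np.ndarray:
    """Vectorised temporary expectancy from the first group boundary for a
    batch of rate schedules (columns of ``nmx``, shape (n_groups, n_batch)).

    Used heavily by the decomposition's finite-difference gradients.
    """
    ages = np.asarray(ages, dtype=float)
    nmx = np.asarray(nmx, dtype=float)
    if nmx.ndim == 1:
        nmx = nmx[:, None]
    widths = np.diff(ages)
    last = closeout_age - ages[-1] if closeout_age is not None else \
        (widths[-1] if widths.size else 1.0)
    n = np.concatenate([widths, [last]])[:, None]
    nax = nax_fraction * n
    nqx = np.minimum(n * nmx / (1.0 + (n - nax) * nmx), 1.0)
    surv = np.cumprod(1.0 - nqx, axis=0)
    lx = np.vstack([np.ones((1, nmx.shape[1])), surv[:-1]])
    ndx = lx * nqx
    nLx = n * (lx - ndx) + nax * ndx
    return nLx.sum(axis=0)


def gap_table(expectancies: dict[str, float], reference: str = "stayer"
              ) -> pd.DataFrame:
    """Differences in temporary expectancy versus the reference, reported in
    months and as a percentage of the reference's expectancy."""
    if reference not in expectancies:
        raise ValueError(f"reference {reference!r} missing")
    e_ref = expectancies[reference]
    rows = []
    for status, e in expectancies.items():
        if status == reference:
            continue
        gap = e - e_ref
        rows.append({"status": status, "reference": reference,
                     "expectancy_years": e, "reference_years": e_ref,
                     "gap_years": gap, "gap_months": gap * 12.0,
                     "gap_pct_of_reference": 100.0 * gap / e_ref if e_ref else np.nan})
    return pd.DataFrame(rows)
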