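"""Negative-binomial generalized additive mortality model.

Death counts D in cells (3-year age group x calendar year x birth region x
migration status) are modelled, separately by sex and cause, as

    D ~ NegBin(mu = m * E, theta),   log m = b_region + b_year + b_status + s_status(x)

with x the age-group midpoint and E the person-years of exposure entering
through a log offset.  Each status has its own smooth age effect s_m(x),
a linear combination of 10 cubic B-splines with a second-derivative
(curvature) penalty, constrained to sum to zero over the status's observed
midpoints so that the status intercept carries the level.  Smoothing
parameters are chosen by Laplace-approximate REML (GCV optional), and the
overdispersion theta by profile likelihood, alternating with the smoothing
optimisation.  Penalised fitting is by iteratively reweighted least
squares; the coefficient covariance is the inverse penalised information
at the optimum, which is what the downstream simulation-based intervals
draw from.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import interpolate, linalg, optimize, special

from .histories import STRUCTURAL_DOMAIN

YEAR_SMOOTH = "__year__"  # label of the optional calendar-year smooth block


@dataclass
class ModelSpec:
    basis_size: int = 10
    response_family: str = "negbin"          # or "poisson"
    smoothing_selection: str = "reml"        # "reml", "gcv" or "fixed"
    fixed_lambda: float = 1.0                # used when smoothing_selection == "fixed"
    year_term: str = "categorical"           # or "smooth"
    theta_init: float = 10.0
    max_iter: int = 200
    tol: float = 1e-8
    outer_iter: int = 3

    def __post_init__(self):
        if self.response_family not in ("negbin", "poisson"):
            raise ValueError("response_family must be 'negbin' or 'poisson'")
        if self.smoothing_selection not in ("reml", "gcv", "fixed"):
            raise ValueError("smoothing_selection must be 'reml', 'gcv' or 'fixed'")
        if self.year_term not in ("categorical", "smooth"):
            raise ValueError("year_term must be 'categorical' or 'smooth'")


# ---------------------------------------------------------------------------
# spline basis with curvature penalty and sum-to-zero constraint


def bspline_knots(lo: float, hi: float, k: int) -> np.ndarray:
    """Clamped cubic B-spline knot vector giving k basis functions on [lo, hi]."""
    if k < 4:
        raise ValueError("need at least 4 cubic B-spline basis functions")
    interior = np.linspace(lo, hi, k - 2)[1:-1]
    return np.concatenate([[lo] * 4, interior, [hi] * 4])


def bspline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    # clamp to the closed interval so the right boundary evaluates cleanly
    xc = np.clip(x, knots[0], knots[-1])
    return interpolate.BSpline.design_matrix(xc, knots, 3, extrapolate=False).toarray()


def curvature_penalty(knots: np.ndarray) -> np.ndarray:
    """S_ij = integral of B_i'' B_j'' over the basis support (exact by
    Gauss-Legendre: the integrand is piecewise quadratic for cubics)."""
    k = len(knots) - 4
    spl = interpolate.BSpline(knots, np.eye(k), 3)
    d2 = spl.derivative(2)
    gx, gw = np.polynomial.legendre.leggauss(3)
    S = np.zeros((k, k))
    spans = np.unique(knots)
    for a, b in zip(spans[:-1], spans[1:]):
        xq = 0.5 * (b - a) * gx + 0.5 * (a + b)
        wq = 0.5 * (b - a) * gw
        Bq = d2(xq)                       # (3, k)
        S += (Bq * wq[:, None]).T @ Bq
    return S


def sum_to_zero_null(constraint: np.ndarray) -> np.ndarray:
    """Orthonormal basis Z of the null space of c^T, so that the constrained
    coefficients are beta = Z @ gamma with c^T beta = 0 exactly."""
    q, _ = np.linalg.qr(constraint[:, None], mode="complete")
    return q[:, 1:]


@dataclass
class SmoothBlock:
    label: str               # status name, or YEAR_SMOOTH
    knots: np.ndarray
    Z: np.ndarray            # (k, k-1)
    S: np.ndarray            # penalised (k-1, k-1) curvature penalty
    sl: slice                # columns of the design
    points: np.ndarray       # covariate values the sum-to-zero constraint averages over
    domain: tuple            # (lo, hi) of fitted covariate values

    def basis_row(self, x) -> np.ndarray:
        return bspline_basis(np.atleast_1d(x), self.knots) @ self.Z

    @property
    def rank(self) -> int:
        ev = np.linalg.eigvalsh(self.S)
        return int((ev > 1e-10 * ev.max()).sum())

    @property
    def log_det_plus(self) -> float:
        ev = np.linalg.eigvalsh(self.S)
        ev = ev[ev > 1e-10 * ev.max()]
        return float(np.log(ev).sum())


@dataclass
class Design:
    X: np.ndarray
    y: np.ndarray
    offset: np.ndarray
    col_names: list
    region_levels: list
    year_levels: list
    status_levels: list
    refs: dict
    smooths: list
    parametric_slices: dict          # term -> slice
    n_dropped_zero_exposure: int
    table: pd.DataFrame              # the fitted rows (for marginalisation support)
    response: str


def build_design(table: pd.DataFrame, spec: ModelSpec, response: str = "D_total",
                 refs: dict | None = None) -> Design:
    """Assemble the model matrix: intercept, reference-coded region / year /
    status indicator blocks and one constrained penalised spline block per
    status (plus an optional year smooth), with offset log E.

    Rows with zero exposure are dropped (count recorded); a rank check
    raises on aliased columns.
    """
    refs = dict(refs or {})
    use = table[table["E"] > 0].reset_index(drop=True)
    n_dropped = len(table) - len(use)
    if use.empty:
        raise ValueError("no rows with positive exposure")

    def levels(col, ref_key):
        lv = sorted(use[col].unique().tolist())
        ref = refs.get(ref_key)
        if ref is not None:
            if ref not in lv:
                raise ValueError(f"reference level {ref!r} not present in {col}")
            lv = [ref] + [v for v in lv if v != ref]
        elif ref_key == "status" and "stayer" in lv:
            lv = ["stayer"] + [v for v in lv if v != "stayer"]
        return lv

    region_levels = levels("birth_region", "region")
    year_levels = levels("year", "year")
    status_levels = levels("status", "status")

    n = len(use)
    blocks = [np.ones((n, 1))]
    col_names = ["(Intercept)"]
    parametric_slices = {}
    pos = 1

    def add_factor(col, lv, name):
        nonlocal pos
        cols = []
        for v in lv[1:]:
            cols.append((use[col] == v).to_numpy(dtype=float)[:, None])
            col_names.append(f"{name}[{v}]")
        if cols:
            blocks.append(np.hstack(cols))
        parametric_slices[name] = slice(pos, pos + len(cols))
        pos += len(cols)

    add_factor("birth_region", region_levels, "region")
    if spec.year_term == "categorical":
        add_factor("year", year_levels, "year")
    else:
        parametric_slices["year"] = slice(pos, pos)
    add_factor("status", status_levels, "status")

    smooths = []

    def add_smooth(label, values, all_points):
        nonlocal pos
        pts = np.unique(all_points)
        if pts.size < 5:
            return  # too few distinct values to support a smooth; level-only
        k = min(spec.basis_size, pts.size)
        knots = bspline_knots(pts.min(), pts.max(), k)
        B_pts = bspline_basis(pts, knots)
        Z = sum_to_zero_null(B_pts.sum(axis=0))
        S = Z.T @ curvature_penalty(knots) @ Z
        Xb = bspline_basis(values, knots) @ Z
        sl = slice(pos, pos + Z.shape[1])
        blocks.append(Xb)
        col_names.extend([f"s({label}).{j}" for j in range(Z.shape[1])])
        smooths.append(SmoothBlock(label=label, knots=knots, Z=Z, S=S, sl=sl,
                                   points=pts, domain=(float(pts.min()), float(pts.max()))))
        pos += Z.shape[1]

    if spec.year_term == "smooth":
        yv = use["year"].to_numpy(dtype=float)
        add_smooth(YEAR_SMOOTH, yv, yv)
    for s in status_levels:
        mask = (use["status"] == s).to_numpy()
        x_s = use.loc[mask, "age_mid"].to_numpy(dtype=float)
        xz = np.zeros(n)
        xz[mask] = 1.0
        pts = np.unique(x_s)
        if pts.size < 5:
            continue
        k = min(spec.basis_size, pts.size)
        knots = bspline_knots(pts.min(), pts.max(), k)
        B_pts = bspline_basis(pts, knots)
        Z = sum_to_zero_null(B_pts.sum(axis=0))
        S = Z.T @ curvature_penalty(knots) @ Z
        Xb = np.zeros((n, Z.shape[1]))
        Xb[mask] = bspline_basis(x_s, knots) @ Z
        sl = slice(pos, pos + Z.shape[1])
        blocks.append(Xb)
        col_names.extend([f"s({s}).{j}" for j in range(Z.shape[1])])
        smooths.append(SmoothBlock(label=s, knots=knots, Z=Z, S=S, sl=sl,
                                   points=pts, domain=(float(pts.min()), float(pts.max()))))
        pos += Z.shape[1]

    X = np.hstack(blocks)
    if X.shape[1] != pos:
        raise AssertionError("column bookkeeping error")

    # alias check on the penalised-null-space-augmented cross-product
    gram = X.T @ X
    for sm in smooths:
        gram[sm.sl, sm.sl] += sm.S
    rank = np.linalg.matrix_rank(gram, hermitian=True)
    if rank < X.shape[1]:
        u, sv, vt = np.linalg.svd(gram)
        aliased = [col_names[i] for i in np.argsort(np.abs(vt[-1]))[::-1][:3]]
        raise ValueError(f"design is rank deficient after constraint absorption; "
                         f"columns involved: {aliased}")

    y = use[response].to_numpy(dtype=float)
    offset = np.log(use["E"].to_numpy(dtype=float))
    return Design(X=X, y=y, offset=offset, col_names=col_names,
                  region_levels=region_levels, year_levels=year_levels,
                  status_levels=status_levels, refs=refs, smooths=smooths,
                  parametric_slices=parametric_slices,
                  n_dropped_zero_exposure=n_dropped, table=use, response=response)


# ---------------------------------------------------------------------------
# likelihood pieces


def _loglik(y, mu, theta, family):
    mu = np.clip(mu, 1e-300, None)
    if family == "poisson":
        return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1.0)))
    return float(np.sum(special.gammaln(y + theta) - special.gammaln(theta)
                        - special.gammaln(y + 1.0)
                        + theta * np.log(theta) + y * np.log(mu)
                        - (y + theta) * np.log(mu + theta)))


def _deviance(y, mu, theta, family):
    mu = np.clip(mu, 1e-300, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
    if family == "poisson":
        return float(2.0 * np.sum(t1 - (y - mu)))
    t2 = (y + theta) * np.log((y + theta) / (mu + theta))
    return float(2.0 * np.sum(t1 - t2))


def _penalty_matrix(smooths, lam, p):
    S = np.zeros((p, p))
    for sm, lm in zip(smooths, lam):
        S[sm.sl, sm.sl] += lm * sm.S
    return S


def _pirls(design: Design, lam, theta, family, beta0=None, max_iter=200, tol=1e-8):
    """Penalised IRLS at fixed smoothing parameters and theta."""
    X, y, off = design.X, design.y, design.offset
    p = X.shape[1]
    S = _penalty_matrix(design.smooths, lam, p)
    if beta0 is None:
        mu = y + np.mean(y) * 0.1 + 0.1
        lp = np.log(mu) - off
    else:
        lp = X @ beta0
    beta = beta0
    dev_old = np.inf
    converged = False
    H = None
    for _ in range(max_iter):
        eta = np.clip(lp + off, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu if family == "poisson" else mu / (1.0 + mu / theta)
        w = np.clip(w, 1e-10, None)
        z = (eta - off) + (y - mu) / mu
        XtW = X.T * w
        H = XtW @ X
        A = H + S
        try:
            c, lo = linalg.cho_factor(A)
        except np.linalg.LinAlgError:
            A = A + 1e-8 * np.eye(p) * np.trace(A) / p
            c, lo = linalg.cho_factor(A)
        beta_new = linalg.cho_solve((c, lo), XtW @ z)
        # step halving on the penalised deviance
        for _half in range(30):
            lp_new = X @ beta_new
            mu_new = np.exp(np.clip(lp_new + off, -30.0, 30.0))
            dev = _deviance(y, mu_new, theta, family) + float(beta_new @ S @ beta_new)
            if np.isfinite(dev) and (dev <= dev_old + 1e-12 or beta is None):
                break
            beta_new = 0.5 * (beta_new + (beta if beta is not None else 0.0))
        beta, lp = beta_new, X @ beta_new
        if abs(dev_old - dev) < tol * (abs(dev) + 0.1):
            converged = True
            dev_old = dev
            break
        dev_old = dev
    eta = np.clip(lp + off, -30.0, 30.0)
    mu = np.exp(eta)
    w = mu if family == "poisson" else mu / (1.0 + mu / theta)
    XtW = X.T * np.clip(w, 1e-10, None)
    H = XtW @ X
    return {"beta": beta, "mu": mu, "H": H, "S": S,
            "deviance": _deviance(y, mu, theta, family),
            "penalized_deviance": dev_old,
            "loglik": _loglik(y, mu, theta, family), "converged": converged}


def _reml_score(fitres, design, lam):
    """Negative Laplace-approximate REML (constants in lambda dropped)."""
    beta, H, S = fitres["beta"], fitres["H"], fitres["S"]
    pen = float(beta @ S @ beta)
    A = H + S
    try:
        c, lo = linalg.cho_factor(A)
        logdet_H = 2.0 * float(np.log(np.diag(c)).sum())
    except np.linalg.LinAlgError:
        sign, logdet_H = np.linalg.slogdet(A + 1e-10 * np.eye(A.shape[0]))
    logdet_S = sum(sm.rank * np.log(lm) + sm.log_det_plus
                   for sm, lm in zip(design.smooths, lam))
    return -(fitres["loglik"] - 0.5 * pen) - 0.5 * logdet_S + 0.5 * logdet_H


def _gcv_score(fitres, design):
    A = fitres["H"] + fitres["S"]
    edf = float(np.trace(linalg.solve(A, fitres["H"], assume_a="pos")))
    n = design.y.size
    return n * fitres["deviance"] / max(n - edf, 1e-3) ** 2


@dataclass
class FittedMortalityModel:
    spec: ModelSpec
    col_names: list
    beta: np.ndarray
    cov: np.ndarray
    theta: float
    lam: np.ndarray
    smooths: list
    region_levels: list
    year_levels: list
    status_levels: list
    refs: dict
    edf: dict
    deviance: float
    loglik: float
    converged: bool
    n_obs: int
    response: str
    parametric_slices: dict
    marginal_support: pd.DataFrame = None   # observed (region, year) combinations

    # -- coefficient views --------------------------------------------
    def _factor_coef(self, term, levels):
        sl = self.parametric_slices[term]
        vals = dict(zip(levels[1:], self.beta[sl]))
        vals[levels[0]] = 0.0
        return vals

    @property
    def beta_region(self):
        return self._factor_coef("region", self.region_levels)

    @property
    def beta_year(self):
        if self.spec.year_term != "categorical":
            raise AttributeError("year entered as a smooth in this fit")
        return self._factor_coef("year", self.year_levels)

    @property
    def beta_status(self):
        return self._factor_coef("status", self.status_levels)

    def smooth_for(self, label):
        for sm in self.smooths:
            if sm.label == label:
                return sm
        return None

    def structural_domain(self, status) -> tuple:
        lo, hi = STRUCTURAL_DOMAIN.get(status, (0, 200))
        sm = self.smooth_for(status)
        if sm is not None:
            return (max(lo, sm.domain[0]), min(hi, sm.domain[1]))
        return (lo, hi)

    # -- prediction ----------------------------------------------------
    def _row(self, x, t, r, m) -> np.ndarray:
        v = np.zeros(self.beta.size)
        v[0] = 1.0
        for term, levels, val in (("region", self.region_levels, r),
                                  ("status", self.status_levels, m)):
            if val not in levels:
                raise ValueError(f"unseen {term} level {val!r}")
            if val != levels[0]:
                sl = self.parametric_slices[term]
                v[sl.start + levels[1:].index(val)] = 1.0
        if self.spec.year_term == "categorical":
            if t not in self.year_levels:
                raise ValueError(f"unseen year {t!r}")
            if t != self.year_levels[0]:
                sl = self.parametric_slices["year"]
                v[sl.start + self.year_levels[1:].index(t)] = 1.0
        else:
            sm = self.smooth_for(YEAR_SMOOTH)
            if sm is not None:
                v[sm.sl] = sm.basis_row(float(t))[0]
        sm = self.smooth_for(m)
        if sm is not None:
            if not (sm.domain[0] - 1e-9 <= x <= sm.domain[1] + 1e-9):
                raise ValueError(f"age {x} outside the fitted domain {sm.domain} "
                                 f"of status {m!r}")
            v[sm.sl] = sm.basis_row(float(x))[0]
        return v

    def predict_log_rate(self, x, t, r, m):
        """Linear predictor and its standard error at (age midpoint, year,
        region, status); ages outside the status's structural domain yield
        the sentinel ('structural_zero', None)."""
        lo, hi = STRUCTURAL_DOMAIN.get(m, (0, 200))
        if not (lo <= x <= hi):
            return ("structural_zero", None)
        v = self._row(x, t, r, m)
        eta = float(v @ self.beta)
        se = float(np.sqrt(v @ self.cov @ v))
        return eta, se

    # -- persistence ----------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        arrays = {"beta": self.beta, "cov": self.cov, "lam": self.lam}
        for i, sm in enumerate(self.smooths):
            arrays[f"smooth{i}_knots"] = sm.knots
            arrays[f"smooth{i}_Z"] = sm.Z
            arrays[f"smooth{i}_S"] = sm.S
            arrays[f"smooth{i}_points"] = sm.points
        np.savez(path / "arrays.npz", **arrays)
        meta = {
            "schema": 1,
            "spec": self.spec.__dict__,
            "col_names": self.col_names,
            "theta": self.theta,
            "smooths": [{"label": sm.label, "sl": [sm.sl.start, sm.sl.stop],
                         "domain": list(sm.domain)} for sm in self.smooths],
            "region_levels": self.region_levels,
            "year_levels": self.year_levels,
            "status_levels": self.status_levels,
            "refs": self.refs,
            "edf": self.edf,
            "deviance": self.deviance,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "response": self.response,
            "parametric_slices": {k: [v.start, v.stop]
                                  for k, v in self.parametric_slices.items()},
        }
        (path / "model.json").write_text(json.dumps(meta, indent=1))
        if self.marginal_support is not None:
            self.marginal_support.to_csv(path / "marginal_support.csv", index=False)

    @classmethod
    def load(cls, path) -> "FittedMortalityModel":
        path = Path(path)
        meta = json.loads((path / "model.json").read_text())
        if meta.get("schema") != 1:
            raise ValueError("unknown model bundle schema")
        arrays = np.load(path / "arrays.npz")
        smooths = []
        for i, sm in enumerate(meta["smooths"]):
            smooths.append(SmoothBlock(
                label=sm["label"], knots=arrays[f"smooth{i}_knots"],
                Z=arrays[f"smooth{i}_Z"], S=arrays[f"smooth{i}_S"],
                sl=slice(*sm["sl"]), points=arrays[f"smooth{i}_points"],
                domain=tuple(sm["domain"])))
        support = None
        if (path / "marginal_support.csv").exists():
            support = pd.read_csv(path / "marginal_support.csv")
        return cls(
            spec=ModelSpec(**meta["spec"]), col_names=meta["col_names"],
            beta=arrays["beta"], cov=arrays["cov"], theta=meta["theta"],
            lam=arrays["lam"], smooths=smooths,
            region_levels=meta["region_levels"], year_levels=meta["year_levels"],
            status_levels=meta["status_levels"], refs=meta["refs"],
            edf=meta["edf"], deviance=meta["deviance"], loglik=meta["loglik"],
            converged=meta["converged"], n_obs=meta["n_obs"],
            response=meta["response"],
            parametric_slices={k: slice(*v)
                               for k, v in meta["parametric_slices"].items()},
            marginal_support=support,
        )


def fit(design: Design, spec: ModelSpec | None = None) -> FittedMortalityModel:
    """Fit the penalised negative-binomial model.

    Outer loop: optimise the log smoothing parameters by the selected
    criterion (Nelder-Mead on the REML/GCV score), then update theta by
    profile likelihood; alternate until theta stabilises.
    """
    if spec is None:
        spec = ModelSpec()
    family = spec.response_family
    theta = spec.theta_init if family == "negbin" else np.inf
    n_s = len(design.smooths)
    rho = np.zeros(n_s)
    cache = {"beta": None}

    def fit_at(rho_vec, th):
        lam = np.exp(np.clip(rho_vec, -15.0, 18.0))
        res = _pirls(design, lam, th, family, beta0=cache["beta"],
                     max_iter=spec.max_iter, tol=spec.tol)
        cache["beta"] = res["beta"]
        return lam, res

    def score(rho_vec, th):
        lam, res = fit_at(rho_vec, th)
        if spec.smoothing_selection == "gcv":
            return _gcv_score(res, design)
        return _reml_score(res, design, lam)

    if spec.smoothing_selection == "fixed" or n_s == 0:
        rho = np.full(n_s, np.log(spec.fixed_lambda))
        lam, res = fit_at(rho, theta)
        if family == "negbin":
            theta = _update_theta(design.y, res["mu"], theta)
            lam, res = fit_at(rho, theta)
    elif spec.smoothing_selection == "gcv":
        for outer in range(spec.outer_iter):
            opt = optimize.minimize(
                score, rho, args=(theta,), method="Nelder-Mead",
                options={"xatol": 0.02, "fatol": 1e-4,
                         "maxfev": 120 * max(n_s, 1) + 60})
            rho = np.clip(opt.x, -15.0, 18.0)
            lam, res = fit_at(rho, theta)
            if family != "negbin":
                break
            theta_new = _update_theta(design.y, res["mu"], theta)
            done = abs(np.log(theta_new) - np.log(theta)) < 1e-3
            theta = theta_new
            lam, res = fit_at(rho, theta)
            if done:
                break
    else:
        # REML by extended Fellner-Schall updates: each iteration fits the
        # penalised model, then multiplies every smoothing parameter by
        # [rank_j/lambda_j - tr(A^-1 S_j)] / (beta' S_j beta), which ascends
        # the Laplace-approximate REML criterion.
        ranks = np.array([sm.rank for sm in design.smooths], dtype=float)
        lam, res = fit_at(rho, theta)
        for outer in range(40):
            A = res["H"] + res["S"]
            try:
                Ainv = linalg.inv(A)
            except np.linalg.LinAlgError:
                Ainv = linalg.inv(A + 1e-8 * np.eye(A.shape[0]) * np.trace(A) / A.shape[0])
            beta = res["beta"]
            rho_new = rho.copy()
            for j, sm in enumerate(design.smooths):
                num = ranks[j] / lam[j] - float(np.trace(Ainv[sm.sl, sm.sl] @ sm.S))
                den = float(beta[sm.sl] @ sm.S @ beta[sm.sl])
                if den <= 1e-12 or num <= 0:
                    factor = 10.0 if den <= 1e-12 else 0.1
                else:
                    factor = np.clip(num / den, 0.05, 20.0)
                rho_new[j] = np.clip(rho[j] + np.log(factor), -15.0, 18.0)
            step = np.max(np.abs(rho_new - rho))
            rho = rho_new
            lam, res = fit_at(rho, theta)
            theta_done = True
            if family == "negbin" and (outer % 3 == 2 or step < 1e-3):
                theta_new = _update_theta(design.y, res["mu"], theta)
                theta_done = abs(np.log(theta_new) - np.log(theta)) < 1e-3
                if not theta_done:
                    theta = theta_new
                    lam, res = fit_at(rho, theta)
            if step < 1e-3 and theta_done:
                break

    # tighten the final fit and assemble results
    res = _pirls(design, lam, theta, family, beta0=res["beta"],
                 max_iter=spec.max_iter, tol=min(spec.tol, 1e-10))
    A = res["H"] + res["S"]
    cov = linalg.inv(A)
    cov = 0.5 * (cov + cov.T)
    F = cov @ res["H"]
    edf = {sm.label: float(np.trace(F[sm.sl, sm.sl])) for sm in design.smooths}
    support = design.table[["birth_region", "year"]].drop_duplicates().reset_index(drop=True)
    return FittedMortalityModel(
        spec=spec, col_names=design.col_names, beta=res["beta"], cov=cov,
        theta=float(theta), lam=np.asarray(lam), smooths=design.smooths,
        region_levels=design.region_levels, year_levels=design.year_levels,
        status_levels=design.status_levels, refs=design.refs, edf=edf,
        deviance=res["deviance"], loglik=res["loglik"],
        converged=bool(res["converged"]), n_obs=design.y.size,
        response=design.response, parametric_slices=design.parametric_slices,
        marginal_support=support,
    )


def _update_theta(y, mu, theta0) -> float:
    def nll(log_t):
        return -_loglik(y, mu, np.exp(log_t), "negbin")
    res = optimize.minimize_scalar(nll, bounds=(-3.0, 16.0), method="bounded",
                                   options={"xatol": 1e-4})
    return float(np.exp(res.x))


def restrict_cause_ages(table: pd.DataFrame, cause: str,
                        min_share: float = 0.005, min_deaths: float = 1000.0,
                        age_range: tuple = (20, 95)) -> tuple:
    """Contiguous hull of age groups where the cause has enough deaths:
    at least ``min_share`` of the cause's deaths OR at least ``min_deaths``
    across all years; returned as a continuous age interval intersected
    with ``age_range``."""
    col = "D_" + cause if cause != "total" else "D_total"
    if col not in table.columns:
        raise ValueError(f"no deaths column for cause {cause!r}")
    by_age = table.groupby("age_mid")[col].sum()
    total = by_age.sum()
    if total <= 0:
        raise ValueError(f"no deaths at any age for cause {cause!r}")
    passing = by_age[(by_age / total >= min_share) | (by_age >= min_deaths)]
    if passing.empty:
        raise ValueError(f"no age group passes the threshold rule for cause {cause!r}")
    width = table.attrs.get("group_width", 3)
    lo = float(passing.index.min()) - width / 2.0
    hi = float(passing.index.max()) + width / 2.0
    return (max(lo, age_range[0]), min(hi, age_range[1]))
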