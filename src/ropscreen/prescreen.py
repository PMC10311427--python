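"""Prescreen treatment-risk model: a flexible-baseline proportional-hazard
model for time to ROP treatment, fitted by Poisson regression on split
person-time.

The hazard for infant *i* at postnatal week *t* is

    h_i(t) = exp( f(t) + x_i' beta )

with ``f`` a restricted cubic spline in ``t`` and ``x_i`` the birth/early
covariates: gestational age (weeks, centered), birth weight (per 100 g,
centered), sex, the three-level parenteral-nutrition-duration category, and
optionally interactions selected by AIC. Follow-up is censored at 20 weeks.
The fit maximizes the Poisson likelihood of per-interval event indicators
with a log-exposure offset — the standard piecewise-exponential device, with
the baseline evaluated at interval midpoints.

Treatment risk by a horizon ``T`` is ``p = 1 - exp(-H(T))`` where the
cumulative hazard ``H`` integrates the fitted hazard by composite Simpson
quadrature; the model also exposes the log-odds ``ln(p/(1-p))`` consumed by
the weekly screen models.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .cohort import BOY, InfantRecord, PND_GE14, PND_UNKNOWN_LABEL, categorize_pnd

__all__ = [
    "rcs_basis",
    "split_person_time",
    "records_to_covariates",
    "PrescreenHazardModel",
    "PrescreenFit",
    "fit_prescreen",
    "cumulative_hazard",
    "predict_risk",
    "HORIZON_WEEKS",
    "GA_CENTER",
    "BW_CENTER",
]

HORIZON_WEEKS = 20.0
GA_CENTER = 28.5   # weeks
BW_CENTER = 1172.0  # grams

#: covariate columns of the prescreen design (before interactions)
MAIN_TERMS = ("ga_c", "bw_100", "male", "pnd_ge14", "pnd_unknown")

#: named interaction candidates -> column products
INTERACTIONS = {
    "sex_pnd": (("male", "pnd_ge14"), ("male", "pnd_unknown")),
    "ga_pnd": (("ga_c", "pnd_ge14"), ("ga_c", "pnd_unknown")),
}


def rcs_basis(t, knots: Sequence[float]) -> np.ndarray:
    """Restricted cubic spline basis (linear tails beyond the outer knots).

    For ``K`` knots returns ``K-1`` columns: the identity plus ``K-2``
    truncated-cubic terms, normalized by the squared outer-knot span.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    k = np.asarray(sorted(knots), dtype=float)
    if len(k) < 3:
        raise ValueError("need at least 3 knots")
    norm = (k[-1] - k[0]) ** 2
    cols = [t]
    pos = lambda u: np.maximum(u, 0.0) ** 3
    for j in range(len(k) - 2):
        cj = (pos(t - k[j])
              - pos(t - k[-2]) * (k[-1] - k[j]) / (k[-1] - k[-2])
              + pos(t - k[-1]) * (k[-2] - k[j]) / (k[-1] - k[-2]))
        cols.append(cj / norm)
    return np.column_stack(cols)


def records_to_covariates(records: Iterable[InfantRecord]) -> pd.DataFrame:
    """Covariate frame (one row per infant) in model coding."""
    rows = []
    for r in records:
        cat = categorize_pnd(r)
        rows.append({
            "infant_id": r.infant_id,
            "ga_c": r.ga_weeks - GA_CENTER,
            "bw_100": (r.bw_g - BW_CENTER) / 100.0,
            "male": 1.0 if r.sex == BOY else 0.0,
            "pnd_ge14": 1.0 if cat == PND_GE14 else 0.0,
            "pnd_unknown": 1.0 if cat == PND_UNKNOWN_LABEL else 0.0,
        })
    return pd.DataFrame(rows)


def split_person_time(records: Iterable[InfantRecord],
                      interval_weeks: float = 1.0,
                      horizon: float = HORIZON_WEEKS) -> pd.DataFrame:
    """Split each infant's follow-up into person-time rows.

    Rows partition ``[0, min(event-or-censor time, horizon)]`` in intervals
    of at most ``interval_weeks``; the event flag sits on the final row iff
    the infant was treated within the horizon.
    """
    if interval_weeks <= 0:
        raise ValueError("interval_weeks must be positive")
    records = list(records)
    cov = records_to_covariates(records)
    rows = []
    for rec, (_, xrow) in zip(records, cov.iterrows()):
        if rec.treated and rec.treatment_pna_weeks is None:
            raise ValueError(f"{rec.infant_id}: treated without treatment time")
        stop = min(rec.followup_weeks, horizon)
        event = rec.treated and rec.treatment_pna_weeks is not None \
            and rec.treatment_pna_weeks <= horizon
        n_full = int(np.ceil(stop / interval_weeks - 1e-12))
        for i in range(max(n_full, 1)):
            t0 = i * interval_weeks
            t1 = min((i + 1) * interval_weeks, stop)
            rows.append({
                "infant_id": rec.infant_id,
                "t_start": t0, "t_stop": t1,
                "exposure": t1 - t0,
                "t_mid": 0.5 * (t0 + t1),
                "event": int(event and i == max(n_full, 1) - 1),
                **{c: xrow[c] for c in MAIN_TERMS},
            })
    return pd.DataFrame(rows)


@dataclass
class PrescreenFit:
    """Serializable fitted-parameter bundle of the prescreen model."""

    knots: list[float] | None
    coef: dict[str, float]
    cov: list[list[float]]
    coef_names: list[str]
    loglik: float
    aic: float
    converged: bool
    interactions: list[str]
    horizon: float = HORIZON_WEEKS
    baseline: str = "spline"
    main_terms: list[str] | None = None
    version: str = "1"

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(self.__dict__, indent=1)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, source: str | Path) -> "PrescreenFit":
        return cls(**json.loads(_read_maybe_path(source)))


def _interaction_columns(X: pd.DataFrame, names: Sequence[str]) -> pd.DataFrame:
    X = X.copy()
    for name in names:
        for a, b in INTERACTIONS[name]:
            X[f"{a}:{b}"] = X[a] * X[b]
    return X


class PrescreenHazardModel(BaseEstimator):
    """Proportional-hazard treatment-risk model with a spline baseline.

    Parameters
    ----------
    interval_weeks : float, default 1.0
        Person-time split granularity for fitting.
    n_knots : int, default 4
        Number of baseline-spline knots placed at event-time quantiles
        (ignored when ``knots`` is given).
    knots : sequence of float, optional
        Explicit knot locations in postnatal weeks.
    interaction_candidates : tuple of str
        Candidate interaction blocks (names in ``INTERACTIONS``); the subset
        minimizing AIC is kept. Pass ``()`` to fit main effects only.
    select_interactions : bool, default True
        If False, all candidates are included without AIC search.
    horizon : float, default 20.0
        Risk-integration horizon in postnatal weeks.

    Attributes
    ----------
    coef_ : ndarray — fitted coefficients (intercept, spline, covariates).
    coef_names_ : list of str
    cov_ : ndarray — coefficient covariance.
    knots_ : ndarray
    aic_, loglik_ : float
    selected_interactions_ : list of str
    converged_ : bool
    penalized_ : bool — True when a separation fallback was used.
    """

    def __init__(self, interval_weeks: float = 1.0, n_knots: int = 4,
                 knots: Sequence[float] | None = None,
                 interaction_candidates: tuple[str, ...] = ("sex_pnd", "ga_pnd"),
                 select_interactions: bool = True,
                 horizon: float = HORIZON_WEEKS,
                 baseline: str = "spline",
                 main_terms: tuple[str, ...] = MAIN_TERMS):
        self.interval_weeks = interval_weeks
        self.n_knots = n_knots
        self.knots = knots
        self.interaction_candidates = interaction_candidates
        self.select_interactions = select_interactions
        self.horizon = horizon
        self.baseline = baseline
        self.main_terms = main_terms

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y=None) -> "PrescreenHazardModel":
        """Fit from records or a pre-split person-time frame.

        ``X`` may be a list of :class:`InfantRecord` (then ``y`` is ignored)
        or a person-time DataFrame as produced by :func:`split_person_time`.
        """
        if isinstance(X, pd.DataFrame) and "exposure" in X.columns:
            pt = X
        else:
            pt = split_person_time(list(X), self.interval_weeks, self.horizon)
        if pt["event"].sum() < 1:
            raise ValueError("need at least one treatment event")
        if self.baseline not in ("spline", "constant"):
            raise ValueError("baseline must be 'spline' or 'constant'")
        if self.baseline == "constant":
            self.knots_ = None
        elif self.knots is not None:
            self.knots_ = np.asarray(sorted(self.knots), dtype=float)
        else:
            ev_t = pt.loc[pt["event"] == 1, "t_mid"].to_numpy()
            qs = np.linspace(0.05, 0.95, self.n_knots)
            kn = np.quantile(ev_t, qs)
            if len(np.unique(kn)) < len(kn):
                kn = kn + np.linspace(0, 1e-6, len(kn))
            self.knots_ = np.asarray(kn, dtype=float)

        candidates: list[tuple[str, ...]] = [()]
        if self.select_interactions:
            pool = list(self.interaction_candidates)
            for r in range(1, len(pool) + 1):
                candidates += [tuple(c) for c in combinations(pool, r)]
        else:
            candidates = [tuple(self.interaction_candidates)]

        best = None
        for cand in candidates:
            res = self._fit_one(pt, cand)
            if best is None or res["aic"] < best["aic"] - 1e-9:
                best = res
        self.coef_ = best["params"]
        self.coef_names_ = best["names"]
        self.cov_ = best["cov"]
        self.aic_ = best["aic"]
        self.loglik_ = best["loglik"]
        self.converged_ = best["converged"]
        self.penalized_ = best["penalized"]
        self.selected_interactions_ = list(best["cand"])
        self.n_params_ = len(self.coef_)
        return self

    def _design(self, t_mid: np.ndarray, X: pd.DataFrame,
                interactions: Sequence[str]) -> tuple[np.ndarray, list[str]]:
        t_mid = np.asarray(t_mid, dtype=float)
        if self.baseline == "constant":
            S = np.empty((len(t_mid), 0))
        else:
            S = rcs_basis(t_mid, self.knots_)
        Xi = _interaction_columns(X, interactions)
        cols = list(self.main_terms) + [f"{a}:{b}" for nm in interactions
                                        for a, b in INTERACTIONS[nm]]
        names = (["intercept"]
                 + [f"spline{j}" for j in range(S.shape[1])] + cols)
        D = np.column_stack([np.ones(len(S)), S] +
                            ([Xi[cols].to_numpy()] if cols else []))
        return D, names

    def _fit_one(self, pt: pd.DataFrame, cand: Sequence[str]) -> dict:
        D, names = self._design(pt["t_mid"].to_numpy(), pt, cand)
        if np.linalg.matrix_rank(D) < D.shape[1]:
            raise ValueError("design matrix is rank deficient")
        y = pt["event"].to_numpy()
        offset = np.log(pt["exposure"].to_numpy())
        penalized = False
        # warn on separation: a covariate level with all or no events
        for j, nm in enumerate(names):
            col = D[:, j]
            if set(np.unique(col)) <= {0.0, 1.0} and nm != "intercept":
                ev = y[col == 1]
                if len(ev) and (ev.sum() == 0 or ev.sum() == len(ev)):
                    warnings.warn(f"possible separation in {nm}; "
                                  "penalized fallback", RuntimeWarning,
                                  stacklevel=2)
                    penalized = True
        model = sm.GLM(y, D, family=sm.families.Poisson(), offset=offset)
        try:
            if penalized:
                raise RuntimeError("separation")
            res = model.fit(maxiter=200)
            if not res.converged:
                raise RuntimeError("Poisson GLM did not converge")
            params = np.asarray(res.params)
            cov = np.asarray(res.cov_params())
            llf, converged = float(res.llf), bool(res.converged)
        except RuntimeError:
            params = _ridge_poisson_irls(D, y, offset, alpha=1e-2)
            mu = np.exp(np.clip(D @ params + offset, -500, 30))
            cov = np.linalg.pinv((D * mu[:, None]).T @ D)
            # y is 0/1 so log(y!) = 0
            llf = float(np.sum(y * np.log(np.clip(mu, 1e-300, None)) - mu))
            converged, penalized = True, True
        k = len(params)
        return {"params": params, "cov": cov, "names": names,
                "loglik": llf, "aic": -2 * llf + 2 * k,
                "converged": converged, "penalized": penalized, "cand": cand}

    # -- prediction --------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "coef_"):
            raise RuntimeError("model is not fitted")

    def _covariate_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            if "ga_c" in X.columns:
                return X
            return records_to_covariates(frame_records(X))
        first = next(iter(X), None)
        if isinstance(first, InfantRecord):
            return records_to_covariates(list(X))
        raise TypeError("X must be InfantRecords or a covariate DataFrame")

    def linear_predictor(self, X) -> np.ndarray:
        """x'beta, the covariate part of the log hazard."""
        self._check_fitted()
        cov = self._covariate_frame(X)
        Xi = _interaction_columns(cov, self.selected_interactions_)
        cols = [n for n in self.coef_names_
                if not n.startswith("spline") and n != "intercept"]
        beta = {n: c for n, c in zip(self.coef_names_, self.coef_)}
        lp = np.zeros(len(Xi) if len(cols) else len(cov))
        for n in cols:
            lp += beta[n] * Xi[n].to_numpy()
        return lp

    def baseline_log_hazard(self, t) -> np.ndarray:
        """f(t) + intercept on a grid of postnatal weeks."""
        self._check_fitted()
        t = np.atleast_1d(np.asarray(t, dtype=float))
        beta = {n: c for n, c in zip(self.coef_names_, self.coef_)}
        g = np.full(len(t), beta["intercept"])
        if self.knots_ is not None:
            S = rcs_basis(t, self.knots_)
            for j in range(S.shape[1]):
                g += beta[f"spline{j}"] * S[:, j]
        return g

    def cumulative_hazard(self, X, t, grid_step: float = 0.1) -> np.ndarray:
        """H(t | x) by composite Simpson quadrature of the hazard.

        ``t`` may be a scalar or one value per row of ``X``; must lie in
        ``[0, horizon]``.
        """
        self._check_fitted()
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any((t_arr < 0) | (t_arr > self.horizon + 1e-9)):
            raise ValueError(f"t must be within [0, {self.horizon}]")
        lp = self.linear_predictor(X)
        if len(t_arr) == 1:
            # shared horizon: the baseline integral factors out
            H0 = _simpson_H(self.baseline_log_hazard, float(t_arr[0]),
                            grid_step)
            return H0 * np.exp(lp)
        out = np.empty(len(lp))
        for i, (ti, li) in enumerate(zip(t_arr, lp)):
            out[i] = _simpson_H(self.baseline_log_hazard, ti, grid_step) \
                * np.exp(li)
        return out

    def predict_risk(self, X, horizon: float | None = None) -> np.ndarray:
        """P(treated by horizon) = 1 - exp(-H(horizon))."""
        h = self.horizon if horizon is None else horizon
        cov = self._covariate_frame(X)
        return 1.0 - np.exp(-self.cumulative_hazard(cov, h))

    def predict_log_odds(self, X, horizon: float | None = None) -> np.ndarray:
        p = np.clip(self.predict_risk(X, horizon), 1e-12, 1 - 1e-12)
        return np.log(p / (1 - p))

    def predict_proba(self, X) -> np.ndarray:
        """scikit-learn-style (n, 2) probabilities [not treated, treated]."""
        p = self.predict_risk(X)
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_risk(X) >= 0.5).astype(int)

    def hazard_ratios(self, level: float = 0.95) -> pd.DataFrame:
        """Per-covariate estimate, SE, hazard ratio with CI, and p-value."""
        from scipy import stats as sps
        self._check_fitted()
        se = np.sqrt(np.diag(self.cov_))
        z = sps.norm.ppf(0.5 + level / 2)
        rows = []
        for n, b, s in zip(self.coef_names_, self.coef_, se):
            rows.append({"term": n, "estimate": b, "se": s,
                         "hr": np.exp(b), "hr_lo": np.exp(b - z * s),
                         "hr_hi": np.exp(b + z * s),
                         "p_value": 2 * sps.norm.sf(abs(b) / s) if s > 0 else np.nan})
        return pd.DataFrame(rows)

    # -- serialization -----------------------------------------------------

    def to_fit(self) -> PrescreenFit:
        self._check_fitted()
        return PrescreenFit(
            knots=(None if self.knots_ is None
                   else list(map(float, self.knots_))),
            coef={n: float(c) for n, c in zip(self.coef_names_, self.coef_)},
            cov=np.asarray(self.cov_).tolist(),
            coef_names=list(self.coef_names_),
            loglik=float(self.loglik_), aic=float(self.aic_),
            converged=bool(self.converged_),
            interactions=list(self.selected_interactions_),
            horizon=float(self.horizon), baseline=self.baseline,
            main_terms=list(self.main_terms))

    @classmethod
    def from_fit(cls, fit: PrescreenFit) -> "PrescreenHazardModel":
        m = cls(knots=fit.knots, horizon=fit.horizon,
                interaction_candidates=tuple(fit.interactions),
                select_interactions=False, baseline=fit.baseline,
                main_terms=tuple(fit.main_terms if fit.main_terms is not None
                                 else MAIN_TERMS))
        m.knots_ = (None if fit.knots is None
                    else np.asarray(fit.knots, dtype=float))
        m.coef_names_ = list(fit.coef_names)
        m.coef_ = np.asarray([fit.coef[n] for n in fit.coef_names], dtype=float)
        m.cov_ = np.asarray(fit.cov, dtype=float)
        m.aic_, m.loglik_ = fit.aic, fit.loglik
        m.converged_, m.penalized_ = fit.converged, False
        m.selected_interactions_ = list(fit.interactions)
        m.n_params_ = len(m.coef_)
        return m


def _simpson_H(log_hazard_fn, t: float, step: float) -> float:
    # composite Simpson of exp(log h0) on [0, t]
    if t <= 0:
        return 0.0
    n = max(2, int(np.ceil(t / step)))
    if n % 2 == 1:
        n += 1
    grid = np.linspace(0.0, t, n + 1)
    vals = np.exp(log_hazard_fn(grid))
    w = np.ones(n + 1)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    return float((t / n) / 3.0 * np.sum(w * vals))


def frame_records(df: pd.DataFrame) -> list[InfantRecord]:
    from .cohort import frame_to_records
    res = frame_to_records(df)
    if res.row_errors:
        raise ValueError(f"invalid rows: {res.row_errors[:3]}")
    return res.records


# -- thin functional wrappers ------------------------------------------------

def fit_prescreen(records_or_person_time, **kwargs) -> PrescreenHazardModel:
    """Fit the prescreen hazard model (wrapper over the estimator)."""
    return PrescreenHazardModel(**kwargs).fit(records_or_person_time)


def cumulative_hazard(fit: PrescreenHazardModel | PrescreenFit,
                      covariates, t) -> np.ndarray:
    model = (PrescreenHazardModel.from_fit(fit)
             if isinstance(fit, PrescreenFit) else fit)
    return model.cumulative_hazard(covariates, t)


def predict_risk(fit: PrescreenHazardModel | PrescreenFit, covariates,
                 horizon: float = HORIZON_WEEKS) -> np.ndarray:
    model = (PrescreenHazardModel.from_fit(fit)
             if isinstance(fit, PrescreenFit) else fit)
    return model.predict_risk(covariates, horizon)


def _read_maybe_path(source) -> str:
    """Accept a path or a JSON document string."""
    from pathlib import Path
    s = str(source)
    if "{" in s or "\n" in s:
        return s
    p = Path(s)
    if p.exists():
        return p.read_text()
    return s


def _ridge_poisson_irls(D: np.ndarray, y: np.ndarray, offset: np.ndarray,
                        alpha: float = 1e-2, maxiter: int = 200,
                        tol: float = 1e-8) -> np.ndarray:
    # L2-penalized Poisson Newton iterations; fallback under separation
    beta = np.zeros(D.shape[1])
    beta[0] = np.log(max(y.sum(), 0.5) / np.exp(offset).sum())
    pen = alpha * np.eye(D.shape[1])
    pen[0, 0] = 0.0
    for _ in range(maxiter):
        mu = np.exp(np.clip(D @ beta + offset, -500, 30))
        g = D.T @ (y - mu) - pen @ beta
        H = (D * mu[:, None]).T @ D + pen
        step = np.linalg.solve(H, g)
        # dampen large steps to keep the iteration stable
        nrm = np.max(np.abs(step))
        if nrm > 2.0:
            step *= 2.0 / nrm
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta
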