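"""Weekly screen models: one logistic regression per postnatal-age week
6-14, combining the prescreen risk log-odds with ROP-detection status.

At each week ``w`` an infant still under screening contributes one
observation with predictors:

* the prescreen model's risk log-odds (carrying GA, BW, sex and the PND
  category),
* a detection indicator: any ROP first diagnosed at postnatal age <= w,
* weeks since first detection, ``w - age_first_rop`` (0 for undetected), and
* optionally a detection x log-odds interaction, selected by AIC.

Infants treated strictly before week ``w`` are excluded from week-``w``
fitting — their outcome is already realized. The binary outcome is ROP
treatment by the follow-up horizon.
"""

from __future__ import annotations

import json
import warnings
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .cohort import InfantRecord

__all__ = ["SCREEN_WEEKS", "build_screen_observations", "WeeklyScreenModel",
           "fit_screen", "predict_screen"]

SCREEN_WEEKS = tuple(range(6, 15))

_PREDICTORS = ("prescreen_log_odds", "rop_detected", "weeks_since_detection")


def build_screen_observations(records: Iterable[InfantRecord],
                              prescreen_model,
                              weeks: Sequence[int] = SCREEN_WEEKS,
                              ) -> pd.DataFrame:
    """One row per infant per week at which the infant is still screened.

    Detection is closed at the examination week: first diagnosis at exactly
    ``w`` postnatal weeks counts as detected at week ``w``. An infant treated
    at time ``t`` contributes weeks ``w <= t`` only.
    """
    records = list(records)
    log_odds = prescreen_model.predict_log_odds(records)
    rows = []
    for rec, lo in zip(records, log_odds):
        t_trt = rec.treatment_pna_weeks if rec.treated else None
        dx = rec.first_rop_dx_pna_weeks
        for w in weeks:
            if t_trt is not None and t_trt < w:
                continue
            detected = dx is not None and dx <= w
            rows.append({
                "infant_id": rec.infant_id,
                "week": int(w),
                "prescreen_log_odds": float(lo),
                "rop_detected": float(detected),
                "weeks_since_detection": float(w - dx) if detected else 0.0,
                "outcome_treated": int(rec.treated),
            })
    return pd.DataFrame(rows)


class WeeklyScreenModel(BaseEstimator):
    """Per-week logistic treatment-risk models (weeks 6-14).

    Parameters
    ----------
    weeks : sequence of int
    interaction_candidates : tuple of str
        Products of predictor columns, written ``"a:b"``; the AIC-minimizing
        subset is kept per week.
    select_interactions : bool, default True

    Attributes
    ----------
    fits_ : dict week -> {"coef": dict, "cov": ndarray, "aic": float,
        "names": list, "auc": float, "penalized": bool}
    """

    def __init__(self, weeks: Sequence[int] = SCREEN_WEEKS,
                 interaction_candidates: tuple[str, ...] = (
                     "rop_detected:prescreen_log_odds",),
                 select_interactions: bool = True):
        self.weeks = weeks
        self.interaction_candidates = interaction_candidates
        self.select_interactions = select_interactions

    @staticmethod
    def _design(obs: pd.DataFrame, interactions: Sequence[str]
                ) -> tuple[np.ndarray, list[str]]:
        cols = list(_PREDICTORS)
        X = obs[cols].copy()
        for term in interactions:
            a, b = term.split(":")
            X[term] = obs[a] * obs[b]
            cols.append(term)
        D = np.column_stack([np.ones(len(X)), X[cols].to_numpy()])
        return D, ["intercept"] + cols

    def fit(self, X: pd.DataFrame, y=None) -> "WeeklyScreenModel":
        """Fit from an observation frame built by
        :func:`build_screen_observations`."""
        obs_all = X
        self.fits_ = {}
        for w in self.weeks:
            obs = obs_all[obs_all["week"] == w]
            ys = obs["outcome_treated"].to_numpy(dtype=float)
            if len(obs) == 0 or ys.sum() == 0 or ys.sum() == len(ys):
                raise ValueError(
                    f"week {w}: need both outcome classes to fit")
            candidates: list[tuple[str, ...]] = [()]
            if self.select_interactions:
                pool = list(self.interaction_candidates)
                for r in range(1, len(pool) + 1):
                    candidates += [tuple(c) for c in combinations(pool, r)]
            else:
                candidates = [tuple(self.interaction_candidates)]
            best = None
            for cand in candidates:
                res = self._fit_one(obs, ys, cand)
                if best is None or res["aic"] < best["aic"] - 1e-9:
                    best = res
            self.fits_[int(w)] = best
        return self

    def _fit_one(self, obs, ys, cand):
        D, names = self._design(obs, cand)
        penalized = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(ys, D).fit(disp=0, maxiter=200)
            if not np.all(np.isfinite(res.bse)):
                raise RuntimeError("non-finite SEs")
            params = np.asarray(res.params)
            cov = np.asarray(res.cov_params())
            llf = float(res.llf)
        except Exception:
            warnings.warn("separation in weekly logistic fit; "
                          "L2-penalized fallback", RuntimeWarning,
                          stacklevel=3)
            penalized = True
            params = _ridge_logit_irls(D, ys, alpha=1.0)
            p = 1 / (1 + np.exp(-(D @ params)))
            p = np.clip(p, 1e-12, 1 - 1e-12)
            llf = float(np.sum(ys * np.log(p) + (1 - ys) * np.log1p(-p)))
            W = p * (1 - p)
            cov = np.linalg.pinv((D * W[:, None]).T @ D)
        p = 1 / (1 + np.exp(-(D @ params)))
        from sklearn.metrics import roc_auc_score
        auc = float(roc_auc_score(ys, p)) if 0 < ys.sum() < len(ys) else np.nan
        return {"coef": {n: float(v) for n, v in zip(names, params)},
                "cov": cov, "names": names, "aic": -2 * llf + 2 * len(params),
                "auc": auc, "penalized": penalized, "cand": list(cand)}

    def predict_proba_frame(self, obs: pd.DataFrame) -> np.ndarray:
        """Treatment probability for each observation row, using the fit for
        that row's week."""
        if not hasattr(self, "fits_"):
            raise RuntimeError("model is not fitted")
        out = np.empty(len(obs))
        week_arr = obs["week"].to_numpy(dtype=int)
        for w in np.unique(week_arr):
            if int(w) not in self.fits_:
                raise KeyError(f"no fit for week {w}")
            fit = self.fits_[int(w)]
            m = week_arr == w
            sub = obs.loc[m]
            lp = np.full(m.sum(), fit["coef"]["intercept"])
            for name in fit["names"][1:]:
                if ":" in name:
                    a, b = name.split(":")
                    col = sub[a].to_numpy(float) * sub[b].to_numpy(float)
                else:
                    col = sub[name].to_numpy(float)
                lp += fit["coef"][name] * col
            out[m] = 1 / (1 + np.exp(-lp))
        return out

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        p = self.predict_proba_frame(X)
        return np.column_stack([1 - p, p])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba_frame(X) >= 0.5).astype(int)

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {"version": "1", "weeks": list(map(int, self.weeks)),
               "fits": {str(w): {"coef": f["coef"], "names": f["names"],
                                 "cov": np.asarray(f["cov"]).tolist(),
                                 "aic": f["aic"], "auc": f["auc"],
                                 "penalized": f["penalized"],
                                 "cand": f["cand"]}
                        for w, f in self.fits_.items()}}
        s = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, source: str | Path) -> "WeeklyScreenModel":
        doc = json.loads(_read_maybe_path(source))
        m = cls(weeks=tuple(doc["weeks"]))
        m.fits_ = {}
        for w, f in doc["fits"].items():
            m.fits_[int(w)] = {"coef": f["coef"], "names": f["names"],
                               "cov": np.asarray(f["cov"]), "aic": f["aic"],
                               "auc": f["auc"], "penalized": f["penalized"],
                               "cand": f["cand"]}
        return m


def fit_screen(observations: pd.DataFrame, **kwargs) -> WeeklyScreenModel:
    """Fit the weekly screen models (wrapper over the estimator)."""
    return WeeklyScreenModel(**kwargs).fit(observations)


def predict_screen(fits: WeeklyScreenModel, observation) -> np.ndarray:
    """Probability of treatment for observation row(s)."""
    obs = observation if isinstance(observation, pd.DataFrame) \
        else pd.DataFrame([observation])
    return fits.predict_proba_frame(obs)


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


def _ridge_logit_irls(D: np.ndarray, y: np.ndarray, alpha: float = 1.0,
                      maxiter: int = 100, tol: float = 1e-8) -> np.ndarray:
    # Newton iterations for L2-penalized logistic; the ridge keeps the
    # Hessian invertible under separation or collinearity
    beta = np.zeros(D.shape[1])
    pen = alpha * np.eye(D.shape[1])
    pen[0, 0] = 0.0  # intercept unpenalized
    for _ in range(maxiter):
        p = 1 / (1 + np.exp(-(D @ beta)))
        W = np.clip(p * (1 - p), 1e-10, None)
        g = D.T @ (y - p) - pen @ beta
        H = (D * W[:, None]).T @ D + pen
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta
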