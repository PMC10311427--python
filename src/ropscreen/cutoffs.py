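"""GA-stratified probability cutoffs enforcing 100% training sensitivity,
and the sequential discharge decision policy built on them.

For every (GA stratum, decision stage) cell the cutoff is the minimum risk
estimate among *treated* infants scored at that cell, minus a small epsilon;
a stratum with no treated infants inherits the pooled all-strata minimum.
Applying the table to its own training cohort therefore never discharges a
treated infant: training sensitivity is exactly 1 by construction.

Decision stages are ``prescreen`` (once the 14-day PND category is known,
postnatal day 14) followed by weekly decisions at postnatal weeks 6-14. An
infant is discharged at the first stage where its risk falls strictly below
the stage cutoff; discharged infants receive no later decisions, and an
infant already treated is never discharged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import InfantRecord
from .screen import SCREEN_WEEKS, build_screen_observations

__all__ = ["STAGES", "PRESCREEN_STAGE", "ga_stratum", "CutoffTable",
           "Decision", "SensitivityCutoffCalibrator", "calibrate_cutoffs",
           "score_stages", "apply_tool", "tool_metrics",
           "DEFAULT_GA_STRATA"]

PRESCREEN_STAGE = "prescreen"
STAGES = (PRESCREEN_STAGE,) + tuple(f"week{w}" for w in SCREEN_WEEKS)

#: decision time (postnatal weeks) of each stage; prescreen at day 14
STAGE_TIMES = {PRESCREEN_STAGE: 2.0,
               **{f"week{w}": float(w) for w in SCREEN_WEEKS}}

#: completed-GA-week strata: <=24, 25, ..., 30, >=31
DEFAULT_GA_STRATA = ("<=24", "25", "26", "27", "28", "29", "30", ">=31")


def ga_stratum(ga_weeks: float,
               strata: Sequence[str] = DEFAULT_GA_STRATA) -> str:
    """Map gestational age to its completed-week stratum label."""
    completed = int(np.floor(ga_weeks))
    lo = int(strata[0].lstrip("<="))
    hi = int(strata[-1].lstrip(">="))
    if completed <= lo:
        return strata[0]
    if completed >= hi:
        return strata[-1]
    return str(completed)


@dataclass
class CutoffTable:
    """Map (GA stratum, stage) -> probability cutoff with 100% training
    sensitivity guaranteed by construction."""

    entries: dict[tuple[str, str], float]
    ga_strata: tuple[str, ...] = DEFAULT_GA_STRATA
    epsilon: float = 1e-6
    version: str = ""

    def cutoff(self, stratum: str, stage: str) -> float:
        return self.entries[(stratum, stage)]

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {"version": self.version, "epsilon": self.epsilon,
               "ga_strata": list(self.ga_strata),
               "entries": [{"stratum": s, "stage": st, "cutoff": c}
                           for (s, st), c in sorted(self.entries.items())]}
        s = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, source: str | Path) -> "CutoffTable":
        doc = json.loads(_read_maybe_path(source))
        return cls(entries={(e["stratum"], e["stage"]): e["cutoff"]
                            for e in doc["entries"]},
                   ga_strata=tuple(doc["ga_strata"]),
                   epsilon=doc["epsilon"], version=doc.get("version", ""))


@dataclass(frozen=True)
class Decision:
    infant_id: str
    stage: str
    risk: float
    cutoff: float

    @property
    def action(self) -> str:
        return "discharge" if self.risk < self.cutoff else "continue_screening"


class SensitivityCutoffCalibrator:
    """Estimator-style wrapper: fit() learns the cutoff table from per-stage
    risks, transform()/predict() emit discharge decisions.

    Parameters
    ----------
    ga_strata : tuple of str
    epsilon : float, default 1e-6
        Safety margin subtracted from each minimum treated-infant risk so
        risk ties with a treated infant never discharge.
    """

    def __init__(self, ga_strata: tuple[str, ...] = DEFAULT_GA_STRATA,
                 epsilon: float = 1e-6, version: str = ""):
        self.ga_strata = ga_strata
        self.epsilon = epsilon
        self.version = version

    def get_params(self, deep=True):
        return {"ga_strata": self.ga_strata, "epsilon": self.epsilon,
                "version": self.version}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y=None) -> "SensitivityCutoffCalibrator":
        """Learn cutoffs from a long-format risk frame.

        ``X`` needs columns ``infant_id, stage, risk, ga_stratum, treated``
        (one row per infant per stage at which it was scored).
        """
        if len(X) == 0:
            raise ValueError("empty risk frame")
        if not np.all(np.isfinite(X["risk"])):
            raise ValueError("risks must be finite")
        entries: dict[tuple[str, str], float] = {}
        treated = X[X["treated"].astype(bool)]
        stages = [s for s in STAGES if s in set(X["stage"])]
        for stage in stages:
            ts = treated[treated["stage"] == stage]
            pooled_min = float(ts["risk"].min()) if len(ts) else 1.0
            for stratum in self.ga_strata:
                sub = ts[ts["ga_stratum"] == stratum]
                base = float(sub["risk"].min()) if len(sub) else pooled_min
                entries[(stratum, stage)] = max(base - self.epsilon, 0.0)
        self.table_ = CutoffTable(entries=entries,
                                  ga_strata=tuple(self.ga_strata),
                                  epsilon=self.epsilon, version=self.version)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Append cutoff and action columns to a risk frame."""
        if not hasattr(self, "table_"):
            raise RuntimeError("calibrator is not fitted")
        cut = np.array([self.table_.cutoff(s, st)
                        for s, st in zip(X["ga_stratum"], X["stage"])])
        out = X.copy()
        out["cutoff"] = cut
        out["action"] = np.where(out["risk"] < cut, "discharge",
                                 "continue_screening")
        return out

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """1 = discharge, 0 = continue, per risk-frame row."""
        return (self.transform(X)["action"] == "discharge").astype(int).to_numpy()


def calibrate_cutoffs(risks: pd.DataFrame,
                      ga_strata: tuple[str, ...] = DEFAULT_GA_STRATA,
                      epsilon: float = 1e-6,
                      version: str = "") -> CutoffTable:
    """Minimum-treated-risk cutoff calibration (wrapper over the
    calibrator estimator); see module docstring for the rule."""
    cal = SensitivityCutoffCalibrator(ga_strata=ga_strata, epsilon=epsilon,
                                      version=version)
    return cal.fit(risks).table_


def score_stages(records: Iterable[InfantRecord], prescreen_model,
                 screen_model,
                 ga_strata: tuple[str, ...] = DEFAULT_GA_STRATA,
                 ) -> pd.DataFrame:
    """Long-format per-infant per-stage risk frame.

    Prescreen risks are scored for every infant; weekly risks only for weeks
    at which the infant is still under screening (not yet treated).
    """
    records = list(records)
    risk_pre = prescreen_model.predict_risk(records)
    rows = []
    for rec, rp in zip(records, risk_pre):
        rows.append({"infant_id": rec.infant_id, "stage": PRESCREEN_STAGE,
                     "risk": float(rp), "ga_stratum": ga_stratum(rec.ga_weeks,
                                                                 ga_strata),
                     "treated": bool(rec.treated)})
    obs = build_screen_observations(records, prescreen_model)
    if len(obs):
        p = screen_model.predict_proba_frame(obs)
        meta = {r.infant_id: (ga_stratum(r.ga_weeks, ga_strata), r.treated)
                for r in records}
        for (_, row), pi in zip(obs.iterrows(), p):
            st, tr = meta[row["infant_id"]]
            rows.append({"infant_id": row["infant_id"],
                         "stage": f"week{int(row['week'])}",
                         "risk": float(pi), "ga_stratum": st, "treated": tr})
    return pd.DataFrame(rows)


def apply_tool(records: Iterable[InfantRecord], prescreen_model,
               screen_model, cutoff_table: CutoffTable,
               forbid_discharge_if_detected: bool = False,
               expected_version: str | None = None,
               ) -> tuple[pd.DataFrame, dict[str, str | None]]:
    """Run the sequential discharge policy over a cohort.

    Returns ``(decisions, discharge_stage)``: one decision row per infant
    per stage actually reached, and the stage at which each infant was
    discharged (``None`` if never). Treated infants stop receiving decisions
    at treatment and are never discharged at a stage after treatment.
    """
    if expected_version is not None and cutoff_table.version != expected_version:
        raise ValueError(
            f"cutoff table version {cutoff_table.version!r} does not match "
            f"fits version {expected_version!r}")
    records = list(records)
    risk_frame = score_stages(records, prescreen_model, screen_model,
                              cutoff_table.ga_strata)
    by_infant = {r.infant_id: r for r in records}
    risk_lookup = {(row["infant_id"], row["stage"]): row["risk"]
                   for _, row in risk_frame.iterrows()}
    decisions = []
    discharge_stage: dict[str, str | None] = {}
    for rec in records:
        discharge_stage[rec.infant_id] = None
        stratum = ga_stratum(rec.ga_weeks, cutoff_table.ga_strata)
        for stage in STAGES:
            t_stage = STAGE_TIMES[stage]
            if rec.treated and rec.treatment_pna_weeks is not None \
                    and rec.treatment_pna_weeks < t_stage:
                break  # outcome realized; no further decisions
            key = (rec.infant_id, stage)
            if key not in risk_lookup:
                continue
            risk = risk_lookup[key]
            cut = cutoff_table.cutoff(stratum, stage)
            if forbid_discharge_if_detected \
                    and rec.first_rop_dx_pna_weeks is not None \
                    and rec.first_rop_dx_pna_weeks <= t_stage:
                cut = 0.0  # detection bars discharge under this policy flag
            decisions.append({"infant_id": rec.infant_id, "stage": stage,
                              "risk": risk, "cutoff": cut,
                              "action": ("discharge" if risk < cut
                                         else "continue_screening")})
            if risk < cut:
                discharge_stage[rec.infant_id] = stage
                break
    return pd.DataFrame(decisions), discharge_stage


def tool_metrics(discharge_stage: dict[str, str | None],
                 treated_by_id: dict[str, bool]) -> dict:
    """Sensitivity, final specificity and cumulative specificity by stage.

    Sensitivity: treated infants never discharged / treated. Cumulative
    specificity at stage s: non-treated infants discharged at or before s /
    non-treated (nondecreasing in s by construction).
    """
    ids = list(treated_by_id)
    treated_ids = [i for i in ids if treated_by_id[i]]
    non_treated = [i for i in ids if not treated_by_id[i]]
    n_treated, n_non = len(treated_ids), len(non_treated)
    missed = [i for i in treated_ids if discharge_stage.get(i) is not None]
    sensitivity = (n_treated - len(missed)) / n_treated if n_treated else np.nan
    stage_index = {s: k for k, s in enumerate(STAGES)}
    cum = {}
    done = 0
    counts = {s: 0 for s in STAGES}
    for i in non_treated:
        s = discharge_stage.get(i)
        if s is not None:
            counts[s] += 1
    for s in STAGES:
        done += counts[s]
        cum[s] = done / n_non if n_non else np.nan
    specificity = cum[STAGES[-1]] if n_non else np.nan
    return {"sensitivity": sensitivity, "specificity": specificity,
            "cumulative_specificity": cum, "n_treated": n_treated,
            "n_non_treated": n_non,
            "n_treated_discharged": len(missed)}


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
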