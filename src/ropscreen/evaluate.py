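"""Model evaluation harness: end-to-end pipeline fitting, k-fold
cross-validation, temporal-split external validation, and calibration.

The "pipeline" is: fit the prescreen hazard model and the weekly screen
models on a training cohort, calibrate the 100%-sensitivity cutoff table on
that same cohort, then run the sequential discharge policy on an evaluation
cohort. Metrics (sensitivity, specificity, cumulative specificity, PPV,
NPV, accuracy, AUC) carry exact-binomial confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .cohort import InfantRecord
from .cutoffs import (DEFAULT_GA_STRATA, STAGES, SensitivityCutoffCalibrator,
                      apply_tool, ga_stratum, score_stages, tool_metrics)
from .prescreen import PrescreenHazardModel
from .screen import WeeklyScreenModel, build_screen_observations
from .stats import IntervalEstimate, clopper_pearson

__all__ = ["PipelineConfig", "MetricsReport", "fit_pipeline",
           "evaluate_pipeline", "cross_validate", "temporal_validate",
           "calibration_curve"]


@dataclass
class PipelineConfig:
    """Options threaded through the full model-build pipeline."""

    interval_weeks: float = 1.0
    n_knots: int = 4
    knots: Sequence[float] | None = None
    baseline: str = "spline"
    select_interactions: bool = True
    interaction_candidates: tuple[str, ...] = ("sex_pnd", "ga_pnd")
    ga_strata: tuple[str, ...] = DEFAULT_GA_STRATA
    epsilon: float = 1e-6
    k_folds: int = 10
    seed: int = 0


@dataclass
class MetricsReport:
    """Decision-level performance of the discharge tool on one cohort."""

    sensitivity: IntervalEstimate
    specificity: IntervalEstimate
    cumulative_specificity_by_stage: dict[str, float]
    ppv: IntervalEstimate
    npv: IntervalEstimate
    accuracy: IntervalEstimate
    auc: float
    n: int
    n_events: int
    discharge_fraction_by_stratum: dict[str, float] = field(
        default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            iv: IntervalEstimate = getattr(self, name)
            rows.append({"metric": name, "value": iv.point,
                         "lo": iv.lo, "hi": iv.hi})
        rows.append({"metric": "auc", "value": self.auc,
                     "lo": np.nan, "hi": np.nan})
        for s, v in self.cumulative_specificity_by_stage.items():
            rows.append({"metric": f"cum_specificity[{s}]", "value": v,
                         "lo": np.nan, "hi": np.nan})
        return pd.DataFrame(rows)


@dataclass
class FittedPipeline:
    prescreen: PrescreenHazardModel
    screen: WeeklyScreenModel
    calibrator: SensitivityCutoffCalibrator
    config: PipelineConfig


def fit_pipeline(records: Iterable[InfantRecord],
                 config: PipelineConfig | None = None) -> FittedPipeline:
    """Fit prescreen + screen models and calibrate cutoffs on one cohort."""
    config = config or PipelineConfig()
    records = list(records)
    pre = PrescreenHazardModel(
        interval_weeks=config.interval_weeks, n_knots=config.n_knots,
        knots=config.knots, baseline=config.baseline,
        interaction_candidates=config.interaction_candidates,
        select_interactions=config.select_interactions).fit(records)
    obs = build_screen_observations(records, pre)
    scr = WeeklyScreenModel(
        select_interactions=config.select_interactions).fit(obs)
    risk_frame = score_stages(records, pre, scr, config.ga_strata)
    cal = SensitivityCutoffCalibrator(
        ga_strata=config.ga_strata, epsilon=config.epsilon).fit(risk_frame)
    return FittedPipeline(prescreen=pre, screen=scr, calibrator=cal,
                          config=config)


def _metrics_from_decisions(records: list[InfantRecord],
                            discharge_stage: dict[str, str | None],
                            scores: np.ndarray,
                            ga_strata=DEFAULT_GA_STRATA) -> MetricsReport:
    treated = {r.infant_id: r.treated for r in records}
    base = tool_metrics(discharge_stage, treated)
    y = np.array([treated[r.infant_id] for r in records], dtype=int)
    kept = np.array([discharge_stage.get(r.infant_id) is None
                     for r in records], dtype=int)  # kept = called positive
    tp = int(((kept == 1) & (y == 1)).sum())
    fn = int(((kept == 0) & (y == 1)).sum())
    tn = int(((kept == 0) & (y == 0)).sum())
    fp = int(((kept == 1) & (y == 0)).sum())
    n = len(records)

    def cp(x, m):
        return clopper_pearson(x, m) if m > 0 else IntervalEstimate(
            np.nan, np.nan, np.nan)

    auc = (float(roc_auc_score(y, scores))
           if 0 < y.sum() < len(y) else np.nan)
    frac_by_stratum: dict[str, float] = {}
    for s in ga_strata:
        ids = [r.infant_id for r in records
               if ga_stratum(r.ga_weeks, ga_strata) == s]
        if ids:
            frac_by_stratum[s] = float(
                np.mean([discharge_stage.get(i) is not None for i in ids]))
    return MetricsReport(
        sensitivity=cp(tp, tp + fn),
        specificity=cp(tn, tn + fp),
        cumulative_specificity_by_stage=base["cumulative_specificity"],
        ppv=cp(tp, tp + fp),
        npv=cp(tn, tn + fn),
        accuracy=cp(tp + tn, n),
        auc=auc, n=n, n_events=int(y.sum()),
        discharge_fraction_by_stratum=frac_by_stratum)


def evaluate_pipeline(pipeline: FittedPipeline,
                      records: Iterable[InfantRecord]) -> MetricsReport:
    """Run the fitted tool on a cohort and compute the metrics report."""
    records = list(records)
    _, discharge_stage = apply_tool(records, pipeline.prescreen,
                                    pipeline.screen,
                                    pipeline.calibrator.table_)
    scores = pipeline.prescreen.predict_risk(records)
    return _metrics_from_decisions(records, discharge_stage, scores,
                                   pipeline.config.ga_strata)


def cross_validate(records: Iterable[InfantRecord],
                   config: PipelineConfig | None = None,
                   ) -> tuple[list[MetricsReport], MetricsReport]:
    """Stratified k-fold cross-validation of the full pipeline.

    Folds are stratified on the treatment outcome combined with a coarse GA
    bin; if that leaves any training fold without events, stratification
    falls back to the outcome alone. Returns (per-fold, pooled) reports.
    """
    config = config or PipelineConfig()
    records = list(records)
    y = np.array([r.treated for r in records], dtype=int)
    if config.k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    ga_bin = np.array([min(max(int(r.ga_weeks), 24, ), 31) for r in records])
    combo = y * 100 + ga_bin
    # require every fold's training part to contain events; fall back from
    # (outcome x GA)-stratified to outcome-stratified to plain shuffled folds
    from sklearn.model_selection import KFold
    folds = None
    for labels in (combo, y, None):
        if labels is None:
            kf = KFold(n_splits=config.k_folds, shuffle=True,
                       random_state=config.seed)
            cand = list(kf.split(np.zeros(len(y))))
        else:
            skf = StratifiedKFold(n_splits=config.k_folds, shuffle=True,
                                  random_state=config.seed)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cand = list(skf.split(np.zeros(len(y)), labels))
            except ValueError:
                continue
        if all(y[tr].sum() > 0 for tr, _ in cand):
            folds = cand
            break
    if folds is None:
        raise ValueError("could not form folds with events in every fold")
    per_fold: list[MetricsReport] = []
    pooled_discharge: dict[str, str | None] = {}
    pooled_scores: dict[str, float] = {}
    for tr_idx, te_idx in folds:
        train = [records[i] for i in tr_idx]
        test = [records[i] for i in te_idx]
        pipe = fit_pipeline(train, config)
        _, disch = apply_tool(test, pipe.prescreen, pipe.screen,
                              pipe.calibrator.table_)
        sc = pipe.prescreen.predict_risk(test)
        per_fold.append(_metrics_from_decisions(test, disch, sc,
                                                config.ga_strata))
        pooled_discharge.update(disch)
        pooled_scores.update({r.infant_id: s for r, s in zip(test, sc)})
    scores = np.array([pooled_scores[r.infant_id] for r in records])
    pooled = _metrics_from_decisions(records, pooled_discharge, scores,
                                     config.ga_strata)
    return per_fold, pooled


def temporal_validate(development: Iterable[InfantRecord],
                      validation: Iterable[InfantRecord],
                      config: PipelineConfig | None = None,
                      ) -> tuple[MetricsReport, MetricsReport]:
    """Fit on the development cohort only; report (development, validation)
    metrics. The validation cohort must be non-empty."""
    development, validation = list(development), list(validation)
    if not validation:
        raise ValueError("validation cohort is empty")
    dev_ids = {r.infant_id for r in development}
    if dev_ids & {r.infant_id for r in validation} and \
            dev_ids != {r.infant_id for r in validation}:
        raise ValueError("development and validation cohorts overlap")
    pipe = fit_pipeline(development, config)
    return (evaluate_pipeline(pipe, development),
            evaluate_pipeline(pipe, validation))


def calibration_curve(predicted, observed, n_bins: int = 10) -> pd.DataFrame:
    """Quantile-binned mean predicted vs observed event rate (plot-ready)."""
    p = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    if len(p) < n_bins:
        raise ValueError("need at least n_bins observations")
    edges = np.unique(np.quantile(p, np.linspace(0, 1, n_bins + 1)))
    if len(edges) < 2:
        # constant predictions: one effective bin
        return pd.DataFrame([{"bin": 0, "n": len(p),
                              "mean_predicted": float(p.mean()),
                              "observed_rate": float(y.mean())}])
    groups = np.clip(np.searchsorted(edges, p, side="right") - 1,
                     0, len(edges) - 2)
    rows = []
    for g in range(len(edges) - 1):
        m = groups == g
        if not m.any():
            continue
        rows.append({"bin": g, "n": int(m.sum()),
                     "mean_predicted": float(p[m].mean()),
                     "observed_rate": float(y[m].mean())})
    return pd.DataFrame(rows)
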