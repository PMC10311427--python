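"""Statistical primitives: odds ratios, score and exact intervals, ROC/Youden
cutoff search, calibration and paired tests.

All intervals default to the 95% level; tests are two-sided with no
multiplicity adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

__all__ = [
    "ContingencyTable2x2",
    "IntervalEstimate",
    "odds_ratio_2x2",
    "adjusted_or_logistic",
    "mn_risk_difference",
    "clopper_pearson",
    "roc_youden",
    "hosmer_lemeshow",
    "sign_test",
    "spearman",
    "table2_report",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Exposure x outcome counts.

    ``a``: exposed events, ``b``: exposed non-events, ``c``: unexposed
    events, ``d``: unexposed non-events.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a nonnegative integer")
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise ValueError("both exposure groups must be non-empty")


@dataclass(frozen=True)
class IntervalEstimate:
    point: float
    lo: float
    hi: float
    level: float = 0.95
    p_value: float | None = None

    def rounded(self, ndigits: int = 2) -> tuple[float, float, float]:
        return (round(self.point, ndigits), round(self.lo, ndigits),
                round(self.hi, ndigits))


def _as_table(table) -> ContingencyTable2x2:
    if isinstance(table, ContingencyTable2x2):
        return table
    a, b, c, d = table
    return ContingencyTable2x2(int(a), int(b), int(c), int(d))


def odds_ratio_2x2(table, level: float = 0.95,
                   continuity: float | None = None) -> IntervalEstimate:
    """Crude odds ratio with the Woolf (log-scale Wald) confidence interval.

    ``continuity`` (e.g. 0.5) is added to every cell when any cell is zero;
    without it a zero cell raises.
    """
    t = _as_table(table)
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if min(a, b, c, d) == 0:
        if continuity is None:
            raise ValueError("zero cell; pass a continuity correction")
        a, b, c, d = a + continuity, b + continuity, c + continuity, d + continuity
    log_or = np.log((a / b) / (c / d))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(0.5 + level / 2)
    p = 2 * sps.norm.sf(abs(log_or) / se)
    return IntervalEstimate(point=float(np.exp(log_or)),
                            lo=float(np.exp(log_or - z * se)),
                            hi=float(np.exp(log_or + z * se)),
                            level=level, p_value=float(p))


def adjusted_or_logistic(df: pd.DataFrame, outcome: str, exposure: str,
                         adjusters: tuple[str, ...] = ("ga_weeks", "bw_g", "sex"),
                         level: float = 0.95,
                         ) -> dict[str, IntervalEstimate | float]:
    """Covariate-adjusted odds ratios for a (possibly categorical) exposure.

    Fits a maximum-likelihood logistic model of ``outcome`` on the exposure
    plus adjusters and returns one Wald-interval odds ratio per non-reference
    exposure level (the first level in sorted order — or the level named
    ``lt14`` when present — is the reference), together with the model AUC
    under key ``"auc"``. Numeric exposures get a single per-unit OR under key
    ``"per_unit"``.

    Perfect separation triggers a warning and an L2-penalized fallback fit
    (no covariance-based CI shrinkage correction is attempted; the flag
    ``"penalized"`` is set in the result).
    """
    import statsmodels.api as sm

    y = np.asarray(df[outcome], dtype=float)
    X = pd.DataFrame(index=df.index)
    level_names: list[str] = []
    exp_col = df[exposure]
    if exp_col.dtype == object or isinstance(exp_col.dtype, pd.CategoricalDtype):
        levels = sorted(map(str, exp_col.unique()))
        if "lt14" in levels:
            levels = ["lt14"] + [l for l in levels if l != "lt14"]
        for lev in levels[1:]:
            name = f"{exposure}[{lev}]"
            X[name] = (exp_col.astype(str) == lev).astype(float)
            level_names.append(name)
    else:
        X[exposure] = np.asarray(exp_col, dtype=float)
        level_names.append(exposure)
    for adj in adjusters:
        col = df[adj]
        if col.dtype == object:
            cats = sorted(map(str, col.unique()))
            for lev in cats[1:]:
                X[f"{adj}[{lev}]"] = (col.astype(str) == lev).astype(float)
        else:
            X[adj] = np.asarray(col, dtype=float)
    X = sm.add_constant(X, has_constant="add")
    penalized = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0)
        if not np.all(np.isfinite(fit.bse)):
            raise np.linalg.LinAlgError("non-finite standard errors")
    except Exception:
        warnings.warn("separation or non-convergence; using L2-penalized fit",
                      RuntimeWarning, stacklevel=2)
        penalized = True
        fit = sm.Logit(y, X).fit_regularized(alpha=1.0, L1_wt=0.0, disp=0)
    z = sps.norm.ppf(0.5 + level / 2)
    result: dict[str, IntervalEstimate | float | bool] = {}
    params = np.asarray(fit.params, dtype=float)
    try:
        bse = np.asarray(fit.bse, dtype=float)
    except Exception:
        bse = np.full_like(params, np.nan)
    cols = list(X.columns)
    for name in level_names:
        i = cols.index(name)
        beta, se = params[i], bse[i]
        pv = 2 * sps.norm.sf(abs(beta) / se) if np.isfinite(se) and se > 0 else np.nan
        result[name] = IntervalEstimate(
            point=float(np.exp(beta)), lo=float(np.exp(beta - z * se)),
            hi=float(np.exp(beta + z * se)), level=level, p_value=float(pv))
    pred = 1.0 / (1.0 + np.exp(-np.asarray(X @ params, dtype=float)))
    result["auc"] = float(roc_auc_score(y, pred))
    result["penalized"] = penalized
    return result


def _mn_constrained_mle(p1_hat: float, p2_hat: float, n1: int, n2: int,
                        delta: float) -> tuple[float, float]:
    # closed-form restricted MLE of (p1, p2) under p1 - p2 = delta
    # (Farrington & Manning cubic solution)
    theta = n2 / n1
    x1, x2 = p1_hat * n1, p2_hat * n2
    a = 1 + theta
    b = -(1 + theta + p1_hat + theta * p2_hat + delta * (theta + 2))
    c = delta * delta + delta * (2 * p1_hat + theta + 1) + p1_hat + theta * p2_hat
    d = -p1_hat * delta * (1 + delta)
    v = b**3 / (27 * a**3) - b * c / (6 * a**2) + d / (2 * a)
    u = np.sign(v) * np.sqrt(max(b**2 / (9 * a**2) - c / (3 * a), 0.0))
    if u == 0:
        w = 0.0
    else:
        w = (np.pi + np.arccos(np.clip(v / u**3, -1, 1))) / 3
    p1t = 2 * u * np.cos(w) - b / (3 * a)
    p1t = min(max(p1t, delta if delta > 0 else 0.0), 1.0)
    p2t = min(max(p1t - delta, 0.0), 1.0)
    return p1t, p2t


def _mn_z(p1_hat, p2_hat, n1, n2, delta):
    p1t, p2t = _mn_constrained_mle(p1_hat, p2_hat, n1, n2, delta)
    var = (p1t * (1 - p1t) / n1 + p2t * (1 - p2t) / n2)
    var *= (n1 + n2) / (n1 + n2 - 1)
    if var <= 0:
        return np.inf if p1_hat - p2_hat - delta > 0 else -np.inf
    return (p1_hat - p2_hat - delta) / np.sqrt(var)


def mn_risk_difference(table, level: float = 0.95,
                       tol: float = 1e-8) -> IntervalEstimate:
    """Miettinen–Nurminen score interval for a difference of two proportions.

    The exposed-group risk is ``a/(a+b)`` and the unexposed ``c/(c+d)``; the
    limits invert the score statistic (with the N/(N-1) variance factor)
    by bisection to ``tol``.
    """
    t = _as_table(table)
    n1, n2 = t.a + t.b, t.c + t.d
    p1_hat, p2_hat = t.a / n1, t.c / n2
    point = p1_hat - p2_hat
    z_crit = sps.norm.ppf(0.5 + level / 2)

    def solve(lo: float, hi: float, target_sign: int) -> float:
        # find delta in (lo, hi) with z(delta) = target_sign * z_crit
        f = lambda d: _mn_z(p1_hat, p2_hat, n1, n2, d) - target_sign * z_crit
        flo, fhi = f(lo), f(hi)
        if flo * fhi > 0:
            return lo if target_sign > 0 else hi
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if f(lo) * f(mid) <= 0:
                hi = mid
            else:
                lo = mid
        return 0.5 * (lo + hi)

    lo = solve(-1 + 1e-12, point, +1)
    hi = solve(point, 1 - 1e-12, -1)
    return IntervalEstimate(point=float(point), lo=float(lo), hi=float(hi),
                            level=level)


def clopper_pearson(x: int, n: int, level: float = 0.95) -> IntervalEstimate:
    """Exact (Clopper–Pearson) binomial confidence interval.

    For ``x == n`` the lower limit is ``(alpha/2)**(1/n)`` and the upper is 1.
    """
    if not (0 <= x <= n) or n <= 0:
        raise ValueError("need 0 <= x <= n, n > 0")
    alpha = 1 - level
    lo = 0.0 if x == 0 else float(sps.beta.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(sps.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return IntervalEstimate(point=x / n, lo=lo, hi=hi, level=level)


def roc_youden(scores, outcomes, candidate_cutoffs) -> dict:
    """ROC AUC plus the Youden-optimal cutoff over a candidate set.

    A score is called positive when ``score >= cutoff``. The best cutoff
    maximizes J = sensitivity + specificity - 1; ties break toward the
    smaller cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=int)
    if len(np.unique(outcomes)) < 2:
        raise ValueError("both outcome classes must be present")
    auc = float(roc_auc_score(outcomes, scores))
    n_pos = outcomes.sum()
    n_neg = len(outcomes) - n_pos
    best = None
    rows = []
    for c in sorted(candidate_cutoffs):
        pred = scores >= c
        sens = float((pred & (outcomes == 1)).sum() / n_pos)
        spec = float((~pred & (outcomes == 0)).sum() / n_neg)
        j = sens + spec - 1
        rows.append({"cutoff": c, "sensitivity": sens,
                     "specificity": spec, "youden_j": j})
        if best is None or j > best["youden_j"] + 1e-12:
            best = rows[-1]
    return {"auc": auc, "best_cutoff": best["cutoff"],
            "youden_j": best["youden_j"], "table": pd.DataFrame(rows)}


def hosmer_lemeshow(predicted, observed, n_groups: int = 10,
                    df_reduction: int = 2) -> tuple[float, float]:
    """Hosmer–Lemeshow goodness-of-fit statistic and p-value.

    Groups by deciles (quantiles) of predicted risk; chi-square reference
    with ``n_groups - df_reduction`` degrees of freedom. Quantile ties can
    merge groups; a warning is issued and the degrees of freedom follow the
    realized group count.
    """
    p = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    if len(p) < n_groups:
        raise ValueError("need at least n_groups observations")
    qs = np.quantile(p, np.linspace(0, 1, n_groups + 1))
    edges = np.unique(qs)
    if len(edges) - 1 < n_groups:
        warnings.warn("tied predictions merged Hosmer-Lemeshow groups",
                      RuntimeWarning, stacklevel=2)
    groups = np.clip(np.searchsorted(edges, p, side="right") - 1,
                     0, len(edges) - 2)
    stat = 0.0
    g_used = 0
    for g in range(len(edges) - 1):
        m = groups == g
        n_g = m.sum()
        if n_g == 0:
            continue
        o, e = y[m].sum(), p[m].sum()
        pbar = e / n_g
        denom = e * (1 - pbar)
        if denom <= 0:
            continue
        stat += (o - e) ** 2 / denom
        g_used += 1
    dof = max(g_used - df_reduction, 1)
    return float(stat), float(sps.chi2.sf(stat, dof))


def sign_test(indicator_a, indicator_b) -> dict:
    """Exact two-sided sign test on paired binary indicators.

    Discordant pairs (a=1,b=0) vs (a=0,b=1) feed an exact binomial test
    against one half. With no discordant pairs the p-value is 1 (warned).
    """
    a = np.asarray(indicator_a, dtype=int)
    b = np.asarray(indicator_b, dtype=int)
    if a.shape != b.shape:
        raise ValueError("paired inputs must have the same length")
    n_a = int(((a == 1) & (b == 0)).sum())
    n_b = int(((a == 0) & (b == 1)).sum())
    n_disc = n_a + n_b
    if n_disc == 0:
        warnings.warn("no discordant pairs; sign test p = 1",
                      RuntimeWarning, stacklevel=2)
        return {"p_value": 1.0, "n_discordant": 0, "n_a_only": 0, "n_b_only": 0}
    p = float(sps.binomtest(n_a, n_disc, 0.5, alternative="two-sided").pvalue)
    return {"p_value": p, "n_discordant": n_disc,
            "n_a_only": n_a, "n_b_only": n_b}


def spearman(x, y) -> float:
    """Spearman rank correlation (midranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    return float(sps.spearmanr(x, y).statistic)


def table2_report(tables: dict[str, ContingencyTable2x2],
                  level: float = 0.95) -> pd.DataFrame:
    """Crude OR + risk-difference report, one row per named 2x2 table."""
    rows = []
    for name, t in tables.items():
        orr = odds_ratio_2x2(t, level=level)
        rd = mn_risk_difference(t, level=level)
        rows.append({
            "comparison": name,
            "events_exposed": t.a, "n_exposed": t.a + t.b,
            "events_unexposed": t.c, "n_unexposed": t.c + t.d,
            "or": round(orr.point, 2), "or_lo": round(orr.lo, 2),
            "or_hi": round(orr.hi, 2),
            "risk_diff_pct": round(100 * rd.point),
            "rd_lo_pct": round(100 * rd.lo), "rd_hi_pct": round(100 * rd.hi),
        })
    return pd.DataFrame(rows)
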