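"""Growth-rule screening criteria (G-ROP-style) and head-to-head tool
comparison.

The rule engine screens an infant when any criterion fires: gestational age
below a threshold, birth weight below a threshold, weight gain below a
window threshold in any of the postnatal-day windows 10-19, 20-29 and
30-39, or hydrocephalus — or when any datum needed by a criterion is
missing (missing data always defaults to screening). Weights at window
boundary days are linearly interpolated between the nearest flanking
measurements.

Threshold values ship as an editable configuration (the rule *structure* is
fixed; the numbers follow the published growth-rule criteria and their
"180 g" variant). Day 0 is the day of birth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .cohort import InfantRecord
from .stats import clopper_pearson, sign_test

__all__ = ["MISSING", "GropRuleSet", "interpolate_weight",
           "grop_screen_decision", "decide_cohort", "compare_tools",
           "GROP_BASE", "GROP_180G"]

#: sentinel for an unobtainable weight
MISSING = None

WINDOWS = ((10, 19), (20, 29), (30, 39))


@dataclass(frozen=True)
class GropRuleSet:
    """Thresholds of the growth-rule screening criteria.

    An infant needs screening when GA < ``ga_threshold_weeks``, BW <
    ``bw_threshold_g``, the weight gain over any window in ``WINDOWS`` is
    strictly below its threshold, hydrocephalus is present, or any needed
    datum is missing. Set ``strict_below=False`` to fire at-or-below
    instead.
    """

    ga_threshold_weeks: float = 28.0
    bw_threshold_g: float = 1051.0
    weight_gain_thresholds_g: tuple[float, float, float] = (120.0, 120.0, 120.0)
    hydrocephalus_rule: bool = True
    strict_below: bool = True
    variant_tag: str = "base"

    def __post_init__(self):
        if self.ga_threshold_weeks <= 0 or self.bw_threshold_g <= 0 \
                or any(t <= 0 for t in self.weight_gain_thresholds_g):
            raise ValueError("thresholds must be positive")

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(self.__dict__, indent=1)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, source: str | Path) -> "GropRuleSet":
        doc = json.loads(_read_maybe_path(source))
        doc["weight_gain_thresholds_g"] = tuple(doc["weight_gain_thresholds_g"])
        return cls(**doc)


GROP_BASE = GropRuleSet()
GROP_180G = GropRuleSet(weight_gain_thresholds_g=(180.0, 180.0, 180.0),
                        variant_tag="180g")


def interpolate_weight(weights_g_by_day: Mapping[int, float] | None,
                       day: int) -> float | None:
    """Weight at a postnatal day: measured value, else linear interpolation
    between the nearest flanking measurements, else ``MISSING``."""
    if day < 0:
        raise ValueError("day must be >= 0")
    if not weights_g_by_day:
        return MISSING
    if day in weights_g_by_day:
        return float(weights_g_by_day[day])
    days = sorted(weights_g_by_day)
    before = [d for d in days if d < day]
    after = [d for d in days if d > day]
    if not before or not after:
        return MISSING
    d0, d1 = before[-1], after[0]
    w0, w1 = weights_g_by_day[d0], weights_g_by_day[d1]
    return float(w0 + (w1 - w0) * (day - d0) / (d1 - d0))


def grop_screen_decision(record: InfantRecord,
                         rules: GropRuleSet = GROP_BASE) -> str:
    """``"screen"`` or ``"no_screen"`` for one infant under the rule set."""
    below = (lambda v, thr: v < thr) if rules.strict_below \
        else (lambda v, thr: v <= thr)
    if below(record.ga_weeks, rules.ga_threshold_weeks):
        return "screen"
    if below(record.bw_g, rules.bw_threshold_g):
        return "screen"
    if rules.hydrocephalus_rule:
        if record.hydrocephalus is None:
            return "screen"
        if record.hydrocephalus:
            return "screen"
    for (d0, d1), thr in zip(WINDOWS, rules.weight_gain_thresholds_g):
        w0 = interpolate_weight(record.weights_g_by_day, d0)
        w1 = interpolate_weight(record.weights_g_by_day, d1)
        if w0 is MISSING or w1 is MISSING:
            return "screen"
        if below(w1 - w0, thr):
            return "screen"
    return "no_screen"


def decide_cohort(records: Iterable[InfantRecord],
                  rules: GropRuleSet = GROP_BASE) -> pd.DataFrame:
    """Rule decisions for a cohort: columns infant_id, decision, discharged
    (a ``no_screen`` verdict releases the infant from screening)."""
    rows = []
    for r in records:
        d = grop_screen_decision(r, rules)
        rows.append({"infant_id": r.infant_id, "decision": d,
                     "discharged": d == "no_screen"})
    return pd.DataFrame(rows)


def compare_tools(treated_by_id: Mapping[str, bool],
                  discharged_a: Mapping[str, bool],
                  discharged_b: Mapping[str, bool],
                  name_a: str = "A", name_b: str = "B") -> dict:
    """Superiority comparison of two discharge decision sets.

    Sensitivity is compared first: a method that discharges (misses) any
    treated infant loses outright against a 100%-sensitive one. When both
    achieve 100% sensitivity, the exact sign test on per-infant discharge
    indicators among non-treated infants decides specificity superiority.
    """
    ids = set(treated_by_id)
    if set(discharged_a) != ids or set(discharged_b) != ids:
        raise ValueError("decision sets must cover the same infants")
    treated = [i for i in ids if treated_by_id[i]]
    non_treated = sorted(i for i in ids if not treated_by_id[i])
    miss_a = sum(discharged_a[i] for i in treated)
    miss_b = sum(discharged_b[i] for i in treated)
    sens_a = 1 - miss_a / len(treated) if treated else np.nan
    sens_b = 1 - miss_b / len(treated) if treated else np.nan
    spec_a = (np.mean([discharged_a[i] for i in non_treated])
              if non_treated else np.nan)
    spec_b = (np.mean([discharged_b[i] for i in non_treated])
              if non_treated else np.nan)
    out = {
        "sensitivity": {name_a: float(sens_a), name_b: float(sens_b)},
        "specificity": {name_a: float(spec_a), name_b: float(spec_b)},
        "sensitivity_ci": {
            name_a: clopper_pearson(len(treated) - miss_a, len(treated))
            if treated else None,
            name_b: clopper_pearson(len(treated) - miss_b, len(treated))
            if treated else None},
        "sign_test_p": None,
    }
    if miss_a > 0 and miss_b == 0:
        out["verdict"] = name_b
        out["reason"] = f"{name_a} missed {miss_a} treated infant(s)"
        return out
    if miss_b > 0 and miss_a == 0:
        out["verdict"] = name_a
        out["reason"] = f"{name_b} missed {miss_b} treated infant(s)"
        return out
    if miss_a > 0 and miss_b > 0:
        out["verdict"] = None
        out["reason"] = "both methods miss treated infants"
        return out
    a_ind = np.array([discharged_a[i] for i in non_treated], dtype=int)
    b_ind = np.array([discharged_b[i] for i in non_treated], dtype=int)
    st = sign_test(a_ind, b_ind)
    out["sign_test_p"] = st["p_value"]
    out["n_discordant"] = st["n_discordant"]
    if st["p_value"] < 0.05:
        out["verdict"] = name_a if st["n_a_only"] > st["n_b_only"] else name_b
        out["reason"] = ("specificity superiority by sign test "
                         f"(p={st['p_value']:.3g})")
    else:
        out["verdict"] = None
        out["reason"] = (f"no specificity superiority (p={st['p_value']:.3g})")
    return out


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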