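"""Cohort domain types, validation and CSV I/O.

This module is the single source of truth for the coding conventions used
throughout the package:

* ages (gestational age, postnatal age of diagnosis/treatment/last exam) are
  decimal **weeks**;
* parenteral nutrition duration (PND) is an integer number of **days**, with
  "unknown" a first-class category (``pnd_days=None``) that is never imputed;
* sex is coded ``girl`` / ``boy``, with girl as the indicator reference level;
* missing values in CSV files are empty cells; files are UTF-8, comma
  separated, header required.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "GIRL",
    "BOY",
    "PND_UNKNOWN_LABEL",
    "ROP_STAGES",
    "InfantRecord",
    "CohortSplit",
    "CohortReadResult",
    "RecordValidationError",
    "categorize_pnd",
    "validate_record",
    "records_to_frame",
    "frame_to_records",
    "read_cohort",
    "write_cohort",
    "DEFAULT_CENSOR_WEEKS",
]

GIRL = "girl"
BOY = "boy"

#: labels for the three-level PND category
PND_LT14 = "lt14"
PND_GE14 = "ge14"
PND_UNKNOWN_LABEL = "unknown"

#: maximum ROP stage coding; "none" means no ROP ever observed
ROP_STAGES = ("none", "1", "2", "3", "5")

#: follow-up horizon (weeks of postnatal age) used when a record carries no
#: explicit last-examination time; matches the risk-integration horizon.
DEFAULT_CENSOR_WEEKS = 20.0

GA_RANGE = (21.0, 40.0)
BW_RANGE = (250.0, 4000.0)


class RecordValidationError(ValueError):
    """A record violates one of the cohort invariants."""


@dataclass
class InfantRecord:
    """One ROP-screened infant.

    Parameters
    ----------
    infant_id : str
        Opaque identifier.
    ga_weeks : float
        Gestational age at birth, decimal weeks.
    sex : str
        ``"girl"`` or ``"boy"``.
    bw_g : float
        Birth weight in grams.
    pnd_days : int or None
        Days of parenteral protein+lipid supplementation; ``None`` = unknown.
    first_rop_dx_pna_weeks : float or None
        Postnatal age (weeks) at first diagnosis of any ROP; ``None`` if the
        infant never had ROP.
    max_rop_stage : str
        Maximum ROP stage reached, one of :data:`ROP_STAGES`.
    treated : bool
        Whether the infant received ROP treatment.
    treatment_pna_weeks : float or None
        Postnatal age (weeks) at first ROP treatment.
    last_exam_pna_weeks : float
        Censoring time (weeks); defaults to 20.
    bwsds : float or None
        Standardized birth-weight score, if available.
    weights_g_by_day : dict[int, float] or None
        Sparse postnatal-day -> grams map (growth-rule comparator use).
    hydrocephalus : bool or None
        Hydrocephalus flag (growth-rule comparator use).
    """

    infant_id: str
    ga_weeks: float
    sex: str
    bw_g: float
    pnd_days: int | None = None
    first_rop_dx_pna_weeks: float | None = None
    max_rop_stage: str = "none"
    treated: bool = False
    treatment_pna_weeks: float | None = None
    last_exam_pna_weeks: float = DEFAULT_CENSOR_WEEKS
    bwsds: float | None = None
    weights_g_by_day: dict[int, float] | None = None
    hydrocephalus: bool | None = None

    @property
    def pnd_category(self) -> str:
        return categorize_pnd(self)

    @property
    def followup_weeks(self) -> float:
        """Observed follow-up: treatment time if treated, else censor time."""
        if self.treated and self.treatment_pna_weeks is not None:
            return float(self.treatment_pna_weeks)
        return float(self.last_exam_pna_weeks)


def categorize_pnd(record_or_days: InfantRecord | int | None,
                   cutoff_days: int = 14) -> str:
    """Three-level PND category: below cutoff / at-or-above cutoff / unknown.

    The default cutoff of 14 days is the early dichotomization used by the
    risk models; unknown exposure is kept as its own level, never imputed.
    """
    if cutoff_days < 1:
        raise ValueError("cutoff_days must be >= 1")
    days = (record_or_days.pnd_days
            if isinstance(record_or_days, InfantRecord) else record_or_days)
    if days is None:
        return PND_UNKNOWN_LABEL
    if days < 0:
        raise RecordValidationError(f"negative pnd_days: {days}")
    return PND_GE14 if days >= cutoff_days else PND_LT14


def validate_record(rec: InfantRecord) -> list[str]:
    """Return a list of invariant violations (empty when valid)."""
    problems: list[str] = []
    if rec.sex not in (GIRL, BOY):
        problems.append(f"unknown sex code {rec.sex!r}")
    if not (GA_RANGE[0] <= rec.ga_weeks <= GA_RANGE[1]):
        problems.append(f"ga_weeks {rec.ga_weeks} outside {GA_RANGE}")
    if not (BW_RANGE[0] <= rec.bw_g <= BW_RANGE[1]):
        problems.append(f"bw_g {rec.bw_g} outside {BW_RANGE}")
    if rec.pnd_days is not None and rec.pnd_days < 0:
        problems.append(f"negative pnd_days {rec.pnd_days}")
    if rec.max_rop_stage not in ROP_STAGES:
        problems.append(f"unknown max_rop_stage {rec.max_rop_stage!r}")
    has_dx = rec.first_rop_dx_pna_weeks is not None
    if has_dx != (rec.max_rop_stage != "none"):
        problems.append(
            "first_rop_dx_pna_weeks must be present exactly when "
            "max_rop_stage is not 'none'")
    if rec.treated:
        if rec.treatment_pna_weeks is None:
            problems.append("treated infant lacks treatment_pna_weeks")
        elif (rec.first_rop_dx_pna_weeks is not None
              and rec.treatment_pna_weeks < rec.first_rop_dx_pna_weeks):
            problems.append("treatment precedes first ROP diagnosis")
    if rec.last_exam_pna_weeks <= 0:
        problems.append("last_exam_pna_weeks must be positive")
    return problems


@dataclass
class CohortSplit:
    """Development/validation partition of a cohort by a date-like rule."""

    development: set[str]
    validation: set[str]
    split_rule: str = ""

    def __post_init__(self) -> None:
        overlap = self.development & self.validation
        if overlap:
            raise ValueError(f"split not disjoint: {sorted(overlap)[:5]}")


@dataclass
class CohortReadResult:
    """Validated records plus row-level exclusion diagnostics."""

    records: list[InfantRecord]
    n_input_rows: int
    n_missing_bw: int = 0
    row_errors: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return self.n_missing_bw + len(self.row_errors)


# canonical column names; a schema config maps file columns onto these
_CANONICAL_COLUMNS = (
    "infant_id", "ga_weeks", "sex", "bw_g", "bwsds", "pnd_days",
    "first_rop_dx_pna_weeks", "max_rop_stage", "treated",
    "treatment_pna_weeks", "last_exam_pna_weeks", "hydrocephalus",
    "weights_g_by_day",
)
_MANDATORY = ("ga_weeks", "sex", "bw_g", "pnd_days", "treated")


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
        return None
    return float(v)


def _parse_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    s = str(v).strip().lower()
    if s in ("1", "true", "yes", "y"):
        return True
    if s in ("0", "false", "no", "n", ""):
        return False
    raise RecordValidationError(f"cannot parse boolean {v!r}")


def frame_to_records(df: pd.DataFrame) -> CohortReadResult:
    """Convert a canonical-column DataFrame into validated records.

    Rows with missing birth weight are dropped and counted (they cannot be
    scored by any model); rows violating invariants are rejected with a
    row-level diagnostic.
    """
    records: list[InfantRecord] = []
    row_errors: list[tuple[int, str]] = []
    n_missing_bw = 0
    for idx, row in df.iterrows():
        bw = _opt_float(row.get("bw_g"))
        if bw is None:
            n_missing_bw += 1
            continue
        try:
            pnd_raw = row.get("pnd_days")
            pnd = _opt_float(pnd_raw)
            if pnd is not None and pnd < 0:
                raise RecordValidationError(f"negative pnd_days {pnd}")
            stage_raw = row.get("max_rop_stage")
            if stage_raw is None or (isinstance(stage_raw, float)
                                     and pd.isna(stage_raw)) or stage_raw == "":
                stage = "none"
            elif isinstance(stage_raw, (int, float)):
                stage = str(int(stage_raw))
            else:
                stage = str(stage_raw).strip() or "none"
            weights = row.get("weights_g_by_day")
            wmap = None
            if isinstance(weights, str) and weights.strip():
                wmap = {int(k): float(v)
                        for k, v in json.loads(weights).items()}
            elif isinstance(weights, dict):
                wmap = {int(k): float(v) for k, v in weights.items()}
            hydro_raw = row.get("hydrocephalus")
            hydro = (None if hydro_raw is None
                     or (isinstance(hydro_raw, float) and pd.isna(hydro_raw))
                     or hydro_raw == "" else _parse_bool(hydro_raw))
            last_exam = _opt_float(row.get("last_exam_pna_weeks"))
            rec = InfantRecord(
                infant_id=str(row.get("infant_id", idx)),
                ga_weeks=float(row["ga_weeks"]),
                sex=str(row["sex"]).strip().lower(),
                bw_g=bw,
                bwsds=_opt_float(row.get("bwsds")),
                pnd_days=None if pnd is None else int(round(pnd)),
                first_rop_dx_pna_weeks=_opt_float(
                    row.get("first_rop_dx_pna_weeks")),
                max_rop_stage=stage,
                treated=_parse_bool(row.get("treated")),
                treatment_pna_weeks=_opt_float(row.get("treatment_pna_weeks")),
                last_exam_pna_weeks=(DEFAULT_CENSOR_WEEKS if last_exam is None
                                     else last_exam),
                weights_g_by_day=wmap,
                hydrocephalus=hydro,
            )
            problems = validate_record(rec)
            if problems:
                raise RecordValidationError("; ".join(problems))
        except (RecordValidationError, ValueError, KeyError) as exc:
            row_errors.append((int(idx), str(exc)))
            continue
        records.append(rec)
    return CohortReadResult(records=records, n_input_rows=len(df),
                            n_missing_bw=n_missing_bw, row_errors=row_errors)


def records_to_frame(records: Iterable[InfantRecord]) -> pd.DataFrame:
    """Serialize records into the canonical-column DataFrame."""
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        d["weights_g_by_day"] = (
            json.dumps(r.weights_g_by_day) if r.weights_g_by_day else "")
        rows.append(d)
    df = pd.DataFrame(rows, columns=list(_CANONICAL_COLUMNS))
    return df


def read_cohort(path: str | Path,
                schema_config: Mapping[str, str] | str | Path | None = None,
                ) -> CohortReadResult:
    """Read a cohort CSV into validated :class:`InfantRecord` objects.

    Parameters
    ----------
    path : path
        CSV file, UTF-8, comma separated, header required.
    schema_config : mapping or path, optional
        Maps *file* column names onto canonical names (e.g.
        ``{"gestational_age": "ga_weeks"}``), given directly or as a JSON
        file. Mandatory columns (ga, sex, bw, pnd, treated) must resolve.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if isinstance(schema_config, (str, Path)):
        schema_config = json.loads(Path(schema_config).read_text())
    df = pd.read_csv(path, dtype={"infant_id": str})
    if schema_config:
        df = df.rename(columns=dict(schema_config))
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"mandatory columns not resolvable: {missing}")
    return frame_to_records(df)


def write_cohort(records: Iterable[InfantRecord], path: str | Path) -> None:
    """Write records as a cohort CSV; lossless round-trip with read_cohort.

    Unknown PND and other optional fields serialize as empty cells.
    """
    df = records_to_frame(records)
    df.to_csv(path, index=False)
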