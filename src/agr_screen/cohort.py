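"""Patient-level cohort model and CSV persistence.

One row per arthroplasty patient with a ground-truth infection label
(periprosthetic joint infection vs aseptic failure, assigned by the 2018
ICM consensus criteria upstream of this package), the serum
albumin-to-globulin ratio (AGR) that the diagnostic work-up evaluates,
and the demographic / laboratory covariates used in group comparisons
and the false-positive confounder analysis.

Everything downstream (ROC analysis, cutoff optimization, diagnostic
metrics, group statistics) consumes :class:`Cohort`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

__all__ = [
    "PatientRecord",
    "Cohort",
    "Violation",
    "ConfigurationError",
    "CohortValidationError",
    "RowParseError",
    "read_cohort_csv",
    "write_cohort_csv",
    "validate_cohort",
    "OPTIONAL_FLOAT_FIELDS",
    "CSV_COLUMNS",
]


class ConfigurationError(Exception):
    """A required column or configuration item is missing or malformed."""


class CohortValidationError(Exception):
    """The cohort violates a structural invariant (e.g. duplicate ids)."""


class RowParseError(Exception):
    """A data row could not be parsed; carries the offending row index."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class PatientRecord(BaseModel):
    """One patient.

    ``infected`` is the ground-truth label (1 = periprosthetic joint
    infection, 0 = aseptic failure); ``agr`` is the serum
    albumin-to-globulin ratio, the index test. All laboratory fields
    other than ``agr`` are optional; missing values stay ``None`` and
    each downstream statistic drops the records it cannot use
    (complete-case analysis).

    Units follow routine clinical chemistry reporting: albumin and
    globulin in g/dL, ESR in mm/h, CRP in mg/L, synovial WBC in
    cells/µL, synovial PMN in percent, creatinine and uremia (blood
    urea) in mg/dL, GOT/GPT/ALP in U/L. The source data do not embed
    units, so they are documented here rather than verified.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    patient_id: str
    infected: int
    agr: float
    albumin: Optional[float] = None
    globulin: Optional[float] = None
    age: Optional[float] = None
    sex: Optional[Literal["male", "female"]] = None
    bmi: Optional[float] = None
    cci: Optional[int] = None
    esr: Optional[float] = None
    crp: Optional[float] = None
    sf_wbc: Optional[float] = None
    sf_pmn: Optional[float] = None
    inr: Optional[float] = None
    creatinine: Optional[float] = None
    uremia: Optional[float] = None
    got: Optional[float] = None
    gpt: Optional[float] = None
    alp: Optional[float] = None


#: canonical CSV column order
CSV_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "infected",
    "agr",
    "albumin",
    "globulin",
    "age",
    "sex",
    "bmi",
    "cci",
    "esr",
    "crp",
    "sf_wbc",
    "sf_pmn",
    "inr",
    "creatinine",
    "uremia",
    "got",
    "gpt",
    "alp",
)

REQUIRED_COLUMNS: tuple[str, ...] = ("patient_id", "infected", "agr")

OPTIONAL_FLOAT_FIELDS: tuple[str, ...] = (
    "albumin",
    "globulin",
    "age",
    "bmi",
    "esr",
    "crp",
    "sf_wbc",
    "sf_pmn",
    "inr",
    "creatinine",
    "uremia",
    "got",
    "gpt",
    "alp",
)

#: fields that must be non-negative when present
_NONNEGATIVE_FIELDS: tuple[str, ...] = (
    "albumin",
    "globulin",
    "age",
    "bmi",
    "esr",
    "crp",
    "sf_wbc",
    "inr",
    "creatinine",
    "uremia",
    "got",
    "gpt",
    "alp",
)


@dataclass
class Cohort:
    """Ordered collection of :class:`PatientRecord`.

    ``provenance`` records whether the cohort was observed (loaded from
    a file) or synthetic (drawn by :mod:`agr_screen.synthetic`); ``seed``
    is kept for synthetic cohorts so a report can cite it.
    """

    records: list[PatientRecord] = field(default_factory=list)
    provenance: Literal["observed", "synthetic"] = "observed"
    seed: Optional[int] = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def n_infected(self) -> int:
        return sum(r.infected == 1 for r in self.records)

    @property
    def n_aseptic(self) -> int:
        return sum(r.infected == 0 for r in self.records)

    def agr_values(self) -> np.ndarray:
        return np.array([r.agr for r in self.records], dtype=float)

    def labels(self) -> np.ndarray:
        return np.array([r.infected for r in self.records], dtype=int)

    def values(self, field_name: str) -> np.ndarray:
        """Column as a float array with NaN for missing (sex is 1=male)."""
        if field_name == "sex":
            return np.array(
                [
                    np.nan if r.sex is None else float(r.sex == "male")
                    for r in self.records
                ]
            )
        return np.array(
            [
                np.nan if getattr(r, field_name) is None else float(getattr(r, field_name))
                for r in self.records
            ]
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = [r.model_dump() for r in self.records]
        df = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
        return df

    def subset(self, mask: Sequence[bool]) -> "Cohort":
        recs = [r for r, keep in zip(self.records, mask) if keep]
        return Cohort(records=recs, provenance=self.provenance, seed=self.seed)


@dataclass(frozen=True)
class Violation:
    """One invariant violation, as data rather than an exception."""

    patient_id: str
    field: str
    rule: str


def _parse_optional_float(value, row: int, column: str) -> Optional[float]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise RowParseError(row, f"non-numeric value {value!r} in column {column}") from exc


def read_cohort_csv(
    path: str | Path,
    column_map: Optional[Mapping[str, str]] = None,
) -> Cohort:
    """Read a cohort from a comma-delimited UTF-8 CSV with a header row.

    Parameters
    ----------
    path
        CSV file; must contain (possibly renamed) ``patient_id``,
        ``infected`` and ``agr`` columns.
    column_map
        Optional mapping from canonical field names to the names used in
        the file, e.g. ``{"agr": "alb_glob_ratio"}``.

    Raises
    ------
    ConfigurationError
        A required column cannot be resolved.
    RowParseError
        A cell that must be numeric is not; names the row index.
    CohortValidationError
        Duplicate patient ids.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"cohort file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    column_map = dict(column_map or {})
    rename = {v: k for k, v in column_map.items()}
    df = df.rename(columns=rename)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ConfigurationError(f"required column missing: {col!r}")

    records: list[PatientRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.to_dict("records")):
        pid = str(row["patient_id"])
        if pid in seen:
            raise CohortValidationError(f"duplicate patient_id: {pid!r}")
        seen.add(pid)
        try:
            infected = int(float(row["infected"]))
        except (TypeError, ValueError) as exc:
            raise RowParseError(i, f"non-numeric infected label {row['infected']!r}") from exc
        agr = _parse_optional_float(row["agr"], i, "agr")
        if agr is None:
            raise RowParseError(i, "missing AGR value")
        kwargs: dict = {"patient_id": pid, "infected": infected, "agr": agr}
        if "sex" in df.columns and row.get("sex", "") != "":
            kwargs["sex"] = str(row["sex"]).strip().lower()
        if "cci" in df.columns:
            cci = _parse_optional_float(row.get("cci", ""), i, "cci")
            if cci is not None:
                kwargs["cci"] = int(round(cci))
        for col in OPTIONAL_FLOAT_FIELDS:
            if col in df.columns:
                val = _parse_optional_float(row.get(col, ""), i, col)
                if val is not None:
                    kwargs[col] = val
        records.append(PatientRecord(**kwargs))
    return Cohort(records=records, provenance="observed")


def write_cohort_csv(cohort: Cohort, path: str | Path) -> None:
    """Write ``cohort`` to CSV; round-trips through :func:`read_cohort_csv`.

    Floats are formatted with :%.10g so values survive the round trip to
    well beyond 6 significant digits; missing optionals become empty cells.
    """
    path = Path(path)
    df = cohort.to_dataframe()
    df.to_csv(path, index=False, float_format="%.10g")


def validate_cohort(cohort: Cohort) -> list[Violation]:
    """Check every record against the data-model invariants.

    Returns an empty list iff the cohort is clean. Violations are data:
    each names the patient, the field and the broken rule. Idempotent and
    side-effect free.
    """
    out: list[Violation] = []
    seen: set[str] = set()
    for r in cohort.records:
        if r.patient_id in seen:
            out.append(Violation(r.patient_id, "patient_id", "patient_id values unique"))
        seen.add(r.patient_id)
        if r.infected not in (0, 1):
            out.append(Violation(r.patient_id, "infected", "infected in {0, 1}"))
        if not (r.agr > 0):
            out.append(Violation(r.patient_id, "agr", "agr > 0"))
        if r.albumin is not None and r.globulin is not None and r.globulin > 0:
            if abs(r.agr - r.albumin / r.globulin) > 0.01:
                out.append(
                    Violation(r.patient_id, "agr", "|agr - albumin/globulin| <= 0.01")
                )
        if r.sf_pmn is not None and not (0 <= r.sf_pmn <= 100):
            out.append(Violation(r.patient_id, "sf_pmn", "sf_pmn in [0, 100]"))
        if r.cci is not None and r.cci < 0:
            out.append(Violation(r.patient_id, "cci", "cci >= 0"))
        for name in _NONNEGATIVE_FIELDS:
            val = getattr(r, name)
            if val is not None and val < 0:
                out.append(Violation(r.patient_id, name, f"{name} >= 0"))
    return out
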