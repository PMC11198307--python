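"""Data model and CSV round trip for randomized pairwise comparisons.

The unit of analysis is one randomized comparison (intervention arm vs
control arm) of an antithrombotic strategy in coronary artery disease.
A multi-arm trial contributes several comparisons sharing a ``trial_id``.
Each comparison carries arm sizes, per-endpoint event counts (major
bleeding, major/minor bleeding, all-cause death, cardiovascular death),
and the stratification attributes used by the subgroup analyses
(enrollment era, follow-up duration, region, ACS population, bleeding
definition labels).

Missing event counts are encoded as empty CSV cells and stay
distinguishable from zero: a comparison simply drops out of analyses
whose endpoint it lacks.
"""

from __future__ import annotations

import enum
import io
import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import pandas as pd

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Endpoint",
    "Region",
    "MajorMinorDefinition",
    "MajorDefinition",
    "TrialComparison",
    "load_comparisons",
    "write_comparisons",
    "filter_eligible",
    "validate_records",
    "CSV_COLUMNS",
]


class Endpoint(str, enum.Enum):
    """Outcome endpoints extracted per comparison."""

    BLEED_MAJOR = "bleed_major"
    BLEED_MAJOR_MINOR = "bleed_major_minor"
    DEATH_ALL = "death_all"
    DEATH_CV = "death_cv"


class Region(str, enum.Enum):
    EAST_ASIA = "east_asia"
    NON_EAST_ASIA = "non_east_asia"


class MajorMinorDefinition(str, enum.Enum):
    """Label of the trial's major-or-minor bleeding definition."""

    BARC_235 = "barc_235"
    BARC_2345 = "barc_2345"
    TIMI_MAJOR_MINOR = "timi_major_minor"
    OTHER = "other"
    NONE = "none"


class MajorDefinition(str, enum.Enum):
    """Label of the trial's major bleeding definition."""

    BARC_35 = "barc_35"
    BARC_345 = "barc_345"
    TIMI_MAJOR = "timi_major"
    GUSTO_MOD_SEVERE = "gusto_mod_severe"
    OTHER = "other"
    NONE = "none"


#: Column order of the canonical comparison-level CSV (UTF-8, one header row).
CSV_COLUMNS = [
    "trial_id",
    "comparison_id",
    "first_enrollment_year",
    "follow_up_months",
    "region",
    "acs_population",
    "major_minor_definition",
    "major_definition",
    "n_treat",
    "n_control",
    "bleed_major_treat",
    "bleed_major_control",
    "bleed_major_minor_treat",
    "bleed_major_minor_control",
    "death_all_treat",
    "death_all_control",
    "death_cv_treat",
    "death_cv_control",
    "reported_or",
    "reported_or_lo",
    "reported_or_hi",
    "reported_hr",
    "reported_hr_lo",
    "reported_hr_hi",
]

YEAR_RANGE = (1990, 2025)
DEFAULT_MIN_TOTAL = 500


@dataclass
class TrialComparison:
    """One randomized pairwise comparison; the unit of analysis.

    ``events`` maps an :class:`Endpoint` to ``(treat_events,
    control_events)``; an endpoint absent from the map was not reported
    by the trial.
    """

    trial_id: str
    comparison_id: str
    first_enrollment_year: int
    follow_up_months: float
    region: Region
    acs_population: bool
    major_minor_definition: MajorMinorDefinition
    major_definition: MajorDefinition
    n_treat: int
    n_control: int
    events: dict = field(default_factory=dict)
    reported_or: Optional[float] = None
    reported_or_ci: Optional[tuple] = None
    reported_hr: Optional[float] = None
    reported_hr_ci: Optional[tuple] = None

    @property
    def n_total(self) -> int:
        return self.n_treat + self.n_control

    def has_endpoint(self, endpoint: Endpoint) -> bool:
        return endpoint in self.events

    def validate(self) -> None:
        """Raise :class:`ValidationError` on any invariant violation."""
        cid = self.comparison_id
        if self.n_treat <= 0 or self.n_control <= 0:
            raise ValidationError(f"{cid}: arm sizes must be positive")
        if self.follow_up_months <= 0:
            raise ValidationError(f"{cid}: follow_up_months must be > 0")
        if not YEAR_RANGE[0] <= self.first_enrollment_year <= YEAR_RANGE[1]:
            raise ValidationError(
                f"{cid}: first_enrollment_year {self.first_enrollment_year} "
                f"outside {YEAR_RANGE}"
            )
        for endpoint, (t, c) in self.events.items():
            endpoint = Endpoint(endpoint)
            if t < 0 or c < 0:
                raise ValidationError(f"{cid}: negative event count for {endpoint.value}")
            if t > self.n_treat:
                raise ValidationError(
                    f"{cid}: {endpoint.value} treat_events {t} exceeds n_treat {self.n_treat}"
                )
            if c > self.n_control:
                raise ValidationError(
                    f"{cid}: {endpoint.value} control_events {c} exceeds "
                    f"n_control {self.n_control}"
                )
        for label, value, ci in (
            ("reported_or", self.reported_or, self.reported_or_ci),
            ("reported_hr", self.reported_hr, self.reported_hr_ci),
        ):
            if value is not None and value <= 0:
                raise ValidationError(f"{cid}: {label} must be positive")
            if ci is not None:
                if value is None:
                    raise ValidationError(f"{cid}: {label} CI given without point estimate")
                lo, hi = ci
                if not (0 < lo <= value <= hi):
                    raise ValidationError(f"{cid}: {label} CI ({lo}, {hi}) inconsistent")


def validate_records(records: list) -> None:
    """Validate every record and the cross-record uniqueness invariant."""
    seen = set()
    for rec in records:
        rec.validate()
        if rec.comparison_id in seen:
            raise ValidationError(f"duplicate comparison_id {rec.comparison_id!r}")
        seen.add(rec.comparison_id)


def filter_eligible(records: list, min_total: int = DEFAULT_MIN_TOTAL) -> list:
    """Drop comparisons below the minimum randomized sample size.

    Idempotent by construction; the number of dropped comparisons is
    logged so the attrition is auditable.
    """
    kept = [r for r in records if r.n_total >= min_total]
    dropped = len(records) - len(kept)
    if dropped:
        logger.info("eligibility filter dropped %d comparison(s) with n < %d",
                    dropped, min_total)
    return kept


def _opt_int(raw: str, col: str, cid: str) -> Optional[int]:
    raw = raw.strip()
    if raw == "":
        return None
    try:
        return int(raw)
    except ValueError as exc:
        raise ValidationError(f"{cid}: column {col} not an integer: {raw!r}") from exc


def _opt_float(raw: str, col: str, cid: str) -> Optional[float]:
    raw = raw.strip()
    if raw == "":
        return None
    try:
        return float(raw)
    except ValueError as exc:
        raise ValidationError(f"{cid}: column {col} not numeric: {raw!r}") from exc


def _parse_bool(raw: str, col: str, cid: str) -> bool:
    token = raw.strip().lower()
    if token in ("true", "1"):
        return True
    if token in ("false", "0"):
        return False
    raise ValidationError(f"{cid}: column {col} not a boolean: {raw!r}")


def _parse_ci(lo, hi, label: str, cid: str) -> Optional[tuple]:
    if lo is None and hi is None:
        return None
    if lo is None or hi is None:
        raise ValidationError(f"{cid}: {label} CI must give both bounds or neither")
    return (lo, hi)


def _row_to_record(row: dict) -> TrialComparison:
    cid = row["comparison_id"].strip()
    if not cid:
        raise ValidationError("row with empty comparison_id")
    events = {}
    for endpoint in Endpoint:
        t = _opt_int(row[f"{endpoint.value}_treat"], f"{endpoint.value}_treat", cid)
        c = _opt_int(row[f"{endpoint.value}_control"], f"{endpoint.value}_control", cid)
        if (t is None) != (c is None):
            raise ValidationError(
                f"{cid}: endpoint {endpoint.value} has one arm count missing"
            )
        if t is not None:
            events[endpoint] = (t, c)
    try:
        region = Region(row["region"].strip())
        mm_def = MajorMinorDefinition(row["major_minor_definition"].strip())
        m_def = MajorDefinition(row["major_definition"].strip())
    except ValueError as exc:
        raise ValidationError(f"{cid}: {exc}") from exc
    ro = _opt_float(row["reported_or"], "reported_or", cid)
    rh = _opt_float(row["reported_hr"], "reported_hr", cid)
    return TrialComparison(
        trial_id=row["trial_id"].strip(),
        comparison_id=cid,
        first_enrollment_year=_opt_int(row["first_enrollment_year"],
                                       "first_enrollment_year", cid),
        follow_up_months=_opt_float(row["follow_up_months"], "follow_up_months", cid),
        region=region,
        acs_population=_parse_bool(row["acs_population"], "acs_population", cid),
        major_minor_definition=mm_def,
        major_definition=m_def,
        n_treat=_opt_int(row["n_treat"], "n_treat", cid),
        n_control=_opt_int(row["n_control"], "n_control", cid),
        events=events,
        reported_or=ro,
        reported_or_ci=_parse_ci(
            _opt_float(row["reported_or_lo"], "reported_or_lo", cid),
            _opt_float(row["reported_or_hi"], "reported_or_hi", cid),
            "reported_or", cid),
        reported_hr=rh,
        reported_hr_ci=_parse_ci(
            _opt_float(row["reported_hr_lo"], "reported_hr_lo", cid),
            _opt_float(row["reported_hr_hi"], "reported_hr_hi", cid),
            "reported_hr", cid),
    )


def load_comparisons(path, apply_eligibility: bool = True,
                     min_total: int = DEFAULT_MIN_TOTAL) -> list:
    """Read and validate the per-comparison CSV.

    Parameters
    ----------
    path
        CSV file in the documented schema (see :data:`CSV_COLUMNS`).
    apply_eligibility
        When true, comparisons with fewer than ``min_total`` randomized
        patients are dropped (and the drop count logged).
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    records = [_row_to_record(row) for row in frame.to_dict("records")]
    validate_records(records)
    if apply_eligibility:
        records = filter_eligible(records, min_total)
    return records


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, enum.Enum):
        return value.value
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _record_to_row(rec: TrialComparison) -> dict:
    row = {
        "trial_id": rec.trial_id,
        "comparison_id": rec.comparison_id,
        "first_enrollment_year": _fmt(rec.first_enrollment_year),
        "follow_up_months": _fmt(float(rec.follow_up_months)),
        "region": rec.region.value,
        "acs_population": _fmt(rec.acs_population),
        "major_minor_definition": rec.major_minor_definition.value,
        "major_definition": rec.major_definition.value,
        "n_treat": _fmt(rec.n_treat),
        "n_control": _fmt(rec.n_control),
    }
    for endpoint in Endpoint:
        pair = rec.events.get(endpoint)
        row[f"{endpoint.value}_treat"] = "" if pair is None else _fmt(pair[0])
        row[f"{endpoint.value}_control"] = "" if pair is None else _fmt(pair[1])
    for label, value, ci in (
        ("reported_or", rec.reported_or, rec.reported_or_ci),
        ("reported_hr", rec.reported_hr, rec.reported_hr_ci),
    ):
        row[label] = _fmt(None if value is None else float(value))
        row[f"{label}_lo"] = _fmt(None if ci is None else float(ci[0]))
        row[f"{label}_hi"] = _fmt(None if ci is None else float(ci[1]))
    return row


def comparisons_to_csv_bytes(records: list) -> bytes:
    """Canonical CSV serialization (used for files and dataset hashing)."""
    validate_records(records)
    frame = pd.DataFrame([_record_to_row(r) for r in records], columns=CSV_COLUMNS)
    buf = io.StringIO()
    frame.to_csv(buf, index=False, lineterminator="\n")
    return buf.getvalue().encode("utf-8")


def write_comparisons(records: list, path) -> None:
    """Write records as CSV; lossless round trip with :func:`load_comparisons`."""
    data = comparisons_to_csv_bytes(records)
    with open(path, "wb") as fh:
        fh.write(data)
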