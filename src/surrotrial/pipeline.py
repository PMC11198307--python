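"""Orchestration of the full surrogacy evaluation.

Runs the endpoint-pairing grid (six bleeding-definition families by two
mortality endpoints), the prespecified subgroup analyses (definition
criteria, enrollment era, follow-up duration, region, ACS population),
the hazard-ratio sensitivity track, and per-endpoint heterogeneity, and
renders the results as CSV / JSON / markdown tables shaped like the
published summary tables.

Reruns on the same input and configuration are bit-identical: there is
no randomness and no timestamping in any rendered artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .effects import build_pairs, estimate_for_endpoint
from .errors import (DegenerateDesignError, InsufficientPairsError,
                     SurrotrialError, UndefinedStatisticError)
from .heterogeneity import HeterogeneityResult, pool_effects
from .surrogacy import (SurrogacyResult, classify_surrogacy, format_regression,
                        r2_confidence_interval, weighted_regression)
from .trial_data import (Endpoint, MajorDefinition, MajorMinorDefinition,
                         Region, comparisons_to_csv_bytes, filter_eligible)

logger = logging.getLogger(__name__)

__all__ = ["SubgroupSpec", "AnalysisConfig", "AnalysisReport", "ReportRow",
           "filter_subgroup", "run_full_analysis", "render_report",
           "DEFINITION_FAMILIES"]

# (family key, bleeding endpoint, admissible major/minor defs, admissible major defs)
# None means "study defined": any trial reporting the endpoint counts.
DEFINITION_FAMILIES = [
    ("study_defined_major_minor", Endpoint.BLEED_MAJOR_MINOR, None),
    ("barc_235", Endpoint.BLEED_MAJOR_MINOR,
     {MajorMinorDefinition.BARC_235, MajorMinorDefinition.BARC_2345}),
    ("timi_major_minor", Endpoint.BLEED_MAJOR_MINOR,
     {MajorMinorDefinition.TIMI_MAJOR_MINOR}),
    ("study_defined_major", Endpoint.BLEED_MAJOR, None),
    ("barc_35", Endpoint.BLEED_MAJOR,
     {MajorDefinition.BARC_35, MajorDefinition.BARC_345}),
    ("timi_major", Endpoint.BLEED_MAJOR, {MajorDefinition.TIMI_MAJOR}),
]

FINAL_ENDPOINTS = [Endpoint.DEATH_ALL, Endpoint.DEATH_CV]

_BARC_MM = {MajorMinorDefinition.BARC_235, MajorMinorDefinition.BARC_2345}
_BARC_M = {MajorDefinition.BARC_35, MajorDefinition.BARC_345}


@dataclass
class SubgroupSpec:
    """Conjunction of record-level filters defining one subgroup.

    The era partition splits on the first enrollment year at 2010/2011
    (a year of exactly 2010 is "before 2010"); the follow-up partition
    puts exactly 12 months into the "<= 12 months" stratum.
    """

    name: str
    bleeding_criteria: Optional[str] = None  # study_defined | barc_only | timi_only
    era: Optional[str] = None                # before_2010 | after_2011
    follow_up: Optional[str] = None          # le_12m | gt_12m
    region: Optional[str] = None             # east_asia | non_east_asia
    acs_only: Optional[bool] = None
    estimand_policy: str = "or_from_counts"

    def matches(self, rec) -> bool:
        if self.bleeding_criteria == "barc_only":
            if not (rec.major_minor_definition in _BARC_MM
                    or rec.major_definition in _BARC_M):
                return False
        elif self.bleeding_criteria == "timi_only":
            if not (rec.major_minor_definition is MajorMinorDefinition.TIMI_MAJOR_MINOR
                    or rec.major_definition is MajorDefinition.TIMI_MAJOR):
                return False
        elif self.bleeding_criteria not in (None, "study_defined"):
            raise ValueError(f"unknown bleeding_criteria {self.bleeding_criteria!r}")
        if self.era == "before_2010" and rec.first_enrollment_year > 2010:
            return False
        if self.era == "after_2011" and rec.first_enrollment_year <= 2010:
            return False
        if self.era not in (None, "before_2010", "after_2011"):
            raise ValueError(f"unknown era {self.era!r}")
        if self.follow_up == "le_12m" and rec.follow_up_months > 12.0:
            return False
        if self.follow_up == "gt_12m" and rec.follow_up_months <= 12.0:
            return False
        if self.follow_up not in (None, "le_12m", "gt_12m"):
            raise ValueError(f"unknown follow_up {self.follow_up!r}")
        if self.region is not None and rec.region is not Region(self.region):
            return False
        if self.acs_only and not rec.acs_population:
            return False
        return True


def filter_subgroup(records: list, spec: SubgroupSpec) -> list:
    """Records satisfying every non-null filter of the subgroup spec."""
    return [r for r in records if spec.matches(r)]


def default_subgroups() -> list:
    """The prespecified subgroup grid: era, follow-up, region, ACS."""
    return [
        SubgroupSpec("era_before_2010", era="before_2010"),
        SubgroupSpec("era_after_2011", era="after_2011"),
        SubgroupSpec("follow_up_le_12m", follow_up="le_12m"),
        SubgroupSpec("follow_up_gt_12m", follow_up="gt_12m"),
        SubgroupSpec("east_asia", region="east_asia"),
        SubgroupSpec("non_east_asia", region="non_east_asia"),
        SubgroupSpec("acs_only", acs_only=True),
    ]


@dataclass
class AnalysisConfig:
    """Tunable knobs of the full evaluation."""

    eligibility_min_n: int = 500
    weighting: str = "patients"       # patients | inverse_variance
    zero_cell: str = "haldane"        # haldane | exclude
    ci_level: float = 0.95
    estimand_policy: str = "or_from_counts"
    include_hr_sensitivity: bool = True
    subgroups: list = field(default_factory=default_subgroups)

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = json.load(fh)
        subgroups = [SubgroupSpec(**sg) for sg in raw.pop("subgroups", [])]
        config = cls(**raw)
        if subgroups:
            config.subgroups = subgroups
        return config

    def to_dict(self) -> dict:
        data = asdict(self)
        data["subgroups"] = [asdict(sg) for sg in self.subgroups]
        return data


@dataclass
class ReportRow:
    """One cell of the analysis grid: a result or a reason it is absent."""

    analysis: str       # primary | hr_sensitivity | subgroup name
    family: str
    final_endpoint: str
    result: Optional[SurrogacyResult]
    reason: Optional[str] = None


@dataclass
class AnalysisReport:
    """Everything one run produces, ready for rendering."""

    rows_table1: list
    rows_table2: list
    heterogeneity: list
    metadata: dict


_FAMILY_LABEL = {
    "study_defined_major_minor": "major_minor",
    "barc_235": "major_minor",
    "timi_major_minor": "major_minor",
    "study_defined_major": "major",
    "barc_35": "major",
    "timi_major": "major",
}


def _family_records(records: list, family: str) -> list:
    key = dict((f[0], f) for f in DEFINITION_FAMILIES)[family]
    _, endpoint, allowed = key
    out = []
    for rec in records:
        if allowed is not None:
            definition = (rec.major_minor_definition
                          if endpoint is Endpoint.BLEED_MAJOR_MINOR
                          else rec.major_definition)
            if definition not in allowed:
                continue
        out.append(rec)
    return out


def _family_endpoint(family: str) -> Endpoint:
    return dict((f[0], f[1]) for f in DEFINITION_FAMILIES)[family]


def analyze_cell(records: list, family: str, final_endpoint: Endpoint,
                 config: AnalysisConfig,
                 estimand_policy: Optional[str] = None) -> SurrogacyResult:
    """Fit one grid cell; raises a package error when not estimable."""
    policy = estimand_policy or config.estimand_policy
    surrogate = _family_endpoint(family)
    subset = _family_records(records, family)
    pairs = build_pairs(subset, surrogate, final_endpoint,
                        estimand_policy=policy, zero_cell=config.zero_cell)
    if config.weighting == "inverse_variance":
        # inverse-variance weights: 1 / var of the final-endpoint log effect
        by_id = {r.comparison_id: r for r in subset}
        reweighted = []
        for p in pairs:
            est = estimate_for_endpoint(by_id[p.comparison_id], final_endpoint,
                                        config.zero_cell)
            reweighted.append(p._replace(w=1.0 / est.se ** 2))
        pairs = reweighted
    elif config.weighting != "patients":
        raise ValueError(f"unknown weighting {config.weighting!r}")
    fit = weighted_regression(pairs, ci_level=config.ci_level)
    r2_ci = r2_confidence_interval(fit.r2, fit.n, level=config.ci_level)
    label_ci, label_point = classify_surrogacy(fit.r2, r2_ci)
    ids = {p.comparison_id for p in pairs}
    contributing = [r for r in subset if r.comparison_id in ids]
    return SurrogacyResult(
        surrogate_endpoint=surrogate.value,
        final_endpoint=final_endpoint.value,
        n_pairs=fit.n,
        n_trials=len({r.trial_id for r in contributing}),
        n_patients=sum(r.n_total for r in contributing),
        slope=fit.slope, slope_ci=fit.slope_ci,
        intercept=fit.intercept, r2=fit.r2, r2_ci=r2_ci,
        label_ci_scheme=label_ci, label_point_scheme=label_point,
        formula_text=format_regression(fit.intercept, fit.slope, "bleeding"))


def _cell_row(records, analysis, family, final_endpoint, config,
              estimand_policy=None) -> ReportRow:
    try:
        result = analyze_cell(records, family, final_endpoint, config,
                              estimand_policy)
        reason = None
    except InsufficientPairsError:
        result, reason = None, "no informative pairs"
    except DegenerateDesignError:
        result, reason = None, "degenerate design"
    except UndefinedStatisticError:
        result, reason = None, "zero outcome variance"
    n_pairs = result.n_pairs if result else 0
    logger.info("cell %s/%s/%s: %s", analysis, family, final_endpoint.value,
                f"{n_pairs} pairs" if result else f"not estimable ({reason})")
    return ReportRow(analysis=analysis, family=family,
                     final_endpoint=final_endpoint.value,
                     result=result, reason=reason)


def run_full_analysis(records: list, config: Optional[AnalysisConfig] = None
                      ) -> AnalysisReport:
    """Run the overall grid, sensitivity track, subgroups, and heterogeneity."""
    config = config or AnalysisConfig()
    if not records:
        raise SurrotrialError("empty dataset")
    eligible = filter_eligible(records, config.eligibility_min_n)
    if not eligible:
        raise SurrotrialError("no comparison meets the eligibility filter")

    rows_table1 = []
    for family, _, _ in DEFINITION_FAMILIES:
        for final_endpoint in FINAL_ENDPOINTS:
            rows_table1.append(_cell_row(eligible, "primary", family,
                                         final_endpoint, config))
    if config.include_hr_sensitivity:
        for family, _, _ in DEFINITION_FAMILIES:
            for final_endpoint in FINAL_ENDPOINTS:
                rows_table1.append(_cell_row(eligible, "hr_sensitivity", family,
                                             final_endpoint, config,
                                             estimand_policy="hr_reported"))

    rows_table2 = []
    for spec in config.subgroups:
        subset = filter_subgroup(eligible, spec)
        for family, _, _ in DEFINITION_FAMILIES:
            for final_endpoint in FINAL_ENDPOINTS:
                rows_table2.append(_cell_row(subset, spec.name, family,
                                             final_endpoint, config,
                                             estimand_policy=spec.estimand_policy))

    heterogeneity = []
    for endpoint in Endpoint:
        estimates = [e for e in
                     (estimate_for_endpoint(r, endpoint, config.zero_cell)
                      for r in eligible)
                     if e is not None and e.informative]
        if len(estimates) >= 2:
            heterogeneity.append(pool_effects(estimates, model="random_dl",
                                              ci_level=config.ci_level))

    metadata = {
        "software": "surrotrial",
        "version": __version__,
        "dataset_sha256": hashlib.sha256(
            comparisons_to_csv_bytes(records)).hexdigest(),
        "n_comparisons_input": len(records),
        "n_comparisons_eligible": len(eligible),
        "config": config.to_dict(),
    }
    return AnalysisReport(rows_table1=rows_table1, rows_table2=rows_table2,
                          heterogeneity=heterogeneity, metadata=metadata)


def _fmt2(value) -> str:
    return "" if value is None else f"{round(value, 2) + 0.0:.2f}"


def _row_record(row: ReportRow) -> dict:
    res = row.result
    return {
        "analysis": row.analysis,
        "bleeding_family": row.family,
        "final_endpoint": row.final_endpoint,
        "comparison_pairs": res.n_pairs if res else "",
        "rcts": res.n_trials if res else "",
        "n": res.n_patients if res else "",
        "regression_formula": res.formula_text if res else "",
        "slope": _fmt2(res.slope) if res else "",
        "slope_lo": _fmt2(res.slope_ci[0]) if res and res.slope_ci else "",
        "slope_hi": _fmt2(res.slope_ci[1]) if res and res.slope_ci else "",
        "r2": _fmt2(res.r2) if res else "",
        "r2_lo": _fmt2(res.r2_ci[0]) if res and res.r2_ci else "",
        "r2_hi": _fmt2(res.r2_ci[1]) if res and res.r2_ci else "",
        "label_ci": res.label_ci_scheme if res else "",
        "label_point": res.label_point_scheme if res else "",
        "reason": row.reason or "",
    }


_TABLE_COLUMNS = list(_row_record(ReportRow("x", "y", "z", None)).keys())


def _csv_table(rows: list) -> str:
    lines = [",".join(_TABLE_COLUMNS)]
    for row in rows:
        rec = _row_record(row)
        lines.append(",".join(f'"{rec[c]}"' if "," in str(rec[c]) else str(rec[c])
                              for c in _TABLE_COLUMNS))
    return "\n".join(lines) + "\n"


def _markdown_table(rows: list) -> str:
    header = "| " + " | ".join(_TABLE_COLUMNS) + " |"
    rule = "|" + "|".join("---" for _ in _TABLE_COLUMNS) + "|"
    body = ["| " + " | ".join(str(_row_record(r)[c]) for c in _TABLE_COLUMNS) + " |"
            for r in rows]
    return "\n".join([header, rule] + body) + "\n"


def _json_rows(rows: list) -> list:
    out = []
    for row in rows:
        res = row.result
        entry = {"analysis": row.analysis, "bleeding_family": row.family,
                 "final_endpoint": row.final_endpoint, "reason": row.reason}
        if res is not None:
            entry["result"] = {
                "surrogate_endpoint": res.surrogate_endpoint,
                "final_endpoint": res.final_endpoint,
                "n_pairs": res.n_pairs, "n_trials": res.n_trials,
                "n_patients": res.n_patients,
                "slope": res.slope,
                "slope_ci": list(res.slope_ci) if res.slope_ci else None,
                "intercept": res.intercept,
                "r2": res.r2,
                "r2_ci": list(res.r2_ci) if res.r2_ci else None,
                "label_ci_scheme": res.label_ci_scheme,
                "label_point_scheme": res.label_point_scheme,
                "formula_text": res.formula_text,
            }
        out.append(entry)
    return out


def render_report(report: AnalysisReport, out_dir,
                  formats: tuple = ("csv", "json", "markdown")) -> list:
    """Write table1/table2 files; returns the paths written.

    CSV and markdown round numbers to two decimals (the convention of
    the published tables); JSON keeps full precision.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for fmt in formats:
        if fmt == "csv":
            for name, rows in (("table1.csv", report.rows_table1),
                               ("table2.csv", report.rows_table2)):
                path = out_dir / name
                path.write_text(_csv_table(rows), encoding="utf-8")
                written.append(path)
        elif fmt == "json":
            payload = {
                "metadata": report.metadata,
                "table1": _json_rows(report.rows_table1),
                "table2": _json_rows(report.rows_table2),
                "heterogeneity": [
                    {"endpoint": h.endpoint, "k": h.k, "model": h.model,
                     "pooled_log_effect": h.pooled_log_effect,
                     "pooled_ci": list(h.pooled_ci), "q": h.q, "df": h.df,
                     "tau2": h.tau2, "i2_percent": h.i2_percent}
                    for h in report.heterogeneity],
            }
            path = out_dir / "report.json"
            path.write_text(json.dumps(payload, indent=2, sort_keys=True),
                            encoding="utf-8")
            written.append(path)
        elif fmt == "markdown":
            text = ("# Overall analyses\n\n" + _markdown_table(report.rows_table1)
                    + "\n# Subgroup analyses\n\n"
                    + _markdown_table(report.rows_table2))
            path = out_dir / "report.md"
            path.write_text(text, encoding="utf-8")
            written.append(path)
        else:
            raise ValueError(f"unknown format {fmt!r}")
    return written
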