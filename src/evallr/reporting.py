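"""Certificate-of-analysis I/O, disclosure audit and evaluative reports.

A certificate of analysis (CoA) is read into validated findings with
attached reference summaries, audited for disclosure completeness
(quantitative value, LoD/LoQ, measurement uncertainty, reference
citation, strength assessment), evaluated through the full pipeline
(propositions -> probabilities -> per-finding LRs -> verbal labels ->
combination), and rendered deterministically as markdown or JSON.

A report that assigns a strength of evidence to every finding is badged
*evaluative*; if any finding could not be assessed the whole report is
badged intelligence/investigative/technical — explicitly not capable of
supporting a definitive judgement about the sample.

CoA machine schema (CSV, comma-separated, UTF-8, mandatory header,
empty string = absent)::

    parameter, mode, value, units, lod, loq, mu,
    condition_direction, condition_threshold, ref_n, ref_k,
    ref_population, ref_source

``mode`` is quantitative or qualitative; for qualitative rows ``value``
holds ``detected`` / ``not_detected`` and ``condition_direction`` is
``detected``.  The trailing ``ref_source`` (citation for the reference
counts) is optional but its absence fails the disclosure audit.  This
schema is a proposal: CoAs have no agreed machine format, which is
precisely the disclosure problem the report layer addresses.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .evidence_model import (
    EvidenceCondition,
    Finding,
    PropositionPair,
    ProbabilityAssignment,
    ReferenceSummary,
    ValidationError,
    make_source_propositions,
)
from .likelihood import (
    LikelihoodRatio,
    VerbalScale,
    assert_probability,
    likelihood_ratio,
    orient,
    prob_from_reference,
    round_sig,
    verbal_equivalent,
)
from .combiner import CombinationPlan, CombinedLR, combine

__all__ = [
    "CoARecord",
    "RowIssue",
    "EvalConfig",
    "DisclosureChecklist",
    "FindingEvaluation",
    "EvaluativeReport",
    "PhrasingError",
    "read_coa",
    "check_disclosure",
    "evaluate",
    "render_report",
    "generate_fixture_coa",
    "POSTERIOR_DENYLIST",
]

logger = logging.getLogger("evallr")

COA_COLUMNS = [
    "parameter", "mode", "value", "units", "lod", "loq", "mu",
    "condition_direction", "condition_threshold", "ref_n", "ref_k",
    "ref_population",
]
COA_OPTIONAL_COLUMNS = ["ref_source"]

#: Transposed-conditional (prosecutor's-fallacy) phrasings that must never
#: appear in a rendered report: they state the probability of a proposition
#: given the evidence, which requires a prior the framework refuses to set.
POSTERIOR_DENYLIST = [
    r"probability\s+that\s+the\s+(honey|sample|product)",
    r"probability\s+(of|that)\s+(adulteration|authenticity)",
    r"probability\s+of\s+the\s+proposition",
    r"(chance|likelihood|odds)\s+that\s+the\s+(honey|sample|product)\s+(is|was)",
    r"is\s+(probably|likely)\s+(adulterated|authentic|atypical)",
    r"(honey|sample|product)\s+is\s+adulterated\s+with\s+probability",
]


class PhrasingError(ValueError):
    """A rendered report contained posterior-probability phrasing."""


@dataclass(frozen=True)
class CoARecord:
    """One CoA row: a finding plus its reference summary, if any."""

    finding: Finding
    reference: Optional[ReferenceSummary] = None

    def to_dict(self) -> dict:
        return {
            "finding": self.finding.to_dict(),
            "reference": self.reference.to_dict() if self.reference else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CoARecord":
        ref = d.get("reference")
        return cls(
            finding=Finding.from_dict(d["finding"]),
            reference=ReferenceSummary.from_dict(ref) if ref else None,
        )


@dataclass(frozen=True)
class RowIssue:
    """A malformed CoA row, reported with its 1-based file line number."""

    row: int
    message: str


# ---------------------------------------------------------------------------
# CoA reading


def _opt_float(cell: str, column: str) -> Optional[float]:
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise ValidationError(f"column {column!r}: {cell!r} is not a number") from None


def _opt_int(cell: str, column: str) -> Optional[int]:
    if cell == "":
        return None
    try:
        return int(cell)
    except ValueError:
        raise ValidationError(f"column {column!r}: {cell!r} is not an integer") from None


def _record_from_row(row: dict[str, str]) -> CoARecord:
    mode = row["mode"].strip()
    direction = row["condition_direction"].strip()
    units = row["units"].strip() or None
    condition = EvidenceCondition(
        direction=direction,
        threshold=_opt_float(row["condition_threshold"].strip(), "condition_threshold"),
        units=units if direction != "detected" else None,
    )
    value: Optional[float] = None
    detected: Optional[bool] = None
    raw_value = row["value"].strip()
    if mode == "qualitative":
        if raw_value not in ("detected", "not_detected"):
            raise ValidationError(
                f"qualitative rows need value 'detected' or 'not_detected', got {raw_value!r}"
            )
        detected = raw_value == "detected"
    else:
        value = _opt_float(raw_value, "value")
    finding = Finding(
        parameter=row["parameter"].strip(),
        mode=mode,
        condition=condition,
        value=value,
        units=units,
        detected=detected,
        lod=_opt_float(row["lod"].strip(), "lod"),
        loq=_opt_float(row["loq"].strip(), "loq"),
        mu=_opt_float(row["mu"].strip(), "mu"),
    )
    n = _opt_int(row["ref_n"].strip(), "ref_n")
    k = _opt_int(row["ref_k"].strip(), "ref_k")
    reference = None
    if n is not None or k is not None:
        if n is None or k is None:
            raise ValidationError("ref_n and ref_k must be given together")
        reference = ReferenceSummary(
            n=n, k=k,
            population=row.get("ref_population", "").strip(),
            source=row.get("ref_source", "").strip(),
        )
    return CoARecord(finding=finding, reference=reference)


def read_coa(path, format: str = "csv") -> tuple[list[CoARecord], list[RowIssue]]:
    """Read a CoA file into validated records plus a per-row issue list.

    Malformed rows never abort the read: they are collected as
    :class:`RowIssue` with their file line number so a laboratory can be
    told exactly which entries are unusable.  An empty file yields an
    empty record list and a logged warning.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        logger.warning("CoA file %s is empty", path)
        return [], []
    records: list[CoARecord] = []
    issues: list[RowIssue] = []
    if format == "json":
        doc = json.loads(text)
        for i, entry in enumerate(doc.get("records", [])):
            try:
                records.append(CoARecord.from_dict(entry))
            except (ValidationError, KeyError, TypeError) as exc:
                issues.append(RowIssue(row=i, message=str(exc)))
        return records, issues
    if format != "csv":
        raise ValidationError(f"format must be 'csv' or 'json', got {format!r}")
    reader = csv.DictReader(text.splitlines())
    header = reader.fieldnames or []
    missing = [c for c in COA_COLUMNS if c not in header]
    if missing:
        raise ValidationError(f"CoA header is missing required columns: {missing}")
    for lineno, row in enumerate(reader, start=2):
        row = {k: (v or "") for k, v in row.items() if k is not None}
        for col in COA_OPTIONAL_COLUMNS:
            row.setdefault(col, "")
        try:
            records.append(_record_from_row(row))
        except ValidationError as exc:
            issues.append(RowIssue(row=lineno, message=str(exc)))
    if not records and not issues:
        logger.warning("CoA file %s contains a header but no data rows", path)
    return records, issues


# ---------------------------------------------------------------------------
# Disclosure audit


_DISCLOSURE_FIELDS = (
    "quantitative_value_reported",
    "lod_or_loq_reported",
    "mu_reported",
    "reference_dataset_cited",
    "strength_assessed",
)
_METHOD_FIELDS = ("tested", "peer_reviewed", "error_rate_known", "generally_accepted")


@dataclass(frozen=True)
class DisclosureChecklist:
    """Field-presence audit of a CoA against the reporting convention.

    Every flag is an explicit boolean — nothing defaults to true.  The
    method-acceptability block (has the technique been tested, peer
    reviewed, is its error rate known, is it generally accepted) cannot
    be derived from a CoA and must be supplied by the caller; absent
    metadata is recorded as False.
    """

    per_finding: dict[str, dict[str, bool]]
    method_acceptability: dict[str, bool]

    def __post_init__(self) -> None:
        for param, flags in self.per_finding.items():
            if set(flags) != set(_DISCLOSURE_FIELDS):
                raise ValidationError(f"checklist for {param!r} must set exactly {_DISCLOSURE_FIELDS}")
            for name, v in flags.items():
                if not isinstance(v, bool):
                    raise ValidationError(f"checklist field {name} for {param!r} must be a bool")
        if set(self.method_acceptability) != set(_METHOD_FIELDS):
            raise ValidationError(f"method acceptability must set exactly {_METHOD_FIELDS}")

    @property
    def complete(self) -> bool:
        return all(all(flags.values()) for flags in self.per_finding.values())

    def to_dict(self) -> dict:
        return {
            "per_finding": {k: dict(v) for k, v in self.per_finding.items()},
            "method_acceptability": dict(self.method_acceptability),
        }


def check_disclosure(
    records: Sequence[CoARecord],
    method_metadata: Optional[dict[str, bool]] = None,
    strength_assessed: Optional[dict[str, bool]] = None,
) -> DisclosureChecklist:
    """Audit findings for the disclosure the reporting convention demands.

    A bare qualitative "detected" without an LoQ fails
    ``lod_or_loq_reported``: without the limit the claim cannot be read
    as "above LoQ" and an impartial observer cannot interpret the datum.
    A reference summary without citation text fails
    ``reference_dataset_cited``.
    """
    per_finding: dict[str, dict[str, bool]] = {}
    strength_assessed = strength_assessed or {}
    for rec in records:
        f = rec.finding
        if f.mode == "qualitative":
            # "detected" is only interpretable as "above LoQ" if the LoQ is given
            lod_loq = f.loq is not None
            value_ok = f.detected is not None and f.loq is not None
        else:
            lod_loq = f.lod is not None or f.loq is not None
            value_ok = f.value is not None
        per_finding[f.parameter] = {
            "quantitative_value_reported": bool(value_ok),
            "lod_or_loq_reported": bool(lod_loq),
            "mu_reported": f.mu is not None,
            "reference_dataset_cited": bool(rec.reference is not None and rec.reference.source),
            "strength_assessed": bool(strength_assessed.get(f.parameter, False)),
        }
    meta = {name: bool((method_metadata or {}).get(name, False)) for name in _METHOD_FIELDS}
    return DisclosureChecklist(per_finding=per_finding, method_acceptability=meta)


# ---------------------------------------------------------------------------
# Evaluation pipeline


@dataclass
class EvalConfig:
    """Configuration for an evaluation run.

    ``correction`` selects the P(E|Hd) estimator for reference counts;
    ``zero_k_method`` is the fallback when the empirical estimator meets
    k = 0.  ``asserted`` maps a parameter name to {"p": ..,
    "justification": ..} for probabilities taken from experience rather
    than counts (asserted values take precedence over reference counts).
    ``groups`` is the combination plan as lists of parameter names; when
    omitted every finding is its own group and the report warns that
    independence was assumed.
    """

    scale: str = "ENFSI"
    conservative_margin: float = 2.0
    correction: str = "empirical"
    zero_k_method: str = "upper_bound"
    confidence: float = 0.95
    sig_figs: int = 3
    groups: Optional[list[list[str]]] = None
    asserted: dict[str, dict] = field(default_factory=dict)
    method_metadata: dict[str, bool] = field(default_factory=dict)
    narrative: str = ""
    reason_texts: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "EvalConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


@dataclass(frozen=True)
class FindingEvaluation:
    """The per-finding outcome, with every input recorded for the case file."""

    parameter: str
    propositions: PropositionPair
    condition_met: bool
    evaluated: bool
    probability: Optional[ProbabilityAssignment]  # P(E|Hd)
    lr: Optional[LikelihoodRatio]
    supported: Optional[str]  # "Hp", "Hd" or None
    label: Optional[str]
    downgraded: bool
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "propositions": self.propositions.to_dict(),
            "condition_met": self.condition_met,
            "evaluated": self.evaluated,
            "probability": self.probability.to_dict() if self.probability else None,
            "lr": self.lr.to_dict() if self.lr else None,
            "supported": self.supported,
            "label": self.label,
            "downgraded": self.downgraded,
            "note": self.note,
        }


@dataclass(frozen=True)
class EvaluativeReport:
    """Structured evaluative report over one CoA."""

    findings: tuple[FindingEvaluation, ...]
    combined: Optional[CombinedLR]
    combined_label: Optional[str]
    combined_downgraded: bool
    checklist: DisclosureChecklist
    badge: str  # "evaluative" or "intelligence_investigative_technical"
    scale_name: str
    conservative_margin: float
    sig_figs: int
    narrative: str = ""

    def to_dict(self) -> dict:
        return {
            "findings": [f.to_dict() for f in self.findings],
            "combined": self.combined.to_dict() if self.combined else None,
            "combined_label": self.combined_label,
            "combined_downgraded": self.combined_downgraded,
            "checklist": self.checklist.to_dict(),
            "badge": self.badge,
            "scale_name": self.scale_name,
            "conservative_margin": self.conservative_margin,
            "sig_figs": self.sig_figs,
            "narrative": self.narrative,
        }


def _assign_probability(rec: CoARecord, config: EvalConfig) -> tuple[Optional[ProbabilityAssignment], str]:
    """P(E|Hd) for one finding, with a note describing the route taken."""
    param = rec.finding.parameter
    if param in config.asserted:
        entry = config.asserted[param]
        pa = assert_probability(float(entry["p"]), str(entry["justification"]))
        logger.info("P(E|Hd) for %s: asserted %g (%s)", param, pa.p, pa.justification)
        return pa, "asserted probability from configuration"
    if rec.reference is None:
        return None, "no reference dataset and no asserted probability"
    method = config.correction
    note = f"{method} estimate from reference counts"
    if method == "empirical" and rec.reference.k == 0:
        method = config.zero_k_method
        note = (
            f"reference count k=0: empirical estimate undefined, "
            f"fell back to {method}"
        )
    pa = prob_from_reference(rec.reference, method=method, confidence=config.confidence)
    logger.info(
        "P(E|Hd) for %s: %s -> %g from k=%d/n=%d (%s)",
        param, method, pa.p, rec.reference.k, rec.reference.n,
        rec.reference.source or "uncited",
    )
    return pa, note


def evaluate(records: Sequence[CoARecord], config: Optional[EvalConfig] = None) -> EvaluativeReport:
    """Run the full evaluative pipeline over a set of CoA records.

    For each finding whose evidence condition is met: form the
    source-level proposition pair, assign P(E|Hd) (asserted value or
    reference-count estimate), set P(E|Hp) = 1, compute the LR, orient
    it and attach its verbal equivalent.  Findings whose condition is
    not met are inconclusive (LR = 1, Null).  Findings whose condition
    is met but for which no probability can be assigned are carried as
    *not evaluated* and force the intelligence/investigative/technical
    badge.  Evaluated findings are then combined under the configured
    correlation plan (default: singletons, independence assumed).
    """
    config = config or EvalConfig()
    scale = VerbalScale.builtin(config.scale)
    evaluations: list[FindingEvaluation] = []
    lrs: dict[str, LikelihoodRatio] = {}
    for rec in records:
        param = rec.finding.parameter
        pair = make_source_propositions(param, config.reason_texts.get(param, ""))
        if not rec.finding.condition_met:
            lr = likelihood_ratio(1.0, 1.0)
            lrs[param] = lr
            evaluations.append(FindingEvaluation(
                parameter=param, propositions=pair, condition_met=False,
                evaluated=True, probability=None, lr=lr, supported=None,
                label="Null", downgraded=False,
                note="evidence condition not met: inconclusive for this pair",
            ))
            continue
        prob, note = _assign_probability(rec, config)
        if prob is None:
            evaluations.append(FindingEvaluation(
                parameter=param, propositions=pair, condition_met=True,
                evaluated=False, probability=None, lr=None, supported=None,
                label=None, downgraded=False, note=note,
            ))
            continue
        numerator = ProbabilityAssignment(
            p=1.0, method="asserted",
            justification="evidence condition met with certainty under Hp",
        )
        lr = likelihood_ratio(numerator, prob)
        lr, supported = orient(lr, pair)
        label, _, downgraded = verbal_equivalent(lr, scale, config.conservative_margin)
        lrs[param] = lr
        evaluations.append(FindingEvaluation(
            parameter=param, propositions=pair, condition_met=True,
            evaluated=True, probability=prob, lr=lr, supported=supported,
            label=label, downgraded=downgraded, note=note,
        ))

    combined = None
    combined_label = None
    combined_downgraded = False
    if lrs:
        plan = None
        if config.groups is not None:
            plan = CombinationPlan.from_lists(config.groups)
        combined = combine(lrs, plan)
        combined_label, _, combined_downgraded = verbal_equivalent(
            combined.value, scale, config.conservative_margin
        )

    all_assessed = bool(evaluations) and all(e.evaluated for e in evaluations)
    badge = "evaluative" if all_assessed else "intelligence_investigative_technical"
    checklist = check_disclosure(
        records,
        method_metadata=config.method_metadata,
        strength_assessed={e.parameter: e.evaluated for e in evaluations},
    )
    return EvaluativeReport(
        findings=tuple(evaluations),
        combined=combined,
        combined_label=combined_label,
        combined_downgraded=combined_downgraded,
        checklist=checklist,
        badge=badge,
        scale_name=scale.name,
        conservative_margin=config.conservative_margin,
        sig_figs=config.sig_figs,
        narrative=config.narrative,
    )


# ---------------------------------------------------------------------------
# Rendering


def _fmt(value: float, sig: int) -> str:
    return f"{round_sig(value, sig):g}"


def _strength_sentence(label: str, lr_value: float, scale_name: str, sig: int, downgraded: bool) -> str:
    s = (
        f"{label} (likelihood ratio {_fmt(lr_value, sig)}, {scale_name} scale)"
    )
    if downgraded:
        s += " — reported one band lower under the conservative demarcation rule"
    return s


def _render_markdown(report: EvaluativeReport) -> str:
    sig = report.sig_figs
    lines: list[str] = []
    lines.append("# Evaluative report")
    lines.append("")
    if report.badge == "evaluative":
        lines.append("**Badge:** evaluative report.")
    else:
        lines.append(
            "**Badge:** intelligence / investigative / technical report. "
            "This document is not capable of supporting a definitive judgement "
            "about the sample; it is provided so that further work can be undertaken."
        )
    lines.append("")
    lines.append("## Findings")
    lines.append("")
    for ev in report.findings:
        lines.append(f"### {ev.parameter}")
        lines.append("")
        lines.append(f"- Hp: {ev.propositions.hp_text}")
        lines.append(f"- Hd: {ev.propositions.hd_text}")
        lines.append(f"- Evidence condition met: {'yes' if ev.condition_met else 'no'}")
        if not ev.evaluated:
            lines.append(f"- Strength of evidence: not evaluated ({ev.note}).")
            lines.append("")
            continue
        if ev.probability is not None:
            p = ev.probability
            interval = ""
            if p.interval is not None:
                interval = f" (interval {_fmt(p.interval[0], sig)} to {_fmt(p.interval[1], sig)})"
            lines.append(
                f"- P(E|Hd) = {_fmt(p.p, sig)}{interval}, method: {p.method}. "
                f"Grounds: {p.justification}"
            )
        assert ev.lr is not None
        if ev.lr.value == 1:
            lines.append(
                f"- Strength of evidence: Null (likelihood ratio 1, {report.scale_name} scale): "
                "the findings are equally likely under either proposition."
            )
        else:
            hp, hd = ev.propositions.hp_text, ev.propositions.hd_text
            first, second = (hp, hd) if ev.supported != "Hd" else (hd, hp)
            lines.append(
                f"- The findings for {ev.parameter} are {_fmt(ev.lr.value, sig)} times "
                f"more likely if [{first}] than if [{second}]."
            )
            if ev.lr.interval is not None:
                lines.append(
                    f"- Interval on the likelihood ratio: {_fmt(ev.lr.interval[0], sig)} "
                    f"to {_fmt(ev.lr.interval[1], sig)}."
                )
            lines.append(
                "- Strength of evidence: "
                + _strength_sentence(ev.label or "", ev.lr.value, report.scale_name, sig, ev.downgraded)
            )
        lines.append("")
    lines.append("## Combined evaluation")
    lines.append("")
    if report.combined is None:
        lines.append("No findings could be combined.")
    else:
        c = report.combined
        if c.independence_assumed:
            lines.append(
                "**Warning:** no correlation plan was supplied; the findings were "
                "treated as fully independent. Independence is an assumption of "
                "this combination, not a demonstrated property of the methods."
            )
            lines.append("")
        for b in c.breakdown:
            ids = ", ".join(b["ids"])
            if len(b["ids"]) > 1:
                lines.append(
                    f"- Correlated group [{ids}]: counted only the largest "
                    f"likelihood ratio, {_fmt(b['contribution'], sig)} ({b['contributing_id']})."
                )
            else:
                lines.append(f"- {ids}: likelihood ratio {_fmt(b['contribution'], sig)}.")
        lines.append("")
        lines.append(
            f"Combined likelihood ratio: {_fmt(c.value, sig)}. "
            + (
                "The combined findings are equally likely under either proposition."
                if c.value == 1
                else (
                    f"Taken together, the findings are {_fmt(c.value, sig)} times more "
                    "likely if the sample is atypical of the reference datasets than "
                    "if it is a typical sample outside them by chance or stated reason."
                )
            )
        )
        if report.combined_label is not None:
            lines.append(
                "Strength of the combined evidence: "
                + _strength_sentence(
                    report.combined_label, c.value, report.scale_name, sig, report.combined_downgraded
                )
            )
    lines.append("")
    lines.append("## Disclosure checklist")
    lines.append("")
    lines.append("| finding | " + " | ".join(_DISCLOSURE_FIELDS) + " |")
    lines.append("|" + "---|" * (len(_DISCLOSURE_FIELDS) + 1))
    for param in report.checklist.per_finding:
        flags = report.checklist.per_finding[param]
        cells = " | ".join("yes" if flags[f] else "NO" for f in _DISCLOSURE_FIELDS)
        lines.append(f"| {param} | {cells} |")
    lines.append("")
    meta = report.checklist.method_acceptability
    lines.append(
        "Method acceptability: "
        + "; ".join(f"{k.replace('_', ' ')}: {'yes' if v else 'NO'}" for k, v in meta.items())
        + "."
    )
    if report.narrative:
        lines.append("")
        lines.append("## Narrative supplement")
        lines.append("")
        lines.append(report.narrative)
    lines.append("")
    return "\n".join(lines)


def render_report(report: EvaluativeReport, format: str = "markdown") -> str:
    """Render a report deterministically as markdown or schema-stable JSON.

    Every likelihood-ratio statement uses the conditional-on-proposition
    phrasing ("the findings are N times more likely if [Hp] than if
    [Hd]"); the output is checked against the posterior-phrasing
    denylist and rendering fails rather than emit a transposed
    conditional.
    """
    if format == "json":
        text = json.dumps(report.to_dict(), sort_keys=True, indent=2)
    elif format == "markdown":
        text = _render_markdown(report)
    else:
        raise ValidationError(f"format must be 'markdown' or 'json', got {format!r}")
    for pattern in POSTERIOR_DENYLIST:
        m = re.search(pattern, text, flags=re.IGNORECASE)
        if m:
            raise PhrasingError(
                f"rendered report contains posterior-probability phrasing: {m.group(0)!r}"
            )
    return text


# ---------------------------------------------------------------------------
# Fixture generation


def generate_fixture_coa(
    seed: int,
    n_parameters: int = 3,
    adulterated: bool = False,
    prevalence_range: tuple[float, float] = (0.05, 0.15),
    directory=".",
) -> tuple[Path, dict]:
    """Write a synthetic CoA (CSV) plus its ground-truth record (JSON).

    Each parameter is a quantitative syrup-marker analogue with evidence
    condition "concentration >= 5 mg/kg" and a reference survey of 1000
    genuine samples whose positive count matches a prevalence drawn from
    ``prevalence_range`` (rounded to 3 decimals so k/1000 is exact).
    ``adulterated=True`` forces every evidence condition to be met; for a
    genuine sample each condition is met with its background prevalence.
    Fully deterministic given ``seed``: repeated calls write identical
    files.
    """
    if n_parameters < 1:
        raise ValidationError(f"need at least one parameter, got {n_parameters}")
    lo, hi = prevalence_range
    if not (0.0 < lo <= hi < 1.0):
        raise ValidationError(f"prevalence range must lie within (0, 1), got {prevalence_range}")
    rng = np.random.default_rng(seed)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ref_n = 1000
    rows = []
    truth_params = []
    expected_combined = 1.0
    for i in range(n_parameters):
        prevalence = round(float(rng.uniform(lo, hi)), 3)
        k = max(1, round(prevalence * ref_n))
        prevalence = k / ref_n
        met = True if adulterated else bool(rng.random() < prevalence)
        if met:
            value = round(float(rng.uniform(6.0, 20.0)), 2)
        else:
            value = round(float(rng.uniform(0.0, 4.0)), 2)
        param = f"marker_{i + 1}"
        rows.append([
            param, "quantitative", f"{value:g}", "mg/kg", "0.5", "5", "0.1",
            "ge", "5", str(ref_n), str(k), "synthetic survey",
            "synthetic reference survey (generated fixture)",
        ])
        lr_if_met = ref_n / k
        truth_params.append({
            "parameter": param,
            "prevalence": prevalence,
            "condition_met": met,
            "value": value,
            "lr_if_met": lr_if_met,
        })
        if met:
            expected_combined *= lr_if_met
    truth = {
        "seed": int(seed),
        "adulterated": bool(adulterated),
        "parameters": truth_params,
        "expected_combined_lr": expected_combined,
    }
    coa_path = directory / f"coa_seed{seed}.csv"
    with open(coa_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COA_COLUMNS + COA_OPTIONAL_COLUMNS)
        writer.writerows(rows)
    truth_path = directory / f"coa_seed{seed}_truth.json"
    truth_path.write_text(json.dumps(truth, sort_keys=True, indent=2), encoding="utf-8")
    return coa_path, truth
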