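"""Domain types for likelihood-ratio evaluation of authenticity findings.

The vocabulary follows forensic evaluative reporting: a *finding* (one
analytical result from a certificate of analysis) is assessed against a
pair of mutually exclusive *propositions* — the sample is atypical of a
reference set of genuine products (Hp), or it is a typical sample whose
composition falls outside the reference set by chance or for a stated
reason (Hd).  Background prevalences come from *reference summaries*
(n genuine samples, k of which meet the evidence condition), and every
probability carries its provenance as a *probability assignment*.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from typing import Optional

__all__ = [
    "ValidationError",
    "PROPOSITION_LEVELS",
    "PROBABILITY_METHODS",
    "EvidenceCondition",
    "PropositionPair",
    "Finding",
    "ReferenceSummary",
    "ProbabilityAssignment",
    "make_source_propositions",
    "normalise_units",
]


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


#: Hierarchy of propositions: source (I), activity (II), offence (III).
#: Only source-level propositions are evaluated; the higher levels are
#: representable for completeness of the case file but carry no computation.
PROPOSITION_LEVELS = ("source", "activity", "offence")

PROBABILITY_METHODS = ("empirical", "laplace", "jeffreys", "upper_bound", "asserted")

_WS = re.compile(r"\s+")


def normalise_units(units: Optional[str]) -> Optional[str]:
    """Canonicalise a unit string (trim, collapse whitespace, lower-case).

    Units are opaque labels compared for equality; there is no conversion
    engine, since each parameter is reported in a single unit (DN, mg/kg...).
    """
    if units is None:
        return None
    return _WS.sub(" ", units.strip()).lower()


@dataclass(frozen=True)
class EvidenceCondition:
    """The predicate that turns a raw result into evidence E.

    Either a threshold predicate (``value <= threshold`` / ``value >=
    threshold`` in the stated units) or plain qualitative detection
    (``direction == "detected"``, e.g. "marker > LoQ").
    """

    direction: str  # "le", "ge" or "detected"
    threshold: Optional[float] = None
    units: Optional[str] = None

    def __post_init__(self) -> None:
        if self.direction not in ("le", "ge", "detected"):
            raise ValidationError(
                f"condition direction must be 'le', 'ge' or 'detected', got {self.direction!r}"
            )
        if self.direction == "detected":
            if self.threshold is not None:
                raise ValidationError("a 'detected' condition carries no threshold")
        else:
            if self.threshold is None:
                raise ValidationError("threshold conditions require a numeric threshold")

    def describe(self) -> str:
        if self.direction == "detected":
            return "detected (above LoQ)"
        op = "≤" if self.direction == "le" else "≥"
        units = f" {self.units}" if self.units else ""
        return f"{op} {self.threshold:g}{units}"

    def to_dict(self) -> dict:
        return {"direction": self.direction, "threshold": self.threshold, "units": self.units}

    @classmethod
    def from_dict(cls, d: dict) -> "EvidenceCondition":
        return cls(
            direction=d["direction"],
            threshold=d.get("threshold"),
            units=d.get("units"),
        )


@dataclass(frozen=True)
class PropositionPair:
    """Two mutually exclusive, exhaustive competing propositions.

    ``hp_text`` asserts atypicality relative to the reference set;
    ``hd_text`` asserts a genuine sample outside the reference set by
    chance or a stated reason.  ``parameter_id`` names the finding the
    pair addresses.
    """

    hp_text: str
    hd_text: str
    parameter_id: str
    level: str = "source"

    def __post_init__(self) -> None:
        if not self.hp_text.strip() or not self.hd_text.strip():
            raise ValidationError("both proposition texts must be non-empty")
        if self.hp_text.strip() == self.hd_text.strip():
            raise ValidationError("the two propositions must be distinct")
        if self.level not in PROPOSITION_LEVELS:
            raise ValidationError(
                f"level must be one of {PROPOSITION_LEVELS}, got {self.level!r}"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PropositionPair":
        return cls(
            hp_text=d["hp_text"],
            hd_text=d["hd_text"],
            parameter_id=d["parameter_id"],
            level=d.get("level", "source"),
        )


@dataclass(frozen=True)
class Finding:
    """One analytical result from a certificate of analysis.

    Quantitative findings carry ``value`` + ``units`` (e.g. diastase
    activity 4.4 DN); qualitative findings carry only ``detected``.
    ``lod``/``loq`` are the method's limits of detection/quantitation and
    ``mu`` its relative measurement uncertainty — all three are disclosure
    metadata: they are audited, never used to soften the binary evidence
    condition.
    """

    parameter: str
    mode: str  # "quantitative" or "qualitative"
    condition: EvidenceCondition
    value: Optional[float] = None
    units: Optional[str] = None
    detected: Optional[bool] = None
    lod: Optional[float] = None
    loq: Optional[float] = None
    mu: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.parameter.strip():
            raise ValidationError("finding parameter name must be non-empty")
        if self.mode not in ("quantitative", "qualitative"):
            raise ValidationError(f"mode must be quantitative or qualitative, got {self.mode!r}")
        if self.mode == "quantitative":
            if self.value is None:
                raise ValidationError(f"{self.parameter}: quantitative finding requires a value")
            if not self.units:
                raise ValidationError(f"{self.parameter}: quantitative finding requires units")
            if self.detected is not None:
                raise ValidationError(f"{self.parameter}: quantitative finding carries no detected flag")
            if self.condition.direction == "detected":
                raise ValidationError(
                    f"{self.parameter}: quantitative finding requires a threshold condition"
                )
            if normalise_units(self.condition.units) != normalise_units(self.units):
                raise ValidationError(
                    f"{self.parameter}: condition units {self.condition.units!r} "
                    f"do not match value units {self.units!r}"
                )
        else:
            if self.detected is None:
                raise ValidationError(f"{self.parameter}: qualitative finding requires detected flag")
            if self.value is not None:
                raise ValidationError(f"{self.parameter}: qualitative finding carries no value")
        if self.lod is not None and self.loq is not None and self.lod > self.loq:
            raise ValidationError(
                f"{self.parameter}: LoD ({self.lod:g}) must not exceed LoQ ({self.loq:g})"
            )

    @property
    def condition_met(self) -> bool:
        """Whether the observed result satisfies the evidence condition."""
        if self.mode == "qualitative":
            return bool(self.detected)
        assert self.value is not None and self.condition.threshold is not None
        if self.condition.direction == "le":
            return self.value <= self.condition.threshold
        return self.value >= self.condition.threshold

    def to_dict(self) -> dict:
        d = asdict(self)
        d["condition"] = self.condition.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Finding":
        d = dict(d)
        d["condition"] = EvidenceCondition.from_dict(d["condition"])
        return cls(**d)


@dataclass(frozen=True)
class ReferenceSummary:
    """Counts from a survey of genuine samples: k of n meet the condition."""

    n: int
    k: int
    population: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.n, int) or not isinstance(self.k, int):
            raise ValidationError("reference counts n and k must be integers")
        if self.n < 1:
            raise ValidationError(f"reference sample count n must be >= 1, got {self.n}")
        if not (0 <= self.k <= self.n):
            raise ValidationError(f"require 0 <= k <= n, got k={self.k}, n={self.n}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceSummary":
        return cls(n=d["n"], k=d["k"], population=d.get("population", ""), source=d.get("source", ""))


@dataclass(frozen=True)
class ProbabilityAssignment:
    """P(E|H) with provenance.

    ``method`` records how the number was obtained: an empirical
    proportion k/n, a small-count correction (Laplace (k+1)/(n+2) or
    Jeffreys (k+1/2)/(n+1)), an exact one-sided binomial upper bound, or
    a value asserted from experience.  ``interval`` is a two-sided exact
    (Clopper–Pearson) interval for count-based methods; asserted values
    carry none.  ``justification`` holds the free-text grounds for an
    asserted value, quoted verbatim in the report's disclosure section.
    """

    p: float
    method: str
    interval: Optional[tuple[float, float]] = None
    justification: str = ""

    def __post_init__(self) -> None:
        if self.method not in PROBABILITY_METHODS:
            raise ValidationError(f"unknown probability method {self.method!r}")
        if not (0.0 < self.p <= 1.0):
            raise ValidationError(f"probability must lie in (0, 1], got {self.p}")
        if self.interval is not None:
            lo, hi = self.interval
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValidationError(f"interval must satisfy 0 <= lo <= hi <= 1, got {self.interval}")
            if not (lo <= self.p <= hi):
                raise ValidationError(
                    f"interval {self.interval} must bracket the point value {self.p}"
                )

    def to_dict(self) -> dict:
        return {
            "p": self.p,
            "method": self.method,
            "interval": list(self.interval) if self.interval is not None else None,
            "justification": self.justification,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProbabilityAssignment":
        interval = d.get("interval")
        return cls(
            p=d["p"],
            method=d["method"],
            interval=tuple(interval) if interval is not None else None,
            justification=d.get("justification", ""),
        )


_HP_TEMPLATE = (
    "This honey sample is atypical owing to the finding for {parameter}: "
    "it contains compound(s) not found in, or is in some way untypical of, "
    "the reference dataset."
)
_HD_TEMPLATE = (
    "This honey sample is a typical sample with compositional or matrix "
    "parameters outside those represented in the reference set, {clause}."
)


def make_source_propositions(parameter: str, reason_text: str = "") -> PropositionPair:
    """Instantiate the standard source-level proposition pair for a parameter.

    Hp: the sample is atypical of the reference dataset owing to this
    finding.  Hd: the sample is typical but falls outside the reference
    set because of the stated reason, or by chance.  An empty
    ``reason_text`` yields the generic chance-only clause.
    """
    if not parameter.strip():
        raise ValidationError("parameter name must be non-empty")
    reason = reason_text.strip()
    clause = f"because {reason}, or arising by chance" if reason else "arising by chance"
    return PropositionPair(
        hp_text=_HP_TEMPLATE.format(parameter=parameter),
        hd_text=_HD_TEMPLATE.format(clause=clause),
        parameter_id=parameter,
        level="source",
    )


def to_json(obj) -> str:
    """Serialise any domain type to its JSON schema."""
    return json.dumps(obj.to_dict(), sort_keys=True)


def from_json(cls, payload: str):
    """Parse a domain type back from its JSON form."""
    return cls.from_dict(json.loads(payload))
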