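"""Probability assignment, likelihood ratios and verbal scales.

The weight of evidence for a finding E under competing propositions is

    LR = P(E | Hp) / P(E | Hd)

with no prior and no posterior: this module can state how much more
likely the findings are under one proposition than the other, and is
structurally unable to emit P(H | E).

P(E | Hd) is the background prevalence of the evidence condition among
genuine samples, estimated from reference counts (k of n) with a choice
of estimator, each accompanied by an exact (Clopper–Pearson) binomial
interval.  P(E | Hp) defaults to 1 for threshold-type findings — a
sample genuinely non-compliant with the condition meets it with
certainty — but smaller numerators are accepted.

LR point values formed from decimal probabilities are computed in exact
rational arithmetic, so 1/0.08 is exactly 12.5; rounding is left to the
report layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal
from fractions import Fraction
from typing import Optional

import yaml
from importlib import resources
from scipy.stats import beta

from .evidence_model import (
    ProbabilityAssignment,
    PropositionPair,
    ReferenceSummary,
    ValidationError,
)

__all__ = [
    "LikelihoodRatio",
    "Band",
    "VerbalScale",
    "prob_from_reference",
    "assert_probability",
    "likelihood_ratio",
    "verbal_equivalent",
    "orient",
    "clopper_pearson",
    "exact_fraction",
    "round_sig",
]


def exact_fraction(x) -> Fraction:
    """Exact rational value of a number via its decimal representation.

    Floats are read through their shortest decimal repr, so 0.08 becomes
    2/25 (the decimal a scientist wrote down), not the binary float.
    """
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    return Fraction(Decimal(str(x)))


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (display convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - math.floor(math.log10(abs(x))))


@dataclass(frozen=True)
class LikelihoodRatio:
    """A likelihood ratio with its two conditional probabilities.

    ``exact`` is the rational point value; ``value`` its float image.
    ``interval`` propagates the denominator's (and numerator's) binomial
    interval bounds through the division.
    """

    value: float
    numerator: ProbabilityAssignment
    denominator: ProbabilityAssignment
    interval: Optional[tuple[float, float]] = None
    exact: Optional[Fraction] = None

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValidationError(f"likelihood ratio must be positive, got {self.value}")
        if self.interval is not None:
            lo, hi = self.interval
            if not (0 <= lo <= self.value <= hi):
                raise ValidationError(
                    f"LR interval {self.interval} must bracket the point value {self.value}"
                )

    def to_dict(self) -> dict:
        return {
            "value": self.value,
            "numerator": self.numerator.to_dict(),
            "denominator": self.denominator.to_dict(),
            "interval": list(self.interval) if self.interval is not None else None,
        }

    @classmethod
    def from_value(cls, value, note: str = "(direct value)") -> "LikelihoodRatio":
        """Build an LR from a bare value (P(E|Hp)=1, P(E|Hd)=1/value), exactly."""
        exact = exact_fraction(value)
        if exact <= 0:
            raise ValidationError(f"likelihood ratio must be positive, got {value}")
        num = ProbabilityAssignment(p=1.0, method="asserted", justification=note)
        den = ProbabilityAssignment(p=float(1 / exact), method="asserted", justification=note)
        return cls(value=float(exact), numerator=num, denominator=den, exact=exact)


@dataclass(frozen=True)
class Band:
    """One row of a verbal scale: lower-exclusive, upper-inclusive."""

    lower: float
    upper: float  # math.inf for the unbounded top band
    label: str

    def contains(self, value: float) -> bool:
        if self.lower == self.upper:  # the point band at LR = 1
            return value == self.lower
        return self.lower < value <= self.upper


@dataclass(frozen=True)
class VerbalScale:
    """An agreed mapping from LR bands to strength-of-evidence phrases.

    The band convention is ``lower < LR <= upper`` with a point band
    [1, 1] labelled Null at the bottom and an unbounded top band.
    """

    name: str
    bands: tuple[Band, ...]

    def __post_init__(self) -> None:
        if len(self.bands) < 2:
            raise ValidationError("a verbal scale needs at least the Null band and one support band")
        first = self.bands[0]
        if not (first.lower == first.upper == 1):
            raise ValidationError("first band must be the point band [1, 1]")
        if math.isfinite(self.bands[-1].upper):
            raise ValidationError("last band must be unbounded above")
        prev_upper = first.upper
        for band in self.bands[1:]:
            if band.lower != prev_upper:
                raise ValidationError(
                    f"bands must be contiguous: expected lower {prev_upper}, got {band.lower}"
                )
            if not band.upper > band.lower:
                raise ValidationError("band bounds must be strictly increasing")
            prev_upper = band.upper

    def band_for(self, value: float) -> Band:
        for band in self.bands:
            if band.contains(value):
                return band
        raise ValidationError(f"LR {value} is below the scale (scales start at 1)")

    @staticmethod
    def _from_entries(name: str, entries: list[dict]) -> "VerbalScale":
        bands = tuple(
            Band(
                lower=float(e["lower"]),
                upper=math.inf if e.get("upper") is None else float(e["upper"]),
                label=str(e["label"]),
            )
            for e in entries
        )
        return VerbalScale(name=name, bands=bands)

    @classmethod
    def builtin(cls, name: str) -> "VerbalScale":
        """Load one of the shipped scales ("ENFSI" or "literature")."""
        text = resources.files("evallr").joinpath("data/scales.yaml").read_text()
        scales = yaml.safe_load(text)["scales"]
        key = {k.lower(): k for k in scales}.get(name.lower())
        if key is None:
            raise ValidationError(f"unknown built-in scale {name!r}; have {sorted(scales)}")
        return cls._from_entries(key, scales[key])

    @classmethod
    def from_yaml(cls, path) -> "VerbalScale":
        """Load a user-supplied scale from a YAML file in the shipped schema."""
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        scales = doc["scales"]
        name, entries = next(iter(scales.items()))
        return cls._from_entries(name, entries)


def clopper_pearson(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval for k successes in n."""
    if not 0 < confidence < 1:
        raise ValidationError(f"confidence must be in (0, 1), got {confidence}")
    alpha = 1.0 - confidence
    lo = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def prob_from_reference(
    ref: ReferenceSummary,
    method: str = "empirical",
    confidence: float = 0.95,
) -> ProbabilityAssignment:
    """Assign P(E|Hd) from reference counts.

    Estimators: ``empirical`` k/n (forbidden at k = 0 — an observed zero
    is not a usable denominator), ``laplace`` (k+1)/(n+2), ``jeffreys``
    (k+1/2)/(n+1), and ``upper_bound``, the exact one-sided binomial
    upper confidence limit at ``confidence``.  Every assignment carries
    the two-sided Clopper–Pearson interval at the same level.
    """
    n, k = ref.n, ref.k
    if method == "empirical":
        if k == 0:
            raise ValidationError(
                "empirical probability is undefined for k = 0: use a correction "
                "(laplace/jeffreys/upper_bound) or assert_probability with stated grounds"
            )
        p = k / n
    elif method == "laplace":
        p = (k + 1) / (n + 2)
    elif method == "jeffreys":
        p = (k + 0.5) / (n + 1)
    elif method == "upper_bound":
        if not 0 < confidence < 1:
            raise ValidationError(f"confidence must be in (0, 1), got {confidence}")
        p = 1.0 if k == n else float(beta.ppf(confidence, k + 1, n - k))
    else:
        raise ValidationError(f"unknown estimation method {method!r}")
    interval = clopper_pearson(k, n, confidence)
    just = f"{method} from k={k} of n={n} genuine samples"
    if ref.population:
        just += f" ({ref.population})"
    if ref.source:
        just += f"; source: {ref.source}"
    return ProbabilityAssignment(p=p, method=method, interval=interval, justification=just)


def assert_probability(p: float, justification: str) -> ProbabilityAssignment:
    """Record a probability asserted from experience rather than counts.

    The justification is mandatory: an asserted number without stated
    grounds cannot be disclosed, so it cannot enter a report.
    """
    if not justification.strip():
        raise ValidationError("an asserted probability requires a non-empty justification")
    if not (0.0 < p <= 1.0):
        raise ValidationError(f"probability must lie in (0, 1], got {p}")
    return ProbabilityAssignment(p=p, method="asserted", interval=None, justification=justification)


def likelihood_ratio(
    num: ProbabilityAssignment | float,
    den: ProbabilityAssignment | float,
) -> LikelihoodRatio:
    """Form LR = P(E|Hp) / P(E|Hd).

    Bare floats are accepted for convenience and wrapped as asserted
    assignments.  Interval bounds divide as (num.lo/den.hi, num.hi/den.lo);
    a zero lower denominator bound yields an unbounded upper LR bound.
    """
    exact_num = exact_fraction(num.p if isinstance(num, ProbabilityAssignment) else num)
    exact_den = exact_fraction(den.p if isinstance(den, ProbabilityAssignment) else den)
    if not isinstance(num, ProbabilityAssignment):
        num = ProbabilityAssignment(p=float(num), method="asserted", justification="(direct value)")
    if not isinstance(den, ProbabilityAssignment):
        den = ProbabilityAssignment(p=float(den), method="asserted", justification="(direct value)")
    if den.p <= 0:
        raise ValidationError("denominator probability must be positive")
    exact = exact_num / exact_den
    num_lo, num_hi = num.interval if num.interval is not None else (num.p, num.p)
    interval = None
    if num.interval is not None or den.interval is not None:
        den_lo, den_hi = den.interval if den.interval is not None else (den.p, den.p)
        lo = num_lo / den_hi if den_hi > 0 else math.inf
        hi = num_hi / den_lo if den_lo > 0 else math.inf
        interval = (lo, hi)
    return LikelihoodRatio(
        value=float(exact), numerator=num, denominator=den, interval=interval, exact=exact
    )


def verbal_equivalent(
    lr: LikelihoodRatio | float,
    scale: VerbalScale,
    conservative_margin: float = 2.0,
) -> tuple[str, Band, bool]:
    """Map an oriented LR (>= 1) to its verbal phrase on a scale.

    Band demarcations are treated conservatively: an LR within
    ``conservative_margin`` of its band's lower bound (value <= lower ×
    margin) is reported one band lower, flagged ``downgraded``.  The
    downgrade never goes below the first support band, and never applies
    at the Null band.
    """
    value = lr.value if isinstance(lr, LikelihoodRatio) else float(lr)
    if value < 1:
        raise ValidationError("verbal scales apply to the supported proposition: orient the LR first")
    if conservative_margin < 1:
        raise ValidationError(f"conservative margin must be >= 1, got {conservative_margin}")
    band = scale.band_for(value)
    idx = scale.bands.index(band)
    downgraded = False
    # idx 0 is Null, idx 1 the lowest support band: neither can be lowered.
    if idx >= 2 and value <= band.lower * conservative_margin:
        band = scale.bands[idx - 1]
        downgraded = True
    return band.label, band, downgraded


def orient(
    lr: LikelihoodRatio,
    pair: Optional[PropositionPair] = None,
) -> tuple[LikelihoodRatio, Optional[str]]:
    """Express an LR relative to the proposition it supports.

    Verbal scales are defined only for the supported proposition, so an
    LR below 1 is replaced by its reciprocal (numerator and denominator
    swapped) and marked as supporting Hd.  LR = 1 supports neither.
    Idempotent: orienting an oriented LR changes nothing.
    """
    if lr.value > 1:
        return lr, "Hp"
    if lr.value == 1:
        return lr, None
    exact = (Fraction(1) / lr.exact) if lr.exact else exact_fraction(1) / exact_fraction(lr.value)
    interval = None
    if lr.interval is not None:
        lo, hi = lr.interval
        interval = (1.0 / hi if hi > 0 else 0.0, 1.0 / lo if lo > 0 else math.inf)
    flipped = LikelihoodRatio(
        value=float(exact),
        numerator=lr.denominator,
        denominator=lr.numerator,
        interval=interval,
        exact=exact,
    )
    return flipped, "Hd"
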