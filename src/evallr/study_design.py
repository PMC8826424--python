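"""Reference-dataset sizing: inverting the likelihood-ratio framework.

Given a desired strength of evidence (a target LR) and the convention
P(E|Hp) = 1, the largest tolerable background prevalence of the evidence
condition among genuine samples is simply 1/LR — e.g. moderate support
(LR > 100) requires that no more than 1% of genuine honeys show the
marker, and strong-to-very-strong support (LR > 1000) no more than 0.1%.
``required_reference_size`` turns that into a survey size: the smallest
number of genuine samples that, with a given observed count and a chosen
small-count correction or exact upper bound, demonstrates a prevalence
at or below the target.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from scipy.stats import beta

from .evidence_model import ValidationError
from .likelihood import exact_fraction

__all__ = [
    "DesignTarget",
    "SizingResult",
    "max_background_prevalence",
    "required_reference_size",
]

SIZING_CORRECTIONS = ("upper_bound", "laplace", "jeffreys")

#: Search ceiling for the survey size; beyond this the design is reported
#: infeasible rather than searched further.
N_MAX = 100_000_000


@dataclass(frozen=True)
class DesignTarget:
    """Target strength of evidence for a planned reference survey."""

    target_lr: float
    confidence: float = 0.95  # used by the upper_bound correction
    correction: str = "laplace"

    def __post_init__(self) -> None:
        if self.target_lr <= 1:
            raise ValidationError(f"target LR must exceed 1, got {self.target_lr}")
        if not (0.0 < self.confidence < 1.0):
            raise ValidationError(f"confidence must lie in (0, 1), got {self.confidence}")
        if self.correction not in SIZING_CORRECTIONS:
            raise ValidationError(
                f"correction must be one of {SIZING_CORRECTIONS}, got {self.correction!r}"
            )


@dataclass(frozen=True)
class SizingResult:
    """Outcome of a sizing computation; infeasibility is a result, not an error."""

    feasible: bool
    n: int | None
    achieved_p: float | None
    target_lr: float
    max_prevalence: float
    correction: str
    confidence: float
    observed_k: int
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "feasible": self.feasible,
            "n": self.n,
            "achieved_p": self.achieved_p,
            "target_lr": self.target_lr,
            "max_prevalence": self.max_prevalence,
            "correction": self.correction,
            "confidence": self.confidence,
            "observed_k": self.observed_k,
            "message": self.message,
        }


def max_background_prevalence(target_lr: float) -> float:
    """Largest P(E|Hd) compatible with LR >= target, given P(E|Hp) = 1.

    Exact in rational arithmetic for decimal targets (1000 -> 0.001).
    A target of 1 imposes no constraint and returns 1.0.
    """
    if target_lr < 1:
        raise ValidationError(f"target LR must be at least 1, got {target_lr}")
    return float(Fraction(1) / exact_fraction(target_lr))


def _bound(correction: str, k: int, n: int, confidence: float) -> float:
    if correction == "laplace":
        return (k + 1) / (n + 2)
    if correction == "jeffreys":
        return (k + 0.5) / (n + 1)
    # exact one-sided binomial upper confidence limit
    if k == n:
        return 1.0
    return float(beta.ppf(confidence, k + 1, n - k))


def required_reference_size(target: DesignTarget, observed_k: int = 0) -> SizingResult:
    """Smallest survey size n demonstrating prevalence <= 1/target_lr.

    The chosen correction/bound applied to (observed_k, n) is strictly
    decreasing in n for fixed k, so the answer is found by exponential
    doubling followed by integer bisection and verified at n-1.
    """
    if observed_k < 0:
        raise ValidationError(f"observed count must be >= 0, got {observed_k}")
    p_target = max_background_prevalence(target.target_lr)

    def ok(n: int) -> bool:
        return _bound(target.correction, observed_k, n, target.confidence) <= p_target

    n_lo = max(observed_k, 1)
    if ok(n_lo):
        n_star = n_lo
    else:
        hi = n_lo
        while not ok(hi):
            hi *= 2
            if hi > N_MAX:
                return SizingResult(
                    feasible=False, n=None, achieved_p=None,
                    target_lr=target.target_lr, max_prevalence=p_target,
                    correction=target.correction, confidence=target.confidence,
                    observed_k=observed_k,
                    message=(
                        f"no n <= {N_MAX} brings the {target.correction} bound with "
                        f"k={observed_k} down to {p_target:g}; the target strength "
                        "cannot be demonstrated with this design"
                    ),
                )
        lo = hi // 2  # ok(lo) is False, ok(hi) is True
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if ok(mid):
                hi = mid
            else:
                lo = mid
        n_star = hi
    achieved = _bound(target.correction, observed_k, n_star, target.confidence)
    return SizingResult(
        feasible=True, n=n_star, achieved_p=achieved,
        target_lr=target.target_lr, max_prevalence=p_target,
        correction=target.correction, confidence=target.confidence,
        observed_k=observed_k,
        message=(
            f"analyse {n_star} genuine samples; with {observed_k} positives the "
            f"{target.correction} estimate is {achieved:.3g} <= {p_target:g}"
        ),
    )
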