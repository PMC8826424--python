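"""Aggregation of per-finding likelihood ratios into an overall LR.

Multiplying LRs is only defensible when the findings are independent.
Findings believed to be correlated are placed in a *correlation group*;
within a group only the largest LR is counted (a deliberately
conservative rule — no attempt is made to model the joint distribution),
and the group maxima are multiplied across groups.  All LRs must be
oriented to the same proposition direction before combination; mixing
evidence for and against is rejected rather than silently multiplied.

``misleading_evidence_rate`` stress-tests a panel design: it simulates
genuine samples under a binary-marker model and estimates how often
their combined LR nevertheless reaches a strength threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Optional, Sequence

import numpy as np

from .evidence_model import ValidationError
from .likelihood import LikelihoodRatio, exact_fraction

__all__ = [
    "CombinationGroup",
    "CombinationPlan",
    "CombinedLR",
    "combine",
    "misleading_evidence_rate",
]


@dataclass(frozen=True)
class CombinationGroup:
    """A set of finding ids treated as fully correlated."""

    ids: tuple[str, ...]
    note: str = ""

    def __post_init__(self) -> None:
        if not self.ids:
            raise ValidationError("a correlation group must contain at least one finding")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError(f"duplicate finding ids within a group: {self.ids}")


@dataclass(frozen=True)
class CombinationPlan:
    """A partition of the findings being combined into correlation groups."""

    groups: tuple[CombinationGroup, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.groups:
            overlap = seen & set(g.ids)
            if overlap:
                raise ValidationError(f"finding ids appear in more than one group: {sorted(overlap)}")
            seen |= set(g.ids)

    @property
    def all_ids(self) -> set[str]:
        return {i for g in self.groups for i in g.ids}

    @classmethod
    def singletons(cls, ids: Sequence[str]) -> "CombinationPlan":
        """Every finding in its own group — full independence assumed."""
        return cls(groups=tuple(CombinationGroup(ids=(i,), note="independence assumed") for i in ids))

    @classmethod
    def from_lists(cls, groups: Sequence[Sequence[str]], notes: Optional[Sequence[str]] = None) -> "CombinationPlan":
        notes = notes or [""] * len(groups)
        return cls(groups=tuple(
            CombinationGroup(ids=tuple(ids), note=note) for ids, note in zip(groups, notes)
        ))

    def to_dict(self) -> dict:
        return {"groups": [{"ids": list(g.ids), "note": g.note} for g in self.groups]}


@dataclass(frozen=True)
class CombinedLR:
    """Overall LR with its per-group breakdown.

    ``independence_assumed`` is set whenever a default singleton plan was
    generated because the caller supplied none — the report must warn
    that independence was an assumption, not a finding.
    """

    value: float
    exact: Fraction
    interval: Optional[tuple[float, float]]
    breakdown: tuple[dict, ...]
    plan: CombinationPlan
    independence_assumed: bool = False

    def to_dict(self) -> dict:
        return {
            "value": self.value,
            "interval": list(self.interval) if self.interval is not None else None,
            "breakdown": [dict(b) for b in self.breakdown],
            "plan": self.plan.to_dict(),
            "independence_assumed": self.independence_assumed,
        }


def combine(
    lrs: Mapping[str, LikelihoodRatio],
    plan: Optional[CombinationPlan] = None,
) -> CombinedLR:
    """Combine per-finding LRs: max within each correlation group, product across.

    Requires every LR to be oriented (value >= 1); combining evidence
    pointing in opposite directions is an error, not a multiplication.
    Interval bounds follow the same max/product rules.  The result is
    invariant to group order and to finding order within a group, and a
    series of inconclusive findings (all LR = 1) combines to exactly 1.
    """
    if not lrs:
        raise ValidationError("no likelihood ratios to combine")
    below = [i for i, lr in lrs.items() if lr.value < 1]
    if below:
        raise ValidationError(
            f"LRs below 1 must be oriented before combination (offending ids: {sorted(below)}); "
            "mixed-direction evidence cannot be multiplied"
        )
    independence_assumed = plan is None
    if plan is None:
        plan = CombinationPlan.singletons(sorted(lrs))
    if plan.all_ids != set(lrs):
        missing = sorted(set(lrs) - plan.all_ids)
        extra = sorted(plan.all_ids - set(lrs))
        raise ValidationError(
            f"combination plan must cover exactly the findings being combined "
            f"(missing from plan: {missing}; not being combined: {extra})"
        )

    total = Fraction(1)
    lo_total, hi_total = 1.0, 1.0
    any_interval = any(lr.interval is not None for lr in lrs.values())
    breakdown = []
    for group in plan.groups:
        # conservative rule for correlated findings: count only the largest
        rep = max(group.ids, key=lambda i: (lrs[i].value, i))
        rep_lr = lrs[rep]
        exact = rep_lr.exact if rep_lr.exact is not None else exact_fraction(rep_lr.value)
        total *= exact
        glo, ghi = rep_lr.interval if rep_lr.interval is not None else (rep_lr.value, rep_lr.value)
        lo_total *= glo
        hi_total *= ghi
        breakdown.append({
            "ids": sorted(group.ids),
            "note": group.note,
            "contributing_id": rep,
            "contribution": rep_lr.value,
        })
    interval = (lo_total, hi_total) if any_interval else None
    return CombinedLR(
        value=float(total),
        exact=total,
        interval=interval,
        breakdown=tuple(breakdown),
        plan=plan,
        independence_assumed=independence_assumed,
    )


def misleading_evidence_rate(
    prevalences: Sequence[float],
    plan: Optional[CombinationPlan] = None,
    threshold: float = 100.0,
    reps: int = 100_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo rate at which genuine samples reach a combined LR threshold.

    Binary-marker model: marker i occurs in a genuine sample (Hd) with
    probability ``prevalences[i]`` and with certainty under Hp.  Markers
    in the same correlation group are fully dependent — one shared
    uniform draw per group — and groups are independent.  The combined
    LR of a simulated sample is the joint-evidence LR: 0 if any marker
    is absent (an evidence pattern impossible under Hp), otherwise the
    group-max/across-group-product of the per-marker LRs 1/prevalence.
    Under this model P(LR >= t | Hd) <= 1/t for every t >= 1.

    Deterministic given ``seed``.
    """
    prevalences = list(prevalences)
    if not prevalences:
        raise ValidationError("at least one marker prevalence is required")
    for p in prevalences:
        if not (0.0 < p < 1.0):
            raise ValidationError(f"prevalences must lie strictly in (0, 1), got {p}")
    if threshold < 1:
        raise ValidationError(f"strength threshold must be >= 1, got {threshold}")
    if reps < 1000:
        raise ValidationError(f"need at least 1000 replicates for a usable estimate, got {reps}")
    ids = [str(i) for i in range(len(prevalences))]
    if plan is None:
        plan = CombinationPlan.singletons(ids)
    if plan.all_ids != set(ids):
        raise ValidationError(
            f"plan must partition marker indices 0..{len(prevalences) - 1} as string ids"
        )

    rng = np.random.default_rng(seed)
    # If all markers are present the combined LR is a constant: product over
    # groups of the largest per-marker LR in the group.
    value_if_all_present = 1.0
    group_min_prev = []
    for group in plan.groups:
        prevs = [prevalences[int(i)] for i in group.ids]
        value_if_all_present *= 1.0 / min(prevs)  # max LR = 1 / smallest prevalence
        group_min_prev.append(min(prevs))
    # Comonotone within a group: one uniform per group; every group member is
    # present iff u < min(prevalences in group).
    u = rng.random((reps, len(plan.groups)))
    all_present = np.all(u < np.asarray(group_min_prev), axis=1)
    lr = np.where(all_present, value_if_all_present, 0.0)
    return float(np.mean(lr >= threshold))
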