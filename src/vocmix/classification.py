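"""MCR substance groups: screening categories for mixture-driven risk.

A classifiable result (at least one contributing HQ) falls in exactly
one group, evaluated in strict precedence:

    I     maxHQ ≥ 1            single-substance concern
    II    HI < 1               low concern
    IIIA  MCR < 2              combined effect dominated by one substance
    IIIB  otherwise (MCR ≥ 2)  combined effect of several substances

The raw region definitions overlap (maxHQ > 1 with MCR < 2 satisfies
both I and IIIA) and leave boundaries open; precedence plus the
configurable boundary assignments (maxHQ = 1 → I, MCR = cutoff → IIIB
by default) make the partition exhaustive and mutually exclusive.

Substances of concern: group I names every chemical with HQ ≥ 1; IIIA
names the dominant (maxHQ) chemical; IIIB names the chemicals jointly
contributing ≥ 90% of HI in descending HQ order — a package convention,
since no published rule pins down the IIIB list.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from .datamodel import ChemicalDescriptor, RunConfig
from .errors import DomainError
from .metrics import RiskResult

__all__ = ["McrGroup", "McrGroupAssignment", "CohortClassification", "classify", "classify_cohort"]

logger = logging.getLogger(__name__)

#: Share of HI that the named group-IIIB substances must jointly reach.
IIIB_CONCERN_SHARE = 0.90


class McrGroup(str, Enum):
    I = "I"
    II = "II"
    IIIA = "IIIA"
    IIIB = "IIIB"


@dataclass
class McrGroupAssignment:
    group: McrGroup
    substances_of_concern: list[ChemicalDescriptor]
    rationale: str

    def __post_init__(self) -> None:
        if self.group is McrGroup.I and not self.substances_of_concern:
            raise DomainError("group I requires at least one substance of concern")


def _descending_hq(result: RiskResult) -> list[tuple[ChemicalDescriptor, float]]:
    return sorted(result.hq_by_chemical.items(), key=lambda kv: (-kv[1], kv[0].name))


def classify(result: RiskResult, config: RunConfig | None = None) -> McrGroupAssignment:
    """Assign one classifiable result to its MCR substance group."""
    config = config or RunConfig()
    if result.n_contributing < 1:
        raise DomainError(
            f"{result.id}: no contributing hazard quotients; unclassifiable"
        )
    hi, peak, mcr = result.hi, result.max_hq, result.mcr
    ranked = _descending_hq(result)

    in_group_i = peak > 1.0 or (peak == 1.0 and config.group_i_boundary_inclusive)
    if in_group_i:
        if peak == 1.0:
            logger.info("%s: maxHQ exactly 1; boundary assigned to group I", result.id)
        concern = [c for c, hq in ranked if hq > 1.0 or (hq == 1.0 and config.group_i_boundary_inclusive)]
        return McrGroupAssignment(
            McrGroup.I,
            concern,
            f"maxHQ {peak:.3g} >= 1: single substance concern ({concern[0].name})",
        )
    if hi < 1.0:
        return McrGroupAssignment(
            McrGroup.II, [], f"HI {hi:.3g} < 1: low concern"
        )
    cutoff = config.mcr_dominance_cutoff
    in_iiia = mcr < cutoff or (mcr == cutoff and not config.mcr_boundary_to_iiib)
    if mcr == cutoff:
        side = "IIIB" if config.mcr_boundary_to_iiib else "IIIA"
        logger.info("%s: MCR exactly %.3g; boundary assigned to group %s", result.id, cutoff, side)
    if in_iiia:
        dominant = result.max_hq_chemical
        return McrGroupAssignment(
            McrGroup.IIIA,
            [dominant],
            f"HI {hi:.3g} >= 1, MCR {mcr:.3g} < {cutoff:.3g}: combined effect "
            f"dominated by {dominant.name}",
        )
    concern = []
    cumulative = 0.0
    for chem, hq in ranked:
        concern.append(chem)
        cumulative += hq
        if cumulative >= IIIB_CONCERN_SHARE * hi:
            break
    return McrGroupAssignment(
        McrGroup.IIIB,
        concern,
        f"HI {hi:.3g} >= 1, maxHQ {peak:.3g} < 1, MCR {mcr:.3g} >= {cutoff:.3g}: "
        f"combined effect of several substances",
    )


@dataclass
class CohortClassification:
    """Group tallies at sample and salon scope plus per-result detail."""

    tally_by_scope: dict[str, Counter] = field(default_factory=dict)
    assignments: list[tuple[str, str, McrGroup, list[ChemicalDescriptor]]] = field(
        default_factory=list
    )  # (scope, id, group, substances of concern)
    n_unclassifiable: int = 0

    def tally(self, scope: str) -> Counter:
        return self.tally_by_scope.get(scope, Counter())


def classify_cohort(
    results: Iterable[RiskResult], config: RunConfig | None = None
) -> CohortClassification:
    """Classify every result, tallying groups per scope.

    Results with an empty contribution set are counted as unclassifiable
    rather than raising, so one all-unresolved sample never aborts a
    cohort run.
    """
    config = config or RunConfig()
    cohort = CohortClassification()
    for res in results:
        if res.n_contributing < 1:
            cohort.n_unclassifiable += 1
            continue
        a = classify(res, config)
        cohort.tally_by_scope.setdefault(res.scope, Counter())[a.group] += 1
        cohort.assignments.append((res.scope, res.id, a.group, a.substances_of_concern))
    return cohort
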