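"""Exposure measures: TVOC, hazard quotients, hazard index, and MCR.

For one sample with concentrations Cᵢ (µg/m³ toluene equivalents) and
resolved limit values RVᵢ:

    HQᵢ  = Cᵢ / RVᵢ                  (hazard quotient, dimensionless)
    HI   = Σᵢ HQᵢ                    (hazard index)
    MCR  = HI / max HQᵢ              (maximum cumulative ratio, ∈ [1, n])

TVOC is the sum of concentrations over analytes in the TVOC window.
Censored analytes contribute to none of these; analytes without a
resolvable limit value still count toward TVOC but are excluded from HI
(listed on the result's ``unresolved`` trail). HI ≥ 1 (by default) flags
potential non-cancer risk; MCR measures how mixture-driven that risk is.
All values are kept at full precision — rounding is a report-time
concern only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .datamodel import ChemicalDescriptor, MeasurementSample, RunConfig
from .errors import DomainError, ValidationError
from .registry import ReferenceEntry, ReferenceRegistry, resolve_reference

__all__ = [
    "RiskResult",
    "compute_tvoc",
    "hazard_quotient",
    "hazard_index",
    "max_hq",
    "maximum_cumulative_ratio",
    "salon_aggregate",
]

logger = logging.getLogger(__name__)


@dataclass
class RiskResult:
    """TVOC, HI, maxHQ, MCR and the HQ breakdown for one sample or salon."""

    scope: str  # "sample" | "salon"
    id: str
    tvoc: float
    hq_by_chemical: dict[ChemicalDescriptor, float]
    hi: float
    max_hq_chemical: Optional[ChemicalDescriptor]
    max_hq: float
    mcr: Optional[float]
    n_contributing: int
    risk_flag: bool
    unresolved: list[ChemicalDescriptor] = field(default_factory=list)
    salon_id: str = ""

    def __post_init__(self) -> None:
        if self.scope not in ("sample", "salon"):
            raise ValidationError(f"scope must be 'sample' or 'salon', got {self.scope!r}")
        total = sum(self.hq_by_chemical.values())
        if not math.isclose(self.hi, total, rel_tol=1e-9, abs_tol=1e-12):
            raise ValidationError(f"hi={self.hi} != sum of HQs {total}")
        peak = max(self.hq_by_chemical.values(), default=0.0)
        if not math.isclose(self.max_hq, peak, rel_tol=1e-9, abs_tol=1e-12):
            raise ValidationError(f"max_hq={self.max_hq} != max of HQs {peak}")
        if self.n_contributing >= 1 and self.mcr is not None:
            if not (1 - 1e-9 <= self.mcr <= self.n_contributing + 1e-9):
                raise ValidationError(
                    f"mcr={self.mcr} outside [1, {self.n_contributing}]"
                )


def compute_tvoc(sample: MeasurementSample) -> float:
    """Total VOC concentration (µg/m³): sum over TVOC-window analytes.

    Censored analytes carry no value and contribute nothing; analytes
    flagged out of the elution window are skipped.
    """
    return sum(v for c, v in sample.concentrations.items() if c.tvoc_included)


def hazard_quotient(c: float, ref: ReferenceEntry) -> float:
    """HQᵢ = Cᵢ / RVᵢ at full precision."""
    if not c > 0:
        raise DomainError(f"concentration must be > 0, got {c}")
    if not ref.value > 0:
        raise DomainError(f"limit value must be > 0, got {ref.value}")
    return c / ref.value


def _build_result(
    scope: str,
    result_id: str,
    tvoc: float,
    hq_map: dict[ChemicalDescriptor, float],
    unresolved: list[ChemicalDescriptor],
    config: RunConfig,
    salon_id: str = "",
) -> RiskResult:
    hi = sum(hq_map.values())
    chem, peak = _max_entry(hq_map)
    mcr = hi / peak if peak > 0 else None
    return RiskResult(
        scope=scope,
        id=result_id,
        tvoc=tvoc,
        hq_by_chemical=hq_map,
        hi=hi,
        max_hq_chemical=chem,
        max_hq=peak,
        mcr=mcr,
        n_contributing=len(hq_map),
        risk_flag=config.flags_risk(hi),
        unresolved=unresolved,
        salon_id=salon_id,
    )


def hazard_index(
    sample: MeasurementSample,
    registry: ReferenceRegistry,
    config: RunConfig | None = None,
) -> RiskResult:
    """HQ for every uncensored, resolvable analyte; HI is their sum.

    Analytes with no limit value in any tier are excluded from HI (they
    remain in TVOC) and listed on ``unresolved``. An empty contribution
    set yields HI 0 with a prominent warning rather than an error.
    """
    config = config or RunConfig()
    hq_map: dict[ChemicalDescriptor, float] = {}
    unresolved: list[ChemicalDescriptor] = []
    for chem, conc in sample.concentrations.items():
        ref = resolve_reference(chem, registry)
        if ref is None:
            unresolved.append(chem)
        else:
            hq_map[chem] = hazard_quotient(conc, ref)
    if not hq_map:
        logger.warning(
            "sample %s/%s: no analyte could be resolved to a limit value; "
            "HI is 0 and certainly underestimates risk",
            sample.salon_id,
            sample.worker_id,
        )
    return _build_result(
        scope="sample",
        result_id=f"{sample.salon_id}/{sample.worker_id}",
        tvoc=compute_tvoc(sample),
        hq_map=hq_map,
        unresolved=unresolved,
        config=config,
        salon_id=sample.salon_id,
    )


def _max_entry(
    hq_map: dict[ChemicalDescriptor, float]
) -> tuple[Optional[ChemicalDescriptor], float]:
    """Maximum HQ and its chemical; exact ties go to the lexicographically
    first name (logged)."""
    if not hq_map:
        return None, 0.0
    peak = max(hq_map.values())
    winners = sorted((c for c, v in hq_map.items() if v == peak), key=lambda c: c.name)
    if len(winners) > 1:
        logger.info(
            "maxHQ tie at %.6g between %s; choosing %s (lexicographic)",
            peak,
            [c.name for c in winners],
            winners[0].name,
        )
    return winners[0], peak


def max_hq(result: RiskResult) -> Optional[tuple[ChemicalDescriptor, float]]:
    """The chemical attaining the maximum HQ, and its value.

    Returns ``None`` (absence, not an exception) for an empty
    contribution set.
    """
    chem, peak = _max_entry(result.hq_by_chemical)
    return None if chem is None else (chem, peak)


def maximum_cumulative_ratio(hi: float, max_hq_value: float) -> Optional[float]:
    """MCR = HI / maxHQ; ``None`` when maxHQ is 0 (never a zero division)."""
    if max_hq_value == 0:
        return None
    if max_hq_value < 0 or hi < max_hq_value * (1 - 1e-12):
        raise DomainError(f"need hi >= max_hq > 0, got hi={hi}, max_hq={max_hq_value}")
    return hi / max_hq_value


def salon_aggregate(
    results: Sequence[RiskResult], config: RunConfig | None = None
) -> RiskResult:
    """Aggregate one salon's sample results into a salon-scope result.

    The salon HQ map is the arithmetic mean of the per-sample HQ maps
    (a chemical absent from a sample counts as 0), and HI, maxHQ and MCR
    are recomputed from that mean map. Because averaging commutes with
    the HI summation, the salon HI equals the arithmetic mean of the
    sample HIs. TVOC is likewise the arithmetic mean.
    """
    config = config or RunConfig()
    results = list(results)
    if not results:
        raise ValidationError("salon_aggregate: need at least one sample result")
    salon_ids = {r.salon_id or r.id.split("/")[0] for r in results}
    if len(salon_ids) != 1:
        raise ValidationError(f"salon_aggregate: mixed salon ids {sorted(salon_ids)}")
    salon_id = salon_ids.pop()

    n = len(results)
    mean_map: dict[ChemicalDescriptor, float] = {}
    for res in results:
        for chem, hq in res.hq_by_chemical.items():
            mean_map[chem] = mean_map.get(chem, 0.0) + hq / n
    unresolved = sorted(
        {c for r in results for c in r.unresolved}, key=lambda c: c.name
    )
    return _build_result(
        scope="salon",
        result_id=salon_id,
        tvoc=sum(r.tvoc for r in results) / n,
        hq_map=mean_map,
        unresolved=unresolved,
        config=config,
        salon_id=salon_id,
    )
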