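"""Reference-value registry and the four-tier limit-value hierarchy.

Every hazard quotient needs one limit value RVᵢ per chemical. Chronic
health-based reference values (RVs) are preferred; where none exists the
fallback order is the Swedish occupational exposure limit (OEL), then the
lowest Nordic OEL, then the lowest international OEL. A chemical with no
limit value in any tier is excluded from the hazard index (never fatal:
it still counts toward TVOC, and the exclusion is logged).

The hierarchy is strict by tier, not by magnitude across tiers: a
numerically lower OEL never overrides an existing RV. Within the Nordic
and international tiers, which may hold several national limits, the
lowest value is chosen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Optional

from .datamodel import ChemicalDescriptor
from .errors import ValidationError

__all__ = [
    "Tier",
    "ReferenceEntry",
    "RegistryRecord",
    "ReferenceRegistry",
    "CoverageSummary",
    "resolve_reference",
    "registry_coverage",
    "load_table3_registry",
    "NORDIC_COUNTRIES",
]

logger = logging.getLogger(__name__)

#: Countries whose national OELs fall in the Nordic tier. The tier of an
#: OEL is a data attribute (a country tag on the registry row), not
#: hard-coded chemistry; this set only assists fixture construction.
NORDIC_COUNTRIES = frozenset(
    {"Sweden", "Norway", "Denmark", "Finland", "Iceland"}
)


class Tier(str, Enum):
    """Provenance tier of a resolved limit value, in fallback order."""

    RV = "RV"
    OEL_SE = "OEL_SE"
    OEL_NORDIC = "OEL_NORDIC"
    OEL_INTL = "OEL_INTL"


@dataclass(frozen=True)
class ReferenceEntry:
    """A resolved limit value: the RVᵢ denominator of one hazard quotient."""

    chemical: ChemicalDescriptor
    value: float
    tier: Tier
    source_label: str = ""

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValidationError(
                f"limit value must be > 0 for {self.chemical.name!r}, "
                f"got {self.value}"
            )


@dataclass
class RegistryRecord:
    """Raw limit values for one chemical, one optional list per tier.

    A tier may hold several (value, source) pairs, e.g. OELs from several
    countries; blanks are recorded as absent (empty lists / None).
    """

    name: str
    cas: str = "NA"
    rv: Optional[float] = None
    rv_source: str = ""
    oel_se: list[tuple[float, str]] = field(default_factory=list)
    oel_nordic: list[tuple[float, str]] = field(default_factory=list)
    oel_intl: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        values = [self.rv] if self.rv is not None else []
        values += [v for v, _ in self.oel_se + self.oel_nordic + self.oel_intl]
        bad = [v for v in values if not v > 0]
        if bad:
            raise ValidationError(
                f"limit values must be > 0 for {self.name!r}: {bad}"
            )

    @property
    def unresolvable(self) -> bool:
        return (
            self.rv is None
            and not self.oel_se
            and not self.oel_nordic
            and not self.oel_intl
        )


def _norm_name(name: str) -> str:
    """Case-insensitive, whitespace-collapsed name key."""
    return " ".join(name.lower().split())


class ReferenceRegistry:
    """Registry of limit values keyed by CAS, with name fallback.

    CAS is the primary join key (grouped analytes match on any member of
    their CAS list); case-insensitive whitespace-collapsed name matching
    is the fallback for analytes without a CAS.
    """

    def __init__(self, records: Iterable[RegistryRecord] = ()):
        self._records: list[RegistryRecord] = []
        self._by_cas: dict[str, RegistryRecord] = {}
        self._by_name: dict[str, RegistryRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, record: RegistryRecord) -> None:
        self._records.append(record)
        if record.cas and record.cas != "NA":
            for cas in _split_cas(record.cas):
                self._by_cas[cas] = record
        self._by_name[_norm_name(record.name)] = record

    def lookup(self, chemical: ChemicalDescriptor) -> Optional[RegistryRecord]:
        if chemical.cas and chemical.cas != "NA":
            for cas in _split_cas(chemical.cas):
                rec = self._by_cas.get(cas)
                if rec is not None:
                    return rec
        return self._by_name.get(_norm_name(chemical.name))

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records)


def _split_cas(cas: str) -> list[str]:
    import re

    return [p.strip() for p in re.split(r"[;,]", cas) if p.strip()]


def resolve_reference(
    chemical: ChemicalDescriptor, registry: ReferenceRegistry
) -> Optional[ReferenceEntry]:
    """Resolve one chemical to the single limit value used in its HQ.

    Fallback order: chronic RV, then Swedish OEL, then lowest Nordic OEL,
    then lowest international OEL. Returns ``None`` when no tier holds a
    value (a valid outcome: the chemical is excluded from HI). Pure in
    (chemical, registry): repeated calls agree.
    """
    record = registry.lookup(chemical)
    if record is None:
        logger.info("no registry row for %s (%s)", chemical.name, chemical.cas)
        return None

    if record.rv is not None:
        return ReferenceEntry(chemical, record.rv, Tier.RV, record.rv_source)
    for tier, options in (
        (Tier.OEL_SE, record.oel_se),
        (Tier.OEL_NORDIC, record.oel_nordic),
        (Tier.OEL_INTL, record.oel_intl),
    ):
        if options:
            value, source = min(options, key=lambda vs: vs[0])
            return ReferenceEntry(chemical, value, tier, source)
    logger.info(
        "no reference or occupational exposure limit for %s (%s); "
        "excluded from hazard-index calculations",
        chemical.name,
        chemical.cas,
    )
    return None


@dataclass
class CoverageSummary:
    """How much of a measured chemical panel the registry resolves."""

    n_chemicals: int
    counts_by_tier: dict[Tier, int]
    n_unresolved: int
    unresolved: list[ChemicalDescriptor]  # sorted by detection frequency, desc

    @property
    def unresolved_fraction(self) -> float:
        return self.n_unresolved / self.n_chemicals if self.n_chemicals else 0.0

    @property
    def resolved_fraction_by_tier(self) -> dict[Tier, float]:
        if not self.n_chemicals:
            return {t: 0.0 for t in Tier}
        return {t: n / self.n_chemicals for t, n in self.counts_by_tier.items()}


def registry_coverage(samples, registry: ReferenceRegistry) -> CoverageSummary:
    """Tally, per detected chemical, which tier (if any) resolves it.

    ``samples`` is an iterable of :class:`~vocmix.datamodel.MeasurementSample`;
    chemicals are counted once regardless of how many samples detect them,
    and unresolved chemicals are listed most-frequently-detected first so
    the gaps that matter most for HI accuracy lead the list.
    """
    detection: dict[ChemicalDescriptor, int] = {}
    for sample in samples:
        for chem in sample.concentrations:
            detection[chem] = detection.get(chem, 0) + 1

    counts = {t: 0 for t in Tier}
    unresolved: list[ChemicalDescriptor] = []
    for chem in detection:
        entry = resolve_reference(chem, registry)
        if entry is None:
            unresolved.append(chem)
        else:
            counts[entry.tier] += 1
    unresolved.sort(key=lambda c: (-detection[c], c.name))
    return CoverageSummary(
        n_chemicals=len(detection),
        counts_by_tier=counts,
        n_unresolved=len(unresolved),
        unresolved=unresolved,
    )


def load_table3_registry() -> ReferenceRegistry:
    """Load the packaged fixture registry of published RVs and OELs.

    The fixture reproduces, verbatim, the limit values printed for the
    hairdresser exposure panel (including a known misprinted formaldehyde
    CAS, kept as printed rather than silently corrected).
    """
    from .io import read_registry

    path = resources.files("vocmix.data") / "table3_registry.csv"
    with resources.as_file(path) as p:
        return read_registry(p)
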