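"""Core domain types for personal VOC/aldehyde exposure data.

Concentrations are µg/m³ toluene equivalents throughout: VOCs are
quantified against a toluene calibration and aldehydes (externally
calibrated) are carried in the same column, with :class:`ChemClass`
distinguishing them. One :class:`MeasurementSample` is one worker-shift's
censored concentration vector; analytes reported below the class-specific
reporting limit carry no numeric value and live in the sample's
``censored`` set, so every downstream computation sees one canonical
censored dataset.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

from .errors import ValidationError

__all__ = [
    "ChemClass",
    "ChemicalDescriptor",
    "MeasurementSample",
    "ReportingLimits",
    "ClimateRecord",
    "RunConfig",
    "CAS_PATTERN",
]

#: A single CAS registry number: 2-7 digits, 2 digits, 1 check digit.
CAS_PATTERN = re.compile(r"^\d{2,7}-\d{2}-\d$")

#: Sentinel for analytes with no listed CAS (e.g. a fragrance compound
#: identified by retention/spectrum only, with no specific structure).
CAS_NA = "NA"


class ChemClass(str, Enum):
    """Analytical class of an analyte (drives the reporting limit)."""

    VOC = "VOC"
    ALDEHYDE = "aldehyde"


def _valid_cas(cas: str) -> bool:
    """True for a CAS number, a delimited list of CAS numbers, or ``NA``."""
    if cas == CAS_NA:
        return True
    parts = [p.strip() for p in re.split(r"[;,]", cas)]
    return len(parts) >= 1 and all(CAS_PATTERN.match(p) for p in parts)


@dataclass(frozen=True, eq=False)
class ChemicalDescriptor:
    """Identity, class, and TVOC-window membership of one analyte.

    Identity (equality/hash) is the pair ``(name, cas)``: grouped analytes
    share one descriptor with a delimited CAS list, and a CAS-less analyte
    uses the sentinel ``"NA"``. ``tvoc_included`` marks membership of the
    hexane–hexadecane elution window that defines TVOC; aldehydes default
    to included so that TVOC means "TVOC including aldehydes".
    """

    name: str
    cas: str = CAS_NA
    chem_class: ChemClass = ChemClass.VOC
    tvoc_included: bool = True

    def __post_init__(self) -> None:
        if not self.name or not self.name.strip():
            raise ValidationError("chemical name must be non-empty")
        if not _valid_cas(self.cas):
            raise ValidationError(
                f"invalid CAS {self.cas!r} for {self.name!r}: expected "
                "d{2,7}-d{2}-d (optionally a ;-separated list) or 'NA'"
            )
        # normalise the enum so ChemClass("VOC") and the member compare equal
        object.__setattr__(self, "chem_class", ChemClass(self.chem_class))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ChemicalDescriptor):
            return NotImplemented
        return (self.name, self.cas) == (other.name, other.cas)

    def __hash__(self) -> int:
        return hash((self.name, self.cas))

    def __repr__(self) -> str:  # compact: descriptors appear in many maps
        return f"ChemicalDescriptor({self.name!r}, {self.cas!r})"


@dataclass(frozen=True)
class ReportingLimits:
    """Analytical reporting limits below which a value is a non-detect.

    Defaults are 3 µg/m³ for VOCs and 0.3 µg/m³ for aldehydes.
    """

    voc_limit: float = 3.0
    aldehyde_limit: float = 0.3

    def __post_init__(self) -> None:
        if not (self.voc_limit > 0 and self.aldehyde_limit > 0):
            raise ValidationError("reporting limits must be > 0")

    def limit_for(self, chem_class: ChemClass) -> float:
        return (
            self.aldehyde_limit
            if ChemClass(chem_class) is ChemClass.ALDEHYDE
            else self.voc_limit
        )


@dataclass
class MeasurementSample:
    """One worker-shift's censored concentration vector.

    ``concentrations`` maps detected analytes to µg/m³ toluene equivalents;
    ``censored`` holds analytes reported below the reporting limit, which
    by construction carry no numeric value and never enter TVOC or HI.
    """

    salon_id: str
    worker_id: str
    duration_min: float = 176.0
    concentrations: dict[ChemicalDescriptor, float] = field(default_factory=dict)
    censored: set[ChemicalDescriptor] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise ValidationError("duration_min must be positive")
        bad = {c.name: v for c, v in self.concentrations.items() if not v > 0}
        if bad:
            raise ValidationError(f"nonpositive concentrations: {bad}")
        overlap = self.censored & set(self.concentrations)
        if overlap:
            names = sorted(c.name for c in overlap)
            raise ValidationError(
                f"censored analytes must carry no numeric value: {names}"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.salon_id, self.worker_id)


@dataclass(frozen=True)
class ClimateRecord:
    """Stationary indoor-climate snapshot for one salon (shift averages)."""

    salon_id: str
    co2_ppm: float
    temp_c: float
    rh_pct: float

    def __post_init__(self) -> None:
        if not self.co2_ppm > 300:
            raise ValidationError(
                f"co2_ppm must exceed the 300 ppm indoor floor, got {self.co2_ppm}"
            )
        if not (0 <= self.rh_pct <= 100):
            raise ValidationError(f"rh_pct must be in [0, 100], got {self.rh_pct}")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline thresholds and reporting options.

    risk_threshold
        HI at/above which a result is flagged as potential non-cancer risk
        (1.0; ``risk_strict`` switches the comparator to strict ``>``).
    mcr_dominance_cutoff
        MCR below which a combined-effect result counts as dominated by a
        single substance (2.0).
    rounding_sigfigs_report
        Significant figures for display columns in written reports (1,
        matching how maximum hazard quotients are conventionally printed).
    group_i_boundary_inclusive / mcr_boundary_to_iiib
        Tie-break choices for the classification boundaries maxHQ = 1
        (assigned to group I) and MCR = cutoff (assigned to group IIIB).
    """

    reporting_limits: ReportingLimits = field(default_factory=ReportingLimits)
    risk_threshold: float = 1.0
    risk_strict: bool = False
    mcr_dominance_cutoff: float = 2.0
    rounding_sigfigs_report: int = 1
    group_i_boundary_inclusive: bool = True
    mcr_boundary_to_iiib: bool = True

    def __post_init__(self) -> None:
        if not (self.risk_threshold > 0 and self.mcr_dominance_cutoff > 0):
            raise ValidationError("thresholds must be > 0")
        if self.rounding_sigfigs_report < 1:
            raise ValidationError("rounding_sigfigs_report must be >= 1")

    def flags_risk(self, hi: float) -> bool:
        return hi > self.risk_threshold if self.risk_strict else hi >= self.risk_threshold


def format_sigfigs(x: float, sigfigs: int) -> str:
    """Format ``x`` to ``sigfigs`` significant figures for display columns.

    >>> format_sigfigs(4.222, 1)
    '4'
    >>> format_sigfigs(0.7142857, 1)
    '0.7'
    """
    if x == 0 or not math.isfinite(x):
        return str(x)
    s = f"{x:.{sigfigs}g}"
    # avoid exponent notation for the magnitudes seen in reports
    if "e" in s or "E" in s:
        s = f"{float(s):f}".rstrip("0").rstrip(".")
    return s
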