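"""CSV readers and writers for measurements, registries, and risk reports.

All tabular I/O is UTF-8 RFC-4180 CSV via pandas. Reporting-limit
enforcement happens here, at ingest: a numeric concentration strictly
below the class-appropriate reporting limit is moved to the sample's
censored set (with a logged warning), and the literal token ``<RL``
marks an explicitly censored cell. Downstream stages therefore never see
a sub-limit numeric value.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .datamodel import (
    ChemClass,
    ChemicalDescriptor,
    ClimateRecord,
    MeasurementSample,
    ReportingLimits,
    RunConfig,
    format_sigfigs,
)
from .errors import DuplicateRecordError, FormatError, ParseError, ValidationError
from .registry import ReferenceRegistry, RegistryRecord

__all__ = [
    "read_measurements",
    "write_measurements",
    "read_registry",
    "read_climate",
    "write_report",
    "read_report",
    "read_config",
]

logger = logging.getLogger(__name__)

CENSORED_TOKEN = "<RL"

_MEASUREMENT_COLUMNS = [
    "salon_id",
    "worker_id",
    "duration_min",
    "chemical",
    "cas",
    "chem_class",
    "concentration",
]

_TRUE_TOKENS = {"true", "1", "yes", "t"}
_FALSE_TOKENS = {"false", "0", "no", "f"}


def _read_csv(path) -> pd.DataFrame:
    # dtype=str + keep_default_na=False: blanks stay "", parsing is explicit
    return pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def _parse_bool(token: str, default: bool = True) -> bool:
    t = token.strip().lower()
    if not t:
        return default
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS:
        return False
    raise ParseError(f"cannot interpret boolean token {token!r}")


def read_measurements(path, limits: ReportingLimits | None = None) -> list[MeasurementSample]:
    """Read a long-format measurement CSV into censored samples.

    Expected columns: ``salon_id, worker_id, duration_min, chemical, cas,
    chem_class, concentration`` (optional ``tvoc_included``). The
    concentration column admits numbers or the token ``<RL``; numbers
    strictly below the class reporting limit are censored with a warning.
    One :class:`MeasurementSample` is returned per (salon, worker).
    """
    limits = limits or ReportingLimits()
    df = _read_csv(path)
    _require_columns(df, _MEASUREMENT_COLUMNS, path)

    samples: dict[tuple[str, str], MeasurementSample] = {}
    seen: set[tuple[str, str, str, str]] = set()
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        chem = ChemicalDescriptor(
            name=row.chemical.strip(),
            cas=row.cas.strip() or "NA",
            chem_class=ChemClass(row.chem_class.strip()),
            tvoc_included=_parse_bool(getattr(row, "tvoc_included", "")),
        )
        key = (row.salon_id, row.worker_id)
        dup_key = (row.salon_id, row.worker_id, chem.name, chem.cas)
        if dup_key in seen:
            raise DuplicateRecordError(
                f"{path}: duplicate record for salon={row.salon_id} "
                f"worker={row.worker_id} chemical={chem.name}"
            )
        seen.add(dup_key)
        if key not in samples:
            try:
                duration = float(row.duration_min)
            except ValueError as exc:
                raise ParseError(
                    f"{path} row {idx}: bad duration_min {row.duration_min!r}"
                ) from exc
            samples[key] = MeasurementSample(
                salon_id=row.salon_id, worker_id=row.worker_id, duration_min=duration
            )
        sample = samples[key]

        token = row.concentration.strip()
        if token.upper() == CENSORED_TOKEN.upper():
            sample.censored.add(chem)
            continue
        try:
            value = float(token)
        except ValueError as exc:
            raise ParseError(
                f"{path} row {idx}: concentration {token!r} is neither numeric "
                f"nor {CENSORED_TOKEN!r}"
            ) from exc
        limit = limits.limit_for(chem.chem_class)
        if value < limit:
            logger.warning(
                "%s row %d: %s concentration %.3g below reporting limit %.3g; censored",
                path,
                idx,
                chem.name,
                value,
                limit,
            )
            sample.censored.add(chem)
        else:
            sample.concentrations[chem] = value
    return list(samples.values())


def write_measurements(samples: Iterable[MeasurementSample], path) -> None:
    """Write samples back to the long-format measurement CSV."""
    rows = []
    for s in samples:
        entries = [(c, v) for c, v in s.concentrations.items()]
        entries += [(c, None) for c in s.censored]
        for chem, value in sorted(entries, key=lambda cv: cv[0].name):
            rows.append(
                {
                    "salon_id": s.salon_id,
                    "worker_id": s.worker_id,
                    "duration_min": s.duration_min,
                    "chemical": chem.name,
                    "cas": chem.cas,
                    "chem_class": chem.chem_class.value,
                    "tvoc_included": str(chem.tvoc_included).lower(),
                    "concentration": CENSORED_TOKEN if value is None else repr(value),
                }
            )
    pd.DataFrame(
        rows, columns=_MEASUREMENT_COLUMNS[:6] + ["tvoc_included", "concentration"]
    ).to_csv(path, index=False, encoding="utf-8")


_REGISTRY_REQUIRED = ["chemical", "cas", "rv", "oel_se", "oel_nordic", "oel_intl"]
_REGISTRY_OPTIONAL = {
    "rv_source",
    "oel_se_source",
    "oel_nordic_source",
    "oel_intl_source",
    "note",
}


def _parse_tier(cell: str, sources: str, chem: str, path) -> list[tuple[float, str]]:
    """Parse one tier cell: blank, a value, or semicolon-separated values."""
    cell = cell.strip()
    if not cell:
        return []
    values = []
    for tok in cell.split(";"):
        try:
            values.append(float(tok))
        except ValueError as exc:
            raise ParseError(f"{path}: bad limit value {tok!r} for {chem!r}") from exc
    labels = [s.strip() for s in sources.split(";")] if sources.strip() else []
    if len(labels) == 1 and len(values) > 1:
        labels = labels * len(values)
    labels += [""] * (len(values) - len(labels))
    return list(zip(values, labels))


def read_registry(path) -> ReferenceRegistry:
    """Read a limit-value registry CSV.

    Columns: ``chemical, cas, rv, oel_se, oel_nordic, oel_intl`` plus
    optional per-tier source-label columns and a free-text ``note``. A
    tier cell may hold several semicolon-separated values (retained for
    later lowest-value selection); blank tiers are recorded as absent.
    """
    df = _read_csv(path)
    _require_columns(df, _REGISTRY_REQUIRED, path)
    unknown = set(df.columns) - set(_REGISTRY_REQUIRED) - _REGISTRY_OPTIONAL
    if unknown:
        raise FormatError(f"{path}: unknown column(s) {sorted(unknown)}")

    registry = ReferenceRegistry()
    for row in df.to_dict("records"):
        name = row["chemical"].strip()
        rv_cell = row["rv"].strip()
        rv: Optional[float] = None
        if rv_cell:
            try:
                rv = float(rv_cell)
            except ValueError as exc:
                raise ParseError(f"{path}: bad RV {rv_cell!r} for {name!r}") from exc
        try:
            record = RegistryRecord(
                name=name,
                cas=row["cas"].strip() or "NA",
                rv=rv,
                rv_source=row.get("rv_source", "").strip(),
                oel_se=_parse_tier(row["oel_se"], row.get("oel_se_source", ""), name, path),
                oel_nordic=_parse_tier(
                    row["oel_nordic"], row.get("oel_nordic_source", ""), name, path
                ),
                oel_intl=_parse_tier(
                    row["oel_intl"], row.get("oel_intl_source", ""), name, path
                ),
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: {exc}") from exc
        if record.unresolvable:
            logger.info("registry: %s has no RV or OEL in any tier", name)
        registry.add(record)
    return registry


def read_climate(path) -> list[ClimateRecord]:
    """Read the optional per-salon indoor-climate table."""
    df = _read_csv(path)
    _require_columns(df, ["salon_id", "co2_ppm", "temp_c", "rh_pct"], path)
    records = []
    seen: set[str] = set()
    for row in df.to_dict("records"):
        if row["salon_id"] in seen:
            raise DuplicateRecordError(f"{path}: duplicate salon {row['salon_id']!r}")
        seen.add(row["salon_id"])
        records.append(
            ClimateRecord(
                salon_id=row["salon_id"],
                co2_ppm=float(row["co2_ppm"]),
                temp_c=float(row["temp_c"]),
                rh_pct=float(row["rh_pct"]),
            )
        )
    return records


def _hq_breakdown_path(path) -> Path:
    p = Path(path)
    return p.with_name(p.stem + "_hq" + (p.suffix or ".csv"))


def write_report(results, path, config: RunConfig | None = None) -> None:
    """Write per-result risk metrics plus a long-format HQ breakdown.

    The main CSV holds, per result: TVOC, HI, the maxHQ chemical, MCR,
    MCR substance group with substances of concern, and the risk flag —
    each numeric column at full precision with a ``*_display`` companion
    rounded to ``config.rounding_sigfigs_report`` significant figures.
    The HQ breakdown goes to ``<stem>_hq<suffix>`` alongside.
    """
    from .classification import classify

    config = config or RunConfig()
    results = list(results)
    if not results:
        raise ValidationError("write_report: results must be non-empty")
    sig = config.rounding_sigfigs_report

    main_rows = []
    hq_rows = []
    for res in results:
        if res.n_contributing >= 1:
            assignment = classify(res, config)
            group = assignment.group.value
            concern = "; ".join(c.name for c in assignment.substances_of_concern)
        else:
            group, concern = "unclassifiable", ""
        main_rows.append(
            {
                "scope": res.scope,
                "id": res.id,
                "tvoc": repr(res.tvoc),
                "tvoc_display": format_sigfigs(res.tvoc, sig),
                "hi": repr(res.hi),
                "hi_display": format_sigfigs(res.hi, sig),
                "max_hq_chemical": res.max_hq_chemical.name if res.max_hq_chemical else "",
                "max_hq": repr(res.max_hq),
                "max_hq_display": format_sigfigs(res.max_hq, sig),
                "mcr": "" if res.mcr is None else repr(res.mcr),
                "mcr_display": "" if res.mcr is None else format_sigfigs(res.mcr, sig),
                "n_contributing": res.n_contributing,
                "substance_group": group,
                "substances_of_concern": concern,
                "risk_flag": str(res.risk_flag).lower(),
            }
        )
        for chem, hq in sorted(res.hq_by_chemical.items(), key=lambda kv: -kv[1]):
            hq_rows.append(
                {
                    "scope": res.scope,
                    "id": res.id,
                    "chemical": chem.name,
                    "cas": chem.cas,
                    "hq": repr(hq),
                    "hq_display": format_sigfigs(hq, sig),
                }
            )
    try:
        pd.DataFrame(main_rows).to_csv(path, index=False, encoding="utf-8")
        pd.DataFrame(
            hq_rows, columns=["scope", "id", "chemical", "cas", "hq", "hq_display"]
        ).to_csv(_hq_breakdown_path(path), index=False, encoding="utf-8")
    except OSError as exc:
        raise ValidationError(f"cannot write report to {path}: {exc}") from exc


def read_report(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read back a written report (main table, HQ breakdown)."""
    main = pd.read_csv(path, encoding="utf-8")
    hq = pd.read_csv(_hq_breakdown_path(path), encoding="utf-8")
    return main, hq


def read_config(path) -> RunConfig:
    """Read a flat ``key = value`` text file into a :class:`RunConfig`.

    Recognised keys: ``voc_limit, aldehyde_limit, risk_threshold,
    risk_strict, mcr_dominance_cutoff, rounding_sigfigs_report,
    group_i_boundary_inclusive, mcr_boundary_to_iiib``. Lines starting
    with ``#`` and blank lines are ignored.
    """
    text = Path(path).read_text(encoding="utf-8")
    kv: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise FormatError(f"{path} line {lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        kv[key.strip()] = value.strip()

    known_float = {"voc_limit", "aldehyde_limit", "risk_threshold", "mcr_dominance_cutoff"}
    known_bool = {"risk_strict", "group_i_boundary_inclusive", "mcr_boundary_to_iiib"}
    known_int = {"rounding_sigfigs_report"}
    unknown = set(kv) - known_float - known_bool - known_int
    if unknown:
        raise FormatError(f"{path}: unknown config key(s) {sorted(unknown)}")

    limits = ReportingLimits(
        voc_limit=float(kv.get("voc_limit", 3.0)),
        aldehyde_limit=float(kv.get("aldehyde_limit", 0.3)),
    )
    kwargs = {"reporting_limits": limits}
    for key in known_float - {"voc_limit", "aldehyde_limit"}:
        if key in kv:
            kwargs[key] = float(kv[key])
    for key in known_int:
        if key in kv:
            kwargs[key] = int(kv[key])
    for key in known_bool:
        if key in kv:
            kwargs[key] = _parse_bool(kv[key])
    return RunConfig(**kwargs)
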