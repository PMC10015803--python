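"""Synthetic measurement campaigns with the study's statistical structure.

The generator emulates a personal-sampling campaign: ``n_salons`` salons
× ``workers_per_salon`` workers, each worker-shift yielding one censored
concentration vector over a chemical panel. Per chemical, detection is a
Bernoulli gate with probability ``detect_prob`` (absence: the analyte was
never identified); a detected concentration is lognormal,

    C = exp(μ + b_salon + e),   μ = ln(GM), σ = ln(GSD),
    b_salon ~ N(0, between_frac·σ²),  e ~ N(0, (1−between_frac)·σ²),

with one salon random effect per (salon, chemical) pair, so
``between_frac`` is the share of log-scale variance attributable to
salons. Detected values below the class reporting limit are additionally
censored, exactly as real data would be (both non-detect mechanisms —
absence and below-limit — occur in real campaigns). Everything is
deterministic given the seed; ground truth is returned alongside.

The default panel mirrors the published hairdresser panel (GM, GSD,
detection frequency per chemical) with the between-salon variance share
at the study's reported 28%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

from .datamodel import (
    ChemClass,
    ChemicalDescriptor,
    ClimateRecord,
    MeasurementSample,
    ReportingLimits,
)
from .errors import ValidationError

__all__ = [
    "ChemicalSim",
    "SyntheticConfig",
    "CampaignTruth",
    "default_panel",
    "generate_campaign",
    "generate_climate",
    "synthetic_registry_panel",
]

#: Indoor-climate campaign means (and coefficients of variation) the
#: climate generator reproduces: 628 ppm CO₂ (CV 32%), 23.2 °C (CV 4.4%),
#: 37.9% RH (CV 31%).
CLIMATE_DEFAULTS = {
    "co2_mean": 628.0,
    "co2_cv": 0.32,
    "temp_mean": 23.2,
    "temp_cv": 0.044,
    "rh_mean": 37.9,
    "rh_cv": 0.31,
}


@dataclass(frozen=True)
class ChemicalSim:
    """Lognormal generating parameters for one panel chemical."""

    descriptor: ChemicalDescriptor
    gm: float
    gsd: float
    detect_prob: float

    def __post_init__(self) -> None:
        if not self.gm > 0:
            raise ValidationError(f"{self.descriptor.name}: gm must be > 0")
        if self.gsd < 1:
            raise ValidationError(f"{self.descriptor.name}: gsd must be >= 1")
        if not (0 <= self.detect_prob <= 1):
            raise ValidationError(f"{self.descriptor.name}: detect_prob outside [0, 1]")


@dataclass
class SyntheticConfig:
    """Campaign design: defaults are the study conditions (10 salons × 3)."""

    n_salons: int = 10
    workers_per_salon: int = 3
    chemicals: list[ChemicalSim] = field(default_factory=lambda: default_panel())
    between_frac: float = 0.28
    reporting_limits: ReportingLimits = field(default_factory=ReportingLimits)
    seed: int = 0
    duration_min: float = 176.0

    def __post_init__(self) -> None:
        if self.n_salons < 1 or self.workers_per_salon < 1:
            raise ValidationError("need at least one salon and one worker per salon")
        if not (0 <= self.between_frac < 1):
            raise ValidationError("between_frac must lie in [0, 1)")
        if not self.chemicals:
            raise ValidationError("chemical panel must be non-empty")


def default_panel(path=None) -> list[ChemicalSim]:
    """Load the packaged default chemical panel (or a panel CSV like it).

    Columns: ``chemical, cas, chem_class, tvoc_included, gm, gsd,
    detect_prob``.
    """
    if path is None:
        res = resources.files("vocmix.data") / "table3_panel.csv"
        with resources.as_file(res) as p:
            df = pd.read_csv(p, dtype=str, keep_default_na=False)
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    panel = []
    for row in df.to_dict("records"):
        desc = ChemicalDescriptor(
            name=row["chemical"].strip(),
            cas=row["cas"].strip() or "NA",
            chem_class=ChemClass(row["chem_class"].strip()),
            tvoc_included=row.get("tvoc_included", "true").strip().lower()
            not in {"false", "0", "no"},
        )
        panel.append(
            ChemicalSim(
                descriptor=desc,
                gm=float(row["gm"]),
                gsd=float(row["gsd"]),
                detect_prob=float(row["detect_prob"]),
            )
        )
    return panel


@dataclass
class CampaignTruth:
    """Ground truth behind one generated campaign."""

    config: SyntheticConfig
    salon_effects: dict[tuple[str, str], float]  # (chemical name, salon_id) -> b
    records: pd.DataFrame  # per (salon, worker, chemical): detected, true conc, censored

    def recover_between_fraction(self) -> float:
        """Between-salon variance share recovered from the truth record.

        Per chemical with spread (GSD > 1), one-way method-of-moments
        variance components of ln(true concentration) grouped by salon;
        the recovered share is the unweighted mean of the per-chemical
        between fractions. Pooling across the panel's independent salon
        effects shrinks the sampling error by ~√K, which a single
        response (e.g. the HI) cannot do: one intraclass correlation
        estimated from 10 groups of 3 has a standard error near 0.2.
        """
        sum_between = sum_within = 0.0
        n_used = 0
        for chem in self.config.chemicals:
            sub = self.records[self.records["chemical"] == chem.descriptor.name]
            groups = [
                np.log(g["concentration_true"].to_numpy())
                for _, g in sub.groupby("salon_id")
            ]
            scale = float(np.log(chem.gsd))
            if scale == 0:  # GSD 1: no spread, no information on the split
                continue
            # standardise by the planted log-scale sigma so every chemical
            # carries equal weight; a data-derived scale would correlate
            # with the components and bias the pooled ratio
            groups = [g / scale for g in groups]
            ns = np.array([g.size for g in groups], dtype=float)
            N, gcount = ns.sum(), len(groups)
            if gcount < 2 or N <= gcount:
                continue
            grand = np.concatenate(groups).mean()
            means = np.array([g.mean() for g in groups])
            ms_b = float(np.sum(ns * (means - grand) ** 2)) / (gcount - 1)
            ms_w = float(sum(np.sum((g - g.mean()) ** 2) for g in groups)) / (
                int(N) - gcount
            )
            n0 = (N - float(np.sum(ns**2)) / N) / (gcount - 1)
            # no per-chemical truncation: negative moment estimates cancel
            # in the pooled sums instead of biasing the ratio upward
            sum_between += (ms_b - ms_w) / n0
            sum_within += ms_w
            n_used += 1
        if n_used == 0:
            raise ValidationError("no chemical with spread; fraction unrecoverable")
        between = max(0.0, sum_between)
        return between / (between + sum_within)

    def parameter_table(self) -> pd.DataFrame:
        """Planted parameters, one row per chemical plus campaign scalars."""
        rows = [
            {
                "chemical": c.descriptor.name,
                "cas": c.descriptor.cas,
                "chem_class": c.descriptor.chem_class.value,
                "gm": c.gm,
                "gsd": c.gsd,
                "detect_prob": c.detect_prob,
                "between_frac": self.config.between_frac,
                "n_salons": self.config.n_salons,
                "workers_per_salon": self.config.workers_per_salon,
                "seed": self.config.seed,
            }
            for c in self.config.chemicals
        ]
        return pd.DataFrame(rows)


def generate_campaign(
    config: SyntheticConfig,
) -> tuple[list[MeasurementSample], CampaignTruth]:
    """Generate one campaign; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    S, W = config.n_salons, config.workers_per_salon
    salon_ids = [f"s{i + 1}" for i in range(S)]
    worker_ids = [f"h{j + 1}" for j in range(W)]

    samples = {
        (s, w): MeasurementSample(
            salon_id=s, worker_id=w, duration_min=config.duration_min
        )
        for s in salon_ids
        for w in worker_ids
    }
    salon_effects: dict[tuple[str, str], float] = {}
    rows = []
    for chem in config.chemicals:
        sigma = float(np.log(chem.gsd))
        mu = float(np.log(chem.gm))
        b = rng.normal(0.0, np.sqrt(config.between_frac) * sigma, size=S)
        e = rng.normal(0.0, np.sqrt(1.0 - config.between_frac) * sigma, size=(S, W))
        detected = rng.random(size=(S, W)) < chem.detect_prob
        conc = np.exp(mu + b[:, None] + e)
        limit = config.reporting_limits.limit_for(chem.descriptor.chem_class)
        for i, s in enumerate(salon_ids):
            salon_effects[(chem.descriptor.name, s)] = float(b[i])
            for j, w in enumerate(worker_ids):
                det = bool(detected[i, j])
                value = float(conc[i, j])
                censored = det and value < limit
                if det and not censored:
                    samples[(s, w)].concentrations[chem.descriptor] = value
                elif censored:
                    samples[(s, w)].censored.add(chem.descriptor)
                rows.append(
                    {
                        "salon_id": s,
                        "worker_id": w,
                        "chemical": chem.descriptor.name,
                        "detected": det,
                        "concentration_true": value,
                        "censored": censored,
                    }
                )
    truth = CampaignTruth(
        config=config, salon_effects=salon_effects, records=pd.DataFrame(rows)
    )
    return list(samples.values()), truth


def generate_climate(
    config: SyntheticConfig,
    co2_exposure_slope: float = 0.0,
    samples: Optional[list[MeasurementSample]] = None,
    co2_cv: float = CLIMATE_DEFAULTS["co2_cv"],
) -> list[ClimateRecord]:
    """Per-salon indoor climate, optionally coupled to exposure.

    CO₂ is drawn around 628 ppm with the given coefficient of variation;
    with a nonzero ``co2_exposure_slope`` (ppm per µg/m³) and the
    generated samples, each salon's CO₂ is shifted by slope × (salon mean
    TVOC − campaign mean TVOC), planting a positive CO₂–exposure
    association while preserving the campaign mean. Values are floored
    just above the 300 ppm physical indoor minimum.
    """
    from .metrics import compute_tvoc

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    d = CLIMATE_DEFAULTS
    salon_ids = [f"s{i + 1}" for i in range(config.n_salons)]

    shift = {s: 0.0 for s in salon_ids}
    if co2_exposure_slope != 0.0 and samples:
        tvoc_by_salon: dict[str, list[float]] = {}
        for sample in samples:
            tvoc_by_salon.setdefault(sample.salon_id, []).append(compute_tvoc(sample))
        means = {s: float(np.mean(v)) for s, v in tvoc_by_salon.items()}
        grand = float(np.mean(list(means.values())))
        shift = {s: co2_exposure_slope * (means.get(s, grand) - grand) for s in salon_ids}

    records = []
    for s in salon_ids:
        co2 = rng.normal(d["co2_mean"], co2_cv * d["co2_mean"]) + shift[s]
        temp = rng.normal(d["temp_mean"], d["temp_cv"] * d["temp_mean"])
        rh = rng.normal(d["rh_mean"], d["rh_cv"] * d["rh_mean"])
        records.append(
            ClimateRecord(
                salon_id=s,
                co2_ppm=float(max(co2, 301.0)),
                temp_c=float(temp),
                rh_pct=float(np.clip(rh, 0.0, 100.0)),
            )
        )
    return records


def synthetic_registry_panel(
    n_chemicals: int = 90, n_rv: int = 18, n_oel: int = 21, seed: int = 0
):
    """Synthetic chemical panel + registry with a chosen coverage profile.

    Builds ``n_chemicals`` synthetic descriptors of which the first
    ``n_rv`` carry a chronic RV, the next ``n_oel`` carry only OELs
    (spread over the Swedish/Nordic/international tiers), and the rest
    resolve to nothing — emulating a campaign where roughly half the
    identified chemicals have no limit value at all. Entirely synthetic;
    deterministic given ``seed``.
    """
    from .registry import ReferenceRegistry, RegistryRecord

    if n_rv + n_oel > n_chemicals:
        raise ValidationError("n_rv + n_oel cannot exceed n_chemicals")
    rng = np.random.default_rng(seed)
    registry = ReferenceRegistry()
    descriptors = []
    for i in range(n_chemicals):
        cas = f"{100000 + i}-{10 + i % 89:02d}-{i % 10}"
        desc = ChemicalDescriptor(name=f"synthetic-compound-{i:03d}", cas=cas)
        descriptors.append(desc)
        value = float(rng.uniform(50, 5000))
        if i < n_rv:
            registry.add(
                RegistryRecord(name=desc.name, cas=cas, rv=value, rv_source="synthetic")
            )
        elif i < n_rv + n_oel:
            tier = i % 3
            if tier == 0:
                registry.add(
                    RegistryRecord(
                        name=desc.name, cas=cas, oel_se=[(value, "synthetic (Sweden)")]
                    )
                )
            elif tier == 1:
                registry.add(
                    RegistryRecord(
                        name=desc.name,
                        cas=cas,
                        oel_nordic=[
                            (value, "synthetic (Denmark)"),
                            (float(rng.uniform(value, 2 * value)), "synthetic (Norway)"),
                        ],
                    )
                )
            else:
                registry.add(
                    RegistryRecord(
                        name=desc.name, cas=cas, oel_intl=[(value, "synthetic (intl)")]
                    )
                )
        else:
            registry.add(RegistryRecord(name=desc.name, cas=cas))
    return descriptors, registry
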