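"""Seeded synthetic country panels with the joint structure the metrics assume.

The generator emulates, per synthetic country: a still live-birth rate drawn
uniformly within an income-tier range (richer countries low, poorer high,
echoing observed group spans), a stillbirth-to-neonatal-death ratio drawn
from a truncated normal around 0.9, a log-uniform live-birth cohort size,
and a life expectancy that declines linearly with the stillbirth rate plus
noise.  Counts are derived from the latent rates, so the metric layer
recovers every latent quantity exactly — the panels are algebra made flesh,
not demographic microsimulation.  Every latent draw is recorded in a
ground-truth table so property tests can assert exact recovery.

Counts are real-valued by default; an ``integerize`` flag rounds them to
whole births, which breaks the exact identities by up to ~0.5/LB — the gap
between rate algebra and count data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import CountryRecord
from .data_io import INCOME_POORER, INCOME_RICHER
from .metrics import BirthCounts, DomainError

__all__ = ["SynthConfig", "generate_panel", "perturb_panel"]

_REGION_CYCLE = ("DR", "SA", "CCA", "EA", "LAC", "NAME", "SEA", "SSA")

#: Lower truncation for the SB:NM ratio draw: keeps the derived NMR
#: (= SLBR / ratio) bounded so neonatal deaths cannot exceed live births.
_RATIO_FLOOR = 0.1


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; identical seed + config give a byte-identical panel.

    Tier SLBR ranges bracket the spans seen across income groups (richer
    roughly 2-15 per 1000, poorer 10-50); the SB:NM ratio is centred at 0.9
    with SD 0.2, truncated at 0.1; life expectancy is a tier baseline minus
    ``le_slope`` years per SLBR point plus N(0, le_noise_sd) noise; cohort
    sizes are log-uniform between 10^4 and 2x10^7 live births.  Between the
    two panel years each tier's SLBR declines multiplicatively by its
    ``decline_*`` fraction.
    """

    n_countries: int = 40
    seed: int = 0
    tier_mix: float = 0.5                       # fraction of poorer countries
    slbr_range_rich: tuple[float, float] = (2.0, 15.0)
    slbr_range_poor: tuple[float, float] = (10.0, 50.0)
    ratio_center: float = 0.9
    ratio_spread: float = 0.2
    le_base_rich: float = 78.0
    le_base_poor: float = 62.0
    le_slope: float = 0.25                      # years lost per SLBR point
    le_noise_sd: float = 1.0
    lb_range: tuple[float, float] = (1e4, 2e7)
    years: tuple[int, int] = (2000, 2015)
    decline_rich: float = 0.35                  # proportionate SLBR decline
    decline_poor: float = 0.25
    integerize: bool = False

    def __post_init__(self) -> None:
        if self.n_countries < 0:
            raise DomainError("n_countries must be >= 0")
        if not (0 <= self.tier_mix <= 1):
            raise DomainError("tier_mix must lie in [0, 1]")
        for name in ("slbr_range_rich", "slbr_range_poor", "lb_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise DomainError(f"{name} must be positive and ordered")
        if self.ratio_center <= 0 or self.ratio_spread < 0:
            raise DomainError("ratio_center must be > 0, ratio_spread >= 0")
        if self.le_base_rich <= 0 or self.le_base_poor <= 0:
            raise DomainError("life-expectancy baselines must be > 0")
        if not (0 <= self.decline_rich < 1 and 0 <= self.decline_poor < 1):
            raise DomainError("decline fractions must lie in [0, 1)")
        if self.years[0] == self.years[1]:
            raise DomainError("the two panel years must differ")


@dataclass
class GroundTruth:
    """Latent draws behind a generated panel, one row per country-year."""

    frame: pd.DataFrame = field(default_factory=pd.DataFrame)


def _truncated_normal(rng: np.random.Generator, center: float, spread: float,
                      floor: float, size: int) -> np.ndarray:
    """Rejection-sample N(center, spread) conditioned on >= floor."""
    if spread == 0:
        return np.full(size, max(center, floor))
    out = rng.normal(center, spread, size)
    while True:
        bad = out < floor
        if not bad.any():
            return out
        out[bad] = rng.normal(center, spread, int(bad.sum()))


def generate_panel(config: SynthConfig) -> tuple[list[CountryRecord], GroundTruth]:
    """Generate a two-year panel of synthetic countries plus ground truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_countries
    n_poor = int(round(n * config.tier_mix))
    tiers = np.array([INCOME_POORER] * n_poor + [INCOME_RICHER] * (n - n_poor))

    records: list[CountryRecord] = []
    truth_rows: list[dict] = []
    y0, y1 = config.years

    for i in range(n):
        poor = tiers[i] == INCOME_POORER
        lo, hi = config.slbr_range_poor if poor else config.slbr_range_rich
        decline = config.decline_poor if poor else config.decline_rich
        base = config.le_base_poor if poor else config.le_base_rich

        slbr0 = rng.uniform(lo, hi)
        slbr_by_year = {y0: slbr0, y1: slbr0 * (1.0 - decline)}
        ratio = float(_truncated_normal(rng, config.ratio_center,
                                        config.ratio_spread, _RATIO_FLOOR, 1)[0])
        region = _REGION_CYCLE[i % len(_REGION_CYCLE)]
        name = f"Synthland-{i:03d}"

        for year in (y0, y1):
            slbr = slbr_by_year[year]
            nmr = slbr / ratio
            lb = float(np.exp(rng.uniform(np.log(config.lb_range[0]),
                                          np.log(config.lb_range[1]))))
            sb = slbr / 1000.0 * lb
            nm = nmr / 1000.0 * lb
            le = base - config.le_slope * slbr + rng.normal(0.0, config.le_noise_sd)
            le = max(le, 1.0)
            if config.integerize:
                lb, sb, nm = round(lb), round(sb), round(nm)
            records.append(CountryRecord(
                country=name,
                iso3=f"S{i:02d}"[:3],
                region=region,
                income_group=str(tiers[i]),
                year=year,
                counts=BirthCounts(stillbirths=sb, live_births=lb,
                                   neonatal_deaths=nm),
                le=le,
            ))
            truth_rows.append({
                "country": name, "year": year, "income_group": tiers[i],
                "region": region, "slbr": slbr, "sb_nm_ratio": ratio,
                "nmr": nmr, "live_births": lb, "le": le,
            })

    truth = GroundTruth(frame=pd.DataFrame(
        truth_rows,
        columns=["country", "year", "income_group", "region", "slbr",
                 "sb_nm_ratio", "nmr", "live_births", "le"],
    ))
    return records, truth


_PERTURBABLE = {"stillbirths", "life_expectancy"}


def perturb_panel(panel: list[CountryRecord], field_name: str,
                  multiplier: float) -> list[CountryRecord]:
    """Return a copy of the panel with one field scaled; original untouched.

    Useful for monotonicity probes: e.g. raising life expectancy with
    stillbirth counts fixed raises the YLL, because each stillbirth then
    forgoes more years.
    """
    if field_name not in _PERTURBABLE:
        raise DomainError(
            f"cannot perturb {field_name!r}; expected one of "
            f"{sorted(_PERTURBABLE)}"
        )
    if multiplier <= 0:
        raise DomainError(f"multiplier must be > 0, got {multiplier}")
    out = []
    for r in panel:
        if field_name == "stillbirths":
            counts = BirthCounts(
                stillbirths=r.counts.stillbirths * multiplier,
                live_births=r.counts.live_births,
                neonatal_deaths=r.counts.neonatal_deaths,
            )
            out.append(replace(r, counts=counts))
        else:
            out.append(replace(r, le=r.le * multiplier))
    return out
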