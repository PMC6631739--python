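"""Regional and income-group aggregation of country-level stillbirth metrics.

A group summary mixes two kinds of statistic deliberately kept distinct:

* *pooled* rates — computed from summed counts across member countries
  (equivalently, the live-birth-weighted mean of member rates); these answer
  "what is the rate of the region treated as one population";
* *cross-country* statistics — the unweighted mean, sample SD and
  coefficient of variation (CV = 100 x SD/mean) of member-country values;
  these answer "how do countries within the region differ".  The CV is the
  dispersion measure of choice because group means differ widely.

Group mean LE/SALE/decrement are unweighted country means; YLL totals are
sums of member person-years.  The sample (n-1) SD is used throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .metrics import (
    BirthCounts,
    DomainError,
    RateSet,
    adjusted_expectancy,
    compute_nmr,
    compute_slbr,
    compute_stbr,
    pct_change,
    stillbirth_yll,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MDG_REGIONS",
    "INCOME_GROUPS",
    "WORLD_KEY",
    "CountryRecord",
    "GroupSummary",
    "pooled_rates",
    "dispersion",
    "group_yll",
    "summarize_group",
    "summarize",
    "group_gap",
    "threshold_count",
]

#: The eight Millennium Development Goal regions: developed region, Southern
#: Asia, Caucasus & Central Asia, Eastern Asia, Latin America & Caribbean,
#: North Africa & Middle East, South-eastern Asia, Sub-Saharan Africa.
MDG_REGIONS = frozenset({"DR", "SA", "CCA", "EA", "LAC", "NAME", "SEA", "SSA"})

#: Two-way income split: high + upper-middle ("richer") vs
#: lower-middle + low ("poorer").
INCOME_GROUPS = frozenset({"high+upper-middle", "lower-middle+low"})

WORLD_KEY = "World"


@dataclass(frozen=True)
class CountryRecord:
    """One country-year panel row binding counts, expectancy and group labels.

    Region/income labels are data, not code: membership in the default label
    sets (:data:`MDG_REGIONS`, :data:`INCOME_GROUPS`) is enforced at panel
    read time, where the allowed sets can be overridden, not here.
    """

    country: str
    region: str
    income_group: str
    year: int
    counts: BirthCounts
    le: float
    iso3: str | None = None

    def __post_init__(self) -> None:
        if not self.country:
            raise DomainError("country name must be non-empty")
        if self.le <= 0:
            raise DomainError(
                f"{self.country}: life expectancy must be > 0, got {self.le}"
            )

    @property
    def key(self) -> str:
        """Join key: ISO3 when present, else exact country name."""
        return self.iso3 if self.iso3 else self.country

    def slbr(self) -> float:
        return compute_slbr(self.counts)

    def nmr(self) -> float:
        return compute_nmr(self.counts)


@dataclass(frozen=True)
class GroupSummary:
    """Pooled rates, cross-country dispersion and YLL total for one group."""

    group_key: str
    n_countries: int
    pooled_slbr: float
    pooled_ratio: float          # SB:NM, dimensionless (x100 for display)
    mean_rate: float             # unweighted mean of member SLBRs
    sd_rate: float               # sample SD of member SLBRs
    cv_percent: float            # 100 * sd / mean
    mean_le: float
    mean_sale: float
    mean_decrement: float
    total_yll: float             # person-years


def _check_same_year(records: Sequence[CountryRecord]) -> None:
    years = {r.year for r in records}
    if len(years) > 1:
        raise DomainError(
            f"records span multiple years {sorted(years)}; "
            "aggregate one year at a time"
        )


def pooled_rates(records: Iterable[CountryRecord]) -> RateSet:
    """Rates for the group treated as a single population.

    Counts are summed across members before dividing, so the pooled SLBR is
    the live-birth-weighted mean of member SLBRs, not their plain mean.
    """
    records = list(records)
    if not records:
        raise DomainError("cannot pool an empty set of records")
    _check_same_year(records)
    totals = BirthCounts(
        stillbirths=sum(r.counts.stillbirths for r in records),
        live_births=sum(r.counts.live_births for r in records),
        neonatal_deaths=sum(r.counts.neonatal_deaths for r in records),
    )
    return RateSet.from_counts(totals)


def dispersion(values: Iterable[float]) -> tuple[float, float, float]:
    """(mean, sample SD, CV%) of a collection of country-level rates."""
    values = list(values)
    n = len(values)
    if n < 2:
        raise DomainError(f"dispersion needs >= 2 values, got {n}")
    mean = sum(values) / n
    if mean <= 0:
        raise DomainError(f"CV undefined for non-positive mean ({mean})")
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    sd = math.sqrt(var)
    return mean, sd, 100.0 * sd / mean


def group_yll(records: Iterable[CountryRecord]) -> float:
    """Total person-years lost to stillbirths across the group."""
    records = list(records)
    if not records:
        raise DomainError("cannot total YLL of an empty set of records")
    _check_same_year(records)
    total = 0.0
    for r in records:
        try:
            adj = adjusted_expectancy(r.le, r.slbr(), r.counts.live_births)
        except DomainError as exc:
            raise DomainError(f"{r.country}: {exc}") from exc
        total += adj.yll
    return total


def summarize_group(records: Iterable[CountryRecord], group_key: str) -> GroupSummary:
    """Full Table-2/4-style summary for one group of country records."""
    records = list(records)
    if not records:
        raise DomainError(f"group {group_key!r} has no records")
    _check_same_year(records)

    pooled = pooled_rates(records)
    slbrs = [r.slbr() for r in records]
    if len(records) >= 2:
        mean_rate, sd_rate, cv = dispersion(slbrs)
    else:
        mean_rate, sd_rate, cv = slbrs[0], 0.0, 0.0

    adjusted = [
        adjusted_expectancy(r.le, s, r.counts.live_births)
        for r, s in zip(records, slbrs)
    ]
    n = len(records)
    return GroupSummary(
        group_key=group_key,
        n_countries=n,
        pooled_slbr=pooled.slbr,
        pooled_ratio=pooled.sb_nm_ratio,
        mean_rate=mean_rate,
        sd_rate=sd_rate,
        cv_percent=cv,
        mean_le=sum(a.le for a in adjusted) / n,
        mean_sale=sum(a.sale for a in adjusted) / n,
        mean_decrement=sum(a.decrement for a in adjusted) / n,
        total_yll=sum(a.yll for a in adjusted),
    )


def summarize(
    records: Iterable[CountryRecord],
    by: str = "region",
) -> list[GroupSummary]:
    """Summaries per region, per income group, or for the world.

    ``by`` is one of ``"region"``, ``"income"``, ``"world"``.  Group order is
    deterministic (sorted keys); the world summary is always appended last
    for the grouped variants so totals can be reconciled at a glance.
    """
    records = list(records)
    if by == "world":
        return [summarize_group(records, WORLD_KEY)]
    if by == "region":
        keyfn = lambda r: r.region  # noqa: E731
    elif by == "income":
        keyfn = lambda r: r.income_group  # noqa: E731
    else:
        raise DomainError(
            f"unknown grouping {by!r}; expected 'region', 'income' or 'world'"
        )
    groups: dict[str, list[CountryRecord]] = {}
    for r in records:
        groups.setdefault(keyfn(r), []).append(r)
    out = [summarize_group(groups[k], k) for k in sorted(groups)]
    out.append(summarize_group(records, WORLD_KEY))
    return out


def group_gap(a: GroupSummary, b: GroupSummary, field: str) -> float:
    """Signed difference ``a.field - b.field`` between two group summaries."""
    if field not in GroupSummary.__dataclass_fields__:
        raise DomainError(
            f"unknown summary field {field!r}; expected one of "
            f"{sorted(GroupSummary.__dataclass_fields__)}"
        )
    va, vb = getattr(a, field), getattr(b, field)
    if not isinstance(va, (int, float)) or isinstance(va, bool):
        raise DomainError(f"field {field!r} is not numeric")
    return va - vb


_THRESHOLD_METRICS = {
    "slbr": lambda r: r.slbr(),
    "nmr": lambda r: r.nmr(),
}


def threshold_count(
    records_t0: Iterable[CountryRecord],
    records_t1: Iterable[CountryRecord],
    metric: str = "nmr",
    min_reduction: float = 40.0,
) -> tuple[int, float | None]:
    """Count countries whose rate fell by more than ``min_reduction`` percent.

    Records are paired across the two years by ISO3 (or name); unpaired
    countries are skipped with a logged warning.  Returns the qualifier
    count and the mean percentage reduction among qualifiers (``None`` when
    nobody qualifies).  Countries whose rate *rose* never qualify, whatever
    the magnitude of the rise.
    """
    if metric not in _THRESHOLD_METRICS:
        raise DomainError(
            f"unknown metric {metric!r}; expected one of "
            f"{sorted(_THRESHOLD_METRICS)}"
        )
    getter = _THRESHOLD_METRICS[metric]
    t0 = {r.key: r for r in records_t0}
    t1 = {r.key: r for r in records_t1}
    for key in sorted(set(t0) ^ set(t1)):
        logger.warning("threshold_count: %s present in only one year; skipped", key)

    reductions: list[float] = []
    for key in sorted(set(t0) & set(t1)):
        change = pct_change(getter(t0[key]), getter(t1[key]))
        if change < 0 and abs(change) > min_reduction:
            reductions.append(abs(change))
    if not reductions:
        return 0, None
    return len(reductions), sum(reductions) / len(reductions)
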