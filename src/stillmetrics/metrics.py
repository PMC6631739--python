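"""Closed-form stillbirth metrics.

Two stillbirth rates circulate in the perinatal-health literature, differing
only in their denominator:

* **SLBR** (still live-birth rate, the ICD "fetal death ratio"):
  stillbirths per 1000 *live* births, ``1000 * SB / LB`` — the same
  denominator as the neonatal mortality rate (NMR).
* **STBR** (still total-birth rate, the ICD "fetal death rate"):
  stillbirths per 1000 *total* (still + live) births, ``1000 * SB / TB``.

The two are linked by an exact algebraic identity,

    SLBR - STBR = SLBR * STBR / 1000 > 0   (for SB > 0)

so either can be recovered from the other without the underlying counts.
Because SLBR shares its denominator with NMR, the ratio SLBR:NMR equals the
count ratio SB:NM; the STBR:NMR ratio does not (it is smaller by the factor
LB/TB).

Sharing the live-birth denominator also lets SLBR adjust life expectancy at
birth for stillbirths.  Life expectancy of 1000 live births is ``1000 * LE``
person-years; spreading that total over the 1000 + SLBR *total* births that
produced them gives the stillbirths-adjusted life expectancy

    SALE = 1000 * LE / (1000 + SLBR)

with decrement ``LE - SALE = SLBR * LE / (1000 + SLBR)``.  Years of life lost
to stillbirths (a YLL-only DALY — stillbirths carry no morbidity term) are the
decrement times the number of live births.

All functions operate on unrounded values; rounding is a presentation
concern (see :func:`round_rate`, :func:`yll_in_units`).  Degenerate inputs
(zero live births, zero NMR) raise :class:`DomainError` rather than
propagating NaNs into aggregates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "DomainError",
    "InconsistencyError",
    "BirthCounts",
    "RateSet",
    "AdjustedExpectancy",
    "GrowthDecomposition",
    "compute_slbr",
    "compute_stbr",
    "compute_nmr",
    "slbr_to_stbr",
    "stbr_to_slbr",
    "rate_gap",
    "live_births_from_nmr",
    "ratio_slbr_nmr",
    "ratio_stbr_nmr",
    "compute_sale",
    "le_decrement",
    "stillbirth_yll",
    "adjusted_expectancy",
    "growth_decomposition",
    "pct_change",
    "round_rate",
    "round_percent",
    "yll_in_units",
    "YLL_UNITS",
]


class DomainError(ValueError):
    """An input is outside the mathematical domain of a metric."""


class InconsistencyError(DomainError):
    """Inputs are individually valid but jointly contradictory."""


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise DomainError(f"{name} must be finite, got {value!r}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BirthCounts:
    """Raw annual counts for one country-year.

    Counts are non-negative reals, not integers: live births are routinely
    back-derived from a neonatal death count and a published NMR
    (:func:`live_births_from_nmr`), which yields fractional values.  Total
    births are always derived (``stillbirths + live_births``), never stored.
    """

    stillbirths: float
    live_births: float
    neonatal_deaths: float

    def __post_init__(self) -> None:
        for name in ("stillbirths", "live_births", "neonatal_deaths"):
            value = getattr(self, name)
            _require_finite(name, value)
            if value < 0:
                raise DomainError(f"{name} must be >= 0, got {value}")
        if self.neonatal_deaths > self.live_births:
            raise InconsistencyError(
                f"neonatal_deaths ({self.neonatal_deaths}) exceeds "
                f"live_births ({self.live_births})"
            )

    @property
    def total_births(self) -> float:
        return self.stillbirths + self.live_births


@dataclass(frozen=True)
class RateSet:
    """The three per-1000 rates plus the SB:NM ratio for one country-year.

    ``sb_nm_ratio`` is stored dimensionless (world 2015 is ~0.977); tables
    conventionally print it multiplied by 100.
    """

    slbr: float
    stbr: float
    nmr: float
    sb_nm_ratio: float

    def __post_init__(self) -> None:
        if not (0 <= self.stbr < 1000):
            raise DomainError(f"stbr must lie in [0, 1000), got {self.stbr}")
        if self.slbr < self.stbr:
            raise InconsistencyError(
                f"slbr ({self.slbr}) < stbr ({self.stbr}): impossible pair"
            )

    @classmethod
    def from_counts(cls, counts: BirthCounts) -> "RateSet":
        """Derive all four quantities from one set of counts."""
        slbr = compute_slbr(counts)
        nmr = compute_nmr(counts)
        if counts.neonatal_deaths == 0:
            raise DomainError(
                "SB:NM ratio undefined with zero neonatal deaths"
            )
        return cls(
            slbr=slbr,
            stbr=compute_stbr(counts),
            nmr=nmr,
            sb_nm_ratio=counts.stillbirths / counts.neonatal_deaths,
        )


@dataclass(frozen=True)
class AdjustedExpectancy:
    """Life expectancy before and after the stillbirth adjustment.

    ``le`` is the traditional life expectancy at birth (of live births),
    ``sale`` the stillbirths-adjusted value (life expectancy of total
    births), ``decrement`` their difference and ``yll`` the person-years
    lost to stillbirths (decrement x live births).
    """

    le: float
    sale: float
    decrement: float
    yll: float

    def __post_init__(self) -> None:
        if self.sale > self.le:
            raise InconsistencyError(
                f"sale ({self.sale}) exceeds le ({self.le})"
            )
        if self.yll < 0:
            raise DomainError(f"yll must be >= 0, got {self.yll}")


@dataclass(frozen=True)
class GrowthDecomposition:
    """Proportionate changes linking SLBR, NMR, and their ratio.

    Because SLBR = NMR x (SLBR:NMR), growth rates satisfy the exact
    multiplicative relation (1 + g_slbr) = (1 + g_nmr)(1 + g_ratio), which in
    simple growth rates is the first-order additive rule
    g_nmr ~= g_slbr - g_ratio.  Both the additive and the exact NMR growth
    are reported; the library never silently substitutes one for the other.
    All fields are dimensionless proportions (0.1 == +10%).
    """

    g_slbr: float
    g_ratio: float
    g_nmr_additive: float
    g_nmr_exact: float


# ---------------------------------------------------------------------------
# Rate definitions and interconversion
# ---------------------------------------------------------------------------

def compute_slbr(counts: BirthCounts) -> float:
    """Still live-birth rate: stillbirths per 1000 live births."""
    if counts.live_births <= 0:
        raise DomainError(
            f"SLBR undefined: zero live births (counts={counts})"
        )
    return 1000.0 * counts.stillbirths / counts.live_births


def compute_stbr(counts: BirthCounts) -> float:
    """Still total-birth rate: stillbirths per 1000 total births."""
    total = counts.total_births
    if total <= 0:
        raise DomainError(
            f"STBR undefined: zero total births (counts={counts})"
        )
    return 1000.0 * counts.stillbirths / total


def compute_nmr(counts: BirthCounts) -> float:
    """Neonatal mortality rate: neonatal deaths per 1000 live births."""
    if counts.live_births <= 0:
        raise DomainError(
            f"NMR undefined: zero live births (counts={counts})"
        )
    return 1000.0 * counts.neonatal_deaths / counts.live_births


def slbr_to_stbr(slbr: float) -> float:
    """Convert a per-1000-live-births rate to a per-1000-total-births rate.

    Solving the gap identity for STBR gives
    ``STBR = 1000 * SLBR / (1000 + SLBR)``.
    """
    _require_finite("slbr", slbr)
    if slbr < 0:
        raise DomainError(f"slbr must be >= 0, got {slbr}")
    return 1000.0 * slbr / (1000.0 + slbr)


def stbr_to_slbr(stbr: float) -> float:
    """Convert a per-1000-total-births rate to a per-1000-live-births rate.

    Exact inverse of :func:`slbr_to_stbr`:
    ``SLBR = 1000 * STBR / (1000 - STBR)``.  Global stillbirth estimates are
    published as STBR, so this is the workhorse conversion.
    """
    _require_finite("stbr", stbr)
    if stbr < 0:
        raise DomainError(f"stbr must be >= 0, got {stbr}")
    if stbr >= 1000:
        raise DomainError(
            f"stbr must be < 1000 per 1000 total births, got {stbr}"
        )
    return 1000.0 * stbr / (1000.0 - stbr)


def rate_gap(slbr: float, stbr: float) -> float:
    """Excess of SLBR over STBR (equals SLBR*STBR/1000 on exact pairs)."""
    _require_finite("slbr", slbr)
    _require_finite("stbr", stbr)
    if slbr < 0 or stbr < 0:
        raise DomainError("rates must be >= 0")
    if slbr < stbr:
        raise InconsistencyError(
            f"slbr ({slbr}) < stbr ({stbr}): not a consistent pair"
        )
    return slbr - stbr


def live_births_from_nmr(neonatal_deaths: float, nmr: float) -> float:
    """Back-derive the live-birth count from NM and its published rate.

    ``LB = 1000 * NM / NMR``.  The result is fractional in general and is
    deliberately not rounded.
    """
    _require_finite("neonatal_deaths", neonatal_deaths)
    _require_finite("nmr", nmr)
    if neonatal_deaths < 0:
        raise DomainError(f"neonatal_deaths must be >= 0, got {neonatal_deaths}")
    if nmr < 0:
        raise DomainError(f"nmr must be >= 0, got {nmr}")
    if nmr == 0:
        if neonatal_deaths > 0:
            raise InconsistencyError(
                f"nmr is 0 but neonatal_deaths is {neonatal_deaths}: "
                "a zero rate cannot produce deaths"
            )
        raise DomainError(
            "live births indeterminate with NM = 0 and NMR = 0; "
            "supply live_births directly"
        )
    return 1000.0 * neonatal_deaths / nmr


# ---------------------------------------------------------------------------
# Stillbirth-rate : NMR ratios
# ---------------------------------------------------------------------------

def ratio_slbr_nmr(slbr: float, nmr: float) -> float:
    """SLBR:NMR ratio; equals the count ratio SB:NM (shared LB denominator)."""
    _require_finite("slbr", slbr)
    _require_finite("nmr", nmr)
    if nmr <= 0:
        raise DomainError(f"nmr must be > 0 for a ratio, got {nmr}")
    if slbr < 0:
        raise DomainError(f"slbr must be >= 0, got {slbr}")
    return slbr / nmr


def ratio_stbr_nmr(stbr: float, nmr: float, lb_share: float | None = None) -> float:
    """STBR:NMR ratio; equals (SB/NM) x (LB/TB), hence always <= SLBR:NMR.

    ``lb_share`` (LB/TB) is accepted for validation against the identity and
    must lie in (0, 1]; it does not enter the quotient.
    """
    _require_finite("stbr", stbr)
    _require_finite("nmr", nmr)
    if nmr <= 0:
        raise DomainError(f"nmr must be > 0 for a ratio, got {nmr}")
    if stbr < 0:
        raise DomainError(f"stbr must be >= 0, got {stbr}")
    if lb_share is not None and not (0 < lb_share <= 1):
        raise DomainError(f"lb_share must lie in (0, 1], got {lb_share}")
    return stbr / nmr


# ---------------------------------------------------------------------------
# Stillbirths-adjusted life expectancy and YLL
# ---------------------------------------------------------------------------

def compute_sale(le: float, slbr: float) -> float:
    """Stillbirths-adjusted life expectancy, ``1000*LE / (1000 + SLBR)``.

    The person-years lived by 1000 live births are attributed to the
    1000 + SLBR total births behind them.  Equals ``le`` iff ``slbr`` is
    zero; strictly decreasing in ``slbr``.
    """
    _require_finite("le", le)
    _require_finite("slbr", slbr)
    if le <= 0:
        raise DomainError(f"le must be > 0 years, got {le}")
    if slbr < 0:
        raise DomainError(f"slbr must be >= 0, got {slbr}")
    return 1000.0 * le / (1000.0 + slbr)


def le_decrement(le: float, slbr: float) -> float:
    """Life-expectancy loss from counting stillbirths.

    ``SLBR * LE / (1000 + SLBR)``, identical to ``le - compute_sale(le,
    slbr)`` and increasing in both arguments: a higher stillbirth rate loses
    more years, and so does a higher life expectancy (each stillbirth
    forgoes more years).
    """
    _require_finite("le", le)
    _require_finite("slbr", slbr)
    if le <= 0:
        raise DomainError(f"le must be > 0 years, got {le}")
    if slbr < 0:
        raise DomainError(f"slbr must be >= 0, got {slbr}")
    return slbr * le / (1000.0 + slbr)


def stillbirth_yll(le: float, sale: float, live_births: float) -> float:
    """Years of life lost to stillbirths: ``(LE - SALE) * LB`` person-years.

    Stillbirths have no life expectancy of their own, so the usual
    deaths-times-expectancy YLL formula does not apply; the loss is instead
    the per-live-birth decrement spread over the live-birth cohort.
    Use :func:`yll_in_units` for table-style unit conversion.
    """
    _require_finite("le", le)
    _require_finite("sale", sale)
    _require_finite("live_births", live_births)
    if sale < 0:
        raise DomainError(f"sale must be >= 0, got {sale}")
    if sale > le:
        raise InconsistencyError(f"sale ({sale}) exceeds le ({le})")
    if live_births < 0:
        raise DomainError(f"live_births must be >= 0, got {live_births}")
    return (le - sale) * live_births


def adjusted_expectancy(le: float, slbr: float, live_births: float) -> AdjustedExpectancy:
    """Bundle LE, SALE, decrement and YLL for one country-year."""
    sale = compute_sale(le, slbr)
    return AdjustedExpectancy(
        le=le,
        sale=sale,
        decrement=le - sale,
        yll=stillbirth_yll(le, sale, live_births),
    )


# ---------------------------------------------------------------------------
# Growth decomposition and percentage change
# ---------------------------------------------------------------------------

def growth_decomposition(v0: float, v1: float, w0: float, w1: float) -> GrowthDecomposition:
    """Decompose NMR growth into SLBR growth minus SLBR:NMR-ratio growth.

    ``(v0, v1)`` are SLBR at two dates, ``(w0, w1)`` the SLBR:NMR ratio.
    Since NMR = SLBR / (SLBR:NMR), the exact NMR growth is
    ``(1 + g_slbr)/(1 + g_ratio) - 1``; the additive variant
    ``g_slbr - g_ratio`` is the first-order approximation commonly used with
    simple percentage changes.  Both are returned, clearly labelled.
    """
    for name, value in (("v0", v0), ("v1", v1), ("w0", w0), ("w1", w1)):
        _require_finite(name, value)
    if v0 <= 0 or w0 <= 0:
        raise DomainError(
            f"baselines must be > 0 (v0={v0}, w0={w0})"
        )
    g_slbr = (v1 - v0) / v0
    g_ratio = (w1 - w0) / w0
    return GrowthDecomposition(
        g_slbr=g_slbr,
        g_ratio=g_ratio,
        g_nmr_additive=g_slbr - g_ratio,
        g_nmr_exact=(1.0 + g_slbr) / (1.0 + g_ratio) - 1.0,
    )


def pct_change(old: float, new: float, magnitude_only: bool = False) -> float:
    """Percentage change from ``old`` to ``new`` (+10.0 means +10%).

    With ``magnitude_only`` the sign is dropped — the convention when
    reporting "percentage reductions" ignoring the negative sign.
    """
    _require_finite("old", old)
    _require_finite("new", new)
    if old == 0:
        raise DomainError("pct_change undefined for a zero baseline")
    change = 100.0 * (new - old) / old
    return abs(change) if magnitude_only else change


# ---------------------------------------------------------------------------
# Presentation helpers (rounding and units live here, never upstream)
# ---------------------------------------------------------------------------

#: YLL display divisors: hundreds of thousands (table convention), millions
#: (running-text convention), raw person-years.
YLL_UNITS: dict[str, float] = {"1e5": 1e5, "1e6": 1e6, "years": 1.0}


def round_rate(value: float, ndigits: int = 2) -> float:
    """Round a rate or a year figure for display (2 dp convention)."""
    return round(value, ndigits)


def round_percent(value: float) -> float:
    """Round a percentage (or a ratio x100) for display (1 dp convention)."""
    return round(value, 1)


def yll_in_units(yll_person_years: float, units: str = "1e5") -> float:
    """Convert person-years to a display unit ('1e5', '1e6' or 'years')."""
    try:
        divisor = YLL_UNITS[units]
    except KeyError:
        raise DomainError(
            f"unknown YLL unit {units!r}; expected one of {sorted(YLL_UNITS)}"
        ) from None
    return yll_person_years / divisor
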