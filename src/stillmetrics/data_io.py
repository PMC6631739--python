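"""Panel I/O, embedded reference tables, and summary writers.

Input is a country-level annual panel as delimited text (comma or tab,
auto-detected; column names case-insensitive).  Required columns::

    country, region, income_group, year,
    stillbirths, neonatal_deaths, neonatal_mortality_rate, life_expectancy

Optional columns: ``iso3``, ``live_births``.  When ``live_births`` is
absent it is back-derived from the neonatal death count and rate
(``LB = 1000 * NM / NMR``) and the derivation is flagged in the read
result's metadata.  Per-row validation failures are collected — with row
numbers and machine-readable reason codes — rather than aborting the read;
only valid rows become records.

The ``TABLE1`` … ``TABLE4`` fixtures embed published reference values
(country rates and gaps, group rates and dispersion for 2000/2015,
country SALE/decrement/YLL, and group means and YLL totals).  They are
literal data, never recomputed: tests use them as oracles, so a check
against them distinguishes "the code reproduces the published numbers"
from "the code trusts its own output".
"""

from __future__ import annotations

import csv
import io
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import pandas as pd
import yaml

from .cohort import INCOME_GROUPS, MDG_REGIONS, CountryRecord, GroupSummary
from .metrics import (
    BirthCounts,
    DomainError,
    InconsistencyError,
    live_births_from_nmr,
    round_percent,
    round_rate,
    yll_in_units,
)

logger = logging.getLogger(__name__)

__all__ = [
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
    "RowError",
    "PanelReadResult",
    "read_panel",
    "read_group_config",
    "records_to_frame",
    "write_panel",
    "write_summary",
    "errors_to_json",
    "TABLE1",
    "TABLE2",
    "TABLE3",
    "TABLE4",
    "INCOME_RICHER",
    "INCOME_POORER",
]

REQUIRED_COLUMNS = (
    "country",
    "region",
    "income_group",
    "year",
    "stillbirths",
    "neonatal_deaths",
    "neonatal_mortality_rate",
    "life_expectancy",
)
OPTIONAL_COLUMNS = ("iso3", "live_births")

INCOME_RICHER = "high+upper-middle"
INCOME_POORER = "lower-middle+low"


# ---------------------------------------------------------------------------
# Reference tables (literal published values; test oracles, not inputs)
# ---------------------------------------------------------------------------

def _frame(columns: Sequence[str], rows: Sequence[tuple]) -> pd.DataFrame:
    return pd.DataFrame(list(rows), columns=list(columns))


#: Ten countries with the highest 2015 stillbirth rates: SLBR, STBR (both
#: per 1000) and their gap.
TABLE1 = _frame(
    ("country", "slbr", "stbr", "gap"),
    [
        ("Pakistan", 45.09, 43.15, 1.94),
        ("Nigeria", 44.81, 42.89, 1.92),
        ("Chad", 41.58, 39.92, 1.66),
        ("Guinea-Bissau", 38.10, 36.70, 1.40),
        ("Niger", 38.07, 36.67, 1.40),
        ("Somalia", 36.80, 35.49, 1.31),
        ("Djibouti", 35.85, 34.61, 1.24),
        ("Central African Republic", 35.59, 34.37, 1.22),
        ("Togo", 35.36, 34.15, 1.21),
        ("Mali", 33.63, 32.53, 1.10),
    ],
)

#: Group-level SLBR and SLBR:NMR (x100) for 2000 and 2015, with the SD and
#: CV (SD/mean, %) of member-country values.  Rates/ratios are pooled for
#: the whole group; SD and mean are across member countries.
TABLE2 = _frame(
    (
        "group",
        "slbr_2000", "slbr_2015", "ratio_2000", "ratio_2015",
        "sd_slbr_2000", "sd_slbr_2015", "sd_ratio_2000", "sd_ratio_2015",
        "cv_slbr_2000", "cv_slbr_2015", "cv_ratio_2000", "cv_ratio_2015",
    ),
    [
        ("DR", 4.51, 3.44, 83.5, 107.0, 2.21, 1.63, 54.7, 68.4,
         45.3, 46.9, 50.9, 49.1),
        ("SA", 36.76, 26.16, 81.1, 89.7, 15.8, 12.8, 14.9, 27.1,
         53.7, 65.2, 18.8, 28.2),
        ("CCA", 17.14, 12.02, 63.3, 74.5, 4.85, 3.53, 26.3, 45.4,
         25.9, 27.5, 34.1, 43.9),
        ("EA", 14.47, 7.21, 69.7, 128.9, 7.14, 4.73, 27.7, 31.6,
         57.3, 62.3, 36.3, 29.2),
        ("LAC", 11.40, 8.28, 77.8, 89.3, 5.64, 4.77, 37.3, 42.3,
         42.9, 46.2, 39.2, 39.1),
        ("NAME", 20.28, 14.75, 94.6, 114.1, 8.91, 6.86, 36.9, 95.7,
         54.9, 57.7, 33.2, 61.0),
        ("SEA", 17.28, 12.37, 81.6, 90.9, 7.22, 5.31, 37.6, 42.7,
         44.2, 41.9, 38.1, 39.6),
        ("SSA", 36.92, 29.50, 90.5, 103.2, 10.2, 8.45, 19.7, 22.8,
         32.9, 34.7, 23.0, 24.2),
        ("World", 25.37, 18.73, 83.1, 97.7, 12.5, 9.86, 38.5, 58.8,
         72.3, 75.5, 40.3, 50.3),
        (INCOME_RICHER, 11.33, 7.40, 75.1, 101.5, 6.43, 5.03, 46.5, 70.9,
         66.4, 69.7, 45.3, 54.4),
        (INCOME_POORER, 33.97, 25.28, 84.9, 97.0, 11.1, 9.15, 19.5, 26.1,
         40.2, 43.2, 22.7, 26.7),
    ],
)

#: Countries with the largest 2015 life-expectancy decrements (first ten
#: rows) and the remaining members of the YLL top ten (last seven): LE and
#: SALE in years, decrement in years, YLL in hundreds of thousands of
#: person-years.
TABLE3 = _frame(
    ("country", "le", "sale", "decrement", "yll_1e5"),
    [
        ("Pakistan", 66.38, 63.52, 2.86, 152.4),
        ("Nigeria", 53.05, 50.77, 2.28, 159.1),
        ("Niger", 61.97, 59.70, 2.27, 21.6),
        ("Djibouti", 62.29, 60.13, 2.16, 0.5),
        ("Chad", 51.87, 49.80, 2.07, 12.5),
        ("Togo", 60.12, 58.07, 2.05, 5.1),
        ("Guinea-Bissau", 55.47, 53.43, 2.04, 1.3),
        ("Somalia", 55.69, 53.71, 1.98, 8.8),
        ("Comoros", 63.55, 61.61, 1.94, 0.5),
        ("Ethiopia", 64.58, 62.66, 1.92, 60.3),
        ("India", 68.35, 66.78, 1.57, 392.0),
        ("China", 75.99, 75.45, 0.54, 91.8),
        ("Bangladesh", 72.00, 70.17, 1.83, 58.1),
        ("Congo, Dem. Rep.", 59.02, 57.41, 1.61, 50.4),
        ("Indonesia", 69.07, 68.16, 0.91, 50.0),
        ("Tanzania", 65.49, 64.02, 1.47, 30.1),
        ("Egypt, Arab Rep.", 71.32, 70.45, 0.87, 24.4),
    ],
)

#: Group-level 2015 means of LE, SALE and the decrement (unweighted across
#: member countries), YLL totals in millions of person-years (the printed
#: column header says hundreds of thousands, but the values are only
#: consistent with the country-level table and the quoted world total when
#: read as millions), and the member-country SD / CV of the year measures.
TABLE4 = _frame(
    (
        "group",
        "mean_le", "mean_sale", "mean_decrement", "yll_millions",
        "sd_le", "sd_sale", "sd_decrement",
        "cv_le", "cv_sale", "cv_decrement",
    ),
    [
        ("DR", 79.31, 79.04, 0.27, 3.6, 3.7, 3.7, 0.11, 4.6, 4.7, 41.8),
        ("SA", 70.53, 69.23, 1.30, 63.4, 5.1, 5.7, 0.79, 7.2, 8.2, 60.2),
        ("CCA", 70.89, 69.99, 0.89, 1.6, 3.1, 3.1, 0.23, 4.3, 4.5, 25.8),
        ("EA", 74.58, 74.03, 0.54, 9.7, 5.8, 6.0, 0.32, 7.7, 8.1, 57.9),
        ("LAC", 74.14, 73.40, 0.75, 6.7, 3.8, 4.0, 0.45, 5.1, 5.4, 41.6),
        ("NAME", 74.06, 73.21, 0.85, 10.4, 3.7, 4.0, 0.45, 5.0, 5.5, 52.3),
        ("SEA", 71.22, 70.34, 0.88, 10.6, 4.7, 5.0, 0.34, 6.6, 7.0, 38.9),
        ("SSA", 60.33, 58.92, 1.41, 59.4, 5.8, 6.0, 0.43, 9.7, 10.1, 30.8),
        ("World", 71.18, 70.33, 0.85, 165.3, 8.38, 8.82, 0.56,
         11.8, 12.5, 65.2),
        (INCOME_RICHER, 76.14, 75.63, 0.51, 27.2, 5.6, 5.9, 0.32,
         7.4, 7.7, 62.5),
        (INCOME_POORER, 64.69, 63.39, 1.30, 138.1, 6.83, 7.07, 0.48,
         10.6, 11.1, 37.0),
    ],
)


# ---------------------------------------------------------------------------
# Panel reading
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RowError:
    """One rejected panel row: position, identity, and a reason code."""

    row: int                 # 1-based data row number (header excluded)
    country: str
    code: str                # machine-readable reason
    message: str


@dataclass
class PanelReadResult:
    """Valid records plus an error report and derivation metadata."""

    records: list[CountryRecord]
    errors: list[RowError] = field(default_factory=list)
    derived_live_births: int = 0    # rows whose LB came from NM / NMR

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def read_group_config(path: str | Path) -> dict:
    """Load a YAML grouping config.

    Recognised keys: ``regions`` / ``income_groups`` (lists replacing the
    allowed label sets) and ``countries`` (mapping country name or ISO3 to
    ``{region: ..., income_group: ...}`` overrides applied before
    validation).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise DomainError(f"group config {path} must be a mapping")
    return cfg


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t").delimiter
    except csv.Error:
        return "\t" if "\t" in sample else ","


def _as_float(raw: object, column: str) -> float:
    if raw is None or (isinstance(raw, str) and not raw.strip()):
        raise ValueError(f"missing value in column {column!r}")
    value = float(raw)  # may raise ValueError
    if not math.isfinite(value):
        raise ValueError(f"non-finite value in column {column!r}")
    return value


def read_panel(
    source: str | Path | TextIO,
    *,
    delimiter: str | None = None,
    group_config: dict | str | Path | None = None,
) -> PanelReadResult:
    """Read and validate a delimited country panel.

    A missing required column is a hard error; everything row-level
    (unparseable numbers, inconsistent counts, unknown group labels) lands
    in the error report and the row is dropped.  The input is never
    modified.
    """
    if isinstance(group_config, (str, Path)):
        group_config = read_group_config(group_config)
    group_config = group_config or {}
    allowed_regions = frozenset(group_config.get("regions", MDG_REGIONS))
    allowed_income = frozenset(group_config.get("income_groups", INCOME_GROUPS))
    overrides = group_config.get("countries", {}) or {}

    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    if not text.strip():
        raise DomainError("panel is empty (no header)")
    if delimiter is None:
        delimiter = _sniff_delimiter(text.splitlines()[0])

    reader = csv.DictReader(io.StringIO(text), delimiter=delimiter)
    header = [h.strip().lower() for h in reader.fieldnames or []]
    missing = [c for c in REQUIRED_COLUMNS if c not in header]
    if missing:
        raise DomainError(f"panel is missing required columns: {missing}")

    records: list[CountryRecord] = []
    errors: list[RowError] = []
    derived = 0

    for idx, raw_row in enumerate(reader, start=1):
        row = {
            (k.strip().lower() if k else k): (v.strip() if isinstance(v, str) else v)
            for k, v in raw_row.items()
        }
        country = row.get("country") or f"<row {idx}>"

        def reject(code: str, message: str) -> None:
            errors.append(RowError(row=idx, country=country, code=code,
                                   message=message))

        if not row.get("country"):
            reject("missing_value", "country name is empty")
            continue
        try:
            year = int(_as_float(row.get("year"), "year"))
            sb = _as_float(row.get("stillbirths"), "stillbirths")
            nm = _as_float(row.get("neonatal_deaths"), "neonatal_deaths")
            nmr = _as_float(row.get("neonatal_mortality_rate"),
                            "neonatal_mortality_rate")
            le = _as_float(row.get("life_expectancy"), "life_expectancy")
        except ValueError as exc:
            reject("bad_number", str(exc))
            continue

        lb_raw = row.get("live_births")
        try:
            if lb_raw is None or lb_raw == "":
                lb = live_births_from_nmr(nm, nmr)
                derived += 1
            else:
                lb = _as_float(lb_raw, "live_births")
        except InconsistencyError as exc:
            reject("nmr_zero_inconsistent", str(exc))
            continue
        except (DomainError, ValueError) as exc:
            reject("bad_number", str(exc))
            continue

        iso3 = row.get("iso3") or None
        region = overrides.get(iso3 or "", {}).get("region") \
            or overrides.get(country, {}).get("region") \
            or row.get("region", "")
        income = overrides.get(iso3 or "", {}).get("income_group") \
            or overrides.get(country, {}).get("income_group") \
            or row.get("income_group", "")
        if region not in allowed_regions:
            reject("bad_label", f"unknown region label {region!r}")
            continue
        if income not in allowed_income:
            reject("bad_label", f"unknown income_group label {income!r}")
            continue

        try:
            counts = BirthCounts(stillbirths=sb, live_births=lb,
                                 neonatal_deaths=nm)
            record = CountryRecord(
                country=country, iso3=iso3, region=region,
                income_group=income, year=year, counts=counts, le=le,
            )
        except DomainError as exc:
            reject("bad_counts", str(exc))
            continue
        records.append(record)

    if errors:
        logger.warning("read_panel: rejected %d of %d rows",
                       len(errors), len(errors) + len(records))
    return PanelReadResult(records=records, errors=errors,
                           derived_live_births=derived)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def records_to_frame(records: Iterable[CountryRecord]) -> pd.DataFrame:
    """Flatten records into a PanelSchema-conformant DataFrame."""
    rows = []
    for r in records:
        rows.append({
            "country": r.country,
            "iso3": r.iso3 or "",
            "region": r.region,
            "income_group": r.income_group,
            "year": r.year,
            "stillbirths": r.counts.stillbirths,
            "live_births": r.counts.live_births,
            "neonatal_deaths": r.counts.neonatal_deaths,
            "neonatal_mortality_rate": (
                1000.0 * r.counts.neonatal_deaths / r.counts.live_births
            ),
            "life_expectancy": r.le,
        })
    return pd.DataFrame(rows)


def _write_frame(frame: pd.DataFrame, destination: str | Path | TextIO,
                 delimiter: str) -> None:
    if isinstance(destination, (str, Path)):
        try:
            frame.to_csv(destination, sep=delimiter, index=False)
        except OSError as exc:
            raise DomainError(f"cannot write {destination}: {exc}") from exc
    else:
        frame.to_csv(destination, sep=delimiter, index=False)


def write_panel(records: Iterable[CountryRecord],
                destination: str | Path | TextIO,
                delimiter: str = ",") -> None:
    """Write records as a panel readable by :func:`read_panel`."""
    _write_frame(records_to_frame(records), destination, delimiter)


_YLL_HEADER = {"1e5": "total_yll_1e5", "1e6": "total_yll_millions",
               "years": "total_yll_person_years"}


def write_summary(
    summaries: Sequence[GroupSummary],
    destination: str | Path | TextIO,
    *,
    yll_units: str = "1e5",
    round_output: bool = True,
    delimiter: str = ",",
) -> pd.DataFrame:
    """Write group summaries as delimited text with unit-annotated headers.

    Column order is deterministic; rates/years are rounded to 2 dp and
    percentages/ratios-x100 to 1 dp when ``round_output`` is set.  Returns
    the frame written (useful for display).
    """
    summaries = list(summaries)
    if not summaries:
        raise DomainError("no summaries to write")
    if yll_units not in _YLL_HEADER:
        raise DomainError(
            f"unknown YLL unit {yll_units!r}; expected one of "
            f"{sorted(_YLL_HEADER)}"
        )
    rows = []
    for s in summaries:
        yll = yll_in_units(s.total_yll, yll_units)
        ratio_x100 = 100.0 * s.pooled_ratio
        if round_output:
            row = {
                "group": s.group_key,
                "n_countries": s.n_countries,
                "pooled_slbr_per1000": round_rate(s.pooled_slbr),
                "sb_nm_ratio_x100": round_percent(ratio_x100),
                "mean_slbr_per1000": round_rate(s.mean_rate),
                "sd_slbr_per1000": round_rate(s.sd_rate),
                "cv_slbr_percent": round_percent(s.cv_percent),
                "mean_le_years": round_rate(s.mean_le),
                "mean_sale_years": round_rate(s.mean_sale),
                "mean_decrement_years": round_rate(s.mean_decrement),
                _YLL_HEADER[yll_units]: round_rate(yll, 1)
                if yll_units != "years" else round(yll),
            }
        else:
            row = {
                "group": s.group_key,
                "n_countries": s.n_countries,
                "pooled_slbr_per1000": s.pooled_slbr,
                "sb_nm_ratio_x100": ratio_x100,
                "mean_slbr_per1000": s.mean_rate,
                "sd_slbr_per1000": s.sd_rate,
                "cv_slbr_percent": s.cv_percent,
                "mean_le_years": s.mean_le,
                "mean_sale_years": s.mean_sale,
                "mean_decrement_years": s.mean_decrement,
                _YLL_HEADER[yll_units]: yll,
            }
        rows.append(row)
    frame = pd.DataFrame(rows)
    _write_frame(frame, destination, delimiter)
    return frame


def errors_to_json(errors: Sequence[RowError]) -> str:
    """Serialise the row-error report (one entry per rejected row)."""
    return json.dumps([asdict(e) for e in errors], indent=2)
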