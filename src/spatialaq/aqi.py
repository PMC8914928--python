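"""Air Quality Index computation and health-category classification.

The AQI maps a pollutant concentration onto a 0-500 health-risk scale by
piecewise-linear interpolation between published breakpoints:

    I_P = (I_Hi - I_LO) / (BP_Hi - BP_LO) * (C_P - BP_LO) + I_LO

where C_P is the concentration truncated to the pollutant's reporting
precision, [BP_LO, BP_Hi] the breakpoint interval containing it, and
[I_LO, I_Hi] the matching index interval.  The final index is rounded
half-up to an integer, which the six standard categories partition:

    Good 0-50 (Green), Moderate 51-100 (Yellow), Unhealthy for Sensitive
    Groups 101-150 (Orange), Unhealthy 151-200 (Red), Very Unhealthy
    201-300 (Purple), Hazardous 301+ (Maroon).

Breakpoint concentrations are configuration data: the shipped JSON carries
the published US-EPA technical-assistance values for O3, CO, SO2 and NO2,
and any table with the same schema can be supplied instead.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

from .errors import AqiRangeError


@dataclass(frozen=True)
class AqiCategory:
    name: str
    color: str
    lo: int
    hi: float  # +inf for Hazardous


CATEGORIES: tuple[AqiCategory, ...] = (
    AqiCategory("Good", "Green", 0, 50),
    AqiCategory("Moderate", "Yellow", 51, 100),
    AqiCategory("Unhealthy for Sensitive Groups", "Orange", 101, 150),
    AqiCategory("Unhealthy", "Red", 151, 200),
    AqiCategory("Very Unhealthy", "Purple", 201, 300),
    AqiCategory("Hazardous", "Maroon", 301, math.inf),
)


@dataclass
class AqiBreakpointTable:
    """Breakpoint rows (BP_LO, BP_Hi, I_LO, I_Hi) for one pollutant.

    Rows must be sorted and contiguous in both concentration and index.
    ``truncation_decimals`` is the pollutant's reporting precision; the
    concentration is truncated (not rounded) to it before lookup.
    """

    pollutant: str
    rows: list  # of (bp_lo, bp_hi, i_lo, i_hi)
    truncation_decimals: int
    units: str = ""

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("breakpoint table has no rows")
        for bp_lo, bp_hi, i_lo, i_hi in self.rows:
            if bp_lo > bp_hi or i_lo > i_hi:
                raise ValueError("breakpoint row has inverted bounds")
        for (a_lo, a_hi, ai_lo, ai_hi), (b_lo, b_hi, bi_lo, bi_hi) in zip(
            self.rows, self.rows[1:]
        ):
            if b_lo <= a_hi:
                raise ValueError("breakpoint rows overlap or are unsorted")
            if bi_lo != ai_hi + 1:
                raise ValueError("index ranges are not contiguous")

    @property
    def max_concentration(self) -> float:
        return self.rows[-1][1]


def _load_packaged_tables() -> dict:
    text = (
        resources.files("spatialaq").joinpath("data/aqi_breakpoints.json")
        .read_text()
    )
    raw = json.loads(text)
    tables = {}
    for pollutant, spec in raw.items():
        if pollutant.startswith("_"):
            continue
        tables[pollutant] = AqiBreakpointTable(
            pollutant=pollutant,
            rows=[tuple(r) for r in spec["rows"]],
            truncation_decimals=int(spec["truncation_decimals"]),
            units=spec.get("units", ""),
        )
    return tables


_TABLES: dict | None = None


def breakpoint_table(pollutant: str) -> AqiBreakpointTable:
    """The shipped breakpoint table for O3, CO, SO2 or NO2."""
    global _TABLES
    if _TABLES is None:
        _TABLES = _load_packaged_tables()
    try:
        return _TABLES[pollutant]
    except KeyError:
        raise KeyError(
            f"no shipped breakpoint table for {pollutant!r}; "
            f"available: {sorted(_TABLES)}"
        ) from None


def load_breakpoint_table(path: str, pollutant: str) -> AqiBreakpointTable:
    """Load a user-supplied breakpoint JSON with the packaged schema."""
    with open(path) as fh:
        raw = json.load(fh)
    spec = raw[pollutant]
    return AqiBreakpointTable(
        pollutant=pollutant,
        rows=[tuple(r) for r in spec["rows"]],
        truncation_decimals=int(spec["truncation_decimals"]),
        units=spec.get("units", ""),
    )


def truncate(cp: float, decimals: int) -> float:
    """Truncate (floor) a non-negative concentration to ``decimals``."""
    scale = 10.0 ** decimals
    # guard against binary-representation error of decimal breakpoints
    return math.floor(cp * scale + 1e-9) / scale


def compute_aqi(cp: float, table: AqiBreakpointTable) -> int:
    """Piecewise-linear AQI for concentration ``cp``, rounded half-up."""
    if not math.isfinite(cp) or cp < 0:
        raise AqiRangeError(f"concentration must be finite and >= 0, got {cp}")
    c = truncate(cp, table.truncation_decimals)
    for bp_lo, bp_hi, i_lo, i_hi in table.rows:
        if bp_lo <= c <= bp_hi:
            if bp_hi == bp_lo:
                raw = float(i_hi)
            else:
                raw = (i_hi - i_lo) / (bp_hi - bp_lo) * (c - bp_lo) + i_lo
            return int(math.floor(raw + 0.5))
    raise AqiRangeError(
        f"concentration {c} {table.units} exceeds the last breakpoint "
        f"{table.max_concentration} for {table.pollutant}"
    )


def classify_aqi(index: float) -> AqiCategory:
    """Map a (rounded) AQI value to its level of concern."""
    if not math.isfinite(index) or index < 0:
        raise AqiRangeError(f"AQI must be finite and >= 0, got {index}")
    i = int(math.floor(index + 0.5))
    for cat in CATEGORIES:
        if cat.lo <= i <= cat.hi:
            return cat
    raise AqiRangeError(f"unclassifiable AQI {index}")  # pragma: no cover


def category_bounds(name: str) -> tuple[int, float]:
    """(lo, hi) index bounds of a named category; Hazardous hi is +inf."""
    for cat in CATEGORIES:
        if cat.name == name:
            return (cat.lo, cat.hi)
    raise KeyError(f"unknown AQI category: {name!r}")


def compute_aqi_batch(
    concentrations: Sequence[float], table: AqiBreakpointTable
) -> list:
    return [compute_aqi(c, table) for c in concentrations]
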