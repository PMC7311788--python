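"""Trait data model and derivation of the 11 functional traits.

Eleven traits in three functional niche dimensions:

==================  ===========================  ==========
dimension           traits                       units
==================  ===========================  ==========
leaf economy        LA, LDMC, SLA, LNC           cm2, g/g, cm2/g, g/kg
mechanical support  STD, MPH, MDBH               g/cm3, m, cm
reproductive        FLT, FRT, FLD, FRD           Julian day, day
phenology
==================  ===========================  ==========

LA/LDMC/SLA/LNC/STD are per-leaf / per-branch ratios, MPH and MDBH are the
95th percentile of height and diameter at breast height over >=20 measured
individuals, and the four phenology traits are Julian-date midpoints and
spans of the flowering and fruiting month windows.  The analysis unit is the
(species_id, biome) pair: a species measured at two sites enters twice.
"""

from __future__ import annotations

import calendar
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BIOMES",
    "TRAIT_NAMES",
    "DIMENSIONS",
    "TraitError",
    "SpeciesRecord",
    "TraitTable",
    "DimensionScheme",
    "DEFAULT_SCHEME",
    "PhenologyWindow",
    "leaf_dry_matter_content",
    "specific_leaf_area",
    "stem_tissue_density",
    "size_percentile",
    "julian_day",
    "phenology_stats",
    "log10_transform",
    "abundance_filter",
]

#: Biome codes: tropical rainforest, subtropical evergreen-deciduous mixed,
#: warm-temperate coniferous-broadleaved mixed, cold-temperate coniferous.
BIOMES = ("TF", "SF", "WF", "CF")

TRAIT_NAMES = (
    "LA", "LDMC", "SLA", "LNC",
    "STD", "MPH", "MDBH",
    "FLT", "FRT", "FLD", "FRD",
)

DIMENSIONS = ("leaf_economy", "mechanical_support", "reproductive_phenology")

#: Non-leap calendar used throughout (fixed by the worked phenology numbers:
#: Aug 1 is Julian day 213 only in a 365-day year).
_REF_YEAR = 1999
_MONTH_LEN = [calendar.monthrange(_REF_YEAR, m)[1] for m in range(1, 13)]
_MONTH_FIRST = np.concatenate([[1], 1 + np.cumsum(_MONTH_LEN[:-1])]).astype(int)
_MONTH_LAST = (_MONTH_FIRST + np.array(_MONTH_LEN) - 1).astype(int)


class TraitError(ValueError):
    """Invalid trait input (nonpositive mass, out-of-range month, ...)."""


@dataclass(frozen=True)
class SpeciesRecord:
    """One species at one site; ``abundance`` counts stems in the 50 plots."""

    species_id: str
    family: str
    genus: str
    biome: str
    abundance: int

    def __post_init__(self) -> None:
        if self.biome not in BIOMES:
            raise TraitError(f"unknown biome code {self.biome!r}; expected one of {BIOMES}")
        if self.abundance < 0:
            raise TraitError(f"{self.species_id}: abundance must be >= 0")


@dataclass(frozen=True)
class PhenologyWindow:
    """First/last month (1-12) of a flowering or fruiting window."""

    species_id: str
    phase: Literal["flowering", "fruiting"]
    first_month: int
    last_month: int

    def __post_init__(self) -> None:
        for m in (self.first_month, self.last_month):
            if not 1 <= int(m) <= 12:
                raise TraitError(f"{self.species_id}: month {m} outside 1..12")

    @property
    def crosses_year(self) -> bool:
        return self.last_month < self.first_month


@dataclass(frozen=True)
class DimensionScheme:
    """Assignment of every trait to exactly one niche dimension."""

    mapping: dict[str, str] = field(default_factory=lambda: dict(_DEFAULT_MAPPING))

    def __post_init__(self) -> None:
        unknown = set(self.mapping.values()) - set(DIMENSIONS)
        if unknown:
            raise TraitError(f"unknown dimensions {sorted(unknown)}")
        missing = set(TRAIT_NAMES) - set(self.mapping)
        if missing:
            raise TraitError(f"traits not assigned to a dimension: {sorted(missing)}")
        for dim in DIMENSIONS:
            if len(self.traits_of(dim)) < 2:
                raise TraitError(f"dimension {dim} has <2 traits; PCA needs at least 2")

    def traits_of(self, dimension: str) -> list[str]:
        return [t for t in TRAIT_NAMES if self.mapping.get(t) == dimension]


_DEFAULT_MAPPING = {
    "LA": "leaf_economy", "LDMC": "leaf_economy",
    "SLA": "leaf_economy", "LNC": "leaf_economy",
    "STD": "mechanical_support", "MPH": "mechanical_support",
    "MDBH": "mechanical_support",
    "FLT": "reproductive_phenology", "FRT": "reproductive_phenology",
    "FLD": "reproductive_phenology", "FRD": "reproductive_phenology",
}

DEFAULT_SCHEME = DimensionScheme()


@dataclass
class TraitTable:
    """Species x 11 trait matrix keyed by (species_id, biome).

    ``data`` is a DataFrame with a two-level (species_id, biome) index and the
    columns of :data:`TRAIT_NAMES`.  All cells are finite; traits are strictly
    positive except the durations FLD/FRD which may be 0; LDMC is a mass
    fraction in (0, 1]; FLT/FRT are Julian days in [1, 365]; FLD/FRD spans in
    [0, 364].
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.copy()
        self.validate()

    def validate(self) -> None:
        df = self.data
        if list(df.columns) != list(TRAIT_NAMES):
            raise TraitError(
                f"trait columns must be {list(TRAIT_NAMES)}, got {list(df.columns)}"
            )
        if df.index.nlevels != 2:
            raise TraitError("index must be (species_id, biome)")
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].tolist()
            raise TraitError(f"duplicate (species_id, biome) rows: {dups}")
        bad_biome = sorted(set(df.index.get_level_values(1)) - set(BIOMES))
        if bad_biome:
            raise TraitError(f"unknown biome codes {bad_biome}")
        if df.isna().any().any():
            cell = _first_offender(df.isna())
            raise TraitError(f"missing value at {cell}")
        strict = [t for t in TRAIT_NAMES if t not in ("FLD", "FRD")]
        if (df[strict] <= 0).any().any():
            cell = _first_offender(df[strict] <= 0)
            raise TraitError(f"nonpositive trait value at {cell}")
        checks = [
            (df[["FLD", "FRD"]] < 0, "negative duration"),
            (df[["LDMC"]] > 1, "LDMC above 1 g/g"),
            (df[["FLT", "FRT"]] > 365, "Julian day above 365"),
            (df[["FLD", "FRD"]] > 364, "duration above 364 days"),
        ]
        for mask, msg in checks:
            if mask.any().any():
                raise TraitError(f"{msg} at {_first_offender(mask)}")

    @property
    def species(self) -> pd.MultiIndex:
        return self.data.index

    def subset(self, biome: str) -> "TraitTable":
        mask = self.data.index.get_level_values(1) == biome
        return TraitTable(self.data.loc[mask])

    def biomes(self) -> list[str]:
        seen = self.data.index.get_level_values(1)
        return [b for b in BIOMES if b in set(seen)]


def _first_offender(mask: pd.DataFrame) -> tuple:
    stacked = mask.stack()
    idx = stacked[stacked].index[0]
    return tuple(idx[:-1]) + (idx[-1],)


# ---------------------------------------------------------------------------
# measured-trait derivations

def leaf_dry_matter_content(dry_mass: float, fresh_mass: float) -> float:
    """LDMC = leaf dry mass / fresh mass, in (0, 1] g/g."""
    if fresh_mass <= 0:
        raise TraitError("fresh_mass: must be > 0")
    if dry_mass <= 0:
        raise TraitError("dry_mass: must be > 0")
    if dry_mass > fresh_mass:
        raise TraitError("dry_mass: exceeds fresh_mass (dry leaves cannot gain mass)")
    return dry_mass / fresh_mass


def specific_leaf_area(leaf_area: float, dry_mass: float) -> float:
    """SLA = leaf area / leaf dry mass (cm2/g)."""
    if leaf_area <= 0:
        raise TraitError("leaf_area: must be > 0")
    if dry_mass <= 0:
        raise TraitError("dry_mass: must be > 0")
    return leaf_area / dry_mass


def stem_tissue_density(dry_mass: float, fresh_volume: float) -> float:
    """STD = branch-segment dry mass / fresh volume (g/cm3)."""
    if dry_mass <= 0:
        raise TraitError("dry_mass: must be > 0")
    if fresh_volume <= 0:
        raise TraitError("fresh_volume: must be > 0")
    return dry_mass / fresh_volume


def size_percentile(
    values: Sequence[float], percentile: float = 95.0, min_n: int = 20
) -> float:
    """Size trait (MPH/MDBH) as a percentile over individual measurements.

    Uses linear interpolation between order statistics (numpy's default,
    Hyndman-Fan type 7).  Fewer than ``min_n`` individuals raises
    :class:`TraitError` so the caller can flag the trait as underivable.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < min_n:
        raise TraitError(
            f"need at least {min_n} individuals for the {percentile:g}th "
            f"percentile, got {arr.size}"
        )
    if (arr <= 0).any():
        raise TraitError("size measurements must be > 0")
    return float(np.percentile(arr, percentile))


def julian_day(month: int, which: Literal["first", "last"]) -> int:
    """Day-of-year of a month's first or last day in a 365-day year."""
    month = int(month)
    if not 1 <= month <= 12:
        raise TraitError(f"month {month} outside 1..12")
    if which == "first":
        return int(_MONTH_FIRST[month - 1])
    if which == "last":
        return int(_MONTH_LAST[month - 1])
    raise TraitError(f"which must be 'first' or 'last', got {which!r}")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def phenology_stats(
    window: PhenologyWindow, allow_wraparound: bool = False
) -> tuple[int, int]:
    """Mean phenological time (Julian day) and duration (days) of a window.

    A window spanning month ``a`` to month ``b`` covers Julian days
    ``julian_day(a, first)`` to ``julian_day(b, last)``; the mean time is the
    half-up-rounded midpoint and the duration the day difference (a window of
    August-October gives mean time 259 and duration 91).

    Windows with ``last_month < first_month`` (e.g. flowering
    November-February) are cross-year; they are refused unless
    ``allow_wraparound`` is set, in which case the window is unrolled into the
    next year and the mean time mapped back into 1..365.
    """
    first = julian_day(window.first_month, "first")
    last = julian_day(window.last_month, "last")
    if window.crosses_year:
        if not allow_wraparound:
            raise TraitError(
                f"{window.species_id}: {window.phase} window "
                f"{window.first_month}->{window.last_month} crosses the year "
                "boundary; enable allow_wraparound to unroll it"
            )
        last += 365
    mean_time = _round_half_up((first + last) / 2)
    if mean_time > 365:
        mean_time -= 365
    return mean_time, last - first


def log10_transform(table: TraitTable | pd.DataFrame) -> pd.DataFrame:
    """Elementwise log10 of a trait table (normality pre-transform).

    Rejects nonpositive cells, naming the (species, trait) offender; a zero
    duration therefore excludes a species from the log-scale analysis.
    """
    df = table.data if isinstance(table, TraitTable) else table
    if (df <= 0).any().any():
        cell = _first_offender(df <= 0)
        raise TraitError(f"log10 undefined for nonpositive value at {cell}")
    return np.log10(df)


def abundance_filter(
    records: Iterable[SpeciesRecord], min_abundance: int = 20
) -> list[SpeciesRecord]:
    """Keep species with abundance strictly above ``min_abundance`` stems.

    Mirrors the field sampling rule that only species with more than 20
    individuals across the 50 plots are measured.  Order-preserving;
    an empty result is legal.
    """
    return [r for r in records if r.abundance > min_abundance]
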