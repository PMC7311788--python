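"""Delimited-text I/O for trait tables and run provenance.

Two input layouts are accepted (comma- or tab-delimited, auto-detected from
the header):

* canonical - phenology already derived, units encoded in column names
  (``flt_day`` etc.); this is what the pipeline and simulator exchange;
* raw-month - ``flower_first_month`` .. ``fruit_last_month`` columns from
  which the four phenology traits are computed at load time.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .traits import (
    TRAIT_NAMES,
    PhenologyWindow,
    SpeciesRecord,
    TraitTable,
    phenology_stats,
)

__all__ = [
    "CANONICAL_COLUMNS",
    "read_trait_table",
    "write_community",
    "write_manifest",
]

log = logging.getLogger(__name__)

#: canonical file column -> trait name
CANONICAL_COLUMNS = {
    "la_cm2": "LA",
    "ldmc_g_g": "LDMC",
    "sla_cm2_g": "SLA",
    "lnc_g_kg": "LNC",
    "std_g_cm3": "STD",
    "mph_m": "MPH",
    "mdbh_cm": "MDBH",
    "flt_day": "FLT",
    "frt_day": "FRT",
    "fld_day": "FLD",
    "frd_day": "FRD",
}

_META_COLUMNS = ["species_id", "family", "genus", "biome", "abundance"]

_RAW_TRAIT_COLUMNS = {
    "la_cm2": "LA",
    "ldmc": "LDMC",
    "sla_cm2_g": "SLA",
    "lnc_g_kg": "LNC",
    "std_g_cm3": "STD",
    "mph_m": "MPH",
    "mdbh_cm": "MDBH",
}
_MONTH_COLUMNS = [
    "flower_first_month", "flower_last_month",
    "fruit_first_month", "fruit_last_month",
]


def _sniff_sep(path: Path) -> str:
    header = Path(path).open().readline()
    return "\t" if "\t" in header else ","


def read_trait_table(
    path: str | Path,
    drop_invalid: bool = False,
    allow_wraparound: bool = False,
) -> tuple[TraitTable, list[SpeciesRecord]]:
    """Load a delimited trait file into a validated table plus records.

    Unknown columns are rejected by name.  Invariant violations either abort
    with the offending (row, column) or, with ``drop_invalid``, drop the row
    and log the count.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    cols = set(df.columns)
    canonical = set(_META_COLUMNS) | set(CANONICAL_COLUMNS)
    raw = set(_META_COLUMNS) | set(_RAW_TRAIT_COLUMNS) | set(_MONTH_COLUMNS)
    if cols == canonical:
        traits = df.rename(columns=CANONICAL_COLUMNS)
    elif cols == raw:
        traits = _derive_from_raw(df, drop_invalid, allow_wraparound)
        df = df.loc[traits.index]
    else:
        unknown = sorted(cols - canonical - raw)
        missing = sorted((canonical - cols) & (raw - cols))
        raise ValueError(
            f"{path.name}: header matches neither layout "
            f"(unknown columns {unknown}, missing {missing})"
        )

    traits = traits.set_index(
        pd.MultiIndex.from_frame(df[["species_id", "biome"]])
    )[list(TRAIT_NAMES)].astype(float)

    if drop_invalid:
        ok = _valid_row_mask(traits)
        n_bad = int((~ok).sum())
        if n_bad:
            log.warning("dropping %d invalid row(s): %s", n_bad,
                        traits.index[~ok].tolist())
        traits = traits.loc[ok]
        df = df.loc[ok.to_numpy()]
    table = TraitTable(traits)  # full validation; raises naming the cell
    records = [
        SpeciesRecord(
            species_id=str(r.species_id), family=str(r.family),
            genus=str(r.genus), biome=str(r.biome), abundance=int(r.abundance),
        )
        for r in df[_META_COLUMNS].itertuples(index=False)
    ]
    log.info("read %d species rows from %s", len(records), path)
    return table, records


def _derive_from_raw(
    df: pd.DataFrame, drop_invalid: bool, allow_wraparound: bool
) -> pd.DataFrame:
    traits = df.rename(columns=_RAW_TRAIT_COLUMNS).copy()
    derived, keep = {}, []
    for i, row in df.iterrows():
        try:
            flt, fld = phenology_stats(
                PhenologyWindow(str(row.species_id), "flowering",
                                int(row.flower_first_month), int(row.flower_last_month)),
                allow_wraparound,
            )
            frt, frd = phenology_stats(
                PhenologyWindow(str(row.species_id), "fruiting",
                                int(row.fruit_first_month), int(row.fruit_last_month)),
                allow_wraparound,
            )
        except Exception as err:
            if not drop_invalid:
                raise ValueError(f"row {i} ({row.species_id}): {err}") from err
            keep.append(False)
            continue
        derived[i] = {"FLT": flt, "FRT": frt, "FLD": fld, "FRD": frd}
        keep.append(True)
    if drop_invalid:
        n_bad = keep.count(False)
        if n_bad:
            log.warning("dropping %d row(s) with invalid phenology windows", n_bad)
        traits = traits.loc[keep]
    phen = pd.DataFrame.from_dict(derived, orient="index")
    return pd.concat([traits, phen], axis=1)


def _valid_row_mask(traits: pd.DataFrame) -> pd.Series:
    strict = [t for t in TRAIT_NAMES if t not in ("FLD", "FRD")]
    ok = traits.notna().all(axis=1)
    ok &= (traits[strict] > 0).all(axis=1)
    ok &= (traits[["FLD", "FRD"]] >= 0).all(axis=1)
    ok &= traits["LDMC"] <= 1
    ok &= (traits[["FLT", "FRT"]] <= 365).all(axis=1)
    ok &= (traits[["FLD", "FRD"]] <= 364).all(axis=1)
    ok &= ~traits.index.duplicated()
    return ok


def write_community(
    table: TraitTable, records: list[SpeciesRecord], path: str | Path, sep: str = "\t"
) -> Path:
    """Write the canonical trait-table layout (round-trips through
    :func:`read_trait_table`)."""
    path = Path(path)
    meta = {(r.species_id, r.biome): r for r in records}
    rows = []
    inverse = {v: k for k, v in CANONICAL_COLUMNS.items()}
    for key, trait_row in table.data.iterrows():
        r = meta[key]
        row = {
            "species_id": r.species_id, "family": r.family, "genus": r.genus,
            "biome": r.biome, "abundance": r.abundance,
        }
        row.update({inverse[t]: trait_row[t] for t in TRAIT_NAMES})
        rows.append(row)
    out = pd.DataFrame(rows, columns=_META_COLUMNS + list(CANONICAL_COLUMNS))
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep=sep, index=False, float_format="%.10g")
    return path


def write_manifest(path: str | Path, config: dict, inputs: list[str | Path]) -> Path:
    """Machine-readable provenance: config echo plus input checksums."""
    from . import __version__

    checksums = {}
    for p in inputs:
        p = Path(p)
        checksums[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    payload = {
        "package": "nichespace",
        "version": __version__,
        "config": _jsonable(config),
        "input_sha256": checksums,
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
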