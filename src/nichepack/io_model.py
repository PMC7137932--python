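"""Tabular I/O, trapping-session selection and the joint data model.

The three input tables are plain CSV:

* ``specimens.csv`` — one row per captured individual
  (``specimen_id,species,site_id,session_id,WT,HB,T,HF,E,CI,GW,IW,UTR,LTR``);
* ``sites.csv`` — ``site_id,locality,ecoregion``;
* ``sessions.csv`` — ``session_id,site_id,season_pure``.

Missing measurements are carried as ``None`` (``NaN`` in matrices), never 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, EmptyInputError, MetadataError, SchemaError

logger = logging.getLogger(__name__)

#: Raw morphometric measurement columns, in canonical order.
MEASUREMENT_COLUMNS: tuple[str, ...] = (
    "WT", "HB", "T", "HF", "E", "CI", "GW", "IW", "UTR", "LTR",
)

ECOREGIONS = ("CLF", "NLF")


@dataclass
class SpecimenRecord:
    """One captured individual with its raw measurements (``None`` = missing)."""

    specimen_id: str
    species: str
    site_id: str
    session_id: str | None = None
    WT: float | None = None
    HB: float | None = None
    T: float | None = None
    HF: float | None = None
    E: float | None = None
    CI: float | None = None
    GW: float | None = None
    IW: float | None = None
    UTR: float | None = None
    LTR: float | None = None

    def __post_init__(self) -> None:
        if not self.species or not self.site_id:
            raise ValueError("species and site_id must be non-empty")

    def measurement(self, name: str) -> float | None:
        return getattr(self, name)


@dataclass
class CommunityData:
    """Site-by-species abundance matrix plus site metadata."""

    sites: list[str]
    species: list[str]
    abundance: np.ndarray  # shape (n_sites, n_species), non-negative ints
    ecoregion: dict[str, str]
    locality: dict[str, str]

    def __post_init__(self) -> None:
        self.abundance = np.asarray(self.abundance)
        if self.abundance.shape != (len(self.sites), len(self.species)):
            raise ValueError("abundance shape does not match site/species lists")
        if (self.abundance < 0).any():
            raise ValueError("abundance must be non-negative")
        missing = [s for s in self.sites if s not in self.ecoregion]
        if missing:
            raise MetadataError(f"sites without ecoregion: {missing}")
        empty = [s for i, s in enumerate(self.sites) if self.abundance[i].sum() == 0]
        if empty:
            raise ValueError(f"sites with no individuals: {empty}")

    def richness(self, site_id: str) -> int:
        i = self.sites.index(site_id)
        return int((self.abundance[i] > 0).sum())

    def site_species(self, site_id: str) -> list[str]:
        i = self.sites.index(site_id)
        return [sp for j, sp in enumerate(self.species) if self.abundance[i, j] > 0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.abundance, index=self.sites, columns=self.species)


@dataclass
class RunConfig:
    """Null-model run configuration; mirrors the YAML config file."""

    n_permutations: int = 1000
    pool_definition: str = "both"  # {total, regional, both}
    model_variant: str = "both"  # {unconstrained, constrained, both}
    n_axes: int | str = "auto"
    seed: int = 0
    min_richness_fric: int = 3
    hull_tolerance: float = 1e-9
    standardize_fric: bool = True
    correction: str = "sqrt"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")
        if self.min_richness_fric < 3:
            raise ConfigError("min_richness_fric must be >= 3")
        if self.pool_definition not in {"total", "regional", "both"}:
            raise ConfigError(f"bad pool_definition: {self.pool_definition}")
        if self.model_variant not in {"unconstrained", "constrained", "both"}:
            raise ConfigError(f"bad model_variant: {self.model_variant}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        payload = {f.name: getattr(self, f.name) for f in dc_fields(self)}
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def _parse_measurement(value, column: str, row_label: str) -> float | None:
    """Coerce a raw CSV cell to a positive float or ``None`` (with a warning)."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip()
    if text == "" or text.lower() in {"na", "nan", "none", "."}:
        return None
    try:
        x = float(text)
    except ValueError:
        logger.warning("row %s: malformed %s cell %r -> missing", row_label, column, value)
        return None
    if not math.isfinite(x) or x <= 0:
        logger.warning("row %s: non-positive %s value %r -> missing", row_label, column, value)
        return None
    return x


def read_specimens(path: str | Path, sep: str = ",") -> list[SpecimenRecord]:
    """Read a specimen table into records, preserving row order.

    Malformed or non-positive numeric cells become missing with a logged
    warning; a missing mandatory column raises :class:`SchemaError`.
    """
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: no data") from exc
    mandatory = ["species", "site_id", *MEASUREMENT_COLUMNS]
    for col in mandatory:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no data rows")
    records: list[SpecimenRecord] = []
    for idx, row in df.iterrows():
        meas = {
            c: _parse_measurement(row[c], c, str(idx)) for c in MEASUREMENT_COLUMNS
        }
        records.append(
            SpecimenRecord(
                specimen_id=str(row["specimen_id"]) if "specimen_id" in df.columns else str(idx),
                species=str(row["species"]),
                site_id=str(row["site_id"]),
                session_id=(
                    str(row["session_id"])
                    if "session_id" in df.columns and pd.notna(row["session_id"])
                    else None
                ),
                **meas,
            )
        )
    return records


def read_site_meta(path: str | Path, sep: str = ",") -> dict[str, dict[str, str]]:
    """Read ``sites.csv`` into ``{site_id: {"locality": ..., "ecoregion": ...}}``."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in ("site_id", "locality", "ecoregion"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")
    return {
        str(r.site_id): {"locality": str(r.locality), "ecoregion": str(r.ecoregion)}
        for r in df.itertuples()
    }


def read_sessions(path: str | Path, sep: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in ("session_id", "site_id", "season_pure"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")
    df["season_pure"] = df["season_pure"].str.strip().str.lower().isin(
        {"true", "1", "yes", "t"}
    )
    return df


def select_sessions(
    records: Sequence[SpecimenRecord],
    sessions: pd.DataFrame | Mapping[str, bool],
) -> list[SpecimenRecord]:
    """Keep, per site, only the single-season session with the most captures.

    Sessions not restricted to a single season are discarded. If several pure
    sessions remain at a site, only records of the session with the greatest
    total abundance there are kept (ties broken by the lexicographically
    smallest ``session_id``, logged). Sites whose records carry no session id
    pass through unchanged; a site where every session is impure is dropped
    with a warning.
    """
    def _truthy(v) -> bool:
        if isinstance(v, str):
            return v.strip().lower() in {"true", "1", "yes", "t"}
        return bool(v)

    if isinstance(sessions, pd.DataFrame):
        pure = {str(r.session_id): _truthy(r.season_pure) for r in sessions.itertuples()}
    else:
        pure = {str(k): _truthy(v) for k, v in sessions.items()}

    by_site: dict[str, list[SpecimenRecord]] = {}
    for rec in records:
        by_site.setdefault(rec.site_id, []).append(rec)

    kept: list[SpecimenRecord] = []
    for site_id, recs in by_site.items():
        session_ids = {r.session_id for r in recs}
        if session_ids == {None} or len(session_ids) == 1:
            kept.extend(recs)
            continue
        counts: dict[str, int] = {}
        for r in recs:
            if r.session_id is not None and pure.get(r.session_id, False):
                counts[r.session_id] = counts.get(r.session_id, 0) + 1
        if not counts:
            logger.warning("site %s: all sessions impure, site dropped", site_id)
            continue
        best_n = max(counts.values())
        candidates = sorted(s for s, n in counts.items() if n == best_n)
        if len(candidates) > 1:
            logger.warning(
                "site %s: abundance tie between sessions %s, keeping %s",
                site_id, candidates, candidates[0],
            )
        chosen = candidates[0]
        kept.extend(r for r in recs if r.session_id == chosen)
    # preserve original record order
    kept_ids = {id(r) for r in kept}
    return [r for r in records if id(r) in kept_ids]


def build_community_matrix(
    records: Sequence[SpecimenRecord],
    site_meta: Mapping[str, Mapping[str, str]],
) -> CommunityData:
    """Count records into a site-by-species abundance matrix."""
    if not records:
        raise EmptyInputError("no specimen records")
    for rec in records:
        if rec.site_id not in site_meta:
            raise MetadataError(f"site {rec.site_id!r} absent from site metadata")
    sites = sorted({r.site_id for r in records})
    species = sorted({r.species for r in records})
    site_ix = {s: i for i, s in enumerate(sites)}
    sp_ix = {s: i for i, s in enumerate(species)}
    abundance = np.zeros((len(sites), len(species)), dtype=int)
    for rec in records:
        abundance[site_ix[rec.site_id], sp_ix[rec.species]] += 1
    return CommunityData(
        sites=sites,
        species=species,
        abundance=abundance,
        ecoregion={s: site_meta[s]["ecoregion"] for s in sites},
        locality={s: site_meta[s].get("locality", "") for s in sites},
    )


RESULT_COLUMNS = (
    "site_id", "metric", "pool", "variant", "observed", "null_mean",
    "null_sd", "ses", "n_perm", "n_valid_perm", "seed", "richness", "reason",
)


def write_results(results: Iterable, path: str | Path) -> None:
    """Write null-model results as CSV, one row per (site, metric, pool, variant).

    Undefined SES cells (null sd = 0) are written empty. Floats use repr
    precision so a round-trip read reproduces values exactly.
    """
    rows = list(results)
    if not rows:
        raise EmptyInputError("no results to write")
    df = pd.DataFrame([{c: getattr(r, c) for c in RESULT_COLUMNS} for r in rows])
    df.to_csv(path, index=False, float_format="%.17g")


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in RESULT_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing results column {col!r}")
    df["reason"] = df["reason"].fillna("")
    return df
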