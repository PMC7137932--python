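"""Specimen records -> species-level derived traits -> Gower distances.

Per individual, appendage lengths are expressed relative to body length
(T/HB, HF/HB, E/HB) and cranial measures relative to condylo-incisive
length (GW/CI, IW/CI, UTR/CI, LTR/CI); WT, HB and CI stay absolute. Within
each species and derived trait, values beyond 1.5x the interquartile range
are discarded before averaging. Distances between species are Gower
distances: range-normalised mean absolute differences with pairwise
deletion of missing traits.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .io_model import SpecimenRecord

logger = logging.getLogger(__name__)

#: Derived trait names, canonical order (3 absolute + 7 ratios).
TRAIT_NAMES: tuple[str, ...] = (
    "WT", "HB", "CI",
    "T_rel", "HF_rel", "E_rel",
    "GW_rel", "IW_rel", "UTR_rel", "LTR_rel",
)

_HB_RATIOS = {"T_rel": "T", "HF_rel": "HF", "E_rel": "E"}
_CI_RATIOS = {"GW_rel": "GW", "IW_rel": "IW", "UTR_rel": "UTR", "LTR_rel": "LTR"}


@dataclass
class DerivedTraitVector:
    """Ten derived trait values for one individual (NaN = undefined)."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.values) != set(TRAIT_NAMES):
            raise ValueError("expected exactly the 10 derived trait slots")

    def __getitem__(self, trait: str) -> float:
        return self.values[trait]


@dataclass
class SpeciesTraitMatrix:
    """Species x derived-trait matrix (NaN = missing) with per-species counts."""

    species: list[str]
    traits: list[str]
    values: np.ndarray
    n_specimens: dict[str, int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.species), len(self.traits)):
            raise ValueError("values shape does not match species/trait lists")
        all_missing = np.isnan(self.values).all(axis=1)
        if all_missing.any():
            bad = [s for s, m in zip(self.species, all_missing) if m]
            raise ValueError(f"species with no trait values at all: {bad}")

    def row(self, species: str) -> np.ndarray:
        return self.values[self.species.index(species)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.species, columns=self.traits)
        df["n_specimens"] = [self.n_specimens[s] for s in self.species]
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="species")


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with species labels."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix diagonal must be zero")

    def submatrix(self, labels: Sequence[str]) -> np.ndarray:
        idx = [self.labels.index(l) for l in labels]
        return self.d[np.ix_(idx, idx)]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.d, index=self.labels, columns=self.labels).to_csv(path)


def derive_traits(record: SpecimenRecord) -> DerivedTraitVector:
    """Compute the 10 derived traits for one specimen.

    Missing raw measurements propagate to the affected slot only; a
    non-positive HB or CI is a :class:`DataError` (physically impossible).
    """
    hb = record.HB
    ci = record.CI
    if hb is not None and hb <= 0:
        raise DataError(f"specimen {record.specimen_id}: HB <= 0")
    if ci is not None and ci <= 0:
        raise DataError(f"specimen {record.specimen_id}: CI <= 0")
    vals: dict[str, float] = {}
    for name in ("WT", "HB", "CI"):
        x = record.measurement(name)
        vals[name] = float(x) if x is not None else math.nan
    for trait, raw in _HB_RATIOS.items():
        x = record.measurement(raw)
        vals[trait] = float(x) / hb if (x is not None and hb is not None) else math.nan
    for trait, raw in _CI_RATIOS.items():
        x = record.measurement(raw)
        vals[trait] = float(x) / ci if (x is not None and ci is not None) else math.nan
    return DerivedTraitVector(vals)


def flag_iqr_outliers(values: Sequence[float]) -> np.ndarray:
    """Flag values beyond 1.5x the interquartile range.

    Quartiles use linear interpolation between order statistics. Fewer than
    4 finite values, or NaNs, are never flagged.
    """
    x = np.asarray(values, dtype=float)
    flags = np.zeros(x.shape, dtype=bool)
    finite = np.isfinite(x)
    if finite.sum() < 4:
        return flags
    q1, q3 = np.percentile(x[finite], [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    flags[finite] = (x[finite] < lo) | (x[finite] > hi)
    return flags


def aggregate_species(records: Sequence[SpecimenRecord]) -> SpeciesTraitMatrix:
    """Average per-individual derived traits into one row per species.

    Outliers are flagged within species x trait and excluded from the mean;
    a cell whose every value is flagged or missing stays missing (warned).
    """
    by_species: dict[str, list[DerivedTraitVector]] = {}
    for rec in records:
        by_species.setdefault(rec.species, []).append(derive_traits(rec))
    species = sorted(by_species)
    values = np.full((len(species), len(TRAIT_NAMES)), np.nan)
    n_specimens: dict[str, int] = {}
    for i, sp in enumerate(species):
        vectors = by_species[sp]
        n_specimens[sp] = len(vectors)
        for j, trait in enumerate(TRAIT_NAMES):
            col = np.array([v[trait] for v in vectors], dtype=float)
            keep = np.isfinite(col) & ~flag_iqr_outliers(col)
            if keep.any():
                values[i, j] = col[keep].mean()
            else:
                logger.warning("species %s: trait %s entirely missing/flagged", sp, trait)
    return SpeciesTraitMatrix(
        species=species, traits=list(TRAIT_NAMES), values=values, n_specimens=n_specimens
    )


def gower_matrix(m: SpeciesTraitMatrix) -> DistanceMatrix:
    """Gower distances between species rows.

    d[i,j] = mean over traits available in both species of
    |x_i - x_j| / range, with the range taken over all species. Traits with
    zero range are dropped with a warning (they carry no information).
    """
    x = m.values.astype(float)
    with warnings.catch_warnings():
        # all-NaN trait columns are handled below as zero-information traits
        warnings.simplefilter("ignore", RuntimeWarning)
        rng = np.nanmax(x, axis=0) - np.nanmin(x, axis=0)
    usable = np.isfinite(rng) & (rng > 0)
    dropped = [t for t, u in zip(m.traits, usable) if not u]
    if dropped:
        logger.warning("gower: dropping zero-range/empty traits %s", dropped)
    x = x[:, usable]
    rng = rng[usable]
    n = x.shape[0]
    # pairwise-deletion Gower, vectorised over trait axis
    diff = np.abs(x[:, None, :] - x[None, :, :]) / rng  # NaN where either missing
    avail = np.isfinite(diff)
    counts = avail.sum(axis=2)
    if (counts == 0)[~np.eye(n, dtype=bool)].any():
        bad = np.argwhere((counts == 0) & ~np.eye(n, dtype=bool))
        raise DataError(
            f"species pairs sharing no traits: "
            f"{[(m.species[i], m.species[j]) for i, j in bad[:3]]}"
        )
    d = np.where(avail, diff, 0.0).sum(axis=2) / counts
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # enforce exact symmetry against FP noise
    return DistanceMatrix(labels=list(m.species), d=d)
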