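"""Identity-randomization null models and standardized effect sizes.

For every community, species identities are redrawn uniformly without
replacement (richness held fixed) from a species pool — either the total
pool of the whole domain or the community's regional (ecoregion) pool —
and the metric recomputed per draw. The constrained variant, applied to
MNND only, first restricts the pool to species lying inside the focal
community's empirical trait hull, isolating packing effects from volume
effects. SES = (observed - null mean) / null SD (sample SD, n-1).
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConstraintError, InfeasibleDrawError, PoolError
from .funcspace import TraitSpace, fric, in_hull, mnnd
from .io_model import CommunityData, RunConfig
from .traits import DistanceMatrix

logger = logging.getLogger(__name__)


@dataclass
class SpeciesPool:
    name: str  # "total" or an ecoregion label
    species: list[str]
    definition: str  # {"total", "regional"}

    def __len__(self) -> int:
        return len(self.species)


@dataclass
class NullModelResult:
    site_id: str
    metric: str
    pool: str
    variant: str
    observed: float
    null_mean: float
    null_sd: float
    ses: float  # NaN when undefined
    n_perm: int
    n_valid_perm: int
    seed: int
    richness: int = 0
    reason: str = ""


def build_pools(community: CommunityData) -> dict[str, SpeciesPool]:
    """Total pool plus one regional pool per ecoregion present."""
    occupied = community.abundance > 0
    total = [sp for j, sp in enumerate(community.species) if occupied[:, j].any()]
    pools = {"total": SpeciesPool("total", total, "total")}
    regions = sorted(set(community.ecoregion.values()))
    for region in regions:
        rows = [i for i, s in enumerate(community.sites) if community.ecoregion[s] == region]
        if not rows:
            raise PoolError(f"ecoregion {region!r} has no sites")
        members = [
            sp for j, sp in enumerate(community.species) if occupied[rows][:, j].any()
        ]
        if not members:
            raise PoolError(f"ecoregion {region!r} has no species")
        pools[region] = SpeciesPool(region, members, "regional")
    return pools


def randomize_community(
    s: int, pool: SpeciesPool, rng: np.random.Generator
) -> list[str]:
    """Uniform draw of ``s`` distinct species from the pool, unweighted."""
    if s > len(pool):
        raise InfeasibleDrawError(f"cannot draw {s} species from pool of {len(pool)}")
    idx = rng.choice(len(pool), size=s, replace=False)
    return [pool.species[i] for i in idx]


def constrain_pool(
    community_species: Sequence[str],
    pool: SpeciesPool,
    space: TraitSpace,
    tol: float = 1e-9,
) -> SpeciesPool:
    """Restrict a pool to species inside the community's empirical trait hull.

    The result always contains the community's own species. Raises
    :class:`ConstraintError` when the community hull is degenerate.
    """
    comm = set(community_species)
    hull_pts = space.coords_for(sorted(comm))
    if len(comm) < space.m + 1:
        raise ConstraintError(f"community too small for a hull (S={len(comm)} < m+1)")
    inside: list[str] = []
    for sp in pool.species:
        if sp in comm:
            inside.append(sp)
            continue
        try:
            ok = in_hull(space.coords_for([sp])[0], hull_pts, tol=tol)
        except ValueError as exc:
            raise ConstraintError(str(exc)) from exc
        if ok:
            inside.append(sp)
    return SpeciesPool(name=pool.name, species=inside, definition=pool.definition)


def ses(observed: float, null_values: Sequence[float]) -> float:
    """(observed - null mean) / null sample SD; NaN when SD is 0 or n < 2."""
    vals = np.asarray(null_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2 or not math.isfinite(observed):
        return math.nan
    sd = float(vals.std(ddof=1))
    if sd == 0:
        return math.nan
    return (observed - float(vals.mean())) / sd


def _cell_rng(seed: int, site: str, metric: str, pool: str, variant: str) -> tuple[np.random.Generator, int]:
    """Independent, order-invariant RNG per (site, metric, pool, variant) cell."""
    key = f"{site}|{metric}|{pool}|{variant}".encode()
    digest = hashlib.sha256(key).digest()
    words = [int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)]
    ss = np.random.SeedSequence([int(seed) & 0xFFFFFFFF, *words])
    return np.random.default_rng(ss), int(ss.generate_state(1)[0])


def null_distribution(
    community_species: Sequence[str],
    metric: str,
    pool: SpeciesPool,
    cfg: RunConfig,
    space: TraitSpace | None,
    d: DistanceMatrix | None,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Metric values over ``cfg.n_permutations`` random communities.

    Returns (values incl. NaN for degenerate draws, n_valid). Degenerate
    permutations are excluded downstream from null mean/SD rather than
    redrawn, so volume-rich draws are not over-represented.
    """
    s = len(list(community_species))
    values = np.full(cfg.n_permutations, np.nan)
    for i in range(cfg.n_permutations):
        draw = randomize_community(s, pool, rng)
        if metric == "FRic":
            values[i] = fric(draw, space, standardize=cfg.standardize_fric).value
        elif metric == "MNND":
            values[i] = mnnd(draw, d).value
        else:
            raise ValueError(f"unknown metric {metric!r}")
    n_valid = int(np.isfinite(values).sum())
    return values, n_valid


def _analysis_cells(cfg: RunConfig) -> list[tuple[str, str, str]]:
    """(metric, pool_definition, variant) combinations requested by the config."""
    pool_defs = ["total", "regional"] if cfg.pool_definition == "both" else [cfg.pool_definition]
    variants = (
        ["unconstrained", "constrained"]
        if cfg.model_variant == "both"
        else [cfg.model_variant]
    )
    cells = []
    for pd_ in pool_defs:
        for variant in variants:
            if variant == "unconstrained":
                cells.append(("FRic", pd_, variant))
            cells.append(("MNND", pd_, variant))  # constrained applies to MNND only
    return cells


def run_null_analysis(
    community: CommunityData,
    space: TraitSpace,
    d: DistanceMatrix,
    cfg: RunConfig,
) -> list[NullModelResult]:
    """Full site x metric x pool-definition x variant sweep.

    Per-site failures (undefined metric, degenerate hull, infeasible draw)
    become flagged rows with a reason; the batch never aborts. RNG streams
    are derived per cell from ``cfg.seed``, so results are order-independent
    and reruns are bit-identical.
    """
    pools = build_pools(community)
    results: list[NullModelResult] = []
    for site in community.sites:
        comm = community.site_species(site)
        s = len(comm)
        for metric, pool_def, variant in _analysis_cells(cfg):
            pool = pools["total"] if pool_def == "total" else pools[community.ecoregion[site]]
            rng, cell_seed = _cell_rng(cfg.seed, site, metric, pool.name, variant)

            def flagged(reason: str, observed: float = math.nan) -> NullModelResult:
                return NullModelResult(
                    site_id=site, metric=metric, pool=pool.name, variant=variant,
                    observed=observed, null_mean=math.nan, null_sd=math.nan,
                    ses=math.nan, n_perm=cfg.n_permutations, n_valid_perm=0,
                    seed=cell_seed, richness=s, reason=reason,
                )

            if metric == "FRic":
                if s < cfg.min_richness_fric:
                    results.append(flagged("S<min_richness_fric"))
                    continue
                obs = fric(comm, space, site_id=site, standardize=cfg.standardize_fric)
            else:
                obs = mnnd(comm, d, site_id=site)
            if not obs.defined:
                results.append(flagged(obs.reason))
                continue

            effective_pool = pool
            if variant == "constrained":
                if s < space.m + 1:
                    results.append(flagged("S<m+1", observed=obs.value))
                    continue
                try:
                    effective_pool = constrain_pool(comm, pool, space, tol=cfg.hull_tolerance)
                except ConstraintError as exc:
                    logger.warning("site %s: %s", site, exc)
                    results.append(flagged(f"constraint:{exc}", observed=obs.value))
                    continue
            if s > len(effective_pool):
                results.append(flagged("S>pool", observed=obs.value))
                continue

            values, n_valid = null_distribution(
                comm, metric, effective_pool, cfg, space, d, rng
            )
            valid = values[np.isfinite(values)]
            null_mean = float(valid.mean()) if n_valid else math.nan
            null_sd = float(valid.std(ddof=1)) if n_valid > 1 else math.nan
            reason = ""
            if len(effective_pool) == s:
                reason = "degenerate_null_pool"
            results.append(
                NullModelResult(
                    site_id=site, metric=metric, pool=pool.name, variant=variant,
                    observed=obs.value, null_mean=null_mean, null_sd=null_sd,
                    ses=ses(obs.value, valid), n_perm=cfg.n_permutations,
                    n_valid_perm=n_valid, seed=cell_seed, richness=s, reason=reason,
                )
            )
    return results
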