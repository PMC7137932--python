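"""End-to-end orchestration: records -> traits -> space -> null models."""

from __future__ import annotations

from typing import Mapping, Sequence

from .funcspace import TraitSpace, build_trait_space
from .io_model import CommunityData, RunConfig, SpecimenRecord, build_community_matrix
from .nullmodels import NullModelResult, run_null_analysis
from .traits import DistanceMatrix, aggregate_species, gower_matrix


def run_pipeline(
    records: Sequence[SpecimenRecord],
    site_meta: Mapping[str, Mapping[str, str]],
    cfg: RunConfig,
) -> tuple[list[NullModelResult], TraitSpace, CommunityData]:
    """Aggregate traits, embed the pool, and run the null-model sweep."""
    community = build_community_matrix(records, site_meta)
    traits = aggregate_species(records)
    d = gower_matrix(traits)
    richnesses = [community.richness(s) for s in community.sites]
    analysed = [r for r in richnesses if r >= cfg.min_richness_fric]
    min_s = min(analysed) if analysed else min(richnesses)
    space = build_trait_space(
        d, n_axes=cfg.n_axes, correction=cfg.correction,
        min_community_richness=min_s,
    )
    results = run_null_analysis(community, space, d, cfg)
    return results, space, community
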