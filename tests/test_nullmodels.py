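import itertools
import math

import numpy as np
import pytest
from scipy.stats import chisquare

from nichepack.errors import ConstraintError, InfeasibleDrawError
from nichepack.funcspace import fric, mnnd
from nichepack.io_model import CommunityData, RunConfig
from nichepack.nullmodels import (
    SpeciesPool,
    build_pools,
    constrain_pool,
    null_distribution,
    randomize_community,
    run_null_analysis,
    ses,
)
from nichepack.traits import DistanceMatrix

from test_funcspace import lp_in_hull, make_space


def make_community(abundance, ecoregions, species=None):
    abundance = np.asarray(abundance)
    sites = [f"s{i}" for i in range(abundance.shape[0])]
    species = species or [f"sp{j}" for j in range(abundance.shape[1])]
    return CommunityData(
        sites=sites, species=species, abundance=abundance,
        ecoregion=dict(zip(sites, ecoregions)),
        locality={s: "L" for s in sites},
    )


class TestBuildPools:
    def test_saturated(self):
        comm = make_community([[1, 1], [1, 1]], ["CLF", "NLF"])
        pools = build_pools(comm)
        assert pools["total"].species == pools["CLF"].species == pools["NLF"].species

    def test_region_restricted_species(self):
        comm = make_community([[1, 0], [1, 1]], ["CLF", "NLF"])
        pools = build_pools(comm)
        assert "sp1" in pools["NLF"].species
        assert "sp1" not in pools["CLF"].species
        assert "sp1" in pools["total"].species

    def test_disjoint_faunas(self):
        comm = make_community([[1, 0], [0, 1]], ["CLF", "NLF"])
        pools = build_pools(comm)
        assert set(pools["CLF"].species) & set(pools["NLF"].species) == set()
        assert set(pools["total"].species) == {"sp0", "sp1"}


class TestRandomizeCommunity:
    def test_exhaustion_returns_pool(self, rng):
        pool = SpeciesPool("total", ["a", "b", "c"], "total")
        assert sorted(randomize_community(3, pool, rng)) == ["a", "b", "c"]

    def test_infeasible_draw(self, rng):
        pool = SpeciesPool("total", ["a"], "total")
        with pytest.raises(InfeasibleDrawError):
            randomize_community(2, pool, rng)

    def test_uniformity_chi_square(self, rng):
        pool = SpeciesPool("total", ["a", "b", "c", "d"], "total")
        counts = {s: 0 for s in pool.species}
        n_draws = 10_000
        for _ in range(n_draws):
            counts[randomize_community(1, pool, rng)[0]] += 1
        freqs = np.array([counts[s] / n_draws for s in pool.species])
        assert np.allclose(freqs, 0.25, atol=0.02)
        assert chisquare(list(counts.values())).pvalue > 0.001

    def test_same_seed_identical(self):
        pool = SpeciesPool("total", list("abcdefgh"), "total")
        draws1 = [randomize_community(3, pool, np.random.default_rng(9)) for _ in range(1)]
        draws2 = [randomize_community(3, pool, np.random.default_rng(9)) for _ in range(1)]
        assert draws1 == draws2


class TestConstrainPool:
    def test_pool_equals_community(self, rng):
        space = make_space(rng.normal(size=(6, 2)))
        comm = space.species[:4]
        pool = SpeciesPool("total", list(comm), "total")
        out = constrain_pool(comm, pool, space)
        assert sorted(out.species) == sorted(comm)

    def test_peripheral_species_excluded(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [1, 1], [10, 10]], float)
        space = make_space(pts)
        comm = space.species[:4]
        pool = SpeciesPool("total", list(space.species), "total")
        out = constrain_pool(comm, pool, space)
        assert "sp4" not in out.species
        assert set(comm) <= set(out.species)

    def test_degenerate_hull_raises(self):
        pts = np.array([[0, 0], [1, 1], [2, 2], [5, 0]], float)
        space = make_space(pts)
        with pytest.raises(ConstraintError):
            constrain_pool(space.species[:2], SpeciesPool("total", space.species, "total"), space)

    def test_agrees_with_lp_oracle(self, rng):
        for _ in range(20):
            space = make_space(rng.normal(size=(12, 2)))
            comm = list(rng.choice(space.species, size=5, replace=False))
            pool = SpeciesPool("total", list(space.species), "total")
            out = constrain_pool(comm, pool, space)
            hull_pts = space.coords_for(sorted(set(comm)))
            for sp in space.species:
                expected = sp in comm or lp_in_hull(space.coords_for([sp])[0], hull_pts)
                assert (sp in out.species) == expected


class TestSes:
    def test_zero_sd_undefined(self):
        assert math.isnan(ses(2.0, [1.0, 1.0, 1.0]))

    def test_formula(self):
        null = [0.5, 1.0, 1.5]  # mean 1, sd 0.5
        assert ses(2.0, null) == pytest.approx(2.0)

    def test_observed_equals_mean(self):
        assert ses(1.0, [0.5, 1.0, 1.5]) == pytest.approx(0.0)

    def test_scale_invariance(self, rng):
        null = rng.uniform(0.1, 0.9, size=50)
        obs = 0.42
        assert ses(obs * 7, null * 7) == pytest.approx(ses(obs, null))


class TestNullDistribution:
    def _setup(self, rng, n_pool=6, m=2):
        space = make_space(rng.normal(size=(n_pool, m)))
        from scipy.spatial.distance import pdist, squareform

        d = DistanceMatrix(labels=space.species, d=squareform(pdist(space.coords)))
        return space, d

    def test_degenerate_pool_all_equal(self, rng):
        space, d = self._setup(rng)
        comm = space.species[:3]
        pool = SpeciesPool("total", list(comm), "total")
        cfg = RunConfig(n_permutations=20, seed=1)
        vals, n_valid = null_distribution(comm, "MNND", pool, cfg, space, d,
                                          np.random.default_rng(0))
        obs = mnnd(comm, d).value
        np.testing.assert_allclose(vals, obs)
        assert math.isnan(ses(obs, vals))

    def test_matches_exhaustive_enumeration_pairs(self, rng):
        space, d = self._setup(rng, n_pool=3)
        pool = SpeciesPool("total", list(space.species), "total")
        cfg = RunConfig(n_permutations=2000, seed=2)
        comm = space.species[:2]
        vals, _ = null_distribution(comm, "MNND", pool, cfg, space, d,
                                    np.random.default_rng(3))
        support = {
            round(mnnd(list(pair), d).value, 12)
            for pair in itertools.combinations(space.species, 2)
        }
        assert {round(v, 12) for v in vals} <= support
        assert len({round(v, 12) for v in vals}) == 3

    @pytest.mark.parametrize("metric", ["MNND", "FRic"])
    def test_enumeration_oracle_mean_sd(self, rng, metric):
        # pool of 7, S=4: exact null mean/sd by full enumeration of C(7,4)
        space, d = self._setup(rng, n_pool=7)
        pool = SpeciesPool("total", list(space.species), "total")
        comm = list(space.species[:4])
        exact_vals = []
        for sub in itertools.combinations(space.species, 4):
            if metric == "MNND":
                exact_vals.append(mnnd(list(sub), d).value)
            else:
                v = fric(list(sub), space, standardize=False).value
                if math.isfinite(v):
                    exact_vals.append(v)
        exact_vals = np.array(exact_vals)
        n_perm = 4000
        cfg = RunConfig(n_permutations=n_perm, seed=4, standardize_fric=False)
        vals, n_valid = null_distribution(comm, metric, pool, cfg, space, d,
                                          np.random.default_rng(5))
        valid = vals[np.isfinite(vals)]
        se = exact_vals.std(ddof=1) / math.sqrt(n_valid)
        assert abs(valid.mean() - exact_vals.mean()) < 3 * se
        assert abs(valid.std(ddof=1) - exact_vals.std(ddof=1)) < 5 * se

    def test_n_permutations_respected(self, rng):
        space, d = self._setup(rng)
        pool = SpeciesPool("total", list(space.species), "total")
        cfg = RunConfig(n_permutations=137, seed=0)
        vals, _ = null_distribution(space.species[:3], "MNND", pool, cfg, space, d,
                                    np.random.default_rng(1))
        assert len(vals) == 137

    def test_constrained_fric_bounded_by_observed(self, rng):
        # every constrained draw lies inside the observed hull
        space, d = self._setup(rng, n_pool=10)
        comm = list(rng.choice(space.species, size=6, replace=False))
        pool = SpeciesPool("total", list(space.species), "total")
        constrained = constrain_pool(comm, pool, space)
        obs = fric(comm, space, standardize=False).value
        cfg = RunConfig(n_permutations=300, seed=6, standardize_fric=False)
        vals, _ = null_distribution(comm, "FRic", constrained, cfg, space, d,
                                    np.random.default_rng(7))
        assert np.all(vals[np.isfinite(vals)] <= obs + 1e-9)


class TestRunNullAnalysis:
    def _pipeline_inputs(self, seed=0):
        from nichepack.synth import ScenarioConfig, generate_dataset
        from nichepack.pipeline import run_pipeline

        cfg = ScenarioConfig(
            n_species_pool=16, n_sites={"CLF": 3, "NLF": 4},
            richness_range=(4, 7), seed=seed, barrier_overlap=0.8,
        )
        ds = generate_dataset(cfg)
        return ds

    def test_row_bookkeeping(self):
        ds = self._pipeline_inputs()
        from nichepack.pipeline import run_pipeline

        rc = RunConfig(n_permutations=30, seed=1)
        results, _, _ = run_pipeline(ds.records, ds.site_meta, rc)
        n_sites = len(ds.community.sites)
        assert len(results) == n_sites * 6  # (FRic+MNND)x2 pools + constrained MNND x2
        keys = {(r.site_id, r.metric, r.pool, r.variant) for r in results}
        assert len(keys) == len(results)

    def test_rerun_same_seed_bit_identical(self):
        ds = self._pipeline_inputs()
        from nichepack.pipeline import run_pipeline

        rc = RunConfig(n_permutations=25, seed=42)
        r1, _, _ = run_pipeline(ds.records, ds.site_meta, rc)
        r2, _, _ = run_pipeline(ds.records, ds.site_meta, rc)
        assert [(r.site_id, r.metric, r.pool, r.variant, r.ses) for r in r1] == \
               [(r.site_id, r.metric, r.pool, r.variant, r.ses) for r in r2]

    def test_ses_scale_invariance_through_distances(self, rng):
        # multiplying all distances by 7 leaves the MNND SES unchanged
        from scipy.spatial.distance import pdist, squareform

        pts = rng.normal(size=(8, 2))
        labels = [f"sp{i}" for i in range(8)]
        d1 = DistanceMatrix(labels=labels, d=squareform(pdist(pts)))
        d7 = DistanceMatrix(labels=labels, d=7 * d1.d)
        pool = SpeciesPool("total", labels, "total")
        comm = labels[:4]
        cfg = RunConfig(n_permutations=400, seed=3)
        v1, _ = null_distribution(comm, "MNND", pool, cfg, None, d1,
                                  np.random.default_rng(11))
        v7, _ = null_distribution(comm, "MNND", pool, cfg, None, d7,
                                  np.random.default_rng(11))
        s1 = ses(mnnd(comm, d1).value, v1)
        s7 = ses(mnnd(comm, d7).value, v7)
        assert s7 == pytest.approx(s1, abs=1e-10)
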