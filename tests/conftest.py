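import numpy as np
import pytest

from nichepack.io_model import SpecimenRecord
from nichepack.traits import TRAIT_NAMES, DistanceMatrix, SpeciesTraitMatrix


def make_record(species="spA", site="s1", session=None, idx=0, **meas):
    defaults = dict(WT=10.0, HB=80.0, T=50.0, HF=12.0, E=8.0,
                    CI=20.0, GW=9.5, IW=4.5, UTR=8.8, LTR=8.2)
    defaults.update(meas)
    return SpecimenRecord(
        specimen_id=f"{species}-{site}-{idx}", species=species, site_id=site,
        session_id=session, **defaults,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_traits():
    """4 species on a unit-ish grid; no missing values."""
    rng = np.random.default_rng(0)
    values = rng.uniform(0.2, 1.0, size=(4, 10))
    return SpeciesTraitMatrix(
        species=["a", "b", "c", "d"], traits=list(TRAIT_NAMES),
        values=values, n_specimens={s: 1 for s in "abcd"},
    )


def random_trait_matrix(rng, n_species=8, missing_rate=0.0):
    values = rng.uniform(0.0, 1.0, size=(n_species, 10))
    if missing_rate:
        mask = rng.random(values.shape) < missing_rate
        mask[:, 0] = False  # keep one trait complete so no pair shares nothing
        values[mask] = np.nan
    species = [f"sp{i}" for i in range(n_species)]
    return SpeciesTraitMatrix(
        species=species, traits=list(TRAIT_NAMES), values=values,
        n_specimens={s: 1 for s in species},
    )


@pytest.fixture
def distance_from_points():
    """Factory: Euclidean DistanceMatrix from an array of points."""
    from scipy.spatial.distance import pdist, squareform

    def _make(points, labels=None):
        points = np.asarray(points, float)
        labels = labels or [f"sp{i}" for i in range(len(points))]
        return DistanceMatrix(labels=labels, d=squareform(pdist(points)))

    return _make
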