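import numpy as np
import pytest

import afblueprint as af


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_species_pair(deltas, vertices_per_region=8, n_tracts=6,
                      count_depth=1e4, seed=7, pairs_per_delta=1):
    """Small two-species fixture with one homolog pair per delta level."""
    n_pairs = len(deltas) * pairs_per_delta
    n_regions = n_pairs
    spec = dict(n_vertices=n_regions * vertices_per_region,
                n_regions=n_regions, n_tracts=n_tracts, count_depth=count_depth,
                lobes=af.parcellation.DEFAULT_LOBES[:min(4, n_regions)])
    sa = af.SpeciesSpec("A", **spec)
    sb = af.SpeciesSpec("B", **spec)
    pairs, k = [], 0
    for d in deltas:
        for _ in range(pairs_per_delta):
            pairs.append((k, k, d))
            k += 1
    return af.generate_species_pair(sa, sb, af.HomologyPlan(tuple(pairs)), seed)


def normalized_blueprints(pair):
    bpa = af.normalize_rows(af.build_blueprint(pair.a.c1, pair.a.c2))
    bpb = af.normalize_rows(af.build_blueprint(pair.b.c1, pair.b.c2))
    return bpa, bpb


@pytest.fixture
def graded_pair():
    return make_species_pair([0.0, 0.25, 0.5, 0.75, 1.0])


def random_simplex(rng, k):
    p = rng.random(k) + 1e-3
    return p / p.sum()
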