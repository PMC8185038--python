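import numpy as np
import pytest

import phenoprof as pp


@pytest.fixture(scope="session")
def ref_fixture():
    """Small synthetic reference: 60 species, 1-4 strains each."""
    return pp.generate_reference_fixture(
        n_species=60, strains_per_species=(1, 4),
        species_flip_prob=0.1, seed=11,
    )


@pytest.fixture(scope="session")
def pool(ref_fixture):
    return pp.make_species_pool(ref_fixture.bpm, pool_size=60, seed=11)


@pytest.fixture(scope="session")
def dataset(ref_fixture, pool):
    """Five truncated-and-collapsed mock communities."""
    return pp.generate_mock_dataset(ref_fixture, pool, 5, seed=7, truncate=True)


@pytest.fixture(scope="session")
def dataset_true(ref_fixture, pool):
    """Five full-length (no collapse) mock communities."""
    return pp.generate_mock_dataset(ref_fixture, pool, 5, seed=7, truncate=False)


@pytest.fixture(scope="session")
def hits(ref_fixture, dataset):
    """All-vs-reference identity hits for the collapsed dataset."""
    return pp.search_reference(dataset.table.sequences, ref_fixture.sequences)


def nj_newick(sequences):
    """Neighbour-joining tree over sequences from identity distances.

    Test-only helper (trees are inputs to the pipeline proper);
    negative NJ branch lengths are clamped to zero.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    from phenoprof.assign import align_identity

    ids = list(sequences)
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - align_identity(sequences[ids[i]], sequences[ids[j]])
            mat[i, j] = mat[j, i] = d
    tree = nj(DistanceMatrix(mat, ids))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return str(tree)


def random_taxonomy(rng, depth=7):
    labels = [f"r{d}_{rng.integers(0, 3)}" for d in range(depth)]
    return pp.Taxonomy(tuple(labels) + ("",) * (7 - depth))
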