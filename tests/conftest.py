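import numpy as np
import pytest

from plexus import (
    BipartiteLinks,
    BuildConfig,
    Layer,
    RWRConfig,
    SyntheticConfig,
    assemble,
    build_from_bundle,
    generate_multiome,
)


def random_multilayer(rng: np.random.Generator):
    """A random small HMLN: 2-4 layers in a chain, random weights/direction."""
    n_layers = int(rng.integers(2, 5))
    layers = []
    for li in range(n_layers):
        n = int(rng.integers(3, 20))
        nodes = [f"n{li}_{i}" for i in range(n)]
        directed = bool(rng.random() < 0.3)
        n_edges = int(rng.integers(0, 3 * n))
        edges = []
        for _ in range(n_edges):
            a, b = rng.choice(n, size=2, replace=True)
            edges.append((nodes[a], nodes[b], float(rng.uniform(0.1, 2.0))))
        layers.append(Layer(f"L{li}", nodes, edges, directed=directed))
    bps = []
    for li in range(n_layers - 1):
        a_nodes, b_nodes = layers[li].nodes, layers[li + 1].nodes
        n_links = int(rng.integers(1, 2 * min(len(a_nodes), len(b_nodes)) + 1))
        edges = [
            (
                a_nodes[rng.integers(len(a_nodes))],
                b_nodes[rng.integers(len(b_nodes))],
                float(rng.uniform(0.1, 2.0)),
            )
            for _ in range(n_links)
        ]
        bps.append(BipartiteLinks(f"L{li}", f"L{li + 1}", edges))
    return assemble(layers, bps)


def random_seeds(m, rng: np.random.Generator):
    ids = m.global_ids()
    k = int(rng.integers(1, 4))
    picks = rng.choice(len(ids), size=k, replace=False)
    return {ids[i]: float(rng.uniform(0.5, 2.0)) for i in picks}


SMALL_CONFIG = SyntheticConfig(
    n_tfs=4,
    n_peaks=40,
    n_genes=24,
    n_regions_methyl=10,
    n_cells_rna=120,
    n_cells_atac=100,
    n_cells_methyl=80,
    genes_per_tf=6,
    peaks_per_tf=3,
    chrom_count=2,
    seed=0,
)


@pytest.fixture(scope="session")
def small_bundle():
    return generate_multiome(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_multilayer(small_bundle):
    return build_from_bundle(small_bundle)


@pytest.fixture(scope="session")
def default_bundle():
    """The standard benchmark bundle: 20 TFs, 500 peaks, 200 genes, seed 0."""
    return generate_multiome(SyntheticConfig())


@pytest.fixture(scope="session")
def default_multilayer(default_bundle):
    return build_from_bundle(default_bundle)


@pytest.fixture(scope="session")
def walk_config():
    return RWRConfig()
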