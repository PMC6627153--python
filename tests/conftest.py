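import pytest

import comorbnet as cn


@pytest.fixture(scope="session")
def default_dataset():
    """One draw from the default synthetic study conditions."""
    return cn.generate(cn.SyntheticSpec(rng_seed=1))


@pytest.fixture(scope="session")
def default_network(default_dataset):
    graph, report = cn.build_network(default_dataset.interactions)
    return graph


@pytest.fixture(scope="session")
def default_clusters(default_network):
    return cn.find_clusters(default_network)


@pytest.fixture(scope="session")
def default_annotation(default_dataset):
    return cn.DiseaseAnnotation(default_dataset.annotations)


def best_cluster(module_members, clusters):
    """(best Jaccard, best cluster) of a planted module among clusters."""
    module = set(module_members)
    best_j, best_c = 0.0, None
    for cluster in clusters:
        j = len(module & cluster.members) / len(module | cluster.members)
        if j > best_j:
            best_j, best_c = j, cluster
    return best_j, best_c
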