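import numpy as np
import pytest

import connkit as ck


@pytest.fixture(scope="session")
def study_atlas():
    """28-node packaged atlas with the default 6-node tumor exclusion."""
    return ck.exclude_nodes(ck.load_atlas(), ck.DEFAULT_EXCLUDED_NODES)


@pytest.fixture(scope="session")
def planted_cohort():
    """Default synthetic cohort: 3 x 10 subjects with planted effects."""
    return ck.generate_cohort(ck.default_config(seed=1))


@pytest.fixture(scope="session")
def null_cohort_fixture():
    return ck.null_cohort(ck.default_config(seed=2))


@pytest.fixture(scope="session")
def backbone_mask(planted_cohort):
    return ck.consistency_mask(planted_cohort)


def binary_matrix(adj, ids=None):
    """Helper: wrap a 0/1 adjacency array as a binary ConnectomeMatrix."""
    adj = np.asarray(adj, dtype=float)
    n = adj.shape[0]
    ids = ids or tuple(f"n{i}_L" for i in range(n))
    return ck.ConnectomeMatrix("test", "binary", adj, tuple(ids))


def weighted_matrix(vals, weighting="FN", ids=None):
    vals = np.asarray(vals, dtype=float)
    n = vals.shape[0]
    ids = ids or tuple(f"n{i}_L" for i in range(n))
    return ck.ConnectomeMatrix("test", weighting, vals, tuple(ids))


def path_graph(n):
    a = np.zeros((n, n))
    for i in range(n - 1):
        a[i, i + 1] = a[i + 1, i] = 1.0
    return binary_matrix(a)


def complete_graph(n):
    a = np.ones((n, n)) - np.eye(n)
    return binary_matrix(a)


def star_graph(n):
    a = np.zeros((n, n))
    a[0, 1:] = a[1:, 0] = 1.0
    return binary_matrix(a)


def ring_lattice(n=20, k=4):
    """Each node connected to its k nearest neighbours on a ring."""
    a = np.zeros((n, n))
    for i in range(n):
        for d in range(1, k // 2 + 1):
            j = (i + d) % n
            a[i, j] = a[j, i] = 1.0
    return binary_matrix(a)
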