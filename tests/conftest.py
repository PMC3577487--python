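import networkx as nx
import pytest

import rigidscan as rs


@pytest.fixture
def banana_graph():
    return rs.double_banana()


@pytest.fixture
def shared_vertex_triangles():
    return rs.two_triangles_shared_vertex()


@pytest.fixture
def small_toy_spec():
    # small enough for fast exact rank tests, dense enough for a giant
    # rigid component at cutoff 0
    return rs.ToyGenomeSpec(
        n_chromosomes=2, fragments_per_chromosome=40, seed=7
    )


@pytest.fixture
def toy_graph(small_toy_spec):
    return rs.toy_conformation_graph(small_toy_spec)


def random_graphs(count, sizes=(5, 7, 8, 9), base_seed=0):
    """Deterministic stream of G(n, p) graphs across densities."""
    densities = (0.35, 0.5, 0.65, 0.8)
    out = []
    i = 0
    while len(out) < count:
        n = sizes[i % len(sizes)]
        p = densities[(i // len(sizes)) % len(densities)]
        out.append(nx.gnp_random_graph(n, p, seed=base_seed + 1009 * i))
        i += 1
    return out


@pytest.fixture
def fragment_line():
    """Five fragments on one chromosome; measured edges reach B, C, D only via A.

    A classic augmentation example: the backbone adds B-C and C-D, which
    together with the measured B-D edge close a triangle; E is unobserved.
    """
    A, B, C, D, E = (rs.FragmentID("c1", 100 * (i + 1)) for i in range(5))
    g = rs.ConformationGraph.from_edges(
        [(A, B, 1.0), (A, C, 2.0), (A, D, 3.0), (B, D, 4.0)]
    )
    frags = rs.FragmentTable({"c1": [100, 200, 300, 400, 500]})
    return g, frags, (A, B, C, D, E)
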