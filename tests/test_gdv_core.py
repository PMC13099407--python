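import numpy as np
import networkx as nx
import pandas as pd
import pytest

from conftest import random_contact_graph
from gdvflex.contact_graph import ContactGraph, GraphParams
from gdvflex.fixtures import make_cloud_structure, make_helix_structure
from gdvflex.gdv_core import (
    count_orbits,
    count_orbits_bruteforce,
    gdv_all_at_once,
    gdv_by_parts,
    read_gdv,
    write_gdv,
)
from gdvflex.structure_io import AtomTable


def row(**orbits):
    out = np.zeros(15, dtype=np.int64)
    for k, v in orbits.items():
        out[int(k[1:])] = v
    return out


class TestBruteForceOracle:
    """Closed-form orbit counts of tiny named graphs."""

    @pytest.mark.parametrize("counter", [count_orbits_bruteforce, count_orbits])
    def test_single_edge(self, counter):
        g = ContactGraph(2, [(0, 1)])
        assert np.array_equal(counter(g), np.stack([row(O0=1), row(O0=1)]))

    @pytest.mark.parametrize("counter", [count_orbits_bruteforce, count_orbits])
    def test_triangle(self, counter):
        g = ContactGraph(3, [(0, 1), (1, 2), (0, 2)])
        expected = np.stack([row(O0=2, O3=1)] * 3)
        assert np.array_equal(counter(g), expected)

    @pytest.mark.parametrize("counter", [count_orbits_bruteforce, count_orbits])
    def test_three_path(self, counter):
        g = ContactGraph(3, [(0, 1), (1, 2)])
        got = counter(g)
        assert np.array_equal(got[0], row(O0=1, O1=1))
        assert np.array_equal(got[1], row(O0=2, O2=1))

    @pytest.mark.parametrize("counter", [count_orbits_bruteforce, count_orbits])
    def test_four_path_end_and_middle(self, counter):
        g = ContactGraph(4, [(0, 1), (1, 2), (2, 3)])
        got = counter(g)
        assert got[0, 4] == 1  # path end
        assert got[1, 5] == 1  # path middle

    @pytest.mark.parametrize("counter", [count_orbits_bruteforce, count_orbits])
    def test_three_star(self, counter):
        g = ContactGraph(4, [(0, 1), (0, 2), (0, 3)])
        got = counter(g)
        assert np.array_equal(got[0], row(O0=3, O2=3, O7=1))  # center
        assert np.array_equal(got[1], row(O0=1, O1=2, O6=1))  # leaf

    @pytest.mark.parametrize("counter", [count_orbits_bruteforce, count_orbits])
    def test_complete_four(self, counter):
        g = ContactGraph(4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)])
        expected = np.stack([row(O0=3, O3=3, O14=1)] * 4)
        assert np.array_equal(counter(g), expected)


class TestWorkedExampleNeighborhood:
    """The tailed-triangle neighborhood {I,J,H,F} with edges I-J, I-H, I-F, J-H.

    Node I touches orbit 0 three times (its three edges), orbit 2 twice
    (the non-adjacent neighbor pairs J,F and H,F) and orbit 3 once (the
    triangle I-J-H).  Under induced semantics the 4-set itself is a tailed
    triangle with I as its hub (orbit 11), not a source of extra 3-paths.
    """

    EDGES = [(0, 1), (0, 2), (0, 3), (1, 2)]  # I, J, H, F

    @pytest.mark.parametrize("counter", [count_orbits, count_orbits_bruteforce])
    def test_node_I_counts(self, counter):
        got = counter(ContactGraph(4, self.EDGES))
        assert got[0, 0] == 3
        assert got[0, 2] == 2
        assert got[0, 3] == 1
        assert np.array_equal(got[0], row(O0=3, O2=2, O3=1, O11=1))


def _identities_hold(graph, counts):
    g = nx.Graph(graph.edges.tolist())
    g.add_nodes_from(range(graph.n_nodes))
    deg = graph.degrees
    tri = np.array([nx.triangles(g, v) for v in range(graph.n_nodes)])
    assert counts[:, 0].sum() == 2 * graph.n_edges
    assert counts[:, 3].sum() == 3 * (sum(nx.triangles(g).values()) // 3)
    assert np.array_equal(counts[:, 2] + counts[:, 3], deg * (deg - 1) // 2)
    nbr_deg = np.array([sum(deg[u] - 1 for u in graph.neighbors(v)) for v in range(graph.n_nodes)])
    assert np.array_equal(counts[:, 1] + 2 * counts[:, 3], nbr_deg)
    assert np.array_equal(counts[:, 3], tri)


class TestFastCounter:
    @pytest.mark.parametrize("p", [0.1, 0.3, 0.5])
    @pytest.mark.parametrize("n", [5, 17, 30])
    def test_matches_bruteforce_on_random_graphs(self, n, p):
        for s in range(3):
            g = random_contact_graph(n, p, seed=9000 + 100 * n + s)
            assert np.array_equal(count_orbits(g), count_orbits_bruteforce(g))

    def test_combinatorial_identities(self):
        for n, p, s in [(25, 0.2, 1), (40, 0.4, 2), (60, 0.1, 3)]:
            g = random_contact_graph(n, p, seed=s)
            _identities_hold(g, count_orbits(g))

    def test_permutation_equivariance(self, rng):
        g = random_contact_graph(24, 0.3, seed=5)
        perm = rng.permutation(g.n_nodes)
        permuted = ContactGraph(
            g.n_nodes, np.column_stack([perm[g.edges[:, 0]], perm[g.edges[:, 1]]])
        )
        assert np.array_equal(count_orbits(permuted)[perm], count_orbits(g))

    def test_empty_and_isolated(self):
        assert count_orbits(ContactGraph(0, [])).shape == (0, 15)
        g = ContactGraph(4, [(0, 1)])  # nodes 2, 3 isolated
        counts = count_orbits(g)
        assert np.array_equal(counts[2], np.zeros(15, dtype=np.int64))
        assert np.array_equal(counts[3], np.zeros(15, dtype=np.int64))


class TestStructurePipelines:
    def test_collinear_triplet(self):
        df = pd.DataFrame(
            {
                "serial": [1, 2, 3],
                "atom_name": "CA",
                "alt_loc": "",
                "res_name": "ALA",
                "chain_id": "A",
                "res_seq": [1, 2, 3],
                "insertion_code": "",
                "x": [0.0, 4.0, 8.0],  # 4 Å spacing: ends are 8 Å apart, no edge
                "y": 0.0,
                "z": 0.0,
                "occupancy": 1.0,
                "b_value": 0.0,
                "element": "C",
                "record": "ATOM",
            }
        )
        counts = gdv_all_at_once(AtomTable(df))
        assert np.array_equal(counts[1], row(O0=2, O2=1))

    def test_identities_on_helix(self, helix60):
        from gdvflex.contact_graph import build_contact_graph

        _identities_hold(build_contact_graph(helix60), gdv_all_at_once(helix60))

    def test_single_chunk_equals_all_at_once(self, cloud40):
        assert np.array_equal(
            gdv_by_parts(cloud40, chunk_size=10_000, surround_radius=15.0),
            gdv_all_at_once(cloud40),
        )

    def test_by_parts_exact_at_three_hop_radius(self):
        atoms = make_helix_structure(220, seed=5)
        assert np.array_equal(
            gdv_by_parts(atoms, chunk_size=50, surround_radius=21.0),
            gdv_all_at_once(atoms),
        )

    def test_independent_clusters(self):
        a = make_cloud_structure(10, seed=1)
        b = make_cloud_structure(10, seed=2)
        sep = b.coords + np.array([70.0, 0.0, 0.0])
        df = pd.concat(
            [a.df, b.df.assign(x=sep[:, 0], y=sep[:, 1], z=sep[:, 2], res_seq=b.df.res_seq + 10)]
        )
        both = AtomTable(df)
        combined = gdv_by_parts(both, chunk_size=10, surround_radius=15.0)
        expected = np.vstack(
            [gdv_all_at_once(a), gdv_all_at_once(AtomTable(b.df.assign(
                x=sep[:, 0], y=sep[:, 1], z=sep[:, 2])))]
        )
        assert np.array_equal(combined, expected)

    def test_gdv_tsv_round_trip(self, tmp_path, cloud40):
        gdv = gdv_all_at_once(cloud40)
        path = tmp_path / "gdv.tsv"
        write_gdv(gdv, path)
        assert path.read_text().splitlines()[0].split("\t") == [f"O{k}" for k in range(15)]
        assert np.array_equal(read_gdv(path), gdv)
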