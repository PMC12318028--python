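"""Hydrogen-bond network graph statistics vs exhaustive oracles."""

import math
from collections import Counter

import networkx as nx
import numpy as np
import pytest

from solvnet.io import config_from_molecules, make_fixture
from solvnet.model import minimum_image, water_template
from solvnet.topology import (
    LinkageCriteria,
    build_graph,
    chain_census,
    cluster_census,
    ring_census,
    topology_report,
    triplet_angles,
)


def sp_ring_oracle(graph, max_size=12):
    """Exhaustive cycle enumeration (networkx) + shortest-path filter."""
    census = Counter()
    spl = dict(nx.all_pairs_shortest_path_length(graph))
    for cycle in nx.simple_cycles(graph, length_bound=max_size):
        n = len(cycle)
        if n < 3:
            continue
        ok = True
        for i in range(n):
            for j in range(i + 1, n):
                around = min(j - i, n - (j - i))
                if spl[cycle[i]][cycle[j]] < around:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            census[n] += 1
    return census


def chain_oracle(graph):
    """Brute-force path enumeration: maximal degree-2-interior simple
    paths that are shortest paths between their endpoints."""
    census = Counter()
    deg = dict(graph.degree)
    nodes = sorted(graph.nodes)
    for i, u in enumerate(nodes):
        if deg[u] == 2:
            continue
        for v in nodes[i:]:
            if deg[v] == 2 or (u == v):
                continue
            for path in nx.all_simple_paths(graph, u, v):
                if all(deg[w] == 2 for w in path[1:-1]) and \
                        nx.shortest_path_length(graph, u, v) == len(path) - 1:
                    census[len(path)] += 1
    # each unordered path counted once by the u <= v scan; u == v excluded
    return census


class TestBuildGraph:
    def test_linear_dimer_is_linked(self):
        cfg = make_fixture("dimer", o_o=2.8)
        g = build_graph(cfg)
        assert set(g.edges) == {(0, 1)}

    def test_large_donor_angle_breaks_link(self):
        # rotate the donor so its best O-H deviates ~45 degrees from O-O
        tpl = water_template()
        ang = np.radians(45.0)
        donor = np.array([
            [0.0, 0.0, 0.0],
            [np.cos(ang), np.sin(ang), 0.0],
            [np.cos(ang + np.radians(109.47)),
             np.sin(ang + np.radians(109.47)), 0.0],
        ])
        half = np.radians(109.47) / 2
        acceptor = np.array([
            [2.8, 0.0, 0.0],
            [2.8 + np.cos(half), np.sin(half), 0.0],
            [2.8 + np.cos(half), -np.sin(half), 0.0],
        ])
        cfg = config_from_molecules(
            30.0, [(tpl, donor + 10.0), (tpl, acceptor + 10.0)])
        assert build_graph(cfg).number_of_edges() == 0
        relaxed = LinkageCriteria(angle_cutoff=50.0)
        assert build_graph(cfg, relaxed).number_of_edges() == 1

    def test_edges_subset_of_distance_graph(self, mixture_frames):
        frame = mixture_frames[0]
        g = build_graph(frame)
        ow = frame.sites_of_label("O_W")
        pos = frame.positions[ow]
        d = np.linalg.norm(minimum_image(
            pos[None] - pos[:, None], frame.box_length), axis=-1)
        mols = [int(frame.mol_index[i]) for i in ow]
        for a, b in g.edges:
            ia, ib = mols.index(a), mols.index(b)
            assert d[ia, ib] <= 3.3

    def test_edge_set_matches_brute_force(self, mixture_frames):
        """Edges equal an independent all-pairs scan with explicit
        vector geometry."""
        frame = mixture_frames[1]
        criteria = LinkageCriteria()
        g = build_graph(frame, criteria)
        ow = frame.sites_of_label("O_W")
        pos, box = frame.positions, frame.box_length
        expected = set()
        for x in range(len(ow)):
            for y in range(x + 1, len(ow)):
                sa, sb = int(ow[x]), int(ow[y])
                axis = minimum_image(pos[sb] - pos[sa], box)
                r = np.linalg.norm(axis)
                if r > criteria.oo_cutoff:
                    continue
                best = 180.0
                for donor, acc in ((sa, sb), (sb, sa)):
                    dmol = int(frame.mol_index[donor])
                    sl = frame.mol_slice(dmol)
                    for s in range(sl.start, sl.stop):
                        if not str(frame.labels[s]).startswith("H"):
                            continue
                        v = minimum_image(pos[s] - pos[donor], box)
                        u = minimum_image(pos[acc] - pos[donor], box)
                        cos = v @ u / np.linalg.norm(v) / np.linalg.norm(u)
                        best = min(best,
                                   math.degrees(math.acos(np.clip(cos, -1, 1))))
                if best <= criteria.angle_cutoff:
                    expected.add(frozenset((int(frame.mol_index[sa]),
                                            int(frame.mol_index[sb]))))
        assert {frozenset(e) for e in g.edges} == expected


class TestTripletAngles:
    def test_tetrahedral_cluster_all_at_109(self):
        cfg = make_fixture("tetrahedral_cluster")
        bins, counts = triplet_angles(cfg)
        occupied = bins[counts > 0]
        assert np.all(np.abs(occupied - 109.47) < 1.0)
        assert counts.sum() == 6  # 4 choose 2 pairs at the centre

    def test_equilateral_triplet_all_at_60(self):
        cfg = make_fixture("equilateral_triplet", side=3.0)
        bins, counts = triplet_angles(cfg)
        assert counts.sum() == 3
        assert np.all(np.abs(bins[counts > 0] - 60.0) < 1.0)

    def test_matches_cubed_brute_force(self, mixture_frames):
        frame = mixture_frames[0]
        bins, counts = triplet_angles(frame, oo_cutoff=3.3)
        ow = frame.sites_of_label("O_W")
        pos, box = frame.positions, frame.box_length
        oracle = np.zeros_like(counts)
        edges = np.arange(0.0, 181.0, 1.0)
        for c in range(len(ow)):
            for a in range(len(ow)):
                for b in range(a + 1, len(ow)):
                    if c in (a, b):
                        continue
                    va = minimum_image(pos[ow[a]] - pos[ow[c]], box)
                    vb = minimum_image(pos[ow[b]] - pos[ow[c]], box)
                    ra, rb = np.linalg.norm(va), np.linalg.norm(vb)
                    if ra > 3.3 or rb > 3.3:
                        continue
                    cos = np.clip(va @ vb / (ra * rb), -1, 1)
                    ang = math.degrees(math.acos(cos))
                    oracle[min(int(ang), 179)] += 1
        np.testing.assert_array_equal(counts, oracle)

    def test_ice_fragment_is_tetrahedral(self):
        cfg = make_fixture("ice_lattice_fragment")
        bins, counts = triplet_angles(cfg)
        near_tet = np.abs(bins - 109.47) <= 5.0
        assert counts[near_tet].sum() / counts.sum() > 0.99

    def test_ideal_gas_follows_sine_null(self):
        """On uniformly random points the centre angle distribution is
        the sin(theta)/2 null; chi-square should not reject it."""
        from solvnet.model import MoleculeTemplate, Site
        point_o = MoleculeTemplate(
            "point_oxygen", (Site("O_W", "O", (0, 0, 0), 0.0, 0.0, 0.0),))
        tot_bins, tot_counts = None, np.zeros(180)
        for s in range(6):
            rng = np.random.default_rng(100 + s)
            box = 14.0
            cfg = config_from_molecules(box, [
                (point_o, rng.uniform(0, box, size=3)) for _ in range(220)])
            b, c = triplet_angles(cfg, oo_cutoff=4.5)
            tot_bins, tot_counts = b, tot_counts + c
        n = tot_counts.sum()
        theta = np.radians(tot_bins)
        p = np.sin(theta)
        p /= p.sum()
        sel = n * p > 15
        chi2 = np.sum((tot_counts[sel] - n * p[sel]) ** 2 / (n * p[sel]))
        dof = int(sel.sum())
        assert chi2 < dof + 5.0 * math.sqrt(2.0 * dof)


class TestRingCensus:
    def test_ice_fragment_rings_are_hexagons(self):
        cfg = make_fixture("ice_lattice_fragment")
        census = ring_census(build_graph(cfg))
        assert set(census) == {6}
        assert census[6] > 0

    def test_chorded_square_gives_two_triangles(self):
        g = nx.Graph([(0, 1), (1, 2), (2, 3), (3, 0), (0, 2)])
        assert dict(ring_census(g)) == {3: 2}

    def test_max_size_validated(self):
        with pytest.raises(ValueError):
            ring_census(nx.cycle_graph(5), max_size=2)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_exhaustive_oracle_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 21))
        g = nx.gnp_random_graph(n, 2.5 / n, seed=seed)
        assert ring_census(g, max_size=12) == sp_ring_oracle(g, 12)


class TestChainCensus:
    def test_path_graph_is_one_chain(self):
        assert dict(chain_census(nx.path_graph(5))) == {5: 1}

    def test_star_graph_chains(self):
        assert dict(chain_census(nx.star_graph(3))) == {2: 3}

    def test_pure_cycle_has_no_chains(self):
        assert dict(chain_census(nx.cycle_graph(6))) == {}

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_path_enumeration_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(4, 21))
        g = nx.gnp_random_graph(n, 1.8 / n, seed=2000 + seed)
        assert chain_census(g) == chain_oracle(g)


class TestClusterCensus:
    def test_isolated_molecules_are_singletons(self):
        cfg = make_fixture("equilateral_triplet", side=5.0)
        assert dict(cluster_census(cfg)) == {1: 3}

    def test_connected_fixture_single_cluster(self):
        cfg = make_fixture("ice_lattice_fragment")
        census = cluster_census(cfg)
        assert census == Counter({64: 1})

    def test_matches_networkx_components(self, mixture_frames):
        frame = mixture_frames[0]
        census = cluster_census(frame, 3.3)
        ow = frame.sites_of_label("O_W")
        pos = frame.positions[ow]
        d = np.linalg.norm(minimum_image(
            pos[None] - pos[:, None], frame.box_length), axis=-1)
        g = nx.Graph()
        g.add_nodes_from(range(len(ow)))
        ii, jj = np.nonzero(np.triu(d <= 3.3, k=1))
        g.add_edges_from(zip(ii.tolist(), jj.tolist()))
        oracle = Counter(len(c) for c in nx.connected_components(g))
        assert census == oracle

    def test_sizes_sum_to_molecule_count(self, mixture_frames):
        for frame in mixture_frames[:3]:
            census = cluster_census(frame)
            n_water = len(frame.sites_of_label("O_W"))
            assert sum(size * cnt for size, cnt in census.items()) == n_water


class TestMixedSpecies:
    def test_ammonia_forms_no_network(self, mixture_frames):
        """Ammonia-ammonia linkages are rare and never percolate, in
        contrast to the water network."""
        ammonia_links = water_links = 0
        for f in mixture_frames:
            ga = build_graph(f, species="ammonia")
            gw = build_graph(f, species="water")
            ammonia_links += ga.number_of_edges()
            water_links += gw.number_of_edges()
            biggest = max((len(c) for c in nx.connected_components(ga)),
                          default=0)
            assert biggest <= 4  # no extended ammonia clusters
        per_ammonia = ammonia_links / (len(mixture_frames) * 18)
        per_water = water_links / (len(mixture_frames) * 66)
        assert per_ammonia < 0.25 * per_water

    def test_report_bundles_all_statistics(self, mixture_frames):
        rep = topology_report(mixture_frames[0])
        assert rep.n_molecules == 66
        assert sum(s * c for s, c in rep.clusters.items()) == 66
        assert all(size >= 3 for size in rep.rings)
        assert all(length >= 2 for length in rep.chains)
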