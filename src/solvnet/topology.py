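"""Hydrogen-bond network topology: triplet angles, shortest-path rings,
linear chains and distance clusters of the water network.

A hydrogen-bonded linkage between two waters requires O_W-O_W <= 3.3 A
and an included angle <= 30 degrees, where the included angle is (by
default) the donor deviation: the angle at the donor oxygen between the
O->H bond vector and the O->O axis, minimised over the four candidate
hydrogens of the pair.  Rings are Franzblau shortest-path rings; chains
are maximal degree-2 paths that are themselves shortest paths between
their endpoints; clusters use the looser distance-only criterion.
Ammonia molecules are excluded from the water-network statistics (a
mixed-species graph is available via ``species`` for checking that
ammonia itself forms no network).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .model import Configuration, minimum_image

__all__ = [
    "LinkageCriteria",
    "TopologyReport",
    "build_graph",
    "triplet_angles",
    "ring_census",
    "chain_census",
    "cluster_census",
    "topology_report",
]


@dataclass(frozen=True)
class LinkageCriteria:
    oo_cutoff: float = 3.3        # A
    angle_cutoff: float = 30.0    # degrees
    angle_convention: str = "donor-deviation"  # or "h-o-o-at-acceptor"


def _heavy_sites(config: Configuration, species: str) -> np.ndarray:
    if species == "water":
        return config.sites_of_label("O_W")
    if species == "ammonia":
        return config.sites_of_label("N_A")
    raise ValueError(f"unknown species {species!r}")


def _hydrogens_of(config: Configuration, mol: int) -> np.ndarray:
    sl = config.mol_slice(mol)
    idx = np.arange(sl.start, sl.stop)
    return idx[np.char.startswith(config.labels[sl].astype(str), "H")]


def build_graph(
    config: Configuration,
    criteria: LinkageCriteria | None = None,
    species: str = "water",
) -> nx.Graph:
    """Hydrogen-bond graph: nodes are molecule ids of ``species``, edges
    the pairs meeting the distance-plus-angle linkage criterion."""
    criteria = criteria or LinkageCriteria()
    heavy = _heavy_sites(config, species)
    graph = nx.Graph()
    mols = [int(config.mol_index[i]) for i in heavy]
    graph.add_nodes_from(mols)
    if len(heavy) < 2:
        return graph
    pos = config.positions
    box = config.box_length
    d = minimum_image(pos[heavy][None, :, :] - pos[heavy][:, None, :], box)
    dist = np.linalg.norm(d, axis=-1)
    ii, jj = np.nonzero(np.triu(dist <= criteria.oo_cutoff, k=1))
    cos_max = np.cos(np.radians(criteria.angle_cutoff))
    for a, b in zip(ii, jj):
        sa, sb = int(heavy[a]), int(heavy[b])
        ma, mb = mols[a], mols[b]
        if _linked(config, sa, sb, ma, mb, criteria, cos_max):
            graph.add_edge(ma, mb)
    return graph


def _linked(config, site_a, site_b, mol_a, mol_b, criteria, cos_max) -> bool:
    """Angle test, trying both molecules of the pair as donor."""
    pos, box = config.positions, config.box_length
    for donor_site, donor_mol, acc_site in (
            (site_a, mol_a, site_b), (site_b, mol_b, site_a)):
        axis = minimum_image(pos[acc_site] - pos[donor_site], box)
        axis = axis / np.linalg.norm(axis)
        for h in _hydrogens_of(config, donor_mol):
            if criteria.angle_convention == "donor-deviation":
                v = minimum_image(pos[h] - pos[donor_site], box)
            elif criteria.angle_convention == "h-o-o-at-acceptor":
                v = minimum_image(pos[h] - pos[acc_site], box)
            else:
                raise ValueError(
                    f"unknown angle convention {criteria.angle_convention!r}")
            cos = float(v @ axis) / np.linalg.norm(v)
            if criteria.angle_convention == "h-o-o-at-acceptor":
                cos = -cos  # measured back along the acceptor->donor axis
            if cos >= cos_max:
                return True
    return False


def triplet_angles(
    config: Configuration,
    oo_cutoff: float = 3.3,
    species: str = "water",
    bin_width: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of the included angle at the centre of heavy-atom
    triplets (e.g. O_W-O_W-O_W) whose two arms are within ``oo_cutoff``.

    Each unordered neighbour pair contributes one angle per centre.
    Returns (bin_centres_degrees, counts).
    """
    heavy = _heavy_sites(config, species)
    edges = np.arange(0.0, 180.0 + bin_width, bin_width)
    counts = np.zeros(len(edges) - 1)
    if len(heavy) < 3:
        return 0.5 * (edges[1:] + edges[:-1]), counts
    pos, box = config.positions, config.box_length
    d = minimum_image(pos[heavy][None, :, :] - pos[heavy][:, None, :], box)
    dist = np.linalg.norm(d, axis=-1)
    np.fill_diagonal(dist, np.inf)
    for c in range(len(heavy)):
        nbr = np.nonzero(dist[c] <= oo_cutoff)[0]
        if len(nbr) < 2:
            continue
        vecs = d[c, nbr]          # centre -> neighbour
        norms = np.linalg.norm(vecs, axis=1)
        unit = vecs / norms[:, None]
        cos = np.clip(unit @ unit.T, -1.0, 1.0)
        iu = np.triu_indices(len(nbr), k=1)
        ang = np.degrees(np.arccos(cos[iu]))
        counts += np.histogram(ang, bins=edges)[0]
    return 0.5 * (edges[1:] + edges[:-1]), counts


def _bounded_cycles(graph: nx.Graph, max_size: int):
    """All simple cycles of length 3..max_size, each reported once, as
    frozensets of nodes with a canonical node tuple.

    DFS enumeration anchored at each cycle's smallest node; orientation
    de-duplicated by requiring the second node to be smaller than the
    last.
    """
    order = {v: k for k, v in enumerate(sorted(graph.nodes))}
    adj = {v: sorted(graph.neighbors(v), key=order.get)
           for v in graph.nodes}
    for root in sorted(graph.nodes, key=order.get):
        stack = [(root, [root])]
        while stack:
            node, path = stack.pop()
            for nxt in adj[node]:
                if order[nxt] < order[root]:
                    continue
                if nxt == root and len(path) >= 3:
                    if order[path[1]] < order[path[-1]]:
                        yield tuple(path)
                elif nxt not in path and len(path) < max_size:
                    stack.append((nxt, path + [nxt]))


def _is_sp_ring(cycle: tuple, spl: dict) -> bool:
    """Franzblau shortest-path criterion: for every pair of members the
    distance around the cycle equals the graph distance."""
    n = len(cycle)
    for i in range(n):
        for j in range(i + 1, n):
            around = min(j - i, n - (j - i))
            if spl[cycle[i]][cycle[j]] < around:
                return False
    return True


def ring_census(graph: nx.Graph, max_size: int = 12) -> Counter:
    """Counts of shortest-path (Franzblau SP) rings by size.

    An SP ring is a cycle in which no two member nodes are joined by a
    strictly shorter path through the rest of the graph.
    """
    if max_size < 3:
        raise ValueError("max_size must be >= 3")
    spl = dict(nx.all_pairs_shortest_path_length(graph))
    census: Counter = Counter()
    for cycle in _bounded_cycles(graph, max_size):
        if _is_sp_ring(cycle, spl):
            census[len(cycle)] += 1
    return census


def chain_census(graph: nx.Graph) -> Counter:
    """Counts of linear chains by length (molecule count >= 2).

    A chain is a maximal simple path whose internal nodes all have
    degree 2 in the graph, and which is itself a shortest path between
    its endpoints.  Pure cycles (every node degree 2) are not chains.
    Traversal order is lexicographic for deterministic output.
    """
    census: Counter = Counter()
    seen_edges: set[frozenset] = set()
    deg = dict(graph.degree)
    for start in sorted(graph.nodes):
        if deg[start] == 2:
            continue  # chains start at degree-1 or branching nodes
        for nbr in sorted(graph.neighbors(start)):
            edge = frozenset((start, nbr))
            if edge in seen_edges:
                continue
            path = [start, nbr]
            seen_edges.add(edge)
            while deg[path[-1]] == 2:
                nxts = [v for v in graph.neighbors(path[-1])
                        if v != path[-2]]
                nxt = nxts[0]
                seen_edges.add(frozenset((path[-1], nxt)))
                if nxt in path:
                    break  # ran into a cycle; not a chain
                path.append(nxt)
            else:
                if nx.shortest_path_length(
                        graph, path[0], path[-1]) == len(path) - 1:
                    census[len(path)] += 1
    return census


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def cluster_census(
    config: Configuration,
    oo_cutoff: float = 3.3,
    species: str = "water",
) -> Counter:
    """Counts of distance clusters by size: connected components of the
    heavy-atom graph with the distance-only criterion (no angle test)."""
    heavy = _heavy_sites(config, species)
    n = len(heavy)
    census: Counter = Counter()
    if n == 0:
        return census
    pos, box = config.positions, config.box_length
    d = minimum_image(pos[heavy][None, :, :] - pos[heavy][:, None, :], box)
    dist = np.linalg.norm(d, axis=-1)
    uf = _UnionFind(n)
    ii, jj = np.nonzero(np.triu(dist <= oo_cutoff, k=1))
    for a, b in zip(ii, jj):
        uf.union(int(a), int(b))
    sizes = Counter(uf.find(k) for k in range(n))
    for size in sizes.values():
        census[size] += 1
    return census


@dataclass
class TopologyReport:
    rings: Counter
    chains: Counter
    clusters: Counter
    angle_bins: np.ndarray
    angle_counts: np.ndarray
    n_molecules: int


def topology_report(
    config: Configuration,
    criteria: LinkageCriteria | None = None,
    max_ring: int = 12,
    species: str = "water",
) -> TopologyReport:
    """All four network statistics of one frame in a single report."""
    criteria = criteria or LinkageCriteria()
    graph = build_graph(config, criteria, species)
    bins, counts = triplet_angles(config, criteria.oo_cutoff, species)
    return TopologyReport(
        rings=ring_census(graph, max_ring),
        chains=chain_census(graph),
        clusters=cluster_census(config, criteria.oo_cutoff, species),
        angle_bins=bins,
        angle_counts=counts,
        n_molecules=graph.number_of_nodes(),
    )
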